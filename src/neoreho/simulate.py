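"""Synthetic data generators for exercising the full pipeline offline.

Local BOLD synchrony is emulated by spatial Gaussian filtering of white
noise: smoothing FWHM is the single synchrony dial, monotone in expected
ReHo and analytically anchored at the independence limit (E[W] = 1/m for an
unsmoothed field). Group effects and maturational trends are implanted
either as extra smoothing inside chosen atlas regions (full BOLD route) or
as additive shifts of the Fisher-z maps (direct z-map route used for
statistical calibration, where thousands of cohorts are needed).

All generators are pure functions of (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .reho import reho_map
from .volume_io import BoldSeries, BrainMask, LabelAtlas

__all__ = [
    "SimulationConfig",
    "CohortSim",
    "generate_atlas",
    "simulate_bold",
    "simulate_motion_params",
    "sample_participants",
    "simulate_cohort",
    "simulate_zmap_cohort",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: cohort structure emulated by default: 18 vs 18 neonates, 13 male / 5
#: female per group, scanned between ~39 and ~45 weeks postmenstrual age
DEFAULT_N_PER_GROUP = 18
DEFAULT_N_MALE = 13
DEFAULT_PMA_RANGE = (39.3, 44.9)


@dataclass
class SimulationConfig:
    """Parameters of a synthetic resting-state cohort.

    Smoothing values are FWHM in voxels. ``group_effect_fwhm`` adds
    smoothing inside the listed regions for R+ participants only;
    ``age_slope_fwhm`` maps group -> FWHM change per week of PMA applied
    inside ``age_effect_rois``. The default grid (24^3, 200 volumes) keeps
    a full cohort simulation to minutes on one CPU; ``acquisition_scale()``
    gives the full-scale preset (1600 analysed volumes at TR 0.392 s,
    2.15 mm voxels).
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    n_volumes: int = 200
    repetition_time: float = 0.392
    voxel_size_mm: float = 2.15
    baseline_fwhm: float = 1.0
    group_effect_rois: tuple[int, ...] = ()
    group_effect_fwhm: float = 0.0
    age_effect_rois: tuple[int, ...] = ()
    age_slope_fwhm: dict = field(default_factory=lambda: {"R+": 0.0, "R-": 0.0})
    n_per_group: int = DEFAULT_N_PER_GROUP
    n_male_per_group: int = DEFAULT_N_MALE
    pma_range: tuple[float, float] = DEFAULT_PMA_RANGE
    ar1: float = 0.0
    n_rois: int = 16
    n_control: int = 1
    motion_spike_rate: float = 0.01
    neighborhood: int = 26
    mode: str = "literal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if any(s < 8 for s in self.shape):
            raise ValueError("all grid dimensions must be >= 8")
        if self.n_volumes < 50:
            raise ValueError("n_volumes must be >= 50")
        if self.pma_range[1] <= self.pma_range[0]:
            raise ValueError("PMA range must be nondegenerate")
        if not 0 <= self.ar1 < 1:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        if self.baseline_fwhm < 0:
            raise ValueError("baseline FWHM must be non-negative")
        if self.n_male_per_group > self.n_per_group:
            raise ValueError("n_male_per_group cannot exceed n_per_group")

    @classmethod
    def acquisition_scale(cls, **overrides) -> "SimulationConfig":
        """Acquisition-scale preset: 1600 analysed volumes, 2.15 mm grid."""
        kw = dict(shape=(48, 48, 48), n_volumes=1600)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class CohortSim:
    """A fully simulated cohort ready for group analysis."""

    participants: pd.DataFrame
    z4d: np.ndarray
    atlas: LabelAtlas
    mask: BrainMask
    motion_params: list[np.ndarray]
    config: SimulationConfig


def _ellipsoid_mask(shape) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    center = (np.asarray(shape) - 1) / 2.0
    semi = 0.45 * np.asarray(shape)
    d2 = sum(((grids[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def generate_atlas(
    shape=(24, 24, 24),
    n_rois: int = 16,
    n_control: int = 1,
    seed: int | None = None,
    roi_radius: float = 2.0,
    max_attempts: int = 50000,
) -> tuple[LabelAtlas, BrainMask]:
    """Pack disjoint spherical blob ROIs inside an ellipsoidal brain mask.

    Labels 1..n_rois are analysis regions; the last ``n_control`` labels are
    flagged as control regions. Deterministic given the seed.
    """
    if seed is None:
        raise ValueError("a seed is mandatory")
    total = n_rois + n_control
    if total < 1:
        raise ValueError("need at least one region")
    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(shape)
    # centers sit deep enough that blobs stay (mostly) inside the mask;
    # blob voxels are additionally clipped to the mask below
    interior = ndimage.binary_erosion(mask, iterations=max(1, int(np.ceil(roi_radius))))
    candidates = np.argwhere(interior)
    if candidates.shape[0] == 0:
        raise ValueError("infeasible packing: mask interior too small for the blob radius")
    centers: list[np.ndarray] = []
    # center distance > 2r guarantees disjoint spheres
    min_sep2 = (2 * roi_radius) ** 2 + 1
    attempts = 0
    while len(centers) < total:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"infeasible packing: placed {len(centers)}/{total} regions "
                f"of radius {roi_radius} in shape {shape}"
            )
        cand = candidates[rng.integers(candidates.shape[0])]
        if all(((cand - c) ** 2).sum() >= min_sep2 for c in centers):
            centers.append(cand)
    atlas_data = np.zeros(shape, dtype=np.int32)
    grids = np.indices(shape).astype(float)
    for label, c in enumerate(centers, start=1):
        d2 = sum((grids[i] - c[i]) ** 2 for i in range(3))
        atlas_data[(d2 <= roi_radius**2) & mask] = label
    labels = {i: f"roi_{i:02d}" for i in range(1, n_rois + 1)}
    labels.update({n_rois + j: f"control_{j:02d}" for j in range(1, n_control + 1)})
    control = frozenset(range(n_rois + 1, total + 1))
    return LabelAtlas(atlas_data, labels=labels, control_labels=control), BrainMask(mask)


def _fwhm_map(config: SimulationConfig, atlas: LabelAtlas, group: str, pma: float) -> np.ndarray:
    pma_mid = 0.5 * (config.pma_range[0] + config.pma_range[1])
    fwhm = np.full(config.shape, config.baseline_fwhm, dtype=np.float64)
    for label in config.group_effect_rois:
        if group == "R+":
            fwhm[atlas.data == label] += config.group_effect_fwhm
    slope = config.age_slope_fwhm.get(group, 0.0)
    for label in config.age_effect_rois:
        fwhm[atlas.data == label] += slope * (pma - pma_mid)
    if (fwhm < 0).any():
        raise ValueError("negative effective smoothing FWHM; reduce slopes or effects")
    return fwhm


def simulate_bold(
    config: SimulationConfig,
    atlas: LabelAtlas,
    group: str,
    pma: float,
    rng: np.random.Generator,
) -> BoldSeries:
    """One participant's 4D series: (optionally AR(1)-filtered) white noise
    spatially smoothed with a per-region FWHM."""
    noise = rng.standard_normal((*config.shape, config.n_volumes))
    if config.ar1 > 0:
        rho = config.ar1
        noise = signal.lfilter([np.sqrt(1 - rho**2)], [1.0, -rho], noise, axis=3)
    fwhm = _fwhm_map(config, atlas, group, pma)
    out = np.empty_like(noise)
    for value in np.unique(fwhm):
        sel = fwhm == value
        if value == 0:
            out[sel] = noise[sel]
        else:
            sigma = value * _FWHM_TO_SIGMA
            smoothed = ndimage.gaussian_filter(noise, sigma=(sigma, sigma, sigma, 0.0))
            out[sel] = smoothed[sel]
    vs = config.voxel_size_mm
    return BoldSeries(out, voxel_size=(vs, vs, vs), repetition_time=config.repetition_time)


def simulate_motion_params(
    n_volumes: int,
    rng: np.random.Generator,
    spike_rate: float = 0.01,
    spike_magnitude_mm: float = 0.8,
    drift_sd_mm: float = 0.01,
    drift_sd_rad: float = 1e-4,
) -> np.ndarray:
    """Random-walk rigid-body parameters with occasional displacement spikes."""
    steps = np.column_stack(
        [
            rng.normal(0, drift_sd_mm, size=(n_volumes, 3)).reshape(n_volumes, 3),
            rng.normal(0, drift_sd_rad, size=(n_volumes, 3)).reshape(n_volumes, 3),
        ]
    )
    spikes = rng.random(n_volumes) < spike_rate
    steps[spikes, 0] += rng.choice([-1, 1], size=int(spikes.sum())) * spike_magnitude_mm
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def sample_participants(
    n_per_group: int,
    n_male_per_group: int,
    pma_range: tuple[float, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Covariate table with the emulated cohort structure.

    PMA at scan is uniform over ``pma_range``; birth GA is drawn near term
    and constrained below PMA; postnatal age is the difference in days.
    """
    rows = []
    idx = 0
    for group in ("R+", "R-"):
        sexes = ["male"] * n_male_per_group + ["female"] * (n_per_group - n_male_per_group)
        for sex in sexes:
            idx += 1
            pma = rng.uniform(*pma_range)
            ga = np.clip(rng.normal(39.6, 1.4), 34.0, min(42.0, pma - 0.2))
            rows.append(
                {
                    "id": f"sim{idx:02d}",
                    "group": group,
                    "sex": sex,
                    "birth_ga_weeks": round(float(ga), 2),
                    "pma_scan_weeks": round(float(pma), 2),
                    "postnatal_age_days": max(1.0, round(float((pma - ga) * 7.0))),
                    "birth_weight_kg": round(float(np.clip(rng.normal(3.4, 0.45), 2.2, 4.8)), 2),
                    "head_circumference_cm": round(float(np.clip(rng.normal(35.8, 1.4), 32.0, 39.0)), 1),
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig) -> CohortSim:
    """Full cohort: atlas, per-participant BOLD -> ReHo -> Fisher z, motion."""
    root = np.random.SeedSequence(config.seed)
    atlas_seed, participant_seed, *_ = root.spawn(3)
    atlas, mask = generate_atlas(
        config.shape, n_rois=config.n_rois, n_control=config.n_control,
        seed=atlas_seed.generate_state(1)[0] % (2**31),
    )
    rng = np.random.default_rng(participant_seed)
    participants = sample_participants(
        config.n_per_group, config.n_male_per_group, config.pma_range, rng
    )
    z_maps = []
    traces = []
    for _, row in participants.iterrows():
        bold = simulate_bold(config, atlas, row["group"], row["pma_scan_weeks"], rng)
        rh = reho_map(bold, mask, neighborhood=config.neighborhood, mode=config.mode)
        z_maps.append(rh.z)
        traces.append(
            simulate_motion_params(config.n_volumes, rng, spike_rate=config.motion_spike_rate)
        )
    z4d = np.stack(z_maps, axis=3)
    return CohortSim(
        participants=participants,
        z4d=z4d,
        atlas=atlas,
        mask=mask,
        motion_params=traces,
        config=config,
    )


def simulate_zmap_cohort(
    n_per_group: int = DEFAULT_N_PER_GROUP,
    n_male_per_group: int = DEFAULT_N_MALE,
    roi_voxels: int = 200,
    effect_z: float = 0.0,
    age_slope_z: dict | None = None,
    noise_sd: float = 0.15,
    noise_fwhm: float = 0.0,
    pma_range: tuple[float, float] = DEFAULT_PMA_RANGE,
    seed: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray, LabelAtlas, BrainMask]:
    """Direct Fisher-z cohort: an effect ROI and a control ROI of equal size.

    Per-participant maps are ``noise_sd``-scaled Gaussian fields (optionally
    spatially smoothed and re-standardised) plus, inside the effect ROI
    only, an additive group shift ``effect_z`` for R+ and a group-specific
    PMA slope ``age_slope_z`` (z units per week, centered at the cohort
    mean PMA). The control ROI carries pure noise. Used for permutation
    calibration and power studies where the full BOLD route is too slow.
    """
    if seed is None:
        raise ValueError("a seed is mandatory")
    if age_slope_z is None:
        age_slope_z = {"R+": 0.0, "R-": 0.0}
    nx = int(np.ceil(roi_voxels / 40.0))
    shape = (2 * nx + 2, 5, 8)  # two nx*5*8 boxes separated by a 2-voxel gap
    if nx * 40 != roi_voxels:
        raise ValueError("roi_voxels must be a multiple of 40")
    atlas_data = np.zeros(shape, dtype=np.int32)
    atlas_data[:nx] = 1
    atlas_data[nx + 2 :] = 2
    atlas = LabelAtlas(
        atlas_data,
        labels={1: "effect_roi", 2: "control_roi"},
        control_labels=frozenset({2}),
    )
    mask = BrainMask(atlas_data > 0)
    rng = np.random.default_rng(seed)
    participants = sample_participants(n_per_group, n_male_per_group, pma_range, rng)
    pma = participants["pma_scan_weeks"].to_numpy(float)
    pma_c = pma - pma.mean()
    n = len(participants)
    noise = rng.standard_normal((*shape, n))
    if noise_fwhm > 0:
        sigma = noise_fwhm * _FWHM_TO_SIGMA
        noise = ndimage.gaussian_filter(noise, sigma=(sigma, sigma, sigma, 0.0))
        noise /= noise[mask.data].std()
    z4d = noise_sd * noise
    in_effect = atlas.data == 1
    for i, row in enumerate(participants.itertuples(index=False)):
        shift = 0.0
        if row.group == "R+":
            shift += effect_z
        shift += age_slope_z.get(row.group, 0.0) * pma_c[i]
        z4d[in_effect, i] += shift
    z4d[~mask.data] = np.nan
    return participants, z4d, atlas, mask
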