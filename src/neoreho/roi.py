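"""ROI-restricted inference and the per-participant summaries behind the
group and maturational-trajectory plots.

Each atlas region (including control regions) is tested separately with the
permutation GLM, FDR is applied within the region's voxel set, significant
voxels are grouped into clusters, and each participant's median z over the
pooled significant voxels is reported — the same voxel set for every
participant, so medians are comparable across the cohort.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glm import (
    DesignMatrix,
    StatResult,
    build_design_interaction,
    build_design_main,
    permutation_glm,
)
from .volume_io import LabelAtlas, check_grid_compatible, participants_frame

__all__ = [
    "RoiResult",
    "roi_voxel_tests",
    "cluster_participant_medians",
    "age_trend_summary",
    "roi_results_table",
]

MODELS = ("main", "interaction")


@dataclass
class RoiResult:
    """Inference outcome for one atlas region under one model."""

    roi_label: int
    roi_name: str
    model: str
    is_control: bool
    stat: StatResult
    clusters: pd.DataFrame
    participant_medians: np.ndarray | None

    @property
    def n_significant(self) -> int:
        return self.stat.n_significant


def _design_for(model: str, participants) -> DesignMatrix:
    if model == "main":
        return build_design_main(participants)
    if model == "interaction":
        return build_design_interaction(participants)
    raise ValueError(f"model must be one of {MODELS}")


def roi_voxel_tests(
    z4d: np.ndarray,
    atlas: LabelAtlas,
    participants,
    model: str = "main",
    q: float = 0.05,
    n_permutations: int = 5000,
    seed: int | None = None,
    mask: np.ndarray | None = None,
    connectivity: int = 26,
) -> list[RoiResult]:
    """Run one model within every atlas region (control regions included).

    FDR is applied within each ROI's voxel set separately. The permutation
    stream for each region is derived deterministically from (seed, label).
    Regions with fewer than 2 usable voxels are skipped with a warning.
    """
    if seed is None:
        raise ValueError("a seed is required")
    z4d = np.asarray(z4d, dtype=np.float64)
    check_grid_compatible(z4d, atlas)
    design = _design_for(model, participants)
    if z4d.shape[3] != design.n:
        raise ValueError("participant axis does not match participant table")
    usable = np.isfinite(z4d).all(axis=3)
    if mask is not None:
        usable &= np.asarray(mask).astype(bool)
    results: list[RoiResult] = []
    for label in atlas.roi_labels:
        roi_mask = (atlas.data == label) & usable
        if roi_mask.sum() < 2:
            warnings.warn(f"ROI {label} ({atlas.labels.get(label)}): <2 usable voxels, skipped")
            continue
        stat = permutation_glm(
            z4d,
            roi_mask,
            design,
            n_permutations=n_permutations,
            seed=[int(seed), int(label)],
            q=q,
            connectivity=connectivity,
        )
        sig_bool = stat.cluster_labels > 0
        medians = cluster_participant_medians(z4d, sig_bool) if sig_bool.any() else None
        results.append(
            RoiResult(
                roi_label=int(label),
                roi_name=atlas.labels.get(int(label), f"roi_{label:02d}"),
                model=model,
                is_control=int(label) in atlas.control_labels,
                stat=stat,
                clusters=stat.clusters,
                participant_medians=medians,
            )
        )
    return results


def cluster_participant_medians(z4d: np.ndarray, cluster_mask: np.ndarray) -> np.ndarray:
    """Per-participant median z over a fixed cluster voxel set."""
    z4d = np.asarray(z4d, dtype=np.float64)
    cluster_mask = np.asarray(cluster_mask).astype(bool)
    if not cluster_mask.any():
        raise ValueError("empty cluster mask")
    return np.median(z4d[cluster_mask], axis=0)


def age_trend_summary(medians, participants, group_split: bool = True) -> pd.DataFrame:
    """Least-squares trend of per-participant median z on PMA.

    Returns one row per group (or a single pooled row) with slope,
    intercept, the slope's 95% CI, and a pointwise 95% confidence band
    evaluated over the group's PMA range (stored as arrays in the row).
    """
    df = participants_frame(list(participants)) if not isinstance(participants, pd.DataFrame) else participants.copy()
    medians = np.asarray(medians, dtype=np.float64)
    if medians.shape[0] != len(df):
        raise ValueError("medians length must match participant count")
    df = df.assign(median_z=medians)
    groups = [(g, sub) for g, sub in df.groupby("group")] if group_split else [("all", df)]
    rows = []
    for g, sub in groups:
        if len(sub) < 3:
            raise ValueError(f"need at least 3 participants per group, group {g} has {len(sub)}")
        pma = sub["pma_scan_weeks"].to_numpy(float)
        if np.ptp(pma) == 0:
            raise ValueError(f"degenerate PMA spread in group {g}")
        x = sm.add_constant(pma)
        fit = sm.OLS(sub["median_z"].to_numpy(float), x).fit()
        grid = np.linspace(pma.min(), pma.max(), 50)
        pred = fit.get_prediction(sm.add_constant(grid))
        ci = pred.conf_int(alpha=0.05)
        slope_ci = fit.conf_int(alpha=0.05)[1]
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "slope_per_week": float(fit.params[1]),
                "slope_se": float(fit.bse[1]),
                "slope_ci_low": float(slope_ci[0]),
                "slope_ci_high": float(slope_ci[1]),
                "slope_sign": int(np.sign(fit.params[1])),
                "intercept": float(fit.params[0]),
                "pma_grid": grid,
                "fit_mean": pred.predicted_mean,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            }
        )
    return pd.DataFrame(rows)


def roi_results_table(results: list[RoiResult]) -> pd.DataFrame:
    """Flat per-ROI summary (one row per region and model)."""
    rows = []
    for res in results:
        n_vox = int(np.isfinite(res.stat.p_perm).sum())
        rows.append(
            {
                "roi_label": res.roi_label,
                "roi_name": res.roi_name,
                "model": res.model,
                "is_control": res.is_control,
                "n_voxels": n_vox,
                "n_significant": res.n_significant,
                "n_clusters": len(res.clusters),
                "largest_cluster": int(res.clusters["size"].max()) if len(res.clusters) else 0,
                "peak_t": float(res.clusters["peak_t"].abs().max()) if len(res.clusters) else float("nan"),
                "min_p_fdr": float(np.nanmin(res.stat.p_fdr)),
            }
        )
    return pd.DataFrame(rows)
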