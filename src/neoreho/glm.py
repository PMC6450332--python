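"""Voxelwise GLM with Freedman–Lane permutation inference and BH-FDR.

The two design builders mirror the study models: a group main effect
adjusted for gestational age at birth, postmenstrual age at scan and sex;
and a group x PMA interaction adjusted for sex. Inference is nonparametric:
the nuisance-only model is fitted, its residuals are permuted, the full
model is refitted to each permuted dataset, and a two-tailed p value is
computed from the permutation distribution of |t| with the +1 smoothing
p = (1 + #{|t*| >= |t_obs|}) / (1 + B). Multiplicity is controlled by
Benjamini–Hochberg step-up FDR, applied within whatever voxel set is being
tested (a single ROI, or the whole mask for exploratory maps).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _all_permutations

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .volume_io import ParticipantRecord, participants_frame

__all__ = [
    "DesignMatrix",
    "StatResult",
    "build_design_main",
    "build_design_interaction",
    "ols_tstat",
    "freedman_lane_permutation",
    "bh_fdr",
    "extract_clusters",
    "permutation_glm",
]


@dataclass
class DesignMatrix:
    """Participants x regressors design with a single contrast vector.

    Rows align with the participant order used to stack the response maps.
    Group is coded 1 for R+ / 0 for R-, sex 1 for male / 0 for female, and
    continuous covariates are mean-centered, so a positive interaction
    contrast means a steeper PMA slope in the R+ group.
    """

    matrix: np.ndarray
    regressor_names: list[str]
    contrast: np.ndarray
    exchangeability: str = "freedman_lane"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.contrast = np.asarray(self.contrast, dtype=np.float64)
        n, k = self.matrix.shape
        if len(self.regressor_names) != k:
            raise ValueError("regressor_names length must match design columns")
        if self.contrast.shape != (k,):
            raise ValueError("contrast length must equal number of regressors")
        if np.linalg.matrix_rank(self.matrix) < k:
            raise ValueError("design matrix is rank deficient")
        if self.exchangeability not in ("full", "freedman_lane"):
            raise ValueError("exchangeability must be 'full' or 'freedman_lane'")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


def _covariate_frame(participants) -> pd.DataFrame:
    if isinstance(participants, pd.DataFrame):
        df = participants.copy()
    else:
        df = participants_frame(list(participants))
    counts = df["group"].value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need at least 2 participants in each of the two groups")
    return df


def build_design_main(participants) -> DesignMatrix:
    """Group main-effect design: intercept, group, birth GA, PMA, sex.

    Continuous covariates are mean-centered; the contrast selects the group
    column (positive = higher in R+).
    """
    df = _covariate_frame(participants)
    group = (df["group"] == "R+").to_numpy(float)
    sex = (df["sex"] == "male").to_numpy(float)
    ga = df["birth_ga_weeks"].to_numpy(float)
    pma = df["pma_scan_weeks"].to_numpy(float)
    x = np.column_stack([
        np.ones(len(df)),
        group,
        ga - ga.mean(),
        pma - pma.mean(),
        sex,
    ])
    return DesignMatrix(
        matrix=x,
        regressor_names=["intercept", "group", "birth_ga_c", "pma_c", "sex"],
        contrast=np.array([0.0, 1.0, 0.0, 0.0, 0.0]),
    )


def build_design_interaction(participants) -> DesignMatrix:
    """Group x PMA interaction design: intercept, group, PMA, group x PMA, sex.

    PMA is mean-centered before forming the interaction, so the group column
    is interpretable at mean PMA; the contrast selects group x PMA
    (positive = steeper PMA slope in the R+ group).
    """
    df = _covariate_frame(participants)
    for g, sub in df.groupby("group"):
        if sub["pma_scan_weeks"].nunique() < 2:
            raise ValueError(f"degenerate design: no PMA spread within group {g}")
    group = (df["group"] == "R+").to_numpy(float)
    sex = (df["sex"] == "male").to_numpy(float)
    pma = df["pma_scan_weeks"].to_numpy(float)
    pma_c = pma - pma.mean()
    x = np.column_stack([np.ones(len(df)), group, pma_c, group * pma_c, sex])
    return DesignMatrix(
        matrix=x,
        regressor_names=["intercept", "group", "pma_c", "group_x_pma", "sex"],
        contrast=np.array([0.0, 0.0, 0.0, 1.0, 0.0]),
    )


def ols_tstat(y_matrix, design: DesignMatrix) -> np.ndarray:
    """Contrast t statistics of an OLS fit, one per row of ``y_matrix``.

    ``y_matrix`` is (voxels, participants); t = c'b / sqrt(s2 * c'(X'X)^-1 c)
    with dof = n - rank(X).
    """
    y = np.atleast_2d(np.asarray(y_matrix, dtype=np.float64))
    x = design.matrix
    n, k = x.shape
    if y.shape[1] != n:
        raise ValueError(f"y has {y.shape[1]} columns but design has {n} rows")
    if n <= k:
        raise ValueError("need more participants than regressors")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y.T  # (k, V)
    resid = y.T - x @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    c = design.contrast
    denom = np.sqrt(sigma2 * float(c @ xtx_inv @ c))
    # a residual variance at float round-off of the response scale means a
    # perfectly fitted (e.g. constant) voxel: its t is defined as 0
    scale = np.sqrt((y**2).mean(axis=1))
    floor = 1e-10 * (scale + np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (c @ beta) / denom
    return np.where(denom > floor, t, 0.0)


def _effect_and_nuisance(design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    effect_cols = np.nonzero(design.contrast)[0]
    nuisance_cols = np.nonzero(design.contrast == 0)[0]
    if effect_cols.size != 1:
        raise ValueError("Freedman-Lane implementation expects a single-column contrast")
    return effect_cols, nuisance_cols


def freedman_lane_permutation(
    y_matrix,
    design: DesignMatrix,
    n_permutations: int = 5000,
    seed=None,
    return_null: bool = False,
):
    """Two-tailed Freedman–Lane permutation p values per voxel.

    Residuals of the nuisance-only (reduced) fit are row-permuted, added
    back to the reduced-model fitted values, and the full model is refitted;
    p = (1 + #{|t*| >= |t_obs|}) / (1 + B). Deterministic given ``seed``.
    When the requested count reaches the number of distinct row permutations
    (tiny n), all n! permutations are enumerated instead and the p value is
    the exact proportion (identity included).
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible permutation inference")
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    y = np.atleast_2d(np.asarray(y_matrix, dtype=np.float64))
    x = design.matrix
    n = x.shape[0]
    _, nuisance_cols = _effect_and_nuisance(design)
    z = x[:, nuisance_cols]
    hz = z @ np.linalg.inv(z.T @ z) @ z.T
    fitted_reduced = hz @ y.T  # (n, V)
    resid_reduced = y.T - fitted_reduced

    t_obs = ols_tstat(y, design)
    abs_obs = np.abs(t_obs)

    exhaustive = math.factorial(n) <= n_permutations
    if exhaustive:
        warnings.warn(
            f"requested {n_permutations} permutations >= {n}! distinct row "
            "permutations; enumerating exhaustively"
        )
        perms = (np.array(p) for p in _all_permutations(range(n)))
        count = np.zeros(y.shape[0])
        b = 0
        null = [] if return_null else None
        for perm in perms:
            y_star = (fitted_reduced + resid_reduced[perm]).T
            t_star = ols_tstat(y_star, design)
            count += np.abs(t_star) >= abs_obs - 1e-12
            if return_null:
                null.append(t_star)
            b += 1
        p = count / b
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(y.shape[0])
        null = [] if return_null else None
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            y_star = (fitted_reduced + resid_reduced[perm]).T
            t_star = ols_tstat(y_star, design)
            count += np.abs(t_star) >= abs_obs
            if return_null:
                null.append(t_star)
        p = (1.0 + count) / (1.0 + n_permutations)
    if return_null:
        return t_obs, p, np.asarray(null)
    return t_obs, p


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (adjusted p, rejection mask) at level q."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


_STRUCTURES = {6: 1, 18: 2, 26: 3}


def extract_clusters(
    sig: np.ndarray,
    connectivity: int = 26,
    t: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Connected components of a boolean 3D map.

    Returns (label volume, table of cluster id / size / peak |t| voxel).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    sig = np.asarray(sig).astype(bool)
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    labels, n_clusters = ndimage.label(sig, structure=structure)
    rows = []
    for cid in range(1, n_clusters + 1):
        voxels = np.argwhere(labels == cid)
        if t is not None:
            tvals = np.abs(t[labels == cid])
            peak = voxels[int(np.nanargmax(tvals))]
            peak_t = float(t[tuple(peak)])
        else:
            peak = voxels[0]
            peak_t = float("nan")
        rows.append(
            {
                "cluster_id": cid,
                "size": int(voxels.shape[0]),
                "peak_x": int(peak[0]),
                "peak_y": int(peak[1]),
                "peak_z": int(peak[2]),
                "peak_t": peak_t,
            }
        )
    table = pd.DataFrame(rows, columns=["cluster_id", "size", "peak_x", "peak_y", "peak_z", "peak_t"])
    return labels, table


@dataclass
class StatResult:
    """Voxelwise permutation-GLM result for one contrast over a test mask."""

    t: np.ndarray
    p_perm: np.ndarray
    p_fdr: np.ndarray
    sig: np.ndarray
    n_permutations: int
    seed: object
    q: float = 0.05
    cluster_labels: np.ndarray | None = None
    clusters: pd.DataFrame | None = None

    @property
    def n_significant(self) -> int:
        return int(np.nansum(self.sig))


def permutation_glm(
    z4d: np.ndarray,
    test_mask: np.ndarray,
    design: DesignMatrix,
    n_permutations: int = 5000,
    seed=None,
    q: float = 0.05,
    connectivity: int = 26,
) -> StatResult:
    """Run the full voxelwise inference over a test mask.

    ``z4d`` stacks per-participant maps along the 4th axis in design row
    order. FDR is applied across the voxels of ``test_mask`` only.
    """
    z4d = np.asarray(z4d, dtype=np.float64)
    test_mask = np.asarray(test_mask).astype(bool)
    if z4d.shape[:3] != test_mask.shape:
        raise ValueError("map grid does not match test mask grid")
    if z4d.shape[3] != design.n:
        raise ValueError("participant axis does not match design rows")
    y = z4d[test_mask]  # (V, n)
    if y.shape[0] < 2:
        raise ValueError("test mask must contain at least 2 voxels")
    if not np.isfinite(y).all():
        raise ValueError("non-finite map values inside the test mask")
    t_vec, p_vec = freedman_lane_permutation(y, design, n_permutations=n_permutations, seed=seed)
    p_adj, reject = bh_fdr(p_vec, q=q)

    def embed(vec, fill=np.nan, dtype=np.float64):
        out = np.full(test_mask.shape, fill, dtype=dtype)
        out[test_mask] = vec
        return out

    t_map = embed(t_vec)
    sig_map = embed(reject.astype(float), fill=np.nan)
    sig_bool = np.zeros(test_mask.shape, dtype=bool)
    sig_bool[test_mask] = reject
    cluster_labels, clusters = extract_clusters(sig_bool, connectivity=connectivity, t=t_map)
    return StatResult(
        t=t_map,
        p_perm=embed(p_vec),
        p_fdr=embed(p_adj),
        sig=sig_map,
        n_permutations=n_permutations,
        seed=seed,
        q=q,
        cluster_labels=cluster_labels,
        clusters=clusters,
    )
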