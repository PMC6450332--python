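"""Regional homogeneity: Kendall's coefficient of concordance over a voxel
neighborhood, and the concordance → correlation → Fisher-z transform chain.

ReHo quantifies the local synchrony of spontaneous BOLD fluctuations: for
each voxel, Kendall's W is computed between its time series and those of its
adjacent neighbors (26-connectivity by default), treating voxels as raters
and time points as ranked items. With m series of length n, mid-ranks for
ties and per-series tie terms T_j = sum(t^3 - t) over tie groups,

    W = 12 S / (m^2 (n^3 - n) - m * sum_j T_j),

where S is the sum of squared deviations of the per-timepoint rank sums from
their mean. W lies in [0, 1]; under independence E[W] = 1/m.

Before group statistics the concordance-scale value is mapped to a
Pearson-scale correlation and Fisher z score. Because the literature is
ambiguous about whether the "ReHo Kendall tau" entering Greiner's relation
r = sin(pi*tau/2) is W itself or a pairwise-tau derivative, three conversion
modes are provided (see :func:`reho_map`); "literal" is the default.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats

from .volume_io import BoldSeries, BrainMask, check_grid_compatible

__all__ = [
    "ReHoMap",
    "kendall_w",
    "mean_pairwise_tau",
    "reho_map",
    "tau_to_pearson",
    "fisher_z",
    "neighborhood_kernel",
    "CONVERSION_MODES",
]

CONVERSION_MODES = ("literal", "mean_spearman", "mean_tau")

_CLIP = 1.0 - 1e-7


@dataclass
class ReHoMap:
    """Per-voxel ReHo maps; NaN everywhere outside the mask.

    ``w`` is Kendall's W; ``tau`` the correlation-scale value the chosen
    conversion mode feeds forward (W for "literal", mean Spearman for
    "mean_spearman", mean pairwise tau-b for "mean_tau"); ``r`` the
    Pearson-scale correlation; ``z`` its Fisher transform; ``m_used`` the
    neighborhood size actually available at each voxel.
    """

    w: np.ndarray
    tau: np.ndarray
    r: np.ndarray
    z: np.ndarray
    m_used: np.ndarray
    mode: str = "literal"
    neighborhood: int = 26


def _tie_term_1d(x: np.ndarray) -> float:
    """sum(t^3 - t) over groups of tied values in one series."""
    _, counts = np.unique(x, return_counts=True)
    counts = counts[counts > 1]
    return float((counts**3 - counts).sum())


def kendall_w(timeseries) -> float:
    """Tie-corrected Kendall coefficient of concordance of m series.

    ``timeseries`` is (m, n): m rank-ordered series over n time points,
    m >= 2 and n >= 2. Returns NaN (with a warning) when the tie-corrected
    denominator vanishes, i.e. every series is constant.
    """
    ts = np.asarray(timeseries, dtype=np.float64)
    if ts.ndim != 2:
        raise ValueError(f"expected (m, n) array, got {ts.shape}")
    m, n = ts.shape
    if m < 2 or n < 2:
        raise ValueError(f"need m >= 2 series and n >= 2 time points, got {ts.shape}")
    if not np.isfinite(ts).all():
        raise ValueError("non-finite values in time series")
    ranks = stats.rankdata(ts, axis=1)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie_total = sum(_tie_term_1d(row) for row in ts)
    denom = m * m * (n**3 - n) - m * tie_total
    if denom <= 0:
        warnings.warn("Kendall W undefined: all series constant (tie-corrected denominator 0)")
        return float("nan")
    return float(np.clip(12.0 * s / denom, 0.0, 1.0))


def mean_pairwise_tau(timeseries) -> float:
    """Mean pairwise Kendall tau-b over all m(m-1)/2 pairs of series."""
    ts = np.asarray(timeseries, dtype=np.float64)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("need an (m >= 2, n) array")
    m = ts.shape[0]
    taus = []
    for i in range(m):
        for j in range(i + 1, m):
            t, _ = stats.kendalltau(ts[i], ts[j])
            if np.isfinite(t):
                taus.append(t)
    if not taus:
        warnings.warn("mean pairwise tau undefined: all pairs degenerate")
        return float("nan")
    return float(np.mean(taus))


def tau_to_pearson(tau):
    """Greiner's relation r = sin(pi * tau / 2); accepts scalars or arrays."""
    arr = np.asarray(tau, dtype=np.float64)
    bad = np.abs(arr[np.isfinite(arr)]) > 1 + 1e-12
    if bad.any():
        raise ValueError("tau values must lie in [-1, 1]")
    r = np.sin(np.pi * np.clip(arr, -1.0, 1.0) / 2.0)
    return float(r) if np.isscalar(tau) else r


def fisher_z(r):
    """Fisher z = atanh(r); |r| >= 1 is clipped to 1 - 1e-7 with a warning."""
    arr = np.asarray(r, dtype=np.float64)
    finite = np.isfinite(arr)
    if np.isscalar(r) and not finite:
        raise ValueError("non-finite correlation")
    clipped = np.clip(arr, -_CLIP, _CLIP)
    if (np.abs(arr[finite]) >= 1).any():
        warnings.warn("correlations at |r| >= 1 clipped before Fisher transform")
    z = np.arctanh(np.where(finite, clipped, np.nan))
    return float(z) if np.isscalar(r) else z


def neighborhood_kernel(neighborhood: int) -> np.ndarray:
    """3x3x3 footprint (center included) for 6/18/26-connectivity."""
    if neighborhood not in (6, 18, 26):
        raise ValueError("neighborhood must be 6, 18 or 26")
    offsets = np.abs(np.indices((3, 3, 3)) - 1).sum(axis=0)
    if neighborhood == 6:
        return (offsets <= 1).astype(np.float64)
    if neighborhood == 18:
        return (offsets <= 2).astype(np.float64)
    return np.ones((3, 3, 3), dtype=np.float64)


def _tie_term_map(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-voxel tie term sum(t^3 - t); 0 outside the mask.

    Vectorised for the tie-free common case; voxels containing ties fall
    back to an explicit per-voxel count.
    """
    tie = np.zeros(data.shape[:3], dtype=np.float64)
    srt = np.sort(data, axis=3)
    has_tie = (np.diff(srt, axis=3) == 0).any(axis=3) & mask
    for idx in np.argwhere(has_tie):
        tie[tuple(idx)] = _tie_term_1d(data[tuple(idx)])
    return tie


def _neighborhood_sum(volume: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    if volume.ndim == 3:
        return ndimage.convolve(volume, kernel, mode="constant", cval=0.0)
    return ndimage.convolve(volume, kernel[..., None], mode="constant", cval=0.0)


def _mean_tau_map(data, mask, kernel, m_used):
    """Mean pairwise tau-b per voxel via sign-matrix inner products.

    O(m * n^2) per voxel — intended for the non-default "mean_tau" mode on
    small grids.
    """
    shape = data.shape[:3]
    n = data.shape[3]
    tau = np.full(shape, np.nan)
    offs = np.argwhere(kernel > 0) - 1
    n0 = n * (n - 1) / 2.0
    for idx in np.argwhere(mask):
        if m_used[tuple(idx)] < 2:
            continue
        nbrs = []
        for off in offs:
            p = idx + off
            if (p >= 0).all() and (p < shape).all() and mask[tuple(p)]:
                nbrs.append(data[tuple(p)])
        arr = np.asarray(nbrs)  # (m, n)
        diff = np.sign(arr[:, :, None] - arr[:, None, :])
        flat = diff.reshape(arr.shape[0], -1)
        gram = flat @ flat.T  # counts each unordered pair twice
        ties = np.array([_tie_term_1d(row) for row in arr])
        # tau-b denominator per series: n0 - (number of tied pairs)
        tied_pairs = np.array(
            [sum(c * (c - 1) / 2 for c in np.unique(row, return_counts=True)[1] if c > 1) for row in arr]
        )
        d = n0 - tied_pairs
        del ties
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.sqrt(np.outer(d, d))
            tmat = (gram / 2.0) / scale
        iu = np.triu_indices(arr.shape[0], k=1)
        vals = tmat[iu]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            tau[tuple(idx)] = vals.mean()
    return tau


def reho_map(
    bold: BoldSeries | np.ndarray,
    mask: BrainMask | np.ndarray,
    neighborhood: int = 26,
    mode: str = "literal",
) -> ReHoMap:
    """Voxelwise ReHo over a mask.

    For each in-mask voxel, Kendall's W is computed over the voxel and its
    in-mask neighbors (neighborhoods truncated at mask/grid boundaries;
    ``m_used`` records the size actually available, and voxels with
    ``m_used < 2`` are NaN). Conversion modes:

    - ``literal``: treat W as tau in r = sin(pi*tau/2) (default);
    - ``mean_spearman``: mean inter-series Spearman correlation
      r = (m*W - 1)/(m - 1), Fisher-transformed directly;
    - ``mean_tau``: mean pairwise Kendall tau-b of the neighborhood series,
      then r = sin(pi*tau/2). Exact but O(m*n^2) per voxel.
    """
    if mode not in CONVERSION_MODES:
        raise ValueError(f"mode must be one of {CONVERSION_MODES}")
    data = bold.data if isinstance(bold, BoldSeries) else np.asarray(bold, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError("expected 4D BOLD data")
    mask_arr = mask.data if isinstance(mask, BrainMask) else np.asarray(mask, dtype=bool)
    check_grid_compatible(data, mask_arr)
    if mask_arr.sum() < 2:
        raise ValueError("need at least 2 in-mask voxels")
    if not np.isfinite(data[mask_arr]).all():
        raise ValueError("non-finite BOLD values inside the mask")
    n = data.shape[3]
    kernel = neighborhood_kernel(neighborhood)

    m_used = np.rint(_neighborhood_sum(mask_arr.astype(np.float64), kernel)).astype(np.int32)
    m_used[~mask_arr] = 0

    ranks = stats.rankdata(data, axis=3)
    ranks[~mask_arr] = 0.0
    tie = _tie_term_map(data, mask_arr)

    rank_sums = _neighborhood_sum(ranks, kernel)  # (x,y,z,t)
    tie_sums = _neighborhood_sum(tie, kernel)
    m = m_used.astype(np.float64)
    s = (rank_sums**2).sum(axis=3) - (rank_sums.sum(axis=3) ** 2) / n
    denom = m * m * (n**3 - n) - m * tie_sums
    valid = mask_arr & (m_used >= 2) & (denom > 0)
    degenerate = mask_arr & (m_used >= 2) & (denom <= 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} voxel(s) with all-constant neighborhood series: W set to NaN"
        )
    w = np.full(data.shape[:3], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        w[valid] = np.clip(12.0 * s[valid] / denom[valid], 0.0, 1.0)

    if mode == "literal":
        tau_map = w.copy()
        r = np.full_like(w, np.nan)
        r[valid] = np.sin(np.pi * tau_map[valid] / 2.0)
    elif mode == "mean_spearman":
        tau_map = np.full_like(w, np.nan)
        tau_map[valid] = (m[valid] * w[valid] - 1.0) / (m[valid] - 1.0)
        r = tau_map.copy()
    else:  # mean_tau
        tau_map = _mean_tau_map(data, mask_arr, kernel, m_used)
        tau_map[~valid] = np.nan
        r = np.full_like(w, np.nan)
        r[valid] = np.sin(np.pi * tau_map[valid] / 2.0)

    z = np.full_like(w, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z[valid] = np.arctanh(np.clip(r[valid], -_CLIP, _CLIP))

    mf = m_used.astype(np.float64)
    mf[~mask_arr] = np.nan
    return ReHoMap(w=w, tau=tau_map, r=r, z=z, m_used=mf, mode=mode, neighborhood=neighborhood)
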