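"""Framewise displacement, minimum-motion window selection, and exclusion.

FD follows the Power convention: per volume, the sum of absolute backward
differences of the six rigid-body parameters, with the three rotations
converted to arc length on a sphere (default radius 50 mm). The first
volume's FD is defined as 0. A continuous analysis window of fixed length
is chosen to minimise total FD, and a participant is excluded when the
number of suprathreshold volumes inside the window strictly exceeds the
allowed count (default: FD > 0.5 mm in more than 5% of the window).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MotionTrace",
    "CensoringDecision",
    "framewise_displacement",
    "select_min_motion_window",
    "motion_exclusion",
    "censor_series",
    "read_motion_trace",
    "write_motion_trace",
]

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.5
DEFAULT_MAX_FRACTION = 0.05


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters and derived framewise displacement.

    ``params`` is (n_volumes, 6): translations in mm then rotations in
    radians.
    """

    params: np.ndarray
    fd: np.ndarray
    head_radius: float = DEFAULT_HEAD_RADIUS_MM

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        self.fd = np.asarray(self.fd, dtype=np.float64)
        if self.fd.shape[0] != self.params.shape[0]:
            raise ValueError("fd length must equal number of volumes")
        if (self.fd < 0).any():
            raise ValueError("framewise displacement must be non-negative")

    @classmethod
    def from_params(cls, params, head_radius: float = DEFAULT_HEAD_RADIUS_MM) -> "MotionTrace":
        return cls(params=np.asarray(params, dtype=np.float64),
                   fd=framewise_displacement(params, head_radius),
                   head_radius=head_radius)

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclass
class CensoringDecision:
    """Outcome of window selection + exclusion for one participant."""

    window_start: int
    window_length: int
    n_suprathreshold: int
    excluded: bool

    def __post_init__(self) -> None:
        if self.n_suprathreshold > self.window_length:
            raise ValueError("suprathreshold count cannot exceed window length")


def framewise_displacement(params, head_radius: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """FD per volume from (n, 6) rigid-body parameters.

    fd[0] = 0; fd[t] = sum |Δtranslation| + head_radius * sum |Δrotation|.
    """
    params = np.asarray(params, dtype=np.float64)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"expected (n_volumes, 6) motion parameters, got {params.shape}")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 volumes of motion parameters")
    if not np.isfinite(params).all():
        raise ValueError("non-finite motion parameters")
    if head_radius <= 0:
        raise ValueError("head_radius must be positive")
    delta = np.abs(np.diff(params, axis=0))
    fd = delta[:, :3].sum(axis=1) + head_radius * delta[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def select_min_motion_window(fd, window_length: int) -> int:
    """Start index of the contiguous window with the smallest total FD.

    Ties are broken toward the earliest start.
    """
    fd = np.asarray(fd, dtype=np.float64)
    n = fd.shape[0]
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if window_length > n:
        raise ValueError(f"window_length {window_length} exceeds series length {n}")
    csum = np.concatenate([[0.0], np.cumsum(fd)])
    totals = csum[window_length:] - csum[:-window_length]
    # exact recomputation of the argmin candidate guards against cumsum
    # round-off reordering near-ties; argmin already returns the first min
    return int(np.argmin(np.round(totals, 12)))


def motion_exclusion(
    fd_window,
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM,
    max_count: int | None = None,
    window_start: int = 0,
) -> CensoringDecision:
    """Exclusion rule: excluded iff #{fd > threshold} strictly exceeds max_count.

    ``max_count`` defaults to 5% of the window length, rounded to nearest
    (80 volumes for the standard 1600-volume window).
    """
    fd_window = np.asarray(fd_window, dtype=np.float64)
    if fd_window.size == 0:
        raise ValueError("empty FD window")
    if fd_threshold <= 0:
        raise ValueError("fd_threshold must be positive")
    if max_count is None:
        max_count = int(round(DEFAULT_MAX_FRACTION * fd_window.size))
    if max_count < 0:
        raise ValueError("max_count must be non-negative")
    n_supra = int((fd_window > fd_threshold).sum())
    return CensoringDecision(
        window_start=window_start,
        window_length=int(fd_window.size),
        n_suprathreshold=n_supra,
        excluded=n_supra > max_count,
    )


def censor_series(
    trace: MotionTrace,
    window_length: int,
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM,
    max_count: int | None = None,
) -> CensoringDecision:
    """Select the minimum-motion window, then apply the exclusion rule."""
    start = select_min_motion_window(trace.fd, window_length)
    return motion_exclusion(
        trace.fd[start : start + window_length],
        fd_threshold=fd_threshold,
        max_count=max_count,
        window_start=start,
    )


def read_motion_trace(
    path: str | Path,
    head_radius: float = DEFAULT_HEAD_RADIUS_MM,
    rotation_units: str = "rad",
) -> MotionTrace:
    """Read a motion-parameter text file: one row per volume, 6 columns
    (translations mm, rotations rad or deg), whitespace- or comma-separated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"motion trace not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    params = df.to_numpy(dtype=np.float64)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"expected 6 motion-parameter columns in {path}, got shape {params.shape}")
    if rotation_units == "deg":
        params = params.copy()
        params[:, 3:] = np.deg2rad(params[:, 3:])
    elif rotation_units != "rad":
        raise ValueError("rotation_units must be 'rad' or 'deg'")
    return MotionTrace.from_params(params, head_radius=head_radius)


def write_motion_trace(params, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(params, dtype=np.float64), fmt="%.8f")
    return path
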