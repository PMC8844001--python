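"""Motion quality control and frame hygiene for ROI time series.

Implements the standard resting-state motion pipeline applied before
windowed connectivity analysis: framewise displacement (FD) from the
6-parameter rigid-body trace, DVARS from the signal itself, marking of
high-motion volumes (with neighbour extension), linear interpolation
across marked frames, initial-frame discarding and a run-level
exclusion rule.

Conventions
-----------
* FD converts rotations to arc length on a 50 mm sphere (the common
  convention; configurable).
* DVARS is computed on the ROI time series and expressed as percent of
  the run's global mean signal.  On voxel data the denominator differs;
  for ROI-level inputs this is the natural analogue.
* Thresholds use strict inequality: a volume exactly at FD = 0.2 mm or
  DVARS = 5% is not marked.
"""
from __future__ import annotations

import numpy as np

from .data import DegenerateDataError, MotionSeries, RoiTimeSeries

__all__ = [
    "framewise_displacement",
    "dvars_series",
    "mark_high_motion",
    "motion_series",
    "interpolate_marked",
    "discard_initial_frames",
    "qc_exclusion",
]

DEFAULT_SPHERE_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.2
DEFAULT_DVARS_THRESHOLD_PCT = 5.0


def framewise_displacement(
    motion_params: np.ndarray, sphere_radius_mm: float = DEFAULT_SPHERE_RADIUS_MM
) -> np.ndarray:
    """Per-volume framewise displacement in mm.

    ``motion_params`` is a T x 6 trace: three translations in mm and
    three rotations in radians.  FD(t) is the sum of absolute backward
    differences of the six parameters, rotations converted to arc
    length at ``sphere_radius_mm``.  FD of the first volume is 0.
    """
    params = np.asarray(motion_params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"motion trace must have 6 columns, got shape {params.shape}")
    if sphere_radius_mm <= 0:
        raise ValueError("sphere radius must be positive")
    diffs = np.abs(np.diff(params, axis=0))
    diffs[:, 3:] *= sphere_radius_mm
    fd = np.zeros(params.shape[0])
    fd[1:] = diffs.sum(axis=1)
    return fd


def dvars_series(ts: RoiTimeSeries) -> np.ndarray:
    """DVARS per volume, as percent of the run's global mean signal.

    DVARS(t) is the root-mean-square over ROIs of the backward signal
    difference; DVARS of the first volume is 0.
    """
    x = ts.values
    if x.shape[0] < 2:
        raise ValueError("DVARS needs at least 2 volumes")
    global_mean = float(x.mean())
    if abs(global_mean) < 1e-12:
        raise DegenerateDataError("run global mean signal is zero; DVARS percent undefined")
    rms = np.sqrt(np.mean(np.diff(x, axis=0) ** 2, axis=1))
    dvars = np.zeros(x.shape[0])
    dvars[1:] = 100.0 * rms / abs(global_mean)
    return dvars


def mark_high_motion(
    fd: np.ndarray,
    dvars: np.ndarray,
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM,
    dvars_threshold: float = DEFAULT_DVARS_THRESHOLD_PCT,
    extend_before: int = 1,
    extend_after: int = 2,
) -> np.ndarray:
    """Boolean mask of high-motion volumes.

    A volume is marked when FD or DVARS strictly exceeds its threshold;
    ``extend_before`` predecessors and ``extend_after`` successors of
    every such volume are marked too, clipped at the run boundaries.
    """
    fd = np.asarray(fd, dtype=float)
    dvars = np.asarray(dvars, dtype=float)
    if len(fd) != len(dvars):
        raise ValueError("fd and dvars must have equal length")
    if fd_threshold < 0 or dvars_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    if extend_before < 0 or extend_after < 0:
        raise ValueError("extension counts must be non-negative")
    n = len(fd)
    spikes = (fd > fd_threshold) | (dvars > dvars_threshold)
    mask = np.zeros(n, dtype=bool)
    for idx in np.flatnonzero(spikes):
        lo = max(0, idx - extend_before)
        hi = min(n, idx + extend_after + 1)
        mask[lo:hi] = True
    return mask


def motion_series(
    motion_params: np.ndarray,
    ts: RoiTimeSeries,
    sphere_radius_mm: float = DEFAULT_SPHERE_RADIUS_MM,
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM,
    dvars_threshold: float = DEFAULT_DVARS_THRESHOLD_PCT,
    extend_before: int = 1,
    extend_after: int = 2,
) -> MotionSeries:
    """Convenience wrapper: FD + DVARS + high-motion mask for one run."""
    fd = framewise_displacement(motion_params, sphere_radius_mm)
    dvars = dvars_series(ts)
    mask = mark_high_motion(fd, dvars, fd_threshold, dvars_threshold, extend_before, extend_after)
    return MotionSeries(fd=fd, dvars=dvars, high_motion_mask=mask)


def interpolate_marked(ts: RoiTimeSeries, mask: np.ndarray) -> RoiTimeSeries:
    """Replace marked volumes by per-ROI linear interpolation.

    Marked volumes are interpolated between the nearest unmarked
    neighbours; leading/trailing marked volumes take the nearest
    unmarked value.  Unmarked volumes pass through bit-identically.
    """
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != ts.n_volumes:
        raise ValueError("mask length must equal the number of volumes")
    if mask.all():
        raise DegenerateDataError("every volume is marked; nothing to interpolate from")
    if not mask.any():
        return ts.copy_with(ts.values)
    keep = np.flatnonzero(~mask)
    bad = np.flatnonzero(mask)
    out = ts.values.copy()
    for j in range(ts.n_roi):
        out[bad, j] = np.interp(bad, keep, ts.values[keep, j])
    return ts.copy_with(out)


def discard_initial_frames(ts: RoiTimeSeries, n: int = 4) -> RoiTimeSeries:
    """Drop the first ``n`` volumes of a run (scanner equilibration)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= ts.n_volumes:
        raise ValueError(f"cannot discard {n} of {ts.n_volumes} volumes")
    return ts.copy_with(ts.values[n:])


def qc_exclusion(mask: np.ndarray, max_fraction: float = 0.5) -> tuple[bool, float]:
    """Run-level exclusion rule.

    Returns ``(passed, fraction_marked)``; the run fails only when the
    marked fraction strictly exceeds ``max_fraction``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("mask must be nonempty")
    fraction = float(mask.mean())
    return fraction <= max_fraction, fraction
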