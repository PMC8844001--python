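"""Core in-memory containers shared across the pipeline stages.

These are deliberately thin: validated ``dataclass`` wrappers around numpy
arrays, in the spirit of statsmodels' data handling.  Heavier tabular
results (occupancy tables, statistical reports) are plain pandas
DataFrames with documented column contracts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DegenerateDataError",
    "RoiTimeSeries",
    "MotionSeries",
    "CortisolSeries",
    "CortisolSummary",
    "SubjectRecord",
]

DEFAULT_CORTISOL_TIMEPOINTS = (-30.0, 0.0, 20.0, 60.0, 90.0)


class DegenerateDataError(ValueError):
    """Raised when an input is syntactically valid but statistically degenerate
    (flat signal, zero variance, every volume marked, ...)."""


@dataclass
class RoiTimeSeries:
    """One run's ROI-averaged BOLD time series.

    Parameters
    ----------
    values : (T, n_roi) array of BOLD signal in arbitrary scanner units.
    tr_seconds : sampling interval (repetition time).
    roi_names : ordered region labels; defaults to ``roi_001`` ... style names.
    """

    values: np.ndarray
    tr_seconds: float = 2.0
    roi_names: Sequence[str] | None = None
    subject_id: str | None = None
    run_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x n_roi matrix")
        if self.values.shape[0] < 1:
            raise ValueError("a run needs at least 1 volume")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.roi_names is None:
            self.roi_names = [f"roi_{i + 1:03d}" for i in range(self.values.shape[1])]
        self.roi_names = list(self.roi_names)
        if len(self.roi_names) != self.values.shape[1]:
            raise ValueError("roi_names length must equal the number of columns")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_roi(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "RoiTimeSeries":
        return RoiTimeSeries(
            values=np.array(values, dtype=float),
            tr_seconds=self.tr_seconds,
            roi_names=list(self.roi_names),
            subject_id=self.subject_id,
            run_id=self.run_id,
        )


@dataclass
class MotionSeries:
    """Per-volume motion QC summary for one run."""

    fd: np.ndarray
    dvars: np.ndarray
    high_motion_mask: np.ndarray

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        self.high_motion_mask = np.asarray(self.high_motion_mask, dtype=bool)
        if not (len(self.fd) == len(self.dvars) == len(self.high_motion_mask)):
            raise ValueError("fd, dvars and mask must have equal length")
        if np.any(self.fd < 0):
            raise ValueError("framewise displacement cannot be negative")

    @property
    def fraction_marked(self) -> float:
        return float(self.high_motion_mask.mean())


@dataclass
class CortisolSeries:
    """Salivary cortisol concentrations sampled around stress onset.

    ``timepoints`` are minutes relative to stressor onset (default
    -30, 0, +20, +60, +90); ``concentrations`` are in ug/dL unless
    ``log_scale`` is set, in which case they are natural-log units.
    """

    timepoints: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_CORTISOL_TIMEPOINTS))
    concentrations: np.ndarray = field(default_factory=lambda: np.full(5, np.nan))
    subject_id: str | None = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.timepoints.ndim != 1 or self.concentrations.ndim != 1:
            raise ValueError("timepoints and concentrations must be 1-D")
        if len(self.timepoints) != len(self.concentrations):
            raise ValueError("timepoints and concentrations must have equal length")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not self.log_scale and np.any(self.concentrations <= 0):
            bad = int(np.flatnonzero(self.concentrations <= 0)[0])
            raise ValueError(
                f"non-positive cortisol concentration at timepoint "
                f"{self.timepoints[bad]:+g} min (sample index {bad})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.timepoints)


@dataclass
class CortisolSummary:
    """Pruessner trapezoid summaries of one cortisol series.

    aucg is the area under the curve with respect to ground; auci the
    increase above a constant baseline (first sample), so that
    ``auci == aucg - baseline * duration`` exactly.
    """

    aucg: float
    auci: float
    log_scale: bool = True


@dataclass
class SubjectRecord:
    """Everything known about one participant outside the imaging data."""

    subject_id: str
    ffmq_total: float | None = None
    stress_change: float | None = None
    alertness_change: float | None = None
    cortisol: CortisolSeries | None = None
    cortisol_summary: CortisolSummary | None = None
    qc_pass: bool = True
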