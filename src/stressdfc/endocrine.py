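"""Salivary cortisol handling: log transform and trapezoid AUC summaries.

Two standard summaries of the cortisol response are computed with the
trapezoid rule over the sampled timepoints:

* AUCg — area under the curve with respect to ground: total output
  over the sampling span.
* AUCi — area of the increase above baseline: AUCg minus the first
  (baseline) sample held constant over the span, so
  ``auci = aucg - c_1 * (t_last - t_first)`` exactly.

Because raw cortisol is positively skewed, summaries are computed on
natural-log concentrations by default; ``log_scale=False`` gives the
raw-scale variant.
"""
from __future__ import annotations

import numpy as np

from .data import CortisolSeries, CortisolSummary

__all__ = [
    "log_transform_cortisol",
    "auc_ground",
    "auc_increase",
    "summarize_cortisol",
]


def log_transform_cortisol(series: CortisolSeries) -> CortisolSeries:
    """Elementwise natural log of the concentrations; timepoints unchanged."""
    if series.log_scale:
        raise ValueError("series is already on the log scale")
    # positivity is enforced by CortisolSeries itself, but give a clear
    # error naming the offending sample if a raw array sneaks through
    bad = np.flatnonzero(series.concentrations <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive concentration at timepoint {series.timepoints[bad[0]]:+g} min"
        )
    return CortisolSeries(
        timepoints=series.timepoints.copy(),
        concentrations=np.log(series.concentrations),
        subject_id=series.subject_id,
        log_scale=True,
    )


def auc_ground(series: CortisolSeries) -> float:
    """Trapezoid area under the concentration curve with respect to ground."""
    if series.n_samples < 2:
        raise ValueError("AUC needs at least 2 samples")
    return float(np.trapezoid(series.concentrations, series.timepoints))


def auc_increase(series: CortisolSeries) -> float:
    """Area of the increase above the baseline (first) sample."""
    aucg = auc_ground(series)
    duration = float(series.timepoints[-1] - series.timepoints[0])
    return aucg - float(series.concentrations[0]) * duration


def summarize_cortisol(series: CortisolSeries, log_scale: bool = True) -> CortisolSummary:
    """AUCg and AUCi for one subject, optionally on the log scale."""
    work = log_transform_cortisol(series) if (log_scale and not series.log_scale) else series
    return CortisolSummary(
        aucg=auc_ground(work), auci=auc_increase(work), log_scale=work.log_scale
    )
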