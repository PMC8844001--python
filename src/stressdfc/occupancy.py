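"""Fractional occupancy of connectivity states and pre/post change scores.

Occupancy is the proportion of a run's retained windows assigned to
each state.  Change scores are simple differences between consecutive
resting-state runs: delta_21 = RS2 - RS1 (the stress effect) and
delta_32 = RS3 - RS2 (recovery).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "fractional_occupancy",
    "occupancy_table",
    "change_scores",
    "RUN_ORDER",
]

logger = logging.getLogger(__name__)

RUN_ORDER = ("RS1", "RS2", "RS3")


def fractional_occupancy(labels: np.ndarray, k: int) -> np.ndarray:
    """Proportion of windows spent in each state (1..k).

    States never visited get exactly 0; the proportions sum to 1.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("label sequence is empty")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in [1, {k}]")
    counts = np.bincount(labels, minlength=k + 1)[1 : k + 1]
    return counts / labels.size


def occupancy_table(
    labels_by_run: dict[tuple[str, str], np.ndarray], k: int
) -> pd.DataFrame:
    """Tidy per-run occupancy: columns (subject, run, state, proportion).

    ``labels_by_run`` maps (subject_id, run_id) to that run's window
    label sequence; state indices are 1-based.
    """
    rows = []
    for (subject, run), labels in sorted(labels_by_run.items()):
        occ = fractional_occupancy(labels, k)
        for s in range(k):
            rows.append(
                {"subject": subject, "run": run, "state": s + 1, "proportion": occ[s]}
            )
    return pd.DataFrame(rows, columns=["subject", "run", "state", "proportion"])


def change_scores(occ: pd.DataFrame) -> pd.DataFrame:
    """Per subject x state change scores delta_21 and delta_32.

    Subjects missing any of the three runs are excluded from the output
    (logged), never imputed as zeros.
    """
    required = {"subject", "run", "state", "proportion"}
    if not required.issubset(occ.columns):
        raise ValueError(f"occupancy table must have columns {sorted(required)}")
    wide = occ.pivot_table(
        index=["subject", "state"], columns="run", values="proportion", aggfunc="first"
    ).reindex(columns=list(RUN_ORDER))
    complete = wide.dropna(subset=list(RUN_ORDER)).index.get_level_values("subject")
    have_all = wide.index.get_level_values("subject").isin(set(complete))
    dropped = sorted(set(wide.index.get_level_values("subject")) - set(complete))
    if dropped:
        logger.warning(
            "excluding %d subject(s) with missing runs from change scores: %s",
            len(dropped),
            ", ".join(map(str, dropped)),
        )
    wide = wide[have_all]
    out = pd.DataFrame(
        {
            "subject": wide.index.get_level_values("subject"),
            "state": wide.index.get_level_values("state"),
            "delta_21": (wide["RS2"] - wide["RS1"]).to_numpy(),
            "delta_32": (wide["RS3"] - wide["RS2"]).to_numpy(),
        }
    ).reset_index(drop=True)
    return out
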