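"""End-to-end orchestration: simulate -> prep -> MTD -> states -> occupancy
-> endocrine -> stats, with deterministic seeding and provenance headers.

Every output table carries ``# config_hash / # seed / # stage`` header
lines; re-running with the same configuration reproduces all stochastic
outputs bit-identically.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .data import CortisolSeries, RoiTimeSeries
from .endocrine import summarize_cortisol
from .io import (
    read_motion,
    read_roi_timeseries,
    read_tsv,
    write_centroids,
    write_motion,
    write_roi_timeseries,
    write_tsv,
    read_centroids,
)
from .mtd import coupling_vectors
from .occupancy import change_scores, occupancy_table
from .prep import discard_initial_frames, interpolate_marked, motion_series, qc_exclusion
from .states import ConnectivityStateModel, match_centroids
from .stats import StressAnalysis
from .synthetic import generate_cohort

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

CORTISOL_COLUMNS = ["cortisol_m30", "cortisol_p00", "cortisol_p20", "cortisol_p60", "cortisol_p90"]
CORTISOL_TIMEPOINTS = np.array([-30.0, 0.0, 20.0, 60.0, 90.0])


class PipelineError(RuntimeError):
    """Structured stage failure."""

    def __init__(self, stage: str, message: str, subject: str | None = None, run: str | None = None):
        self.stage, self.subject, self.run = stage, subject, run
        where = f" (subject={subject}, run={run})" if subject else ""
        super().__init__(f"[{stage}]{where} {message}")


@dataclass
class PipelineResult:
    """Handles to everything a finished run produced."""

    out_dir: Path
    config: AnalysisConfig
    qc: pd.DataFrame
    state_results: object
    occupancy: pd.DataFrame
    deltas: pd.DataFrame
    cortisol: pd.DataFrame
    report: object
    centroid_match: object | None = None
    files: dict[str, Path] = field(default_factory=dict)


def _provenance(config: AnalysisConfig, stage: str) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage": stage,
        "stressdfc_version": __version__,
    }


def _load_inputs(config: AnalysisConfig, out_dir: Path):
    """Return (runs, motion, subjects_df) either simulated or from disk."""
    if config.cohort is not None:
        cohort = generate_cohort(config.cohort, generate_bold=True)
        sim_dir = out_dir / "simulated"
        rows = []
        for rec in cohort.subjects:
            row = {
                "subject": rec.subject_id,
                "ffmq_total": rec.ffmq_total,
                "stress_change": rec.stress_change,
                "alertness_change": rec.alertness_change,
            }
            row.update(dict(zip(CORTISOL_COLUMNS, rec.cortisol.concentrations)))
            rows.append(row)
        subjects = pd.DataFrame(rows)
        prov = _provenance(config, "simulate")
        write_tsv(subjects, sim_dir / "subjects.tsv", prov)
        write_tsv(cohort.ground_truth, sim_dir / "ground_truth.tsv", prov)
        write_tsv(cohort.occupancy_truth, sim_dir / "occupancy_truth.tsv", prov)
        for (sid, run), ts in cohort.bold.items():
            write_roi_timeseries(ts, sim_dir / "runs" / f"{sid}_{run}_bold.tsv", prov)
            write_motion(cohort.motion[(sid, run)], sim_dir / "runs" / f"{sid}_{run}_motion.tsv", prov)
        return cohort.bold, cohort.motion, subjects

    if config.input_dir is None:
        raise PipelineError("validate", "neither a cohort spec nor an input_dir was provided")
    root = Path(config.input_dir)
    runs_dir = root / "runs"
    subjects_path = root / "subjects.tsv"
    if not runs_dir.is_dir() or not subjects_path.is_file():
        raise PipelineError("validate", f"input layout not found under {root} (runs/ + subjects.tsv)")
    subjects = read_tsv(subjects_path)
    runs: dict[tuple[str, str], RoiTimeSeries] = {}
    motion: dict[tuple[str, str], np.ndarray] = {}
    for bold_path in sorted(runs_dir.glob("*_bold.tsv")):
        sid, run = bold_path.stem.removesuffix("_bold").rsplit("_", 1)
        runs[(sid, run)] = read_roi_timeseries(bold_path)
        motion_path = bold_path.with_name(bold_path.name.replace("_bold", "_motion"))
        if not motion_path.is_file():
            raise PipelineError("validate", f"missing motion file {motion_path}", sid, run)
        motion[(sid, run)] = read_motion(motion_path)
    if not runs:
        raise PipelineError("validate", f"no *_bold.tsv runs found in {runs_dir}")
    return runs, motion, subjects


def run_pipeline(config: AnalysisConfig, out_dir: str | Path) -> PipelineResult:
    """Execute all stages in fixed order and write every table under
    ``out_dir``.  Deterministic for a fixed configuration."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    files: dict[str, Path] = {}

    runs, motion, subjects = _load_inputs(config, out_dir)

    # ---- prep: discard, FD/DVARS, mark, interpolate, QC ------------------
    qc_rows = []
    prepped: dict[tuple[str, str], RoiTimeSeries] = {}
    for (sid, run), ts in sorted(runs.items()):
        try:
            ts_d = discard_initial_frames(ts, config.discard_frames)
            params = motion[(sid, run)][config.discard_frames :]
            ms = motion_series(
                params,
                ts_d,
                fd_threshold=config.fd_threshold_mm,
                dvars_threshold=config.dvars_threshold_pct,
                extend_before=config.extend_before,
                extend_after=config.extend_after,
            )
            passed, fraction = qc_exclusion(ms.high_motion_mask, config.max_marked_fraction)
            if ms.high_motion_mask.any():
                ts_d = interpolate_marked(ts_d, ms.high_motion_mask)
            prepped[(sid, run)] = ts_d
            qc_rows.append(
                {
                    "subject": sid,
                    "run": run,
                    "fraction_marked": fraction,
                    "mean_fd": float(ms.fd.mean()),
                    "pass": passed,
                }
            )
        except Exception as err:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError("prep", str(err), sid, run) from err
    qc = pd.DataFrame(qc_rows)
    files["qc"] = out_dir / "qc.tsv"
    write_tsv(qc, files["qc"], _provenance(config, "prep"))

    passing = {(r["subject"], r["run"]) for _, r in qc.iterrows() if r["pass"]}
    excluded_subjects = {s for (s, _r) in prepped if (s, _r) not in passing}

    # ---- MTD coupling vectors -------------------------------------------
    vectors_by_run: dict[tuple[str, str], np.ndarray] = {}
    for key in sorted(prepped):
        if key not in passing or key[0] in excluded_subjects:
            continue
        try:
            vectors_by_run[key] = coupling_vectors(prepped[key], w=config.window)
        except Exception as err:  # noqa: BLE001
            raise PipelineError("mtd", str(err), key[0], key[1]) from err

    if not vectors_by_run:
        raise PipelineError("mtd", "no runs survived QC")

    # ---- state clustering ------------------------------------------------
    keys = sorted(vectors_by_run)
    stacked = np.vstack([vectors_by_run[k] for k in keys])
    try:
        model = ConnectivityStateModel(stacked, k=config.k, n_restarts=config.n_restarts)
        state_results = model.fit(seed=config.seed)
    except Exception as err:  # noqa: BLE001
        raise PipelineError("fit-states", str(err)) from err
    files["centroids"] = out_dir / "centroids.tsv"
    write_centroids(state_results.centroids, files["centroids"], _provenance(config, "fit-states"))

    label_rows = []
    labels_by_run: dict[tuple[str, str], np.ndarray] = {}
    offset = 0
    for key in keys:
        n = vectors_by_run[key].shape[0]
        lab = state_results.labels[offset : offset + n]
        labels_by_run[key] = lab
        offset += n
        label_rows.extend(
            {"subject": key[0], "run": key[1], "window_index": m + 1, "state": int(s)}
            for m, s in enumerate(lab)
        )
    files["labels"] = out_dir / "labels.tsv"
    write_tsv(pd.DataFrame(label_rows), files["labels"], _provenance(config, "fit-states"))

    centroid_match = None
    if config.reference_centroids:
        reference = read_centroids(config.reference_centroids)
        centroid_match = state_results.match(reference)
        match_df = pd.DataFrame(
            [
                {"state": a, "reference_state": b, "rho": rho}
                for (a, b), rho in zip(centroid_match.mapping, centroid_match.rho)
            ]
        )
        files["centroid_match"] = out_dir / "centroid_match.tsv"
        write_tsv(match_df, files["centroid_match"], _provenance(config, "fit-states"))

    # ---- occupancy + change scores --------------------------------------
    occ = occupancy_table(labels_by_run, k=config.k)
    deltas = change_scores(occ)
    files["occupancy"] = out_dir / "occupancy.tsv"
    files["deltas"] = out_dir / "deltas.tsv"
    write_tsv(occ, files["occupancy"], _provenance(config, "occupancy"))
    write_tsv(deltas, files["deltas"], _provenance(config, "occupancy"))

    # ---- endocrine -------------------------------------------------------
    cort_rows = []
    for _, row in subjects.iterrows():
        conc = row.reindex(CORTISOL_COLUMNS).to_numpy(dtype=float)
        if np.isnan(conc).any():
            logger.warning("subject %s: incomplete cortisol series; skipped", row["subject"])
            continue
        series = CortisolSeries(
            timepoints=CORTISOL_TIMEPOINTS, concentrations=conc, subject_id=str(row["subject"])
        )
        summ = summarize_cortisol(series, log_scale=config.auc_log_scale)
        cort_rows.append({"subject": row["subject"], "aucg": summ.aucg, "auci": summ.auci})
    cortisol = pd.DataFrame(cort_rows, columns=["subject", "aucg", "auci"])
    files["cortisol"] = out_dir / "cortisol.tsv"
    write_tsv(cortisol, files["cortisol"], _provenance(config, "endocrine"))

    # ---- statistical report ---------------------------------------------
    subj_table = subjects.merge(cortisol, on="subject", how="left")
    subj_table["qc_pass"] = ~subj_table["subject"].isin(excluded_subjects)
    # TRS/HAS/LAS naming: via reference-centroid matching when a reference
    # was supplied (reference rows ordered TRS, HAS, LAS, ...); otherwise
    # fitted states 1-3 stand in positionally.
    named_states = {"TRS": 1, "HAS": 2, "LAS": 3}
    if centroid_match is not None:
        to_fitted = {b: a for a, b in centroid_match.mapping}
        if {1, 2, 3} <= set(to_fitted):
            named_states = {"TRS": to_fitted[1], "HAS": to_fitted[2], "LAS": to_fitted[3]}
    try:
        analysis = StressAnalysis(
            occ, subj_table, named_states=named_states, adjust_method=config.adjust_method
        )
        report = analysis.fit()
    except Exception as err:  # noqa: BLE001
        raise PipelineError("stats", str(err)) from err
    files["report"] = out_dir / "report.tsv"
    write_tsv(report.table, files["report"], _provenance(config, "stats"))
    files["report_json"] = out_dir / "report.json"
    with open(files["report_json"], "w") as fh:
        json.dump(
            {"config_hash": config.config_hash(), "edges": report.edge_list()},
            fh,
            indent=2,
        )
    (out_dir / "summary.txt").write_text(report.summary() + "\n")

    return PipelineResult(
        out_dir=out_dir,
        config=config,
        qc=qc,
        state_results=state_results,
        occupancy=occ,
        deltas=deltas,
        cortisol=cortisol,
        report=report,
        centroid_match=centroid_match,
        files=files,
    )
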