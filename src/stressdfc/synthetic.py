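"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a three-run acute-stress resting-state design:
each subject contributes one pre-stress run (RS1) and two post-stress
runs (RS2, RS3) of covariance-switching BOLD whose window-level
connectivity alternates among k centroid patterns.  The stress effect
is a subject-level drop in the occupancy of a designated state between
RS1 and RS2; trait-mindfulness scores and cortisol output are generated
with specified correlations to that latent drop, and motion spikes are
injected into both the rigid-body trace and the signal.

All generators are pure functions of their seed.  Defaults mirror the
study design this package targets: 40 subjects, 3 runs of 300 volumes
at TR = 2 s, 114 ROIs, 5 states.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    DEFAULT_CORTISOL_TIMEPOINTS,
    CortisolSeries,
    RoiTimeSeries,
    SubjectRecord,
)

__all__ = [
    "CentroidSet",
    "StateSequence",
    "CohortSpec",
    "Cohort",
    "generate_centroids",
    "generate_state_sequence",
    "generate_bold_run",
    "generate_cortisol_series",
    "generate_cohort",
    "window_labels",
    "nearest_correlation",
]

DEFAULT_STATE_NAMES = ("TRS", "HAS", "LAS", "S4", "S5")


def nearest_correlation(matrix: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix
    (eigenvalue clipping followed by diagonal renormalisation)."""
    sym = (matrix + matrix.T) / 2.0
    w, v = np.linalg.eigh(sym)
    fixed = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


@dataclass
class CentroidSet:
    """k symmetric correlation-structured connectivity patterns."""

    matrices: np.ndarray  # (k, n_roi, n_roi)
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be (k, n_roi, n_roi)")
        if not self.names:
            self.names = [f"state_{s + 1}" for s in range(self.k)]

    @property
    def k(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_roi(self) -> int:
        return self.matrices.shape[1]

    def upper_vectors(self) -> np.ndarray:
        """(k, n_roi*(n_roi-1)/2) vectorised upper triangles."""
        iu = np.triu_indices(self.n_roi, k=1)
        return self.matrices[:, iu[0], iu[1]]

    def pairwise_spearman(self) -> np.ndarray:
        from scipy.stats import spearmanr

        vecs = self.upper_vectors()
        out = np.eye(self.k)
        for i in range(self.k):
            for j in range(i + 1, self.k):
                out[i, j] = out[j, i] = spearmanr(vecs[i], vecs[j]).statistic
        return out


def generate_centroids(
    k: int,
    n_roi: int,
    seed: int,
    n_factors: int = 3,
    identity_blend: float = 0.1,
    max_pairwise_rho: float = 0.95,
) -> CentroidSet:
    """Draw k distinct correlation-structured connectivity centroids.

    Each centroid is built from a low-rank random factor model
    (``n_factors`` latent factors), blended with the identity for
    conditioning, and projected to the nearest correlation matrix.
    Redraws any centroid whose pattern overlaps an earlier one beyond
    ``max_pairwise_rho`` Spearman concordance.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_roi < 4:
        raise ValueError("n_roi must be >= 4")
    from scipy.stats import spearmanr

    root = np.random.SeedSequence(seed)
    iu = np.triu_indices(n_roi, k=1)
    matrices: list[np.ndarray] = []
    vecs: list[np.ndarray] = []
    stream = iter(root.spawn(20 * k))
    for _ in range(k):
        for _attempt in range(20):
            rng = np.random.default_rng(next(stream))
            loadings = rng.normal(size=(n_roi, n_factors))
            cov = loadings @ loadings.T
            d = np.sqrt(np.diag(cov))
            corr = cov / np.outer(d, d)
            corr = (1.0 - identity_blend) * corr + identity_blend * np.eye(n_roi)
            corr = nearest_correlation(corr)
            vec = corr[iu]
            if all(abs(spearmanr(vec, v).statistic) < max_pairwise_rho for v in vecs):
                matrices.append(corr)
                vecs.append(vec)
                break
        else:  # pragma: no cover - astronomically unlikely with random factors
            raise RuntimeError("could not draw sufficiently distinct centroids")
    names = list(DEFAULT_STATE_NAMES[:k]) if k <= len(DEFAULT_STATE_NAMES) else []
    return CentroidSet(matrices=np.stack(matrices), names=names)


@dataclass
class StateSequence:
    """Blockwise state-label sequence with its generating targets."""

    labels: np.ndarray
    dwell_lengths: np.ndarray
    target_occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.dwell_lengths = np.asarray(self.dwell_lengths, dtype=int)
        self.target_occupancy = np.asarray(self.target_occupancy, dtype=float)
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels out of range")
        if np.any(self.dwell_lengths < 1):
            raise ValueError("dwell lengths must be >= 1")

    @property
    def k(self) -> int:
        return len(self.target_occupancy)

    @property
    def n(self) -> int:
        return len(self.labels)

    def empirical_occupancy(self) -> np.ndarray:
        counts = np.bincount(self.labels, minlength=self.k + 1)[1 : self.k + 1]
        return counts / self.n


def generate_state_sequence(
    n_windows: int,
    target_occupancy: np.ndarray,
    mean_dwell: float,
    seed: int,
) -> StateSequence:
    """Blockwise sequence with geometric dwell lengths and quota-guided
    state choice, so empirical occupancy tracks the target closely.

    Block states are sampled with probability proportional to each
    state's remaining occupancy quota, which bounds the deviation of the
    empirical occupancy by roughly one block length.
    """
    target = np.asarray(target_occupancy, dtype=float)
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if np.any(target < 0) or abs(target.sum() - 1.0) > 1e-9:
        raise ValueError("target occupancy must be non-negative and sum to 1")
    if mean_dwell < 1:
        raise ValueError("mean_dwell must be >= 1")
    k = len(target)
    rng = np.random.default_rng(seed)
    labels = np.empty(n_windows, dtype=int)
    dwells: list[int] = []
    remaining = target * n_windows
    pos = 0
    while pos < n_windows:
        length = int(rng.geometric(1.0 / mean_dwell))
        length = min(length, n_windows - pos)
        quota = np.clip(remaining, 0.0, None)
        probs = quota / quota.sum() if quota.sum() > 0 else target
        state = int(rng.choice(k, p=probs))
        labels[pos : pos + length] = state + 1
        remaining[state] -= length
        dwells.append(length)
        pos += length
    return StateSequence(
        labels=labels, dwell_lengths=np.array(dwells), target_occupancy=target
    )


def window_labels(volume_labels: np.ndarray, w: int) -> np.ndarray:
    """Ground-truth state per retained MTD window.

    Window m of the MTD stage averages derivative products touching
    volumes m+1 .. m+w+1 (0-based); its ground-truth label is the
    majority state over those volumes, ties toward the lowest index.
    """
    volume_labels = np.asarray(volume_labels, dtype=int)
    n_vol = len(volume_labels)
    n_win = n_vol - 1 - w
    if n_win < 1:
        raise ValueError("run too short for this window size")
    out = np.empty(n_win, dtype=int)
    for m in range(n_win):
        out[m] = np.bincount(volume_labels[m + 1 : m + w + 2]).argmax()
    return out


def generate_bold_run(
    sequence: StateSequence,
    centroids: CentroidSet,
    noise_sd: float,
    seed: int,
    baseline: float = 1000.0,
    tr_seconds: float = 2.0,
    subject_id: str | None = None,
    run_id: str | None = None,
) -> RoiTimeSeries:
    """Covariance-switching BOLD: each volume is drawn from a zero-mean
    multivariate normal whose correlation matrix is the active state's
    centroid, plus independent noise and a constant baseline offset.

    The baseline (default 1000 a.u., a typical scanner scale) keeps
    percent-based QC metrics meaningful downstream.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if sequence.k > centroids.k:
        raise ValueError("sequence refers to more states than centroids provided")
    n_roi = centroids.n_roi
    transforms = []
    for s in range(centroids.k):
        w, v = np.linalg.eigh(centroids.matrices[s])
        if w.min() < -1e-8:
            raise ValueError(f"centroid {s + 1} is not positive semidefinite")
        transforms.append(v * np.sqrt(np.clip(w, 0.0, None)))
    rng = np.random.default_rng(seed)
    t = sequence.n
    z = rng.standard_normal((t, n_roi))
    noise = rng.standard_normal((t, n_roi))
    values = np.empty((t, n_roi))
    for s in range(1, centroids.k + 1):
        rows = sequence.labels == s
        if rows.any():
            values[rows] = z[rows] @ transforms[s - 1].T
    values += noise_sd * noise + baseline
    return RoiTimeSeries(
        values=values,
        tr_seconds=tr_seconds,
        subject_id=subject_id,
        run_id=run_id,
    )


def generate_cortisol_series(
    baseline: float,
    peak_delta: float,
    timepoints: np.ndarray = DEFAULT_CORTISOL_TIMEPOINTS,
    noise_sd: float = 0.0,
    seed: int = 0,
    peak_time_min: float = 30.0,
    subject_id: str | None = None,
) -> CortisolSeries:
    """Gamma-shaped stress response with multiplicative log-normal noise.

    Concentration is ``baseline`` before onset, rising after time 0 as
    ``peak_delta * (t/tp) * exp(1 - t/tp)`` (peak at ``tp`` minutes) and
    decaying back toward baseline.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(timepoints) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if baseline <= 0:
        raise ValueError("baseline concentration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rel = np.clip(timepoints / peak_time_min, 0.0, None)
    response = np.where(timepoints > 0, rel * np.exp(1.0 - rel), 0.0)
    conc = (baseline + peak_delta * response) * np.exp(
        rng.normal(0.0, noise_sd, size=len(timepoints))
    )
    return CortisolSeries(
        timepoints=timepoints, concentrations=conc, subject_id=subject_id
    )


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults correspond to the targeted design: 40 subjects, three runs
    of 300 volumes at TR 2 s over 114 ROIs, five states with a
    pre-to-post occupancy drop in the designated (task-ready-like)
    state, and subject-level couplings between that drop, the trait
    score and cortisol output.
    """

    n_subjects: int = 40
    runs_per_subject: int = 3
    volumes_per_run: int = 300
    tr_seconds: float = 2.0
    n_roi: int = 114
    k: int = 5
    state_names: tuple[str, ...] = DEFAULT_STATE_NAMES
    occupancy_pre: tuple[float, ...] = (0.30, 0.20, 0.20, 0.15, 0.15)
    occupancy_post: tuple[float, ...] = (0.18, 0.26, 0.26, 0.15, 0.15)
    designated_state: int = 1
    delta_sd: float = 0.10
    r_trait_delta: float = 0.32
    r_cortisol_delta: float = -0.33
    r_trait_stress: float = -0.41
    noise_sd: float = 0.5
    mean_dwell_volumes: float = 30.0
    motion_spike_rate: float = 0.01
    motion_jitter_mm: float = 0.06  # approximate mean framewise displacement
    cortisol_baseline_ug_dl: float = 0.18
    cortisol_peak_gain: float = 1.5
    cortisol_noise_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        # normalise sequence fields so YAML round-trips compare equal
        self.state_names = tuple(self.state_names)
        self.occupancy_pre = tuple(float(x) for x in self.occupancy_pre)
        self.occupancy_post = tuple(float(x) for x in self.occupancy_post)
        for name in ("n_subjects", "runs_per_subject", "volumes_per_run", "n_roi", "k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for occ in (self.occupancy_pre, self.occupancy_post):
            arr = np.asarray(occ, dtype=float)
            if len(arr) != self.k:
                raise ValueError("occupancy vectors must have length k")
            if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError("occupancies must be non-negative and sum to 1")
        for name in ("r_trait_delta", "r_cortisol_delta", "r_trait_stress"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie strictly in (-1, 1)")
        if not 1 <= self.designated_state <= self.k:
            raise ValueError("designated_state must lie in [1, k]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _reweight_occupancy(base: np.ndarray, idx: int, value: float) -> np.ndarray:
    """Set state ``idx`` occupancy to ``value`` and rescale the rest."""
    out = np.asarray(base, dtype=float).copy()
    value = float(np.clip(value, 0.02, 0.90))
    others = np.delete(out, idx)
    out[idx] = value
    scale = (1.0 - value) / others.sum()
    j = 0
    for s in range(len(out)):
        if s != idx:
            out[s] = others[j] * scale
            j += 1
    return out


@dataclass
class Cohort:
    """A generated cohort: subjects, sequences, optional BOLD + motion,
    and the ground-truth tables needed for recovery tests."""

    spec: CohortSpec
    centroids: CentroidSet
    subjects: list[SubjectRecord]
    sequences: dict[tuple[str, str], StateSequence]
    bold: dict[tuple[str, str], RoiTimeSeries]
    motion: dict[tuple[str, str], np.ndarray]
    ground_truth: pd.DataFrame
    occupancy_truth: pd.DataFrame
    occupancy_targets: pd.DataFrame

    @property
    def run_ids(self) -> list[str]:
        return [f"RS{r + 1}" for r in range(self.spec.runs_per_subject)]

    def subject_table(self, log_scale: bool = True) -> pd.DataFrame:
        """One row per subject with trait, ratings and cortisol AUCs —
        the ``subjects`` input expected by the inferential battery."""
        from .endocrine import summarize_cortisol

        rows = []
        for rec in self.subjects:
            summ = summarize_cortisol(rec.cortisol, log_scale=log_scale)
            rows.append(
                {
                    "subject": rec.subject_id,
                    "ffmq_total": rec.ffmq_total,
                    "stress_change": rec.stress_change,
                    "alertness_change": rec.alertness_change,
                    "aucg": summ.aucg,
                    "auci": summ.auci,
                }
            )
        return pd.DataFrame(rows)

    def window_label_truth(self, w: int = 7, discard: int = 0) -> dict[tuple[str, str], np.ndarray]:
        """Ground-truth per-window labels after ``discard`` initial
        volumes and MTD windowing with window ``w``."""
        return {
            key: window_labels(seq.labels[discard:], w)
            for key, seq in self.sequences.items()
        }


def generate_cohort(spec: CohortSpec, generate_bold: bool = True) -> Cohort:
    """Generate a full cohort from a :class:`CohortSpec`.

    With ``generate_bold=False`` only the latent structure (state
    sequences, trait, cortisol, ratings, ground truth) is produced —
    the fast path for statistical calibration studies.
    """
    rng_master = np.random.default_rng(spec.seed)
    seed_of = lambda: int(rng_master.integers(0, 2**31 - 1))  # noqa: E731

    centroids = generate_centroids(spec.k, spec.n_roi, seed=seed_of())
    rng_subj = np.random.default_rng(seed_of())
    d = spec.designated_state - 1
    pre = np.asarray(spec.occupancy_pre, dtype=float)
    post = np.asarray(spec.occupancy_post, dtype=float)

    subjects: list[SubjectRecord] = []
    sequences: dict[tuple[str, str], StateSequence] = {}
    bold: dict[tuple[str, str], RoiTimeSeries] = {}
    motion: dict[tuple[str, str], np.ndarray] = {}
    gt_rows = []
    occ_rows = []
    target_rows = []
    run_ids = [f"RS{r + 1}" for r in range(spec.runs_per_subject)]

    for i in range(spec.n_subjects):
        sid = f"sub-{i + 1:03d}"
        z_delta = rng_subj.standard_normal()
        r1, r2, r3 = spec.r_trait_delta, spec.r_cortisol_delta, spec.r_trait_stress
        trait_z = r1 * z_delta + np.sqrt(1 - r1**2) * rng_subj.standard_normal()
        cort_z = r2 * z_delta + np.sqrt(1 - r2**2) * rng_subj.standard_normal()
        stress_z = r3 * trait_z + np.sqrt(1 - r3**2) * rng_subj.standard_normal()
        ffmq = int(np.clip(round(117 + 20 * trait_z), 39, 195))
        stress_change = float(np.clip(round(3.0 + 1.8 * stress_z), -9, 9))
        alertness_change = float(np.clip(round(0.8 * rng_subj.standard_normal()), -9, 9))

        occ_run2 = _reweight_occupancy(post, d, post[d] + spec.delta_sd * z_delta)
        latent_delta = occ_run2[d] - pre[d]
        targets = {"RS1": pre, "RS2": occ_run2, "RS3": occ_run2}

        baseline_c = spec.cortisol_baseline_ug_dl * np.exp(
            0.10 * rng_subj.standard_normal()
        )
        peak_delta = baseline_c * spec.cortisol_peak_gain * np.exp(0.5 * cort_z)
        cortisol = generate_cortisol_series(
            baseline=baseline_c,
            peak_delta=peak_delta,
            noise_sd=spec.cortisol_noise_sd,
            seed=seed_of(),
            subject_id=sid,
        )
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                ffmq_total=ffmq,
                stress_change=stress_change,
                alertness_change=alertness_change,
                cortisol=cortisol,
            )
        )
        gt_rows.append(
            {
                "subject": sid,
                "z_delta": z_delta,
                "latent_delta": latent_delta,
                "trait_z": trait_z,
                "cortisol_z": cort_z,
                "ffmq_total": ffmq,
                "stress_change": stress_change,
                "alertness_change": alertness_change,
                "target_occ_run2": occ_run2[d],
            }
        )

        for run in run_ids[: spec.runs_per_subject]:
            seq = generate_state_sequence(
                spec.volumes_per_run,
                targets.get(run, occ_run2),
                spec.mean_dwell_volumes,
                seed=seed_of(),
            )
            sequences[(sid, run)] = seq
            emp = seq.empirical_occupancy()
            tgt = targets.get(run, occ_run2)
            for s in range(spec.k):
                occ_rows.append(
                    {"subject": sid, "run": run, "state": s + 1, "proportion": emp[s]}
                )
                target_rows.append(
                    {"subject": sid, "run": run, "state": s + 1, "proportion": tgt[s]}
                )
            if generate_bold:
                run_seed = seed_of()
                ts = generate_bold_run(
                    seq,
                    centroids,
                    noise_sd=spec.noise_sd,
                    seed=run_seed,
                    tr_seconds=spec.tr_seconds,
                    subject_id=sid,
                    run_id=run,
                )
                rng_run = np.random.default_rng(seed_of())
                params = np.cumsum(
                    rng_run.normal(
                        0.0,
                        spec.motion_jitter_mm / 6.0,
                        size=(spec.volumes_per_run, 6),
                    )
                    * np.array([1, 1, 1, 1 / 50.0, 1 / 50.0, 1 / 50.0]),
                    axis=0,
                )
                spikes = np.flatnonzero(
                    rng_run.random(spec.volumes_per_run) < spec.motion_spike_rate
                )
                spikes = spikes[spikes > 0]
                if spikes.size:
                    params[spikes, 0] += 0.5
                    glitch = rng_run.normal(0.0, 60.0, size=(spikes.size, spec.n_roi))
                    ts.values[spikes] += glitch
                bold[(sid, run)] = ts
                motion[(sid, run)] = params
            else:
                # keep the master seed stream identical either way
                seed_of(), seed_of()

    return Cohort(
        spec=spec,
        centroids=centroids,
        subjects=subjects,
        sequences=sequences,
        bold=bold,
        motion=motion,
        ground_truth=pd.DataFrame(gt_rows),
        occupancy_truth=pd.DataFrame(
            occ_rows, columns=["subject", "run", "state", "proportion"]
        ),
        occupancy_targets=pd.DataFrame(
            target_rows, columns=["subject", "run", "state", "proportion"]
        ),
    )
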