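"""Inferential battery for the stress / mindfulness / connectivity study.

Pre-planned paired t-tests on state occupancy (RS1 vs RS2, RS2 vs RS3),
Pearson correlations linking occupancy change scores to subjective
ratings, cortisol summaries and trait mindfulness, Spearman rank
correlations, and family-wise p-value adjustment (Holm by default,
Bonferroni available).  Alpha is 0.05 two-tailed throughout.

The battery is exposed statsmodels-style: build a
:class:`StressAnalysis` from an occupancy table and a subject table,
call :meth:`StressAnalysis.fit`, and read the
:class:`StressAnalysisResults` table / summary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data import DegenerateDataError

__all__ = [
    "FFMQ_REVERSE_ITEMS",
    "StatResult",
    "score_ffmq",
    "paired_ttest",
    "pearson_corr",
    "spearman_corr",
    "adjust_pvalues",
    "StressAnalysis",
    "StressAnalysisResults",
]

logger = logging.getLogger(__name__)

# 39-item five-facet mindfulness questionnaire: items keyed in reverse
# belong to the Non-Judging and Acting-with-Awareness facets.
FFMQ_REVERSE_ITEMS = frozenset({3, 5, 8, 10, 13, 14, 17, 18, 23, 25, 28, 30, 34, 35, 38, 39})


def score_ffmq(items, reverse_set=FFMQ_REVERSE_ITEMS) -> int:
    """Full-scale FFMQ score from 39 item responses (1..5 Likert).

    Reverse-keyed items are mapped x -> 6 - x before summation; the
    full-scale score therefore lies in [39, 195].
    """
    items = np.asarray(items, dtype=float)
    if items.shape != (39,):
        raise ValueError(f"expected exactly 39 item responses, got {items.shape}")
    if np.any((items < 1) | (items > 5)) or np.any(items != np.round(items)):
        raise ValueError("item responses must be integers in 1..5")
    reverse = np.zeros(39, dtype=bool)
    for idx in reverse_set:
        if not 1 <= idx <= 39:
            raise ValueError(f"reverse item index {idx} out of range 1..39")
        reverse[idx - 1] = True
    scored = np.where(reverse, 6 - items, items)
    return int(scored.sum())


@dataclass
class StatResult:
    """One row of the inferential report."""

    name: str
    kind: str          # "paired_t", "pearson", "spearman"
    estimate: float    # t, r or rho
    df: float          # degrees of freedom (t, pearson) or n (spearman)
    n: int
    p: float
    p_adjusted: float | None = None
    family: str | None = None

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> bool:
        p = self.p_adjusted if (adjusted and self.p_adjusted is not None) else self.p
        return p < alpha


def paired_ttest(x, y, name: str = "paired_t") -> StatResult:
    """Two-sided paired-samples t-test (t on differences, n-1 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if len(x) < 3:
        raise ValueError("paired t-test needs at least 3 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing pairs are not allowed; filter first")
    d = x - y
    if np.ptp(d) == 0:
        raise DegenerateDataError("differences have zero variance")
    res = sps.ttest_rel(x, y)
    return StatResult(
        name=name,
        kind="paired_t",
        estimate=float(res.statistic),
        df=float(len(x) - 1),
        n=len(x),
        p=float(res.pvalue),
    )


def pearson_corr(x, y, name: str = "pearson") -> StatResult:
    """Pearson correlation with two-sided p via the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in one of the variables")
    res = sps.pearsonr(x, y)
    return StatResult(
        name=name,
        kind="pearson",
        estimate=float(res.statistic),
        df=float(len(x) - 2),
        n=len(x),
        p=float(res.pvalue),
    )


def spearman_corr(x, y, name: str = "spearman") -> StatResult:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("all-tied vector; ranks undefined")
    res = sps.spearmanr(x, y)
    return StatResult(
        name=name,
        kind="spearman",
        estimate=float(res.statistic),
        df=float(len(x)),
        n=len(x),
        p=float(res.pvalue),
    )


def adjust_pvalues(pvalues, method: str = "holm") -> np.ndarray:
    """Family-wise adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method not in {"holm", "bonferroni"}:
        raise ValueError("method must be 'holm' or 'bonferroni'")
    return multipletests(p, method=method)[1]


class StressAnalysis:
    """The study's pre-planned inferential battery as a fitted model.

    Parameters
    ----------
    occupancy : tidy per-run occupancy table with columns
        (subject, run, state, proportion), runs RS1/RS2/RS3.
    subjects : one row per subject with columns ``subject`` and any of
        ``ffmq_total``, ``stress_change``, ``alertness_change``,
        ``aucg``, ``auci``, ``qc_pass``.  Missing values stay missing;
        each test uses its pairwise-complete subjects.
    named_states : mapping from the three analysed state names
        ("TRS", "HAS", "LAS") to 1-based state indices.
    """

    CORTISOL_FAMILY = "cortisol_x_states"   # the six cortisol-state tests
    FFMQ_FAMILY = "ffmq_x_states"           # the three trait-state tests

    def __init__(
        self,
        occupancy: pd.DataFrame,
        subjects: pd.DataFrame,
        named_states: dict[str, int] | None = None,
        alpha: float = 0.05,
        adjust_method: str = "holm",
    ) -> None:
        self.occupancy = occupancy.copy()
        self.subjects = subjects.copy()
        self.named_states = named_states or {"TRS": 1, "HAS": 2, "LAS": 3}
        if set(self.named_states) != {"TRS", "HAS", "LAS"}:
            raise ValueError("named_states must map exactly TRS, HAS and LAS")
        self.alpha = alpha
        self.adjust_method = adjust_method
        if "qc_pass" in self.subjects.columns:
            n_fail = int((~self.subjects["qc_pass"].astype(bool)).sum())
            if n_fail:
                logger.info("excluding %d subject(s) failing QC", n_fail)
            self.subjects = self.subjects[self.subjects["qc_pass"].astype(bool)]

    @classmethod
    def from_cohort_tables(cls, occupancy, subjects, **kwargs) -> "StressAnalysis":
        return cls(occupancy, subjects, **kwargs)

    # -- variable assembly -------------------------------------------------

    def _variables(self) -> pd.DataFrame:
        from .occupancy import change_scores

        keep = self.occupancy[
            self.occupancy["subject"].isin(self.subjects["subject"])
        ]
        deltas = change_scores(keep)
        wide = {}
        for label, state in self.named_states.items():
            sub = deltas[deltas["state"] == state].set_index("subject")
            wide[f"delta21_{label}"] = sub["delta_21"]
            wide[f"delta32_{label}"] = sub["delta_32"]
            for run in ("RS1", "RS2", "RS3"):
                occ = keep[(keep["state"] == state) & (keep["run"] == run)]
                wide[f"occ_{run}_{label}"] = occ.set_index("subject")["proportion"]
        df = pd.DataFrame(wide)
        return df.join(self.subjects.set_index("subject"), how="left")

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "StressAnalysisResults":
        """Run every pre-planned test and adjust within families."""
        data = self._variables()
        rows: list[StatResult] = []

        def add(fn, cols, name, family=None, kind_kwargs=None):
            pair = data[list(cols)].dropna()
            if len(pair) < 3:
                logger.warning("skipping %s: only %d complete subjects", name, len(pair))
                return
            try:
                res = fn(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy(), name=name)
            except DegenerateDataError as err:
                logger.warning("skipping %s: %s", name, err)
                return
            rows.append(replace(res, family=family))

        # pre-planned paired t-tests on the three named states
        for label in ("TRS", "HAS", "LAS"):
            add(paired_ttest, (f"occ_RS2_{label}", f"occ_RS1_{label}"),
                f"ttest_{label}_RS2_vs_RS1")
            add(paired_ttest, (f"occ_RS3_{label}", f"occ_RS2_{label}"),
                f"ttest_{label}_RS3_vs_RS2")

        # subjective change vs arousal-state changes
        for rating in ("stress_change", "alertness_change"):
            for label in ("HAS", "LAS"):
                if rating in data.columns:
                    add(pearson_corr, (rating, f"delta21_{label}"),
                        f"corr_{rating}_delta{label}")

        # cortisol output vs state changes: the six-test family
        for auc in ("aucg", "auci"):
            for label in ("TRS", "HAS", "LAS"):
                if auc in data.columns:
                    add(pearson_corr, (auc, f"delta21_{label}"),
                        f"corr_{auc}_delta{label}", family=self.CORTISOL_FAMILY)

        # trait mindfulness: baseline TRS, then the three-test family
        if "ffmq_total" in data.columns:
            add(pearson_corr, ("ffmq_total", "occ_RS1_TRS"), "corr_ffmq_baselineTRS")
            for label in ("TRS", "HAS", "LAS"):
                add(pearson_corr, ("ffmq_total", f"delta21_{label}"),
                    f"corr_ffmq_delta{label}", family=self.FFMQ_FAMILY)

        # coupling among the named states' change scores
        for a, b in (("HAS", "LAS"), ("HAS", "TRS"), ("LAS", "TRS")):
            add(pearson_corr, (f"delta21_{a}", f"delta21_{b}"),
                f"corr_delta{a}_delta{b}")

        # family-wise adjustment; tests outside a family keep their raw p
        by_family: dict[str, list[int]] = {}
        for i, r in enumerate(rows):
            if r.family is not None:
                by_family.setdefault(r.family, []).append(i)
        for indices in by_family.values():
            adj = adjust_pvalues([rows[i].p for i in indices], self.adjust_method)
            for i, p_adj in zip(indices, adj):
                rows[i] = replace(rows[i], p_adjusted=float(p_adj))
        for i, r in enumerate(rows):
            if r.p_adjusted is None:
                rows[i] = replace(r, p_adjusted=r.p)

        return StressAnalysisResults(
            results=rows,
            alpha=self.alpha,
            adjust_method=self.adjust_method,
            n_subjects=int(self.subjects["subject"].nunique()),
            data=data,
        )


@dataclass
class StressAnalysisResults:
    """Fitted inferential battery; ``table`` is the tidy report."""

    results: list[StatResult]
    alpha: float
    adjust_method: str
    n_subjects: int
    data: pd.DataFrame

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "test": r.name,
                    "kind": r.kind,
                    "estimate": r.estimate,
                    "df": r.df,
                    "n": r.n,
                    "p": r.p,
                    "p_adjusted": r.p_adjusted,
                    "family": r.family if r.family is not None else "none",
                }
                for r in self.results
            ]
        )

    def __getitem__(self, name: str) -> StatResult:
        for r in self.results:
            if r.name == name:
                return r
        raise KeyError(name)

    def edge_list(self) -> list[dict]:
        """JSON-ready significant-relationship edge list."""
        out = []
        for r in self.results:
            if r.kind != "pearson":
                continue
            stem = r.name.removeprefix("corr_")
            if "_delta" in stem:
                a, _, rest = stem.rpartition("_delta")
                b = "delta" + rest
            else:
                a, _, b = stem.partition("_")
            out.append(
                {
                    "variable_a": a,
                    "variable_b": b,
                    "estimate": r.estimate,
                    "p": r.p,
                    "p_adjusted": r.p_adjusted,
                    "family": r.family,
                    "significant_raw": r.significant(self.alpha),
                }
            )
        return out

    def summary(self) -> str:
        lines = [
            f"Stress / connectivity-state inferential battery "
            f"(n = {self.n_subjects}, alpha = {self.alpha}, "
            f"adjustment = {self.adjust_method})",
            "-" * 78,
            f"{'test':<32}{'kind':<10}{'estimate':>10}{'df':>7}"
            f"{'p':>10}{'p_adj':>10}",
        ]
        for r in self.results:
            star = " *" if r.significant(self.alpha) else ""
            lines.append(
                f"{r.name:<32}{r.kind:<10}{r.estimate:>10.3f}{r.df:>7.0f}"
                f"{r.p:>10.4f}{r.p_adjusted:>10.4f}{star}"
            )
        lines.append("-" * 78)
        lines.append("* raw two-tailed p < alpha")
        return "\n".join(lines)
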