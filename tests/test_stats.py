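"""FFMQ scoring, basic tests, p adjustment and the analysis battery."""
import numpy as np
import pandas as pd
import pytest

from stressdfc import (
    DegenerateDataError,
    StressAnalysis,
    adjust_pvalues,
    paired_ttest,
    pearson_corr,
    score_ffmq,
    spearman_corr,
)
from stressdfc.stats import FFMQ_REVERSE_ITEMS


class TestScoreFfmq:
    def test_midpoint_is_reverse_invariant(self):
        assert score_ffmq([3] * 39) == 117

    def test_maximum_without_reverse_items(self):
        assert score_ffmq([5] * 39, reverse_set=frozenset()) == 195

    def test_hand_scored_mixed_vector(self, rng):
        items = rng.integers(1, 6, size=39)
        reverse = frozenset({1, 5, 22})
        expected = sum(
            (6 - items[i - 1]) if i in reverse else items[i - 1] for i in range(1, 40)
        )
        assert score_ffmq(items, reverse_set=reverse) == expected

    def test_default_reverse_set_flips_16_items(self):
        items = np.full(39, 5)
        # 23 straight items contribute 5, 16 reversed contribute 1
        assert score_ffmq(items) == 23 * 5 + len(FFMQ_REVERSE_ITEMS) * 1

    def test_out_of_range_response_rejected(self):
        bad = [3] * 39
        bad[10] = 6
        with pytest.raises(ValueError):
            score_ffmq(bad)

    def test_wrong_item_count_rejected(self):
        with pytest.raises(ValueError):
            score_ffmq([3] * 38)


class TestBasicTests:
    def test_paired_t_hand_oracle(self):
        # differences (1, 1, 2): mean 4/3, sd 1/sqrt(3), t = 4, df = 2
        res = paired_ttest([2.0, 3.0, 5.0], [1.0, 2.0, 3.0])
        assert res.estimate == pytest.approx(4.0)
        assert res.df == 2

    def test_paired_t_zero_mean_difference(self):
        res = paired_ttest([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert res.estimate == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_paired_t_sign_flip_negates_t(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        a, b = paired_ttest(x, y), paired_ttest(y, x)
        assert a.estimate == pytest.approx(-b.estimate)
        assert a.p == pytest.approx(b.p)

    def test_paired_t_equals_one_sample_on_differences(self, rng):
        from scipy import stats as sps

        x, y = rng.normal(size=15), rng.normal(size=15)
        res = paired_ttest(x, y)
        one = sps.ttest_1samp(x - y, 0.0)
        assert res.estimate == pytest.approx(one.statistic)
        assert res.p == pytest.approx(one.pvalue)

    def test_paired_t_degenerate_differences(self):
        with pytest.raises(DegenerateDataError):
            paired_ttest([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_pearson_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_corr(x, 2 * x + 1).estimate == pytest.approx(1.0)
        assert pearson_corr(x, -x).estimate == pytest.approx(-1.0)

    def test_pearson_matches_covariance_formula(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert pearson_corr(x, y).estimate == pytest.approx(expected, abs=1e-12)

    def test_pearson_constant_input_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_spearman_monotone_invariance(self, rng):
        x = rng.normal(size=15)
        assert spearman_corr(x, np.exp(x)).estimate == pytest.approx(1.0)
        assert spearman_corr(x, -x).estimate == pytest.approx(-1.0)

    def test_spearman_ties_match_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([5.0, 5.0, 7.0, 8.0, 9.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        expected = pearson_corr(avg_ranks(x), avg_ranks(y)).estimate
        assert spearman_corr(x, y).estimate == pytest.approx(expected, abs=1e-12)


class TestAdjustment:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_bonferroni_multiplies_by_family_size(self):
        adj = adjust_pvalues([0.01] + [0.5] * 5, method="bonferroni")
        assert adj[0] == pytest.approx(0.06)

    def test_holm_step_down_hand_oracle(self):
        adj = adjust_pvalues([0.01, 0.02, 0.04], method="holm")
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_holm_never_exceeds_bonferroni(self, rng):
        p = rng.uniform(size=8)
        holm = adjust_pvalues(p, "holm")
        bonf = adjust_pvalues(p, "bonferroni")
        assert np.all(holm <= bonf + 1e-12)
        assert np.all(holm >= p - 1e-12)
        assert np.all(bonf <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])


def make_cohort_tables(n=50, r_trait=0.0, seed=0):
    """Direct occupancy/subject tables with an optionally injected
    trait <-> delta-TRS correlation (independent of the generator)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    trait = 117 + 20 * (r_trait * z + np.sqrt(1 - r_trait**2) * rng.standard_normal(n))
    rows = []
    subj_rows = []
    for i in range(n):
        sid = f"s{i:03d}"
        base = np.array([0.3, 0.2, 0.2, 0.15, 0.15])
        occ1 = base + rng.normal(0, 0.01, 5)
        occ1 = np.abs(occ1) / np.abs(occ1).sum()
        delta = 0.05 * z[i]
        occ2 = occ1.copy()
        occ2[0] += delta
        occ2[1:] -= delta / 4
        occ3 = occ2 + rng.normal(0, 0.005, 5)
        occ3 = np.abs(occ3) / np.abs(occ3).sum()
        for run, occ in (("RS1", occ1), ("RS2", occ2), ("RS3", occ3)):
            rows.extend(
                {"subject": sid, "run": run, "state": s + 1, "proportion": occ[s]}
                for s in range(5)
            )
        subj_rows.append(
            {
                "subject": sid,
                "ffmq_total": trait[i],
                "stress_change": rng.integers(-2, 6),
                "alertness_change": rng.integers(-3, 4),
                "aucg": rng.normal(400, 40),
                "auci": rng.normal(60, 30),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(subj_rows)


class TestAnalysisBattery:
    def test_injected_trait_correlation_recovered(self):
        occ, subj = make_cohort_tables(n=200, r_trait=0.6, seed=4)
        report = StressAnalysis(occ, subj).fit()
        row = report["corr_ffmq_deltaTRS"]
        assert 0.45 <= row.estimate <= 0.72

    def test_all_preplanned_tests_present(self):
        occ, subj = make_cohort_tables(n=40, seed=1)
        report = StressAnalysis(occ, subj).fit()
        names = set(report.table["test"])
        assert {"ttest_TRS_RS2_vs_RS1", "ttest_LAS_RS3_vs_RS2"} <= names
        assert {"corr_aucg_deltaTRS", "corr_auci_deltaLAS"} <= names
        assert {"corr_ffmq_baselineTRS", "corr_ffmq_deltaHAS"} <= names
        assert {"corr_deltaHAS_deltaLAS"} <= names
        fam = report.table.set_index("test")["family"]
        assert (fam.loc[[f"corr_{a}_delta{s}" for a in ("aucg", "auci")
                         for s in ("TRS", "HAS", "LAS")]] == "cortisol_x_states").all()

    def test_adjusted_p_at_least_raw(self):
        occ, subj = make_cohort_tables(n=40, seed=2)
        table = StressAnalysis(occ, subj).fit().table
        assert (table["p_adjusted"] >= table["p"] - 1e-12).all()

    def test_subject_order_invariance(self):
        occ, subj = make_cohort_tables(n=30, seed=3)
        a = StressAnalysis(occ, subj).fit().table
        occ_shuffled = occ.sample(frac=1.0, random_state=7).reset_index(drop=True)
        subj_shuffled = subj.sample(frac=1.0, random_state=8).reset_index(drop=True)
        b = StressAnalysis(occ_shuffled, subj_shuffled).fit().table
        merged = a.merge(b, on="test", suffixes=("_a", "_b"))
        assert np.allclose(merged["estimate_a"], merged["estimate_b"])

    def test_tiny_cohort_skips_everything(self, caplog):
        occ, subj = make_cohort_tables(n=2, seed=5)
        with caplog.at_level("WARNING"):
            report = StressAnalysis(occ, subj).fit()
        assert len(report.results) == 0
        assert "skipping" in caplog.text

    def test_qc_failures_are_excluded(self):
        occ, subj = make_cohort_tables(n=30, seed=6)
        subj["qc_pass"] = True
        subj.loc[:4, "qc_pass"] = False
        report = StressAnalysis(occ, subj).fit()
        assert report.n_subjects == 25
        assert report["corr_ffmq_deltaTRS"].n == 25

    def test_edge_list_names_variables(self):
        occ, subj = make_cohort_tables(n=30, seed=9)
        edges = StressAnalysis(occ, subj).fit().edge_list()
        pairs = {(e["variable_a"], e["variable_b"]) for e in edges}
        assert ("aucg", "deltaTRS") in pairs
        assert ("ffmq", "deltaTRS") in pairs
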