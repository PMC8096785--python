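"""Survival, exact-test and group-comparison tie-outs against hand oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, hypergeom

from immunophen.io import MutationTable
from immunophen.stats import (
    fisher_exact_2x2,
    group_difference_test,
    km_estimate,
    logrank_test,
    mutation_frequency_table,
    tumor_mutation_burden,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def fisher_two_sided_oracle(table):
    """Full hypergeometric enumeration: sum of all table probabilities not
    exceeding the observed table's probability."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = hypergeom.pmf(x, n, row1, col1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def logrank_two_group_oracle(times, events, groups):
    """Hand tabulation of observed-minus-expected at each event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    gs = np.unique(groups)
    assert len(gs) == 2
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == gs[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == gs[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_all_censored_stays_at_one(self):
        s = km_estimate([5, 10, 15], [0, 0, 0], ["g"] * 3)
        assert (s.curves["g"]["survival"] == 1.0).all()

    def test_single_event_drops_to_zero(self):
        s = km_estimate([5.0], [1], ["g"])
        assert s.survival_at("g", 4.9) == 1.0
        assert s.survival_at("g", 5.0) == 0.0

    def test_hand_product_limit_with_censoring(self):
        # censor at t=1, event at t=2 with 3 still at risk -> S(2) = 2/3
        s = km_estimate([1, 2, 3, 4], [0, 1, 0, 0], ["g"] * 4)
        assert s.survival_at("g", 2.0) == pytest.approx(2 / 3)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 50).round(2)
        s = km_estimate(times, np.ones(50, int), ["g"] * 50)
        for t in [1.0, 5.0, 12.0]:
            assert s.survival_at("g", t) == pytest.approx((times > t).mean())

    def test_steps_only_at_event_times(self):
        s = km_estimate([1, 2, 3, 4, 5], [0, 1, 0, 1, 0], ["g"] * 5)
        curve = s.curves["g"]
        step_times = curve["time"][curve["survival"].diff().fillna(0) != 0]
        assert set(step_times) <= {2.0, 4.0}

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [], [])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [3, 5, 8, 3, 5, 8]
        e = [1, 0, 1, 1, 0, 1]
        g = ["a"] * 3 + ["b"] * 3
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_six_subject_example_matches_hand_oracle(self):
        t = [1.0, 2.0, 3.0, 1.5, 2.5, 4.0]
        e = [1, 1, 0, 1, 0, 1]
        g = ["a", "a", "a", "b", "b", "b"]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(logrank_two_group_oracle(t, e, g), rel=1e-9)

    def test_two_group_p_is_chi2_tail(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        e[0] = 1
        g = np.array(["a", "b"] * 20)
        res = logrank_test(t, e, g)
        assert res.p == pytest.approx(float(chi2.sf(res.statistic, 1)), rel=1e-9)

    def test_three_groups_df_two(self):
        rng = np.random.default_rng(2)
        res = logrank_test(rng.exponential(5, 30), np.ones(30, int),
                           np.repeat(["a", "b", "c"], 10))
        assert res.df == 2

    def test_all_censored_errors(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p == pytest.approx(1.0)

    def test_zero_margin_p_one(self):
        assert fisher_exact_2x2([[0, 0], [5, 5]]).p == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        tables = [[[1, 9], [11, 3]], [[3, 7], [5, 5]], [[10, 2], [4, 8]], [[0, 5], [5, 0]]]
        for tab in tables:
            assert fisher_exact_2x2(tab).p == pytest.approx(
                fisher_two_sided_oracle(tab), rel=1e-9
            ), tab

    def test_known_value(self):
        assert fisher_exact_2x2([[1, 9], [11, 3]]).p == pytest.approx(0.00276, abs=5e-5)

    def test_invariance_under_transpose_and_swaps(self):
        tab = np.array([[2, 8], [9, 5]])
        p = fisher_exact_2x2(tab).p
        assert fisher_exact_2x2(tab.T).p == pytest.approx(p)
        assert fisher_exact_2x2(tab[::-1]).p == pytest.approx(p)
        assert fisher_exact_2x2(tab[:, ::-1]).p == pytest.approx(p)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


# ---------------------------------------------------------------------------
# TMB
# ---------------------------------------------------------------------------


def _mutation_table(rows, mb=38.0):
    df = pd.DataFrame(rows, columns=["sample_id", "gene_id", "variant_classification"])
    df["is_nonsynonymous"] = ~df["variant_classification"].str.lower().isin(["silent"])
    df["covered_megabases"] = mb
    return MutationTable(df)


class TestTMB:
    def test_definition(self):
        rows = [("S1", f"G{i}", "Missense_Mutation") for i in range(38)]
        tmb = tumor_mutation_burden(_mutation_table(rows, mb=38.0))
        assert tmb["S1"] == pytest.approx(1.0)

    def test_synonymous_only_sample_is_zero(self):
        rows = [("S1", "G1", "Silent"), ("S1", "G2", "Silent")]
        assert tumor_mutation_burden(_mutation_table(rows))["S1"] == 0.0

    def test_missing_coverage_requires_default(self):
        df = pd.DataFrame(
            [("S1", "G1", "Missense_Mutation")],
            columns=["sample_id", "gene_id", "variant_classification"],
        )
        df["is_nonsynonymous"] = True
        df["covered_megabases"] = np.nan
        mt = MutationTable(df)
        with pytest.raises(ValueError):
            tumor_mutation_burden(mt)
        assert tumor_mutation_burden(mt, default_megabases=38.0)["S1"] == pytest.approx(1 / 38)


# ---------------------------------------------------------------------------
# group difference tests
# ---------------------------------------------------------------------------


class TestGroupDifference:
    def test_identical_groups_not_significant(self):
        v = np.concatenate([np.arange(20.0), np.arange(20.0)])
        g = np.repeat(["a", "b"], 20)
        res = group_difference_test(v, g, mode="wilcoxon")
        assert res.p > 0.95

    def test_shifted_normals_select_t_and_reject(self):
        rng = np.random.default_rng(4)
        v = np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 1, 30)])
        g = np.repeat(["a", "b"], 30)
        res = group_difference_test(v, g, mode="auto")
        assert res.method == "t"
        assert res.p < 1e-3

    def test_heavy_tailed_selects_rank_test(self):
        rng = np.random.default_rng(6)
        v = np.concatenate([rng.standard_cauchy(40), rng.standard_cauchy(40) + 5])
        g = np.repeat(["a", "b"], 40)
        res = group_difference_test(v, g, mode="auto")
        assert res.method == "wilcoxon"

    def test_three_groups_use_kruskal(self):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 1, 60)
        g = np.repeat(["a", "b", "c"], 20)
        res = group_difference_test(v, g, mode="auto")
        assert res.method == "kruskal"
        assert res.df == 2

    def test_tiny_group_falls_back_to_rank(self):
        v = np.array([1.0, 2.0, 5.0, 6.0, 7.0, 8.0])
        g = np.array(["a", "a", "b", "b", "b", "b"])
        res = group_difference_test(v, g, mode="auto")
        assert res.method == "wilcoxon"

    def test_chi2_mode(self):
        res = group_difference_test([[10, 20], [30, 5]], None, mode="chi2")
        assert res.method == "chi2"
        assert res.p < 0.01


# ---------------------------------------------------------------------------
# mutation frequency table
# ---------------------------------------------------------------------------


class TestMutationFrequencies:
    def _labels(self, n_per_class=50):
        ids = [f"S{i:03d}" for i in range(3 * n_per_class)]
        return pd.Series(np.repeat(["x", "y", "z"], n_per_class), index=ids)

    def test_unmutated_gene_all_zero_p_one(self):
        labels = self._labels(10)
        rows = [("S000", "OTHER", "Missense_Mutation")]
        out = mutation_frequency_table(_mutation_table(rows), labels, genes=["GHOST"])
        row = out.loc["GHOST"]
        assert all(row[f"freq_{c}"] == 0.0 for c in ("x", "y", "z"))
        assert all(row[f"p_{c}"] == pytest.approx(1.0) for c in ("x", "y", "z"))

    def test_frequencies_equal_counts_over_denominators(self):
        labels = self._labels(10)
        rows = [(f"S00{i}", "TP53", "Missense_Mutation") for i in range(4)]  # class x
        out = mutation_frequency_table(_mutation_table(rows), labels, genes=["TP53"])
        assert out.loc["TP53", "freq_x"] == pytest.approx(0.4)
        assert out.loc["TP53", "n_mutated_x"] == 4
        assert out.loc["TP53", "freq_y"] == 0.0

    def test_planted_difference_detected_in_most_seeds(self):
        """A 0.19-vs-0.05 planted frequency difference at n=300 should be
        flagged at FDR < 0.05 in most replicates."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            labels = pd.Series(
                np.repeat(["hot", "cold"], 150),
                index=[f"S{i:03d}" for i in range(300)],
            )
            rows = []
            for sid, lab in labels.items():
                p = 0.19 if lab == "hot" else 0.05
                if rng.random() < p:
                    rows.append((sid, "TP53", "Missense_Mutation"))
                for bg in ("B1", "B2", "B3"):
                    if rng.random() < 0.05:
                        rows.append((sid, bg, "Missense_Mutation"))
            out = mutation_frequency_table(_mutation_table(rows), labels)
            if out.loc["TP53", "fdr_hot"] < 0.05:
                hits += 1
        assert hits >= 8

    def test_empty_class_errors(self):
        labels = pd.Series(["x"] * 5, index=[f"S{i}" for i in range(5)])
        labels.iloc[0] = None
        rows = [("S1", "G1", "Missense_Mutation")]
        # a class present in labels but with zero members cannot happen via
        # value_counts; instead check the documented error on empty input
        with pytest.raises(ValueError):
            mutation_frequency_table(_mutation_table(rows), labels.iloc[0:0])
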