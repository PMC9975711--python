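import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from immunostrat import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    common_upregulated,
    correlate_features_with_vector,
    differential_expression,
    double_fold_filter,
    fibrosis_score,
    group_partition_report,
    median_split,
    ora_hypergeometric,
    score_unidirectional,
)
from immunostrat.fibrosis import FIBROSIS_MARKERS
from immunostrat.synthetic import SynthConfig, generate_cohort


class TestFibrosisScore:
    def test_markers_on_top_attain_bound(self, rng):
        vals = rng.uniform(1, 10, 20)
        genes = [f"G{i:02d}" for i in range(15)] + list(FIBROSIS_MARKERS)
        vals[-5:] = 100.0 + np.arange(5)  # markers are the 5 top-ranked genes
        expr = ExpressionMatrix(pd.DataFrame({"S1": vals}, index=genes))
        assert fibrosis_score(expr).iloc[0] == pytest.approx(0.5)

    def test_equals_unidirectional_on_marker_set(self, small_cohort):
        expr = small_cohort[0]
        np.testing.assert_allclose(fibrosis_score(expr),
                                   score_unidirectional(expr, FIBROSIS_MARKERS))

    def test_failing_exceed_healthy_at_unit_effect(self):
        cfg = SynthConfig(n_failing=50, n_healthy=50, n_genes=600, fibrosis_effect=1.0,
                          n_specific_sets_per_subtype=2, n_null_sets=5, set_size=10,
                          n_panel_genes_per_subtype=5, seed=11)
        expr, _, _, _, _, truth = generate_cohort(cfg)
        fs = fibrosis_score(expr)
        p = mannwhitneyu(fs[~truth.healthy], fs[truth.healthy], alternative="greater").pvalue
        assert p < 0.01

    def test_too_few_markers_rejected(self, rng):
        expr = ExpressionMatrix(pd.DataFrame({"S1": rng.uniform(1, 9, 3)},
                                             index=["POSTN", "A", "B"]))
        with pytest.raises(ValueError):
            fibrosis_score(expr)


class TestMedianSplit:
    def test_odd_count_of_distinct_scores_splits_below_half(self):
        s = pd.Series(np.arange(1.0, 104.0), index=[f"S{i}" for i in range(103)])
        lab = median_split(s)
        assert (lab == "high").sum() == 51 and (lab == "low").sum() == 52

    def test_all_equal_scores_go_low(self):
        lab = median_split(pd.Series([2.0, 2.0, 2.0]))
        assert (lab == "low").all()

    def test_two_samples_split_one_each(self):
        lab = median_split(pd.Series([1.0, 2.0]))
        assert sorted(lab) == ["high", "low"]


class TestPartitionReport:
    def test_printed_count_percentages(self):
        sub = [1] * 34 + [2] * 69
        fib = ["high"] * 20 + ["low"] * 14 + ["high"] * 31 + ["low"] * 38
        rep = group_partition_report(sub, fib)
        assert rep.counts.loc[1, "high"] == 20 and rep.counts.loc[2, "low"] == 38
        assert rep.percent_of_total.loc[1, "high"] == 19.42
        assert rep.percent_of_total.loc[1, "low"] == 13.59
        assert rep.percent_of_total.loc[2, "high"] == 30.10
        assert rep.percent_of_total.loc[2, "low"] == 36.89

    def test_single_cell_is_hundred_percent(self):
        rep = group_partition_report([1, 1, 1], ["high", "high", "high"])
        assert rep.percent_of_total.loc[1, "high"] == 100.00

    def test_percentages_sum_to_hundred_within_rounding(self, rng):
        sub = rng.integers(1, 3, 200)
        fib = np.where(rng.random(200) > 0.5, "high", "low")
        rep = group_partition_report(sub, fib)
        assert rep.percent_of_total.to_numpy().sum() == pytest.approx(100.0, abs=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            group_partition_report([1, 2], ["high"])


def make_expr(a, b, prefix="G"):
    """Two-group expression on linear scale from log2 group matrices."""
    data = np.exp2(np.c_[a, b])
    cols = [f"A{i}" for i in range(a.shape[1])] + [f"B{i}" for i in range(b.shape[1])]
    genes = [f"{prefix}{i:03d}" for i in range(a.shape[0])]
    expr = ExpressionMatrix(pd.DataFrame(data, index=genes, columns=cols))
    return expr, cols[: a.shape[1]], cols[a.shape[1]:]


class TestDifferentialExpression:
    def test_identical_groups_flat(self, rng):
        a = rng.normal(5, 1, (20, 10))
        expr, ca, cb = make_expr(a, a)
        de = differential_expression(expr, ca, cb)
        assert np.allclose(de["log2fc"], 0.0) and np.allclose(de["p"], 1.0)

    def test_planted_fourfold_gene_recovered(self, rng):
        a = rng.normal(5, 0.3, (30, 20))
        b = a.copy() + rng.normal(0, 0.3, (30, 20))
        a[0] += 2.0  # 4-fold on linear scale
        expr, ca, cb = make_expr(a, b)
        de = differential_expression(expr, ca, cb)
        # log2(x+1) compresses the shift slightly at these expression levels
        assert 1.7 <= de.iloc[0]["log2fc"] <= 2.3
        assert de.iloc[0]["padj"] < 0.01

    def test_constant_gene_flagged_with_p_one(self, rng):
        a = rng.normal(5, 0.5, (5, 8))
        a[2] = 3.0
        expr, ca, cb = make_expr(a, a + rng.normal(0, 0.5, (5, 8)) * (np.arange(5) != 2)[:, None])
        de = differential_expression(expr, ca, cb)
        assert bool(de.iloc[2]["constant"]) and de.iloc[2]["p"] == 1.0

    def test_small_group_rejected(self, rng):
        a = rng.normal(5, 1, (4, 3))
        expr, ca, cb = make_expr(a, a)
        with pytest.raises(ValueError, match="2 samples"):
            differential_expression(expr, ca[:1], cb)


def de_table(log2fc, padj=None, genes=None):
    genes = genes or [f"G{i}" for i in range(len(log2fc))]
    return pd.DataFrame({
        "log2fc": log2fc,
        "padj": padj if padj is not None else [0.001] * len(log2fc),
    }, index=genes)


class TestFoldFilters:
    @pytest.mark.parametrize("fc1,fc2,kept", [
        (2.0, 0.5, True),
        (1.0, 0.8, False),
        (0.5, -1.0, True),   # negative subtype-2 fold passes when fc1 > 0
        (-0.5, -2.0, False),  # fc1 must be positive
    ])
    def test_double_fold_rule(self, fc1, fc2, kept):
        got = double_fold_filter(de_table([fc1]), de_table([fc2]))
        assert (got == ["G0"]) is kept

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="universes"):
            double_fold_filter(de_table([1.0]), de_table([1.0], genes=["X"]))

    def test_common_upregulated_rules(self):
        a = de_table([1.0, 1.0, -1.0, 1.0], padj=[0.01, 0.01, 0.01, 0.2])
        b = de_table([0.5, -0.5, 1.0, 1.0], padj=[0.01, 0.01, 0.01, 0.01])
        assert common_upregulated(a, b) == ["G0"]

    def test_common_upregulated_recovers_planted_shared_genes(self, rng):
        # 40 genes shared-up in both comparisons, 160 null
        n, shift = 20, 1.0
        base = rng.normal(5, 0.5, (200, 4 * n))
        up = np.zeros((200, 4 * n))
        up[:40, :n] = shift
        up[:40, 2 * n: 3 * n] = shift
        x = base + up
        expr1, ca1, cb1 = make_expr(x[:, :n], x[:, n: 2 * n])
        expr2, ca2, cb2 = make_expr(x[:, 2 * n: 3 * n], x[:, 3 * n:])
        de1 = differential_expression(expr1, ca1, cb1)
        de2 = differential_expression(expr2, ca2, cb2)
        got = set(common_upregulated(de1, de2))
        planted = {f"G{i:03d}" for i in range(40)}
        assert len(got & planted) / 40 >= 0.8


class TestCorrelation:
    def test_perfect_and_anti_correlation(self, rng):
        v = rng.normal(0, 1, 30)
        mat = pd.DataFrame([v, -v, np.full(30, 2.0)], index=["same", "anti", "flat"])
        tab = correlate_features_with_vector(mat, v, method="pearson")
        assert tab.loc["same", "r"] == pytest.approx(1.0)
        assert tab.loc["anti", "r"] == pytest.approx(-1.0)
        assert bool(tab.loc["flat", "zero_variance"]) and math.isnan(tab.loc["flat", "r"])

    def test_length_mismatch_rejected(self, rng):
        mat = pd.DataFrame(rng.normal(size=(2, 5)))
        with pytest.raises(ValueError, match="length"):
            correlate_features_with_vector(mat, np.zeros(4))


class TestOra:
    def test_full_overlap_matches_closed_form(self):
        universe = [f"G{i}" for i in range(100)]
        target = universe[:10]
        coll = GeneSetCollection([GeneSet("S", target)])
        tab = ora_hypergeometric(target, coll, universe)
        assert tab.loc["S", "p"] == pytest.approx(1.0 / math.comb(100, 10), rel=1e-9)

    def test_zero_overlap_p_at_least_half(self):
        universe = [f"G{i}" for i in range(100)]
        coll = GeneSetCollection([GeneSet("S", universe[50:60])])
        tab = ora_hypergeometric(universe[:10], coll, universe)
        assert tab.loc["S", "p"] >= 0.5

    def test_set_equal_to_universe_p_one(self):
        universe = [f"G{i}" for i in range(30)]
        coll = GeneSetCollection([GeneSet("S", universe)])
        tab = ora_hypergeometric(universe[:5], coll, universe)
        assert tab.loc["S", "p"] == pytest.approx(1.0)

    def test_hits_outside_universe_rejected(self):
        coll = GeneSetCollection([GeneSet("S", ["A", "B"])])
        with pytest.raises(ValueError, match="subset"):
            ora_hypergeometric(["Z"], coll, ["A", "B"])
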