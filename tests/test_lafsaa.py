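import numpy as np
import pandas as pd
import pytest

from immunostrat import (
    AssociationRecord,
    GeneSet,
    GeneSetCollection,
    ScoreMatrix,
    cluster_gene_sets,
    filter_by_enrichment,
    intersect_fibrosis_specific,
    intra_cluster_scores,
    screen_subtype_specific,
    select_representatives,
    validate_specific_sets,
)


def score_matrix_from_latents(rng, n_per_subtype=100, rho=0.7, n_null=20, seed_shift=0.0):
    """Scores built directly from latent factors: SPEC1 couples to the target
    only in subtype 1, SPEC2 only in subtype 2, BOTH in both, nulls nowhere."""
    n = 2 * n_per_subtype
    labels = pd.Series(np.r_[np.ones(n_per_subtype, int), np.full(n_per_subtype, 2, int)],
                       index=[f"S{i:03d}" for i in range(n)])
    f = rng.normal(0, 1, n)

    def coupled(mask):
        z = rng.normal(0, 1, n)
        u = np.where(mask, rho * f + np.sqrt(1 - rho**2) * z, rng.normal(0, 1, n))
        return u

    cols = {
        "TGS": f,
        "SPEC1": coupled(labels.to_numpy() == 1),
        "SPEC2": coupled(labels.to_numpy() == 2),
        "BOTH": rho * f + np.sqrt(1 - rho**2) * rng.normal(0, 1, n),
    }
    for j in range(n_null):
        cols[f"NULL{j:02d}"] = rng.normal(0, 1, n)
    data = pd.DataFrame(cols, index=labels.index) / 10.0  # keep inside [-0.5, 0.5]
    data = data.clip(-0.5, 0.5)
    return ScoreMatrix(data, mode="uni"), labels


class TestScreen:
    def test_planted_one_sided_couplings_flagged_for_their_subtype(self, rng):
        scores, labels = score_matrix_from_latents(rng)
        tgs = scores.data["TGS"].rename("TGS")
        rec = {r.set_name: r for r in screen_subtype_specific(scores, tgs, labels)}
        assert rec["SPEC1"].subtype == 1 and rec["SPEC1"].rho_in > 0.4
        assert rec["SPEC2"].subtype == 2

    def test_symmetric_coupling_not_flagged(self, rng):
        scores, labels = score_matrix_from_latents(rng)
        tgs = scores.data["TGS"].rename("TGS")
        names = [r.set_name for r in screen_subtype_specific(scores, tgs, labels)]
        assert "BOTH" not in names

    def test_tgs_column_excluded_from_screen(self, rng):
        scores, labels = score_matrix_from_latents(rng)
        tgs = scores.data["TGS"].rename("TGS")
        assert all(r.set_name != "TGS" for r in screen_subtype_specific(scores, tgs, labels))

    def test_constant_score_column_skipped(self, rng, caplog):
        scores, labels = score_matrix_from_latents(rng, n_null=2)
        data = scores.data.copy()
        data["FLAT"] = 0.25
        scores = ScoreMatrix(data, mode="uni")
        tgs = scores.data["TGS"].rename("TGS")
        with caplog.at_level("WARNING"):
            recs = screen_subtype_specific(scores, tgs, labels)
        assert all(r.set_name != "FLAT" for r in recs) and "zero-variance" in caplog.text

    def test_tiny_subtype_rejected(self, rng):
        scores, labels = score_matrix_from_latents(rng, n_per_subtype=10)
        labels.iloc[:7] = 2
        with pytest.raises(ValueError, match="fewer than"):
            screen_subtype_specific(scores, scores.data["TGS"].rename("TGS"), labels)


class TestValidation:
    def test_reproducible_coupling_validates(self, rng):
        s1, l1 = score_matrix_from_latents(rng)
        s2, l2 = score_matrix_from_latents(rng)
        recs = screen_subtype_specific(s1, s1.data["TGS"].rename("TGS"), l1)
        recs = validate_specific_sets(recs, s2, s2.data["TGS"].rename("TGS"), l2)
        spec = {r.set_name: r for r in recs}
        assert spec["SPEC1"].validated and spec["SPEC2"].validated

    def test_sign_flip_fails_validation(self, rng):
        s1, l1 = score_matrix_from_latents(rng)
        recs = [r for r in screen_subtype_specific(s1, s1.data["TGS"].rename("TGS"), l1)
                if r.set_name == "SPEC1"]
        flipped = ScoreMatrix(s1.data.assign(SPEC1=-s1.data["SPEC1"]), mode="uni")
        out = validate_specific_sets(recs, flipped, s1.data["TGS"].rename("TGS"), l1)
        assert not out[0].validated

    def test_missing_set_in_validation_matrix_named(self, rng):
        s1, l1 = score_matrix_from_latents(rng)
        recs = [AssociationRecord("GONE", 1, 0.5, 0.001, 0.0, 0.9)]
        with pytest.raises(ValueError, match="GONE"):
            validate_specific_sets(recs, s1, s1.data["TGS"].rename("TGS"), l1)


class TestEnrichmentFilter:
    @pytest.fixture()
    def setup(self):
        universe = [f"G{i:03d}" for i in range(200)]
        coll = GeneSetCollection([
            GeneSet("HIT", universe[:20]),
            GeneSet("MISS", universe[100:120]),
        ])
        de = {1: universe[:30], 2: []}
        recs = [AssociationRecord("HIT", 1, 0.6, 1e-4, 0.1, 0.5),
                AssociationRecord("MISS", 1, 0.5, 1e-3, 0.1, 0.6)]
        return recs, de, coll, universe

    def test_enriched_set_retained_disjoint_dropped(self, setup):
        recs, de, coll, universe = setup
        out = filter_by_enrichment(recs, de, coll, universe)
        assert [r.set_name for r in out] == ["HIT"]
        assert out[0].enrichment_p < 0.05

    def test_alpha_one_keeps_everything(self, setup):
        recs, de, coll, universe = setup
        assert len(filter_by_enrichment(recs, de, coll, universe, alpha=1.1)) == 2

    def test_empty_de_list_drops_subtype_records(self, setup, caplog):
        recs, de, coll, universe = setup
        recs2 = [AssociationRecord("HIT", 2, 0.6, 1e-4, 0.1, 0.5)]
        with caplog.at_level("WARNING"):
            out = filter_by_enrichment(recs2, de, coll, universe)
        assert out == [] and "subtype 2" in caplog.text


def block_scores(rng, n=80, block_rho=0.9):
    """Two blocks of mutually coupled score columns plus the index."""
    f1, f2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
    cols = {}
    for j in range(4):
        cols[f"A{j}"] = block_rho * f1 + np.sqrt(1 - block_rho**2) * rng.normal(0, 1, n)
    for j in range(4):
        cols[f"B{j}"] = block_rho * f2 + np.sqrt(1 - block_rho**2) * rng.normal(0, 1, n)
    data = (pd.DataFrame(cols, index=[f"S{i}" for i in range(n)]) / 10).clip(-0.5, 0.5)
    return ScoreMatrix(data, mode="uni")


class TestClustering:
    def test_two_planted_blocks_recovered(self, rng):
        scores = block_scores(rng)
        corr, clusters = cluster_gene_sets(scores, list(scores.set_names), k="auto")
        a = {clusters[f"A{j}"] for j in range(4)}
        b = {clusters[f"B{j}"] for j in range(4)}
        assert len(a) == 1 and len(b) == 1 and a != b

    def test_corr_matrix_symmetric_unit_diagonal(self, rng):
        scores = block_scores(rng)
        corr, _ = cluster_gene_sets(scores, list(scores.set_names), k=2)
        np.testing.assert_array_equal(corr.to_numpy(), corr.to_numpy().T)
        np.testing.assert_array_equal(np.diag(corr.to_numpy()), np.ones(len(corr)))

    def test_duplicated_columns_share_a_cluster(self, rng):
        scores = block_scores(rng)
        data = scores.data.assign(A0copy=scores.data["A0"])
        scores = ScoreMatrix(data, mode="uni")
        _, clusters = cluster_gene_sets(scores, list(scores.set_names), k=2)
        assert clusters["A0"] == clusters["A0copy"]

    def test_k_one_rejected(self, rng):
        scores = block_scores(rng)
        with pytest.raises(ValueError, match="k must be >= 2"):
            cluster_gene_sets(scores, list(scores.set_names), k=1)

    def test_fewer_than_two_sets_rejected(self, rng):
        scores = block_scores(rng)
        with pytest.raises(ValueError, match="at least 2"):
            cluster_gene_sets(scores, ["A0"])


class TestIcs:
    def test_hand_computed_three_set_cluster(self):
        corr = pd.DataFrame(
            [[1.0, 0.6, 0.2], [0.6, 1.0, 0.4], [0.2, 0.4, 1.0]],
            index=["s1", "s2", "s3"], columns=["s1", "s2", "s3"])
        ics = intra_cluster_scores(corr, {"s1": 1, "s2": 1, "s3": 1})
        assert ics["s1"] == pytest.approx(0.6)
        assert ics["s2"] == pytest.approx((0.6 + 1.0 + 0.4) / 3)

    def test_identical_members_all_score_one(self):
        corr = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        ics = intra_cluster_scores(corr, {"a": 1, "b": 1, "c": 1})
        assert all(v == pytest.approx(1.0) for v in ics.values())

    def test_singleton_cluster_scores_one(self):
        corr = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]], index=["a", "b"], columns=["a", "b"])
        ics = intra_cluster_scores(corr, {"a": 1, "b": 2})
        assert ics["a"] == 1.0 and ics["b"] == 1.0

    def test_missing_set_rejected(self):
        corr = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError, match="absent"):
            intra_cluster_scores(corr, {"a": 1, "ghost": 1})

    def test_representatives_invariant_to_self_term(self, rng):
        # within a fixed cluster the two ICS variants are monotone transforms
        n = 12
        M = rng.uniform(-0.3, 0.9, (n, n))
        corr = pd.DataFrame((M + M.T) / 2, index=[f"s{i}" for i in range(n)],
                            columns=[f"s{i}" for i in range(n)])
        np.fill_diagonal(corr.values, 1.0)
        clusters = {f"s{i}": (1 if i < 7 else 2) for i in range(n)}
        with_self = intra_cluster_scores(corr, clusters, include_self=True)
        without = intra_cluster_scores(corr, clusters, include_self=False)
        assert (select_representatives(with_self, clusters)
                == select_representatives(without, clusters))


class TestRepresentatives:
    def test_cluster_of_ten_yields_three(self):
        clusters = {f"s{i}": 1 for i in range(10)}
        ics = {f"s{i}": i / 10 for i in range(10)}
        reps = select_representatives(ics, clusters, top_frac=0.3)
        assert reps[1] == ["s9", "s8", "s7"]

    def test_singleton_cluster_represents_itself(self):
        assert select_representatives({"a": 1.0}, {"a": 3}) == {3: ["a"]}

    def test_boundary_ties_all_included(self):
        clusters = {f"s{i}": 1 for i in range(4)}
        ics = {f"s{i}": 0.5 for i in range(4)}
        reps = select_representatives(ics, clusters)
        assert sorted(reps[1]) == ["s0", "s1", "s2", "s3"]


class TestIntersection:
    def test_same_subtype_intersection_tagged(self):
        emt = [AssociationRecord("S", 1, 0.6, 1e-3, 0.1, 0.5, validated=True)]
        fib = [AssociationRecord("S", 1, 0.5, 1e-3, 0.1, 0.5)]
        assert intersect_fibrosis_specific(emt, fib) == [("S", 1)]

    def test_cross_subtype_specificity_excluded(self):
        emt = [AssociationRecord("S", 1, 0.6, 1e-3, 0.1, 0.5)]
        fib = [AssociationRecord("S", 2, 0.5, 1e-3, 0.1, 0.5)]
        assert intersect_fibrosis_specific(emt, fib) == []

    def test_empty_inputs_give_empty_output(self):
        assert intersect_fibrosis_specific([], []) == []

    def test_unvalidated_records_ignored(self):
        emt = [AssociationRecord("S", 1, 0.6, 1e-3, 0.1, 0.5, validated=False)]
        fib = [AssociationRecord("S", 1, 0.5, 1e-3, 0.1, 0.5)]
        assert intersect_fibrosis_specific(emt, fib) == []
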