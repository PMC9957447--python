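import math

import networkx as nx
import numpy as np
import pytest

from trnkit import go_annotation as goa
from trnkit.datamodel import GOCorpus, TrnkitError

from oracles import hypergeom_upper_tail_exact


class TestEaseScore:
    @pytest.mark.parametrize("overlap", [0, 1])
    def test_overlap_at_most_one_scores_one(self, overlap):
        assert goa.ease_score(overlap, 10, 10, 100) == 1.0

    def test_matches_exact_combinatorial_sum(self):
        got = goa.ease_score(3, 10, 10, 100)
        want = hypergeom_upper_tail_exact(2, 10, 10, 100)  # penalized overlap 2
        assert got == pytest.approx(float(want), abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_randomized_against_exact_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        pool = int(rng.integers(1, n))
        term = int(rng.integers(1, n))
        overlap = int(rng.integers(0, min(pool, term) + 1))
        got = goa.ease_score(overlap, pool, term, n)
        if overlap <= 1:
            assert got == 1.0
        else:
            want = float(hypergeom_upper_tail_exact(overlap - 1, pool, term, n))
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_penalty_is_conservative(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(10, 60))
        pool = int(rng.integers(1, n))
        term = int(rng.integers(1, n))
        overlap = int(rng.integers(0, min(pool, term) + 1))
        plain = float(hypergeom_upper_tail_exact(overlap, pool, term, n))
        assert goa.ease_score(overlap, pool, term, n) >= plain - 1e-15

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(TrnkitError):
            goa.ease_score(5, 3, 10, 100)


class TestEnrichPool:
    def test_pool_equal_to_rare_term_set_ranks_first(self, toy_corpus):
        df = goa.enrich_pool({"g1", "g2", "g6", "g7"}, toy_corpus, threshold=1.0)
        assert df.iloc[0]["term"] == "L1"
        assert df.iloc[0]["overlap"] == 4

    def test_unannotated_pool_is_empty(self, toy_corpus):
        df = goa.enrich_pool({"x1", "x2"}, toy_corpus)
        assert df.empty

    def test_fold_enrichment_definition(self, toy_corpus):
        df = goa.enrich_pool({"g1", "g2", "g6", "g7"}, toy_corpus, threshold=1.0)
        row = df[df.term == "L1"].iloc[0]
        n = toy_corpus.n_universe
        assert row.fold_enrichment == pytest.approx((4 / 4) / (4 / n))

    def test_empty_pool_warns(self, toy_corpus):
        with pytest.warns(UserWarning, match="empty"):
            df = goa.enrich_pool(set(), toy_corpus)
        assert df.empty


class TestNullCurves:
    def test_default_sizes_floor_expression(self):
        sizes = goa.default_null_sizes()
        assert len(sizes) == 18
        assert sizes[:6] == [2, 4, 5, 8, 11, 16]
        # independent evaluation of the floor expression
        want = [int(math.floor(2.0 ** (1.5 + 0.5 * i))) for i in range(18)]
        assert sizes == want

    @staticmethod
    def _uninformative_corpus():
        dag = nx.DiGraph()
        dag.add_node("root")
        return GOCorpus(dag, {f"g{i}": {"root"} for i in range(30)})

    def test_no_significant_terms_gives_zero_curves(self):
        corpus = self._uninformative_corpus()
        curves = goa.build_null_curves(corpus, sizes=[2, 4, 8, 16], reps=20, seed=1)
        assert np.all(curves.mu == 0)
        assert curves.mu_slope == pytest.approx(0.0)
        assert curves.sigma_slope == pytest.approx(0.0)

    def test_deterministic_under_fixed_seed(self, toy_corpus):
        a = goa.build_null_curves(toy_corpus, sizes=[2, 4, 6], reps=20, seed=7)
        b = goa.build_null_curves(toy_corpus, sizes=[2, 4, 6], reps=20, seed=7)
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.sigma, b.sigma)

    def test_size_exceeding_universe_rejected(self, toy_corpus):
        with pytest.raises(TrnkitError, match="universe"):
            goa.build_null_curves(toy_corpus, sizes=[100], reps=5, seed=0)


class TestAnnotationZscore:
    def _curves(self):
        return goa.NullCurves(
            sizes=np.array([2.0, 4.0]), mu=np.array([0.5, 1.0]),
            sigma=np.array([0.5, 0.5]), mu_se=np.array([0.1, 0.1]),
            mu_slope=0.25, mu_intercept=0.0,
            sigma_slope=0.0, sigma_intercept=0.5, reps=10, threshold=0.05,
        )

    def test_observed_equal_to_mean_gives_zero(self):
        assert goa.annotation_zscore(1, 4, self._curves()) == pytest.approx(0.0)

    def test_two_sigma_boundary(self):
        curves = self._curves()
        t = curves.predict_mu(4) + 2 * curves.predict_sigma(4)
        z = goa.annotation_zscore(t, 4, curves)
        assert z == pytest.approx(2.0)
        assert z >= goa.Z_SIGNIFICANT

    def test_nonpositive_sigma_gives_nan_with_warning(self):
        curves = self._curves()
        curves.sigma_intercept = -1.0
        with pytest.warns(UserWarning, match="sigma"):
            assert math.isnan(goa.annotation_zscore(3, 4, curves))


class TestSpecificity:
    def test_single_term_reciprocal_count(self, toy_corpus):
        assert goa.specificity("L1", toy_corpus) == pytest.approx(0.25)

    def test_set_takes_max(self, toy_corpus):
        # L1 annotates 4 genes, B1 annotates 5 (g1,g2,g3,g6,g7)
        assert goa.specificity({"L1", "B1"}, toy_corpus) == pytest.approx(0.25)

    def test_root_is_least_specific(self, toy_corpus):
        n = toy_corpus.n_universe
        root_spec = goa.specificity("root", toy_corpus)
        assert root_spec == pytest.approx(1.0 / n)
        assert all(
            goa.specificity(t, toy_corpus) >= root_spec
            for t in toy_corpus.terms()
            if toy_corpus.term_size(t) > 0
        )

    def test_strictly_decreasing_in_annotation_count(self, toy_corpus):
        sizes_specs = sorted(
            (toy_corpus.term_size(t), goa.specificity(t, toy_corpus))
            for t in toy_corpus.terms()
            if toy_corpus.term_size(t) > 0
        )
        for (s1, c1), (s2, c2) in zip(sizes_specs, sizes_specs[1:]):
            if s2 > s1:
                assert c2 < c1

    def test_unannotated_term_rejected(self, toy_corpus):
        toy_corpus.dag.add_node("orphan")
        with pytest.raises(TrnkitError, match="undefined"):
            goa.specificity("orphan", toy_corpus)


class TestWangSimilarity:
    def test_identical_singletons_are_one(self, toy_corpus):
        assert goa.wang_similarity({"L1"}, {"L1"}, toy_corpus) == pytest.approx(1.0)

    def test_hand_computed_s_values_on_toy_dag(self, toy_corpus):
        # L1: {L1:1, B1:0.8, root:0.64}, SV=2.44
        # L2 (part_of to B1): {L2:1, B1:0.6, root:0.48}, SV=2.08
        # shared: B1, root -> (0.8+0.6)+(0.64+0.48) = 2.52; sim = 2.52/4.52
        got = goa.wang_term_similarity("L1", "L2", toy_corpus)
        assert got == pytest.approx(2.52 / 4.52, abs=1e-12)

    def test_deep_terms_sharing_only_root_score_low(self):
        dag = nx.DiGraph()
        for chain in ("a", "b"):
            dag.add_edge(f"{chain}1", "root", relation="is_a")
            dag.add_edge(f"{chain}2", f"{chain}1", relation="is_a")
            dag.add_edge(f"{chain}3", f"{chain}2", relation="is_a")
        corpus = GOCorpus(dag, {"g1": {"a3"}, "g2": {"b3"}})
        got = goa.wang_term_similarity("a3", "b3", corpus)
        # S-values along each chain: 1, .8, .64, .512; SV = 2.952
        assert got == pytest.approx(2 * 0.512 / (2 * 2.952), abs=1e-12)
        assert got <= 0.3

    def test_symmetry(self, toy_corpus):
        a, b = {"L1", "L4"}, {"L2", "L3"}
        assert goa.wang_similarity(a, b, toy_corpus) == pytest.approx(
            goa.wang_similarity(b, a, toy_corpus)
        )

    def test_bounded_by_unit_interval(self, toy_corpus):
        terms = [t for t in toy_corpus.terms()]
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = set(rng.choice(terms, size=rng.integers(1, 4), replace=False))
            b = set(rng.choice(terms, size=rng.integers(1, 4), replace=False))
            s = goa.wang_similarity(a, b, toy_corpus)
            assert 0.0 <= s <= 1.0 + 1e-12

    def test_missing_term_rejected(self, toy_corpus):
        with pytest.raises(TrnkitError):
            goa.wang_similarity({"nope"}, {"L1"}, toy_corpus)


class TestCompareWithReference:
    def test_identical_sets_full_overlap_and_unit_similarity(self, toy_corpus):
        df = goa.compare_with_reference(
            {"TF1": {"L1", "L2"}}, {"TF1": {"L1", "L2"}}, toy_corpus
        )
        row = df.iloc[0]
        assert row.overlap == 2
        assert row.wang_similarity == pytest.approx(1.0)

    def test_disjoint_shallow_sets(self, toy_corpus):
        df = goa.compare_with_reference({"TF1": {"L1"}}, {"TF1": {"L3"}}, toy_corpus)
        row = df.iloc[0]
        assert row.overlap == 0
        assert row.wang_similarity < 1.0

    def test_child_predictions_are_more_specific(self, toy_corpus):
        # predicted L4 (1 gene) is a child of reference L3 (2 genes)
        df = goa.compare_with_reference({"TF1": {"L4"}}, {"TF1": {"L3"}}, toy_corpus)
        row = df.iloc[0]
        assert row.specificity_predicted > row.specificity_reference

    def test_trivial_reference_flagged(self, toy_corpus):
        df = goa.compare_with_reference(
            {"TF1": {"L1"}, "TF2": {"L1"}},
            {"TF1": {"B2"}, "TF2": {"L3"}},
            toy_corpus,
            trivial_terms={"B2"},
        )
        flags = df.set_index("tf")["trivially_annotated"]
        assert bool(flags["TF1"]) and not bool(flags["TF2"])


def test_annotate_network_counts_and_flags(toy_corpus):
    pools = {"TF1": {"g1", "g2", "g6", "g7"}, "TF2": {"g4"}}
    records, summary = goa.annotate_network(pools, toy_corpus, threshold=0.5)
    assert set(summary["tf"]) == {"TF1", "TF2"}
    t1 = summary.set_index("tf").loc["TF1", "n_significant_terms"]
    assert t1 == len(records[records.tf == "TF1"])
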