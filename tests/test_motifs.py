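import itertools

import numpy as np
import pytest

from trnkit import motifs as mm
from trnkit.datamodel import PWM, RegulatoryNetwork, TrnkitError

from oracles import hypergeom_upper_tail_exact


class TestEnumerateKmers:
    def test_single_base(self):
        assert mm.enumerate_kmers([1]) == ["A", "C", "G", "T"]

    def test_dimers_lexicographic(self):
        kmers = mm.enumerate_kmers([2])
        assert len(kmers) == 16
        assert kmers[0] == "AA" and kmers[-1] == "TT"
        assert kmers == sorted(kmers)

    def test_invalid_k_rejected(self):
        with pytest.raises(TrnkitError):
            mm.enumerate_kmers([0])
        with pytest.raises(TrnkitError):
            mm.enumerate_kmers([])


class TestIndexPromoters:
    def test_exact_six_mers_of_short_promoter(self):
        idx = mm.index_promoters({"g": "ACGTACG"}, ks=[6])
        assert set(idx.motifs) == {"ACGTAC", "CGTACG"}
        assert idx.L("ACGTAC") == 1

    def test_presence_is_binary(self):
        idx = mm.index_promoters({"g": "AAAAAAAA"}, ks=[6])
        assert idx.L("AAAAAA") == 1  # 3 windows, one gene

    def test_n_windows_never_match(self):
        idx = mm.index_promoters({"g": "ACGNACGTAC"}, ks=[4])
        assert idx.L("ACGN") == 0
        assert idx.L("ACGT") == 1

    def test_duplicate_fasta_records_rejected(self, tmp_path):
        from trnkit import io

        path = tmp_path / "dup.fasta"
        path.write_text(">g1\nACGTACG\n>g1\nACGTACG\n")
        with pytest.raises(TrnkitError, match="duplicate"):
            io.read_promoters(path)

    def test_both_strands_or_in_reverse_complement(self):
        idx_f = mm.index_promoters({"g": "ACGTTT"}, ks=[6])
        idx_b = mm.index_promoters({"g": "ACGTTT"}, ks=[6], both_strands=True)
        assert idx_f.L("AAACGT") == 0
        assert idx_b.L("AAACGT") == 1  # revcomp of ACGTTT

    def test_planted_motif_reaches_expected_presence(self, motif_fixture):
        model, truth, _, index = motif_fixture
        tf = model.tf_ids[0]
        motif, pi = model.motif_plants[tf]
        targets = truth.targets(tf)
        # ~pi of the targets carry a planted copy, plus background occurrences
        assert index.L(motif) >= pi * len(targets) * 0.7


class TestMotifEnrichment:
    def test_motif_in_every_promoter_gives_p_one(self):
        idx = mm.index_promoters({f"g{i}": "AAAAAA" for i in range(5)}, ks=[6])
        hit = mm.motif_enrichment({"g0", "g1"}, "AAAAAA", idx)
        assert hit.overlap == hit.pool_size == 2
        assert hit.p_value == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one(self):
        seqs = {"g0": "AAAAAA", "g1": "CCCCCC"}
        idx = mm.index_promoters(seqs, ks=[6])
        hit = mm.motif_enrichment({"g1"}, "AAAAAA", idx)
        assert hit.overlap == 0 and hit.p_value == pytest.approx(1.0)

    def test_small_case_equals_exhaustive_pool_enumeration(self):
        """n=10, L=4, k=3, l=2: count qualifying pools among all C(10,3)."""
        seqs = {f"g{i}": ("ACGTAC" if i < 4 else "CCCCCC") for i in range(10)}
        idx = mm.index_promoters(seqs, ks=[6])
        hit = mm.motif_enrichment({"g0", "g1", "g9"}, "ACGTAC", idx)
        genes = list(seqs)
        carriers = {f"g{i}" for i in range(4)}
        qualifying = sum(
            1
            for pool in itertools.combinations(genes, 3)
            if len(set(pool) & carriers) >= 2
        )
        total = 120
        assert qualifying / total == pytest.approx(40 / 120)
        assert hit.p_value == pytest.approx(qualifying / total, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_randomized_against_combinatorial_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 25))
        L = int(rng.integers(0, n + 1))
        seqs = {f"g{i}": ("ACGTACG" if i < L else "CCCCCCC") for i in range(n)}
        idx = mm.index_promoters(seqs, ks=[7])
        k = int(rng.integers(1, n + 1))
        pool = set(rng.choice(list(seqs), size=k, replace=False))
        hit = mm.motif_enrichment(pool, "ACGTACG", idx)
        want = float(hypergeom_upper_tail_exact(hit.overlap, k, L, n))
        assert hit.p_value == pytest.approx(want, abs=1e-12)


class TestBHCorrect:
    @staticmethod
    def _hits(ps):
        return [
            mm.MotifHit("tf", f"m{i}", 5, 10, 20, 100, p) for i, p in enumerate(ps)
        ]

    def test_identical_pvalues_unchanged(self):
        out = mm.bh_correct(self._hits([0.03, 0.03, 0.03]))
        assert all(h.bh_adjusted == pytest.approx(0.03) for h in out)

    def test_textbook_step_up_example(self):
        out = mm.bh_correct(self._hits([0.001, 0.013, 0.04, 0.8]), q=0.05)
        adj = [h.bh_adjusted for h in out]
        assert adj == pytest.approx([0.004, 0.026, 0.04 * 4 / 3, 0.8])
        assert [h.significant for h in out] == [True, True, False, False]

    def test_single_pvalue_equals_raw(self):
        (out,) = mm.bh_correct(self._hits([0.2]))
        assert out.bh_adjusted == pytest.approx(0.2)

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(3)
        ps = rng.uniform(size=50)
        out = mm.bh_correct(self._hits(ps))
        ranked = sorted(out, key=lambda h: h.p_value)
        adj = [h.bh_adjusted for h in ranked]
        assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))

    def test_empty_and_bad_q(self):
        assert mm.bh_correct([]) == []
        with pytest.raises(TrnkitError):
            mm.bh_correct(self._hits([0.5]), q=1.5)


class TestScreenedPValuePath:
    def test_screened_flags_match_exact_computation(self, motif_fixture):
        """The mean + 0.5 sd screen must not change any BH flag or the
        adjusted p-value of a flagged pair."""
        _, truth, _, index = motif_fixture
        pools = truth.target_pools()
        c_fast, df_fast = mm._significant_counts_for_pools(pools, index, 0.05, collect=True)
        c_exact, df_exact = mm._significant_counts_for_pools(
            pools, index, 0.05, collect=True, exact_all=True
        )
        assert c_fast == c_exact
        key = ["tf", "motif"]
        assert df_fast[key].values.tolist() == df_exact[key].values.tolist()
        np.testing.assert_allclose(df_fast["bh_adjusted"], df_exact["bh_adjusted"])

    def test_screened_matches_exact_on_random_pools(self, motif_fixture):
        _, _, _, index = motif_fixture
        rng = np.random.default_rng(17)
        pools = {
            f"R{i}": set(rng.choice(index.gene_ids, size=80, replace=False))
            for i in range(5)
        }
        c_fast, _ = mm._significant_counts_for_pools(pools, index, 0.05)
        c_exact, _ = mm._significant_counts_for_pools(pools, index, 0.05, exact_all=True)
        assert c_fast == c_exact


class TestRewireNull:
    def test_permute_mode_preserves_pool_sizes_and_multiset(self):
        net = RegulatoryNetwork(
            [("T1", "g1", 1.0), ("T1", "g2", 1.0), ("T2", "g3", 1.0)]
        )
        idx = mm.index_promoters({f"g{i}": "ACGTACG" for i in range(1, 6)}, ks=[7])
        res = mm.rewire_null(net, idx, reps=3, seed=0, mode="permute")
        assert len(res.null_counts) == 3

    def test_determinism(self, motif_fixture):
        _, truth, _, index = motif_fixture
        a = mm.rewire_null(truth, index, reps=5, seed=4)
        b = mm.rewire_null(truth, index, reps=5, seed=4)
        assert np.array_equal(a.null_counts, b.null_counts)
        assert a.observed == b.observed

    def test_planted_network_beats_small_null_sample(self, motif_fixture):
        _, truth, _, index = motif_fixture
        res = mm.rewire_null(truth, index, reps=5, seed=1)
        assert res.observed > res.null_counts.max()
        assert res.frac_observed_exceeds == 1.0
        assert res.empirical_p == 0.0


def _conserved_pwm(width=7, base="A"):
    mat = np.zeros((4, width))
    mat["ACGT".index(base), :] = 1.0
    return PWM(mat, id="pwmA")


class TestICScore:
    def test_perfect_consensus_scores_one(self):
        aln = mm.ic_score(_conserved_pwm(), "AAAAAAA")
        assert aln.window_score == pytest.approx(14.0)
        assert aln.s_max == pytest.approx(14.0)
        assert aln.ic_score == pytest.approx(1.0, abs=1e-12)

    def test_one_mismatch_loses_that_column(self):
        aln = mm.ic_score(_conserved_pwm(), "AAAAAAC")
        assert aln.window_score == pytest.approx(12.0)
        assert aln.ic_score == pytest.approx(12.0 / 14.0, abs=1e-12)

    def test_short_pwm_rejected(self):
        with pytest.raises(TrnkitError, match="shorter"):
            mm.ic_score(_conserved_pwm(width=5), "AAAAAAA")

    def test_bounded_by_one_on_random_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            t = int(rng.integers(7, 15))
            mat = rng.dirichlet(np.ones(4) * rng.uniform(0.2, 3.0), size=t).T
            pwm = PWM(mat)
            motif = "".join("ACGT"[i] for i in rng.integers(0, 4, size=7))
            aln = mm.ic_score(pwm, motif)
            if not np.isnan(aln.ic_score):
                assert aln.ic_score <= 1.0 + 1e-12

    def test_uniform_flanks_do_not_change_scores(self):
        core = _conserved_pwm()
        flank = np.full((4, 3), 0.25)
        padded = PWM(np.hstack([flank, core.matrix, flank]))
        a = mm.ic_score(core, "AAAAAAA")
        b = mm.ic_score(padded, "AAAAAAA")
        assert b.s_max == pytest.approx(a.s_max)
        assert b.ic_score == pytest.approx(a.ic_score, abs=1e-12)

    def test_tie_breaks_to_smallest_start(self):
        pwm = PWM(np.full((4, 9), 0.25))
        # degenerate: all windows score 0; ties -> start 0, nan score warned
        with pytest.warns(UserWarning):
            aln = mm.ic_score(pwm, "ACGTACG")
        assert aln.best_start == 0

    def test_literal_sign_variant_flips_contributions(self):
        pwm = _conserved_pwm()
        aln = mm.ic_score(pwm, "AAAAAAA", sign="literal")
        # with the leading minus, conserved columns contribute -2 each
        assert aln.window_score == pytest.approx(-14.0)


class TestScoreShuffleBaseline:
    def test_planted_assignments_beat_shuffled(self, motif_fixture):
        from trnkit import synthetic

        model, truth, _, index = motif_fixture
        pwms = synthetic.generate_reference_pwms(model, width=11, seed=3)
        assignments = {tf: [model.motif_plants[tf][0]] for tf in model.tf_ids}
        res = mm.score_shuffle_baseline(assignments, pwms, seed=2)
        assert res.true_scores.mean() > res.shuffled_scores.mean()
        assert res.p_value < 0.01

    def test_self_shuffle_t_near_zero(self):
        pwms = {f"T{i}": _conserved_pwm() for i in range(4)}
        assignments = {f"T{i}": ["AAAAAAA"] for i in range(4)}
        res = mm.score_shuffle_baseline(assignments, pwms, seed=0)
        assert res.t_statistic == pytest.approx(0.0, abs=1e-9) or np.isnan(res.t_statistic)

    def test_deterministic(self, motif_fixture):
        from trnkit import synthetic

        model, _, _, _ = motif_fixture
        pwms = synthetic.generate_reference_pwms(model, width=11, seed=3)
        assignments = {tf: [model.motif_plants[tf][0]] for tf in model.tf_ids}
        a = mm.score_shuffle_baseline(assignments, pwms, seed=5)
        b = mm.score_shuffle_baseline(assignments, pwms, seed=5)
        assert np.array_equal(a.shuffled_scores, b.shuffled_scores)
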