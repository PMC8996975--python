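"""Enrichment-score and permutation-statistics behavior.

The weighted-KS running sum is checked against an independent
brute-force walk; exhaustive 3-vs-3 phenotype enumeration is checked
against direct enumeration of label splits.
"""

import math
from itertools import combinations

import numpy as np
import pytest

from crosspath import (
    EnrichmentResult,
    GeneSet,
    GeneSetCollection,
    GseaConfig,
    RankedList,
    enrichment_score,
    leading_edge_stats,
    permutation_statistics,
    rank_genes,
    significant_sets,
)
from crosspath.gsea import _es_sparse

from conftest import make_matrix


def brute_force_es(genes, scores, members, p):
    """Independent walk over the ranked list; positive extremum wins ties."""
    member_set = set(members)
    hits = [g in member_set for g in genes]
    n, n_s = len(genes), sum(hits)
    n_r = sum(abs(s) ** p for s, h in zip(scores, hits) if h)
    run, cur = [], 0.0
    for s, h in zip(scores, hits):
        if h:
            cur += (abs(s) ** p) / n_r if n_r > 0 else 1.0 / n_s
        else:
            cur -= 1.0 / (n - n_s)
        run.append(cur)
    hi, lo = max(run), min(run)
    return hi if hi + lo >= -1e-9 else lo  # positive extremum wins ties


def random_instance(rng, max_n=12):
    n = int(rng.integers(3, max_n + 1))
    scores = np.sort(np.round(rng.uniform(0, 5, size=n), 3))[::-1]
    genes = tuple(f"g{i}" for i in range(n))
    k = int(rng.integers(1, n))
    members = list(rng.choice(genes, size=k, replace=False))
    return RankedList(genes, scores), members


class TestEnrichmentScore:
    def test_perfect_enrichment_single_top_gene(self):
        rl = RankedList(("a", "b", "c", "d"), np.ones(4))
        es, _, peak, leading = enrichment_score(rl, ["a"], p=0)
        assert es == pytest.approx(1.0)
        assert peak == 1 and leading == ("a",)

    def test_rank2_member_running_sum(self):
        rl = RankedList(("a", "b", "c", "d"), np.ones(4))
        es, run, peak, _ = enrichment_score(rl, ["b"], p=0)
        assert run == pytest.approx([-1 / 3, 2 / 3, 1 / 3, 0.0], abs=1e-12)
        assert es == pytest.approx(2 / 3) and peak == 2

    def test_degenerate_sets_rejected(self):
        rl = RankedList(("a", "b"), np.ones(2))
        with pytest.raises(ValueError):
            enrichment_score(rl, [], p=1)
        with pytest.raises(ValueError):
            enrichment_score(rl, ["a", "b"], p=1)

    @pytest.mark.parametrize("p", [0.0, 1.0, 2.0])
    def test_brute_force_oracle(self, rng, p):
        for _ in range(100):
            rl, members = random_instance(rng)
            es, _, _, _ = enrichment_score(rl, members, p=p)
            assert es == pytest.approx(
                brute_force_es(rl.genes, rl.scores, members, p), abs=1e-12
            )

    def test_sparse_path_matches_dense(self, rng):
        """The permutation fast path gives the same ES as the full walk."""
        for _ in range(100):
            rl, members = random_instance(rng, max_n=30)
            es_dense, _, _, _ = enrichment_score(rl, members, p=1.0)
            member_set = set(members)
            pos = np.array([i for i, g in enumerate(rl.genes) if g in member_set])
            w = np.abs(rl.scores[pos]) ** 1.0
            assert _es_sparse(pos, w, len(rl)) == pytest.approx(es_dense, abs=1e-12)

    def test_running_sum_ends_at_zero_when_unweighted(self, rng):
        rl, members = random_instance(rng)
        _, run, _, _ = enrichment_score(rl, members, p=0)
        assert run[-1] == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_of_scores(self, rng):
        rl, members = random_instance(rng)
        es1, _, _, _ = enrichment_score(rl, members, p=1)
        scaled = RankedList(rl.genes, rl.scores * 7.5)
        es2, _, _, _ = enrichment_score(scaled, members, p=1)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_list_reversal_negates_es_under_equal_weights(self, rng):
        rl, members = random_instance(rng)
        uniform = RankedList(rl.genes, np.ones(len(rl)))
        es_f, _, _, _ = enrichment_score(uniform, members, p=0)
        rev = RankedList(tuple(reversed(uniform.genes)), np.ones(len(rl)))
        es_r, run_r, _, _ = enrichment_score(rev, members, p=0)
        # reversing the list mirrors the walk, so the extrema swap sign;
        # when |max| == |min| the positive branch wins on both sides
        run_f = enrichment_score(uniform, members, p=0)[1]
        hi_f, lo_f = max(run_f), min(run_f)
        if abs(hi_f) != abs(lo_f):
            assert es_r == pytest.approx(-es_f, abs=1e-12)
        else:
            assert abs(es_r) == pytest.approx(abs(es_f), abs=1e-12)

    def test_abs_es_never_exceeds_one(self, rng):
        for _ in range(50):
            rl, members = random_instance(rng)
            es, _, _, _ = enrichment_score(rl, members, p=1)
            assert abs(es) <= 1.0 + 1e-12


class TestRankGenes:
    def test_signal_to_noise_direct(self):
        # two disease samples at mean 2, two control at mean 1, sd 0.5 each
        m = make_matrix([[1.5, 2.5, 0.5, 1.5]])
        rl = rank_genes(m, absolute_mode=False)
        mu_d, mu_c = 2.0, 1.0
        sd = np.std([1.5, 2.5], ddof=1)  # ~0.707
        expected = (mu_d - mu_c) / (sd + sd)
        assert rl.scores[0] == pytest.approx(expected)

    def test_absolute_mode_orders_by_magnitude(self):
        # gene1 ~ +small, gene2 ~ -large: absolute mode puts gene2 first
        m = make_matrix(
            [[5.0, 5.2, 4.9, 5.1], [1.0, 1.2, 8.0, 8.2]], n_disease=2
        )
        rl = rank_genes(m, absolute_mode=True)
        assert rl.genes[0] == "r1"
        assert np.all(rl.scores >= 0)

    def test_variance_floor_for_constant_gene(self):
        # constant within class: sigma floored at 0.2|mu|
        m = make_matrix([[5.0, 5.0, 4.0, 4.0]], n_disease=2)
        rl = rank_genes(m, absolute_mode=False)
        expected = (5.0 - 4.0) / (0.2 * 5.0 + 0.2 * 4.0)
        assert rl.scores[0] == pytest.approx(expected)

    def test_class_below_two_samples_rejected(self):
        m = make_matrix([[1.0, 2.0, 3.0]], n_disease=1)
        with pytest.raises(ValueError, match="< 2 samples"):
            rank_genes(m)


def _planted_matrix(rng, n_genes=30, n_per_class=3, planted=10, delta=3.0):
    vals = rng.normal(5, 1, size=(n_genes, 2 * n_per_class))
    vals[:planted, :n_per_class] += delta
    return make_matrix(vals, n_disease=n_per_class)


class TestPermutationStatistics:
    def test_exhaustive_enumeration_matches_direct_count(self, rng):
        """3-vs-3: nominal p equals (1+k)/(1+19) with k counted by a
        brute-force loop over all label splits."""
        m = _planted_matrix(rng)
        members = tuple(f"r{i}" for i in range(10))
        coll = GeneSetCollection([GeneSet("SET", "", members)])
        cfg = GseaConfig(n_permutations=1000, min_set_size=5, seed=1)
        (res,) = permutation_statistics(m, coll, cfg)

        # independent enumeration
        X = m.values.to_numpy()
        genes = np.array(m.row_ids, dtype=object)

        def es_for(mask):
            mu_d = X[:, mask].mean(axis=1)
            mu_c = X[:, ~mask].mean(axis=1)
            sd_d = X[:, mask].std(axis=1, ddof=1)
            sd_c = X[:, ~mask].std(axis=1, ddof=1)
            fd = np.maximum(sd_d, np.where(mu_d == 0, 0.2, 0.2 * np.abs(mu_d)))
            fc = np.maximum(sd_c, np.where(mu_c == 0, 0.2, 0.2 * np.abs(mu_c)))
            s = np.abs((mu_d - mu_c) / (fd + fc))
            order = np.lexsort((genes, -s))
            rl = RankedList(tuple(genes[order]), s[order])
            es, _, _, _ = enrichment_score(rl, members, p=1)
            return es

        obs_mask = np.array([True] * 3 + [False] * 3)
        es_obs = es_for(obs_mask)
        assert res.es == pytest.approx(es_obs, abs=1e-12)
        perm_es = []
        for combo in combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(combo)] = True
            if mask.tolist() == obs_mask.tolist():
                continue
            perm_es.append(es_for(mask))
        assert len(perm_es) == 19
        same_sign = [e for e in perm_es if e >= 0] if es_obs >= 0 else [
            e for e in perm_es if e < 0
        ]
        k = sum(abs(e) >= abs(es_obs) for e in same_sign)
        assert res.nom_p == pytest.approx((1 + k) / (1 + len(same_sign)))

    def test_planted_set_hits_enumeration_floor(self, rng):
        m = _planted_matrix(rng, delta=5.0)
        members = tuple(f"r{i}" for i in range(10))
        coll = GeneSetCollection(
            [GeneSet("PLANTED", "", members),
             GeneSet("DECOY", "", tuple(f"r{i}" for i in range(15, 25)))]
        )
        cfg = GseaConfig(n_permutations=1000, min_set_size=5, seed=1)
        results = permutation_statistics(m, coll, cfg)
        by_name = {r.set_name: r for r in results}
        assert results[0].set_name == "PLANTED"
        assert by_name["PLANTED"].nom_p <= by_name["DECOY"].nom_p
        # the label-swapped complement of the observed split yields the
        # same |s2n| scores, so it always ties the observed ES: the
        # enumeration floor in absolute mode is (1+1)/(1+19)
        assert by_name["PLANTED"].nom_p == pytest.approx(2 / 20)

    def test_seeded_determinism(self, rng):
        m = _planted_matrix(rng, n_per_class=5)
        coll = GeneSetCollection(
            [GeneSet("S1", "", tuple(f"r{i}" for i in range(10)))]
        )
        cfg = GseaConfig(n_permutations=50, min_set_size=5, seed=42)
        r1 = permutation_statistics(m, coll, cfg)
        r2 = permutation_statistics(m, coll, cfg)
        assert [(a.nes, a.nom_p, a.fdr_q, a.fwer_p) for a in r1] == [
            (a.nes, a.nom_p, a.fdr_q, a.fwer_p) for a in r2
        ]

    def test_gene_set_permutation_mode(self, rng):
        m = _planted_matrix(rng, n_per_class=4, delta=4.0)
        coll = GeneSetCollection(
            [GeneSet("PLANTED", "", tuple(f"r{i}" for i in range(10)))]
        )
        cfg = GseaConfig(n_permutations=200, min_set_size=5, seed=3,
                         permutation_mode="gene_set")
        (res,) = permutation_statistics(m, coll, cfg)
        assert res.nom_p < 0.05

    def test_fdr_q_monotone_in_nes(self, rng):
        m = _planted_matrix(rng, n_genes=60, n_per_class=6, planted=15, delta=2.0)
        sets = [GeneSet(f"S{k}", "", tuple(f"r{i}" for i in range(k * 5, k * 5 + 10)))
                for k in range(8)]
        cfg = GseaConfig(n_permutations=100, min_set_size=5, seed=11)
        results = permutation_statistics(m, GeneSetCollection(sets), cfg)
        pos = sorted([r for r in results if r.nes >= 0], key=lambda r: -r.nes)
        qs = [r.fdr_q for r in pos]
        assert qs == sorted(qs)


class TestLeadingEdgeStats:
    def test_perfect_toy(self):
        res = EnrichmentResult("S", size=1, es=1.0, leading_edge=("a",), peak_rank=1)
        tag, gene, signal = leading_edge_stats(res, N=4)
        assert (tag, gene) == (1.0, 0.25)
        assert signal == pytest.approx(1.0 * 0.75 * (4 / 3))

    def test_degenerate_zero_es(self):
        res = EnrichmentResult("S", size=5, es=0.0, leading_edge=(), peak_rank=0)
        assert leading_edge_stats(res, N=10) == (0.0, 0.0, 0.0)

    def test_negative_es_measures_from_list_bottom(self):
        res = EnrichmentResult("S", size=4, es=-0.5,
                               leading_edge=("a", "b"), peak_rank=8)
        tag, gene, signal = leading_edge_stats(res, N=10)
        assert tag == pytest.approx(0.5)
        assert gene == pytest.approx((10 - 8 + 1) / 10)
        assert 0 <= signal <= 1


class TestSignificantSets:
    def test_boundary_conventions_and_enumeration(self):
        cfg = GseaConfig()
        mk = lambda n, p, q: EnrichmentResult(n, 10, 0.5, nom_p=p, fdr_q=q)
        results = [
            mk("keep_boundary_q", 0.04, 0.25),   # q boundary inclusive
            mk("drop_p_at_alpha", 0.05, 0.10),   # p strict
            mk("keep_small", 0.001, 0.01),
            mk("drop_q", 0.01, 0.30),
            mk("drop_both", 0.50, 0.90),
        ]
        kept = significant_sets(results, cfg)
        assert [r.set_name for r in kept] == [
            r.set_name for r in results
            if r.nom_p < 0.05 and r.fdr_q <= 0.25
        ]
        assert {r.set_name for r in kept} == {"keep_boundary_q", "keep_small"}
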