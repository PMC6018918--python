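"""Expression decoding: normalization, selection, mHG enrichment, controls."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcdecode import decoding as dec
from fcdecode.synthetic import generate_parcellation
from fcdecode.types import Parcellation


def _matrix(energies, normalized=False, genes=None, regions=None):
    energies = np.asarray(energies, float)
    genes = genes or [f"g{i}" for i in range(energies.shape[0])]
    regions = regions or [f"r{j}" for j in range(energies.shape[1])]
    return dec.ExpressionMatrix(
        gene_ids=genes, region_labels=regions, energies=energies, normalized=normalized
    )


class TestEnergyByRegion:
    def test_uniform_volume(self):
        parc = generate_parcellation((4, 4, 2), 3, rng_seed=0)
        vols = {"gA": np.full((4, 4, 2), 2.5)}
        out = dec.expression_energy_by_region(vols, parc)
        np.testing.assert_allclose(out.energies, 2.5)

    def test_hand_computed_two_regions(self):
        labels = np.array([[[1, 1, 2, 2]]], dtype=np.int32)
        parc = Parcellation(labels=labels)
        vol = np.array([[[1.0, 3.0, 10.0, 20.0]]])
        out = dec.expression_energy_by_region({"g": vol}, parc)
        np.testing.assert_allclose(out.energies, [[2.0, 15.0]])

    def test_shape_mismatch_raises(self):
        parc = generate_parcellation((4, 4, 2), 3, rng_seed=0)
        with pytest.raises(ValueError, match="gX"):
            dec.expression_energy_by_region({"gX": np.zeros((3, 3, 1))}, parc)


class TestNormalize:
    def test_uniform_gene_gets_1_over_R(self):
        out = dec.normalize_by_total(_matrix(np.ones((3, 5))))
        np.testing.assert_allclose(out.energies, 0.2)

    def test_rows_sum_to_one_and_zero_rows_dropped(self):
        m = _matrix([[1.0, 3.0], [0.0, 0.0], [2.0, 2.0]])
        out = dec.normalize_by_total(m)
        assert out.gene_ids == ["g0", "g2"]
        np.testing.assert_allclose(out.energies.sum(axis=1), 1.0, atol=1e-9)

    def test_elementwise_division_oracle(self):
        rng = np.random.default_rng(40)
        e = rng.uniform(0.1, 5, (20, 6))
        out = dec.normalize_by_total(_matrix(e))
        np.testing.assert_allclose(out.energies, e / e.sum(axis=1, keepdims=True))

    def test_double_normalization_rejected(self):
        out = dec.normalize_by_total(_matrix(np.ones((2, 2))))
        with pytest.raises(ValueError):
            dec.normalize_by_total(out)


class TestTopQuantile:
    def test_q_one_returns_all(self):
        m = dec.normalize_by_total(_matrix(np.random.default_rng(1).uniform(1, 2, (10, 3))))
        assert dec.top_quantile_intersection(m, ("r0", "r1"), q=1.0) == set(m.gene_ids)

    def test_identical_columns(self):
        rng = np.random.default_rng(41)
        col = rng.uniform(1, 5, 10)
        e = np.column_stack([col, col, rng.uniform(1, 5, 10)])
        m = _matrix(e / e.sum(1, keepdims=True), normalized=True)
        out = dec.top_quantile_intersection(m, ("r0", "r1"), q=0.3)
        k = int(np.ceil(0.3 * 10))
        genes = np.array(m.gene_ids)
        expect = set(genes[np.lexsort((genes, -m.energies[:, 0]))][:k])
        assert out == expect

    def test_brute_force_double_sort(self):
        rng = np.random.default_rng(42)
        e = rng.uniform(0.5, 3, (10, 2))
        m = _matrix(e / e.sum(1, keepdims=True), normalized=True)
        out = dec.top_quantile_intersection(m, ("r0", "r1"), q=0.4)
        k = int(np.ceil(0.4 * 10))
        tops = []
        for j in range(2):
            order = sorted(range(10), key=lambda i: (-m.energies[i, j], m.gene_ids[i]))
            tops.append({m.gene_ids[i] for i in order[:k]})
        assert out == tops[0] & tops[1]

    def test_unknown_label_raises(self):
        m = _matrix(np.ones((4, 2)) / 2, normalized=True)
        with pytest.raises(KeyError):
            dec.top_quantile_intersection(m, ("r0", "nope"))


class TestL1Rank:
    def test_single_region_specialist_outranks(self):
        e = np.array([[1.0, 0.0, 0.0], [0.3, 0.3, 0.4]])
        m = _matrix(e, normalized=True)
        ranked = dec.l1_rank(m, ("r0", "r1"))
        assert ranked.genes[0] == "g0"
        assert ranked.scores[0] == pytest.approx(1.0)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(43)
        e = rng.uniform(0.1, 1, (8, 3))
        e /= e.sum(1, keepdims=True)
        genes = [f"g{i}" for i in range(8)]
        m1 = _matrix(e, normalized=True, genes=genes)
        perm = rng.permutation(8)
        m2 = _matrix(e[perm], normalized=True, genes=[genes[i] for i in perm])
        r1 = dec.l1_rank(m1, ("r0", "r2"))
        r2 = dec.l1_rank(m2, ("r0", "r2"))
        assert r1.genes == r2.genes
        np.testing.assert_allclose(r1.scores, r2.scores)

    def test_independent_sort_oracle(self):
        rng = np.random.default_rng(44)
        e = rng.uniform(0.1, 1, (12, 4))
        e /= e.sum(1, keepdims=True)
        m = _matrix(e, normalized=True)
        ranked = dec.l1_rank(m, ("r1", "r3"))
        score = {g: e[i, 1] + e[i, 3] for i, g in enumerate(m.gene_ids)}
        expect = sorted(m.gene_ids, key=lambda g: (-score[g], g))
        assert ranked.genes == expect


class TestHypergeometricTail:
    def test_k_zero_is_one(self):
        assert dec.hypergeometric_tail(0, 10, 4, 3) == 1.0

    def test_impossible_k_is_zero(self):
        assert dec.hypergeometric_tail(3, 10, 2, 3) == 0.0

    def test_enumeration_case(self):
        # P[X >= 2] for N=10, B=4, n=3: enumerate all C(10,3) draws
        count = sum(
            1
            for draw in itertools.combinations(range(10), 3)
            if sum(1 for x in draw if x < 4) >= 2
        )
        expect = count / comb(10, 3)
        assert abs(dec.hypergeometric_tail(2, 10, 4, 3) - expect) < 1e-12
        assert abs(expect - 1 / 3) < 1e-12

    @given(st.integers(1, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_scipy_survival(self, N, B, n):
        from scipy.stats import hypergeom

        B, n = min(B, N), min(n, N)
        k = min(B, n)
        for kk in {0, 1, k}:
            if kk <= n:
                assert dec.hypergeometric_tail(kk, N, B, n) == pytest.approx(
                    float(hypergeom.sf(kk - 1, N, B, n)), abs=1e-12
                )


def _enum_mhg_p(N, B, stat):
    """Full enumeration of orderings: fraction with mHG statistic <= stat."""
    count = 0
    for pos in itertools.combinations(range(N), B):
        hits = np.zeros(N, bool)
        hits[list(pos)] = True
        s, _ = dec.mhg_statistic(hits)
        if s <= stat * (1 + 1e-9):
            count += 1
    return count / comb(N, B)


class TestMhg:
    def test_top_block_small_case(self):
        """N=4, B=2, targets at ranks 1-2: p = 1/6 by full enumeration."""
        ranked = dec.RankedGeneList(genes=["a", "b", "c", "d"], scores=[4.0, 3.0, 2.0, 1.0])
        res = dec.mhg_enrichment(ranked, {"a", "b"})
        assert res.exact_p == pytest.approx(1 / 6, abs=1e-12)
        assert res.optimal_rank == 2

    def test_bottom_targets_are_null(self):
        for N in (6, 8):
            genes = [f"g{i}" for i in range(N)]
            ranked = dec.RankedGeneList(genes=genes, scores=list(range(N, 0, -1)))
            res = dec.mhg_enrichment(ranked, set(genes[-2:]))
            assert res.exact_p >= 0.5

    @pytest.mark.parametrize("N,B", [(5, 2), (6, 3), (7, 3), (8, 4)])
    def test_dp_equals_enumeration(self, N, B):
        rng = np.random.default_rng(100 + N + B)
        for _ in range(5):
            hits = np.zeros(N, bool)
            hits[rng.choice(N, B, replace=False)] = True
            stat, _ = dec.mhg_statistic(hits)
            assert dec.mhg_exact_pvalue(N, B, stat) == pytest.approx(
                _enum_mhg_p(N, B, stat), abs=1e-12
            )

    def test_dp_matches_monte_carlo(self):
        """Exact p agrees with a 10,000-shuffle permutation p within 3 SE."""
        N, B = 50, 8
        rng = np.random.default_rng(7)
        hits = np.zeros(N, bool)
        hits[rng.choice(N, B, replace=False)] = True
        stat, _ = dec.mhg_statistic(hits)
        p_dp = dec.mhg_exact_pvalue(N, B, stat)
        M = 10_000
        count = 0
        for _ in range(M):
            h = np.zeros(N, bool)
            h[rng.choice(N, B, replace=False)] = True
            s, _ = dec.mhg_statistic(h)
            if s <= stat * (1 + 1e-9):
                count += 1
        p_mc = count / M
        se = np.sqrt(max(p_mc * (1 - p_mc), 1e-9) / M)
        assert abs(p_dp - p_mc) <= 3 * se

    def test_p_bounds_around_statistic(self):
        """stat <= exact_p <= N * stat (union bound over thresholds)."""
        rng = np.random.default_rng(8)
        for N, B in [(30, 5), (60, 12), (100, 20)]:
            hits = np.zeros(N, bool)
            hits[rng.choice(N, B, replace=False)] = True
            stat, _ = dec.mhg_statistic(hits)
            p = dec.mhg_exact_pvalue(N, B, stat)
            assert stat * (1 - 1e-9) <= p <= N * stat + 1e-12

    def test_adding_target_at_rank_one_never_hurts(self):
        rng = np.random.default_rng(9)
        N = 20
        hits = np.zeros(N, bool)
        hits[rng.choice(np.arange(1, N), 5, replace=False)] = True
        stat0, _ = dec.mhg_statistic(hits)
        p0 = dec.mhg_exact_pvalue(N, int(hits.sum()), stat0)
        hits[0] = True
        stat1, _ = dec.mhg_statistic(hits)
        p1 = dec.mhg_exact_pvalue(N, int(hits.sum()), stat1)
        assert p1 <= p0 + 1e-12

    def test_empty_target_raises(self):
        ranked = dec.RankedGeneList(genes=["a", "b"], scores=[2.0, 1.0])
        with pytest.raises(ValueError):
            dec.mhg_enrichment(ranked, set())


class TestDecodePair:
    def test_extreme_overlap_set_is_minimal(self):
        rng = np.random.default_rng(50)
        e = rng.uniform(0.1, 1, (40, 5))
        m = dec.normalize_by_total(_matrix(e))
        selected = dec.top_quantile_intersection(m, ("r0", "r1"), q=0.5)
        assert selected
        annotations = {"exact_match": sorted(selected)}
        for size in (len(selected),):
            rng2 = np.random.default_rng(51)
            annotations["random_same_size"] = sorted(
                rng2.choice(m.gene_ids, size=size, replace=False)
            )
        out = dec.decode_pair(m, ("r0", "r1"), annotations, q=0.5)
        fixed = out[out["mode"] == "fixed"].set_index("set")
        assert fixed.loc["exact_match", "exact_p"] <= fixed.loc["random_same_size", "exact_p"]
        k = len(selected)
        expect = dec.hypergeometric_tail(k, len(m.gene_ids), k, k)
        assert fixed.loc["exact_match", "exact_p"] == pytest.approx(expect, abs=1e-12)

    def test_planted_set_wins_both_modes(self, planted_expression):
        cfg, matrix, annotations = planted_expression
        m = dec.normalize_by_total(matrix)
        pair = (m.region_labels[cfg.focal_pair[0]], m.region_labels[cfg.focal_pair[1]])
        out = dec.decode_pair(m, pair, annotations)
        for mode in ("fixed", "mhg"):
            sub = out[out["mode"] == mode].sort_values("q", kind="stable")
            assert sub.iloc[0]["set"] == "planted_set"
            assert sub.iloc[0]["q"] < 0.05

    def test_label_permutation_destroys_signal(self, planted_expression):
        cfg, matrix, annotations = planted_expression
        m = dec.normalize_by_total(matrix)
        pair = (m.region_labels[cfg.focal_pair[0]], m.region_labels[cfg.focal_pair[1]])
        rng = np.random.default_rng(60)
        null_ok = 0
        n_perm = 20
        for _ in range(n_perm):
            shuffled = dec.permute_gene_labels(m, rng)
            out = dec.decode_pair(shuffled, pair, annotations)
            qs = out[out["set"] == "planted_set"]["q"]
            if (qs > 0.05).all():
                null_ok += 1
        assert null_ok >= 0.8 * n_perm


class TestRandomPairControl:
    def test_seeded_determinism(self, planted_expression):
        cfg, matrix, annotations = planted_expression
        m = dec.normalize_by_total(matrix)
        pair = (m.region_labels[cfg.focal_pair[0]], m.region_labels[cfg.focal_pair[1]])
        t1 = dec.random_pair_control(m, annotations, focal_pair=pair, n_pairs=3, rng_seed=9)
        t2 = dec.random_pair_control(m, annotations, focal_pair=pair, n_pairs=3, rng_seed=9)
        assert t1.equals(t2)

    def test_zero_controls_gives_focal_row_only(self, planted_expression):
        cfg, matrix, annotations = planted_expression
        m = dec.normalize_by_total(matrix)
        pair = (m.region_labels[cfg.focal_pair[0]], m.region_labels[cfg.focal_pair[1]])
        out = dec.random_pair_control(m, annotations, focal_pair=pair, n_pairs=0, rng_seed=0)
        assert len(out) == 1 and bool(out.iloc[0]["is_focal"])

    def test_focal_pair_never_drawn_as_control(self, planted_expression):
        cfg, matrix, annotations = planted_expression
        m = dec.normalize_by_total(matrix)
        pair = (m.region_labels[cfg.focal_pair[0]], m.region_labels[cfg.focal_pair[1]])
        out = dec.random_pair_control(m, annotations, focal_pair=pair, n_pairs=10, rng_seed=1)
        controls = out[~out["is_focal"]]
        assert not (
            (controls["region_1"].isin(pair)) & (controls["region_2"].isin(pair))
        ).any()
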