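"""Enrichment statistics against independent oracles (enumeration, Monte Carlo)."""
import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olnet.datatypes import GeneModule, GeneSet
from olnet.enrichment import (
    bh_adjust,
    celltype_annotation,
    fisher_enrichment,
    go_enrichment,
    multiset_intersection_test,
)
from olnet.errors import ParameterError


def hypergeom_tail_enumeration(k: int, n_u: int, n_b: int, n_a: int) -> float:
    """P(overlap >= k) by direct summation of hypergeometric point masses."""
    total = comb(n_u, n_a)
    return sum(
        comb(n_b, j) * comb(n_u - n_b, n_a - j)
        for j in range(k, min(n_a, n_b) + 1)
        if n_a - j <= n_u - n_b
    ) / total


class TestFisherEnrichment:
    def test_fold_enrichment_arithmetic(self):
        u = [f"g{i}" for i in range(100)]
        a = set(u[:10])
        b = set(u[5:25])
        r = fisher_enrichment(a, b, u)
        assert r.overlap == 5
        assert r.fold_enrichment == pytest.approx((5 / 10) / (20 / 100))  # 2.5

    def test_full_overlap_small_universe(self):
        u = [chr(65 + i) for i in range(10)]
        r = fisher_enrichment(set(u[:5]), set(u[:5]), u)
        assert r.p_value == pytest.approx(1 / comb(10, 5), rel=1e-12)

    def test_set_equal_to_universe(self):
        u = [f"g{i}" for i in range(30)]
        r = fisher_enrichment(set(u), set(u[:7]), u)
        assert r.p_value == pytest.approx(1.0)
        assert r.fold_enrichment == pytest.approx(1.0)

    def test_empty_inputs_signalled(self):
        with pytest.raises(ParameterError):
            fisher_enrichment(set(), {"a"}, ["a", "b"])
        with pytest.raises(ParameterError):
            fisher_enrichment({"a"}, {"b"}, [])
        with pytest.raises(ParameterError):
            fisher_enrichment({"x"}, {"a"}, ["a", "b"])  # empty after intersection

    def test_matches_enumeration_oracle_small_universes(self):
        for n_u in (5, 10, 15):
            u = [f"g{i}" for i in range(n_u)]
            for n_a, n_b in itertools.product(range(1, n_u + 1), repeat=2):
                a = set(u[:n_a])
                b = set(u[n_u - n_b:])
                r = fisher_enrichment(a, b, u)
                expected = hypergeom_tail_enumeration(r.overlap, n_u, n_b, n_a)
                assert r.p_value == pytest.approx(expected, rel=1e-12)

    def test_null_p_superuniform(self):
        rng = np.random.default_rng(11)
        u = [f"g{i}" for i in range(200)]
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            a = set(rng.choice(u, 20, replace=False))
            b = set(rng.choice(u, 30, replace=False))
            if fisher_enrichment(a, b, u).p_value < 0.05:
                hits += 1
        rate = hits / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rate <= 0.05 + 2 * se


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_equal_values(self):
        assert bh_adjust([0.5]) == [0.5]
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_domain_error(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_on_sorted_input(self, ps):
        adj = bh_adjust(sorted(ps))
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))
        assert all(0 <= a <= 1 for a in adj)


class TestCelltypeAnnotation:
    def _universe(self, n=5000):
        return [f"g{i}" for i in range(n)]

    def test_identical_module_is_argmax(self):
        u = self._universe(500)
        mark = GeneSet("olig", frozenset(u[:60]))
        other = GeneSet("neuron", frozenset(u[100:160]))
        mod = GeneModule("turquoise", frozenset(u[:60]))
        mat, best = celltype_annotation([mod], [mark, other], u, min_module_size=50)
        assert best["turquoise"] == "olig"
        assert mat.loc["turquoise", "olig"] >= mat.loc["turquoise", "neuron"]

    def test_disjoint_module_all_adjusted_one(self):
        u = self._universe(2000)
        mark = GeneSet("olig", frozenset(u[:100]))
        mod = GeneModule("blue", frozenset(u[1000:1060]))
        mat, _ = celltype_annotation([mod], [mark], u, min_module_size=50)
        assert mat.loc["blue", "olig"] == pytest.approx(0.0)  # -log10(1)

    def test_size_floor_excludes_small_modules(self):
        u = self._universe(200)
        small = GeneModule("tiny", frozenset(u[:10]))
        mark = GeneSet("olig", frozenset(u[:50]))
        with pytest.raises(ParameterError):
            celltype_annotation([small], [mark], u, min_module_size=50)

    def test_planted_half_marker_module_argmax(self):
        rng = np.random.default_rng(2)
        u = self._universe(5000)
        marker = GeneSet("O", frozenset(u[:100]))
        decoys = [GeneSet(f"D{j}", frozenset(u[200 + 100 * j: 300 + 100 * j])) for j in range(4)]
        wins = 0
        for rep in range(100):
            half = rng.choice(u[:100], 30, replace=False)
            rest = rng.choice(u[1000:], 30, replace=False)
            mod = GeneModule("m", frozenset(half) | frozenset(rest))
            _, best = celltype_annotation([mod], [marker, *decoys], u, min_module_size=50)
            wins += best["m"] == "O"
        assert wins >= 99


class TestGoEnrichment:
    def _setup(self):
        u = [f"g{i}" for i in range(5000)]
        deg = GeneSet("deg", frozenset(u[:150]))
        return u, deg

    def test_strict_size_window(self):
        u, deg = self._setup()
        t100 = GeneSet("t100", frozenset(u[:100]))
        t101 = GeneSet("t101", frozenset(u[:101]))
        t800 = GeneSet("t800", frozenset(u[:800]))
        t799 = GeneSet("t799", frozenset(u[:799]))
        tab = go_enrichment([deg], [t100, t101, t800, t799], u)
        assert set(tab["term"]) == {"t101", "t799"}

    def test_no_surviving_terms_signalled(self):
        u, deg = self._setup()
        with pytest.raises(ParameterError):
            go_enrichment([deg], [GeneSet("small", frozenset(u[:10]))], u)

    def test_matching_term_ranks_first(self):
        u, _ = self._setup()
        target = GeneSet("match", frozenset(u[:150]))
        decoy = GeneSet("decoy", frozenset(u[2000:2200]))
        deg = GeneSet("deg", frozenset(u[:150]))
        tab = go_enrichment([deg], [target, decoy], u)
        assert tab.iloc[0]["term"] == "match"

    def test_bh_within_each_deg_set(self):
        u, _ = self._setup()
        terms = [GeneSet(f"t{j}", frozenset(u[200 * j: 200 * j + 150])) for j in range(5)]
        d1 = GeneSet("d1", frozenset(u[:150]))
        d2 = GeneSet("d2", frozenset(u[200:350]))
        tab = go_enrichment([d1, d2], terms, u)
        for name, grp in tab.groupby("deg_set"):
            assert np.allclose(grp["adjusted_p"], bh_adjust(list(grp["p_value"])))


class TestMultisetIntersection:
    def test_two_sets_reduce_to_fisher(self):
        u = [f"g{i}" for i in range(60)]
        a = GeneSet("a", frozenset(u[:20]))
        b = GeneSet("b", frozenset(u[10:40]))
        rm = multiset_intersection_test([a, b], universe=u)
        rf = fisher_enrichment(a, b, u)
        assert rm.p_value == pytest.approx(rf.p_value, rel=1e-9)

    def test_expectation_and_unit_fold_enrichment(self):
        r = multiset_intersection_test(
            [frozenset(f"g{i}" for i in range(50)), frozenset(f"g{i}" for i in range(50))],
            universe_size=100, observed=25,
        )
        assert r.expected == pytest.approx(25.0)
        assert r.fold_enrichment == pytest.approx(1.0)

    def test_inconsistent_observed_rejected(self):
        with pytest.raises(ParameterError):
            multiset_intersection_test(
                [frozenset("AB"), frozenset("ABC")], universe_size=10, observed=5
            )

    def test_duplicated_set_degenerates_consistently(self):
        u = [f"g{i}" for i in range(40)]
        s = GeneSet("s", frozenset(u[:15]))
        r = multiset_intersection_test([s, s, s], universe=u)
        assert r.overlap == 15
        assert r.p_value < 1e-6  # far beyond chance for independent draws

    def test_matches_monte_carlo_oracle(self):
        # actual random set draws, independent of the convolution implementation
        rng = np.random.default_rng(5)
        n_u, sizes, B = 80, (15, 25, 35), 40_000
        u = [f"g{i}" for i in range(n_u)]
        for inst in range(5):
            sets = [frozenset(rng.choice(u, s, replace=False)) for s in sizes]
            obs = len(sets[0] & sets[1] & sets[2])
            r = multiset_intersection_test([GeneSet(str(i), s) for i, s in enumerate(sets)],
                                           universe=u)
            masks = []
            for s in sizes:
                order = np.argsort(rng.random((B, n_u)), axis=1)[:, :s]
                m = np.zeros((B, n_u), dtype=bool)
                np.put_along_axis(m, order, True, axis=1)
                masks.append(m)
            inter = (masks[0] & masks[1] & masks[2]).sum(axis=1)
            mc = (inter >= obs).mean()
            se = max(np.sqrt(mc * (1 - mc) / B), 1.0 / B)
            assert abs(r.p_value - mc) <= 3 * se

    def test_extreme_p_representable_in_log_space(self):
        u_size = 20_000
        sets = [frozenset(f"g{i}" for i in range(1500)) for _ in range(3)]
        r = multiset_intersection_test(sets, universe_size=u_size, observed=1500)
        assert r.p_value == 0.0 or r.p_value < 1e-300
        assert np.isfinite(r.log_p) and r.log_p < -200
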