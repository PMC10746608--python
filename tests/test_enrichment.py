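import numpy as np
import pytest
from conftest import bh_stepup_oracle, hypergeom_tail_oracle, make_library
from hypothesis import given
from hypothesis import strategies as st

from coretf.enrichment import (
    EnrichmentTable,
    bh_adjust,
    combine_libraries,
    enrich,
    odds_ratio,
    overlap_pvalue,
)
from coretf.io import GeneList


class TestOverlapPvalue:
    @pytest.mark.parametrize("K,n,N", [(3, 3, 10), (10, 10, 100), (0, 5, 20), (5, 0, 20)])
    def test_zero_overlap_gives_one(self, K, n, N):
        assert overlap_pvalue(0, K, n, N) == 1.0

    def test_complete_containment_small(self):
        # drawing 3 of 3 marked genes in 3 tries out of 10: 1/C(10,3)
        assert overlap_pvalue(3, 3, 3, 10) == pytest.approx(1 / 120, rel=1e-12)

    def test_half_overlap_matches_bruteforce(self):
        expected = hypergeom_tail_oracle(5, 10, 10, 100)
        assert expected == pytest.approx(6.716277482651382e-04, rel=1e-9)
        assert overlap_pvalue(5, 10, 10, 100) == pytest.approx(expected, rel=1e-12)

    def test_bruteforce_equivalence_on_small_grid(self):
        for N in (1, 2, 7, 19, 40, 60):
            for K in range(0, N + 1, max(1, N // 7)):
                for n in range(0, N + 1, max(1, N // 7)):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        assert overlap_pvalue(k, K, n, N) == pytest.approx(
                            hypergeom_tail_oracle(k, K, n, N), rel=1e-12
                        )

    def test_pmf_conservation(self):
        # the oracle's full-support tail from the minimum k is the whole mass
        for K, n, N in [(10, 10, 100), (50, 100, 2000), (7, 3, 12)]:
            assert hypergeom_tail_oracle(max(0, K + n - N), K, n, N) == pytest.approx(1.0, abs=1e-12)

    @given(st.data())
    def test_monotone_in_k_and_K(self, data):
        N = data.draw(st.integers(2, 80))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        ks = range(max(0, K + n - N), min(K, n) + 1)
        ps = [overlap_pvalue(k, K, n, N) for k in ks]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        # enlarging the set cannot make the same overlap more surprising
        k = data.draw(st.sampled_from(list(ks)))
        if K + 1 <= N and k <= min(K + 1, n) and k >= max(0, K + 1 + n - N):
            assert overlap_pvalue(k, K + 1, n, N) >= overlap_pvalue(k, K, n, N) - 1e-15

    def test_bounds_violation_rejected(self):
        with pytest.raises(ValueError):
            overlap_pvalue(5, 3, 3, 10)
        with pytest.raises(ValueError):
            overlap_pvalue(0, 11, 3, 10)
        with pytest.raises(ValueError):
            overlap_pvalue(0, 3, 3, 0)


class TestOddsRatio:
    def test_direct_arithmetic(self):
        # table [[5,5],[5,85]]
        assert odds_ratio(5, 10, 10, 100) == pytest.approx(17.0)

    def test_independence_case(self):
        # table [[1,9],[9,81]]: equal cross-products
        assert odds_ratio(1, 10, 10, 100) == pytest.approx(1.0)

    def test_zero_cell_stays_finite(self):
        value = odds_ratio(3, 3, 3, 10)  # complete containment, two zero cells
        assert np.isfinite(value) and value > 0
        # Haldane-Anscombe: (3.5*7.5)/(0.5*0.5)
        assert value == pytest.approx(3.5 * 7.5 / 0.25)


class TestBHAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.005, 0.04, 0.04, 0.8], [0.02, 0.8 / 15, 0.8 / 15, 0.8]),
        ],
    )
    def test_worked_stepup_vectors(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected, rel=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_stepup_oracle_and_dominates_input(self, p):
        q = bh_adjust(p)
        assert q == pytest.approx(bh_stepup_oracle(p), rel=1e-9, abs=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12) and np.all(q <= 1 + 1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.randoms())
    def test_permutation_equivariant(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = bh_adjust(p)
        q_perm = bh_adjust([p[i] for i in perm])
        assert q_perm == pytest.approx([q[i] for i in perm], rel=1e-12, abs=1e-15)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.sampled_from([0.01, 0.05, 0.1]))
    def test_thresholding_equals_stepup_rejection_set(self, p, alpha):
        """p_adj < alpha selects exactly the BH step-up rejection set
        (with the strict-inequality convention used throughout)."""
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        k_rej = 0
        for rank in range(1, m + 1):
            if p[order[rank - 1]] * m / rank < alpha:
                k_rej = rank
        expected = set(order[:k_rej])
        got = {i for i, q in enumerate(bh_adjust(p)) if q < alpha}
        assert got == expected

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestEnrich:
    def _query(self, symbols, label="q"):
        return GeneList.from_iterable(symbols, label=label)

    def test_disjoint_query_all_null(self):
        lib = make_library({"S1": {"A", "B"}, "S2": {"C"}}, background_size=100)
        table = enrich(self._query(["X", "Y", "Z"]), lib, threshold=0.5)
        assert all(r.p_raw == 1.0 and r.p_adj == 1.0 for r in table.records)
        assert table.significant() == ()

    def test_set_identical_to_query_hits_minimal_p(self):
        genes = {f"G{i}" for i in range(10)}
        lib = make_library({"EXACT": genes}, background_size=22000)
        table = enrich(self._query(sorted(genes)), lib)
        (rec,) = table.records
        assert rec.k == 10
        assert rec.p_raw == pytest.approx(hypergeom_tail_oracle(10, 10, 10, 22000), rel=1e-12)

    def test_adjustment_spans_whole_library(self):
        sets = {f"S{i}": {f"G{i}"} for i in range(20)}
        sets["HIT"] = {f"Q{j}" for j in range(5)}
        lib = make_library(sets, background_size=1000)
        table = enrich(self._query([f"Q{j}" for j in range(5)]), lib)
        hit = next(r for r in table.records if r.set_name == "HIT")
        # m=21 tests; the only non-unit p gets the full BH multiplicity
        assert hit.p_adj == pytest.approx(min(1.0, hit.p_raw * 21), rel=1e-9)

    def test_set_order_irrelevant(self):
        sets = {f"S{i}": {f"G{j}" for j in range(i, i + 5)} for i in range(10)}
        lib_fwd = make_library(sets, background_size=500)
        lib_rev = make_library(dict(reversed(list(sets.items()))), background_size=500)
        q = self._query(["G0", "G1", "G2", "G7"])
        assert enrich(q, lib_fwd).records == enrich(q, lib_rev).records

    def test_effective_query_restricted_to_universe(self):
        universe = {f"G{i}" for i in range(50)}
        lib = make_library({"S": {"G0", "G1"}}, background_size=50, universe=universe)
        table = enrich(self._query(["G0", "G1", "NOT_THERE"]), lib)
        assert table.records[0].n == 2

    def test_record_invariants(self):
        lib = make_library({"S1": {"A", "B", "C"}, "S2": {"A"}}, background_size=30)
        table = enrich(self._query(["A", "B", "X"]), lib)
        for r in table.records:
            assert 0 <= r.k <= min(r.K, r.n)
            assert len(r.overlap_members) == r.k
            assert r.p_raw <= r.p_adj <= 1.0

    def test_empty_inputs_rejected(self):
        lib = make_library({"S": {"A"}}, background_size=10)
        with pytest.raises(ValueError):
            enrich(GeneList(label="e", symbols=()), lib)
        empty_lib = make_library({}, background_size=10)
        with pytest.raises(ValueError):
            enrich(self._query(["A"]), empty_lib)


class TestCombineLibraries:
    def _table(self, lib_id, name_p):
        lib = make_library({n: {f"X{i}" for i in range(3)} for n, _ in name_p},
                           library_id=lib_id, background_size=100)
        # build via enrich to keep records internally consistent
        q = GeneList.from_iterable([f"X{i}" for i in range(3)], label="q")
        return enrich(q, lib)

    def test_single_table_identity(self):
        t = self._table("L1", [("A", 0.1)])
        combined = combine_libraries([t])
        assert combined.records == t.records

    def test_merged_order_sorted_by_adjusted_p(self):
        lib1 = make_library({"A1": {"Q0", "Q1"}, "A2": {"Z0"}}, "L1", background_size=200)
        lib2 = make_library({"B1": {"Q0", "Q1", "Q2"}, "B2": {"Z1"}}, "L2", background_size=200)
        q = GeneList.from_iterable(["Q0", "Q1", "Q2"], label="q")
        combined = combine_libraries([enrich(q, lib1), enrich(q, lib2)])
        ps = [r.p_adj for r in combined.records]
        assert ps == sorted(ps)
        assert {r.library_id for r in combined.records} == {"L1", "L2"}

    def test_mixed_queries_rejected(self):
        lib = make_library({"A": {"Q0"}}, background_size=100)
        t1 = enrich(GeneList.from_iterable(["Q0"], label="q1"), lib)
        t2 = enrich(GeneList.from_iterable(["Q0"], label="q2"), lib)
        with pytest.raises(ValueError, match="different queries"):
            combine_libraries([t1, t2])

    def test_duplicate_set_names_kept_distinct(self):
        lib1 = make_library({"SAME": {"Q0"}}, "L1", background_size=100)
        lib2 = make_library({"SAME": {"Q0"}}, "L2", background_size=100)
        q = GeneList.from_iterable(["Q0"], label="q")
        combined = combine_libraries([enrich(q, lib1), enrich(q, lib2)])
        assert len(combined) == 2
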