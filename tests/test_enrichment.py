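import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from setnet import (
    DataError,
    GeneSetLibrary,
    benjamini_hochberg,
    bonferroni,
    fisher_overlap,
    overlap_matrix,
    rank_terms,
)
from conftest import gl
from oracles import bh_step_up, hypergeom_upper_tail


class TestFisherOverlap:
    def test_full_overlap_single_tail_term(self):
        # N=20, a=b=k=5: p = 1/C(20,5) = 1/15504
        universe = {f"G{i}" for i in range(20)}
        shared = sorted(universe)[:5]
        t = fisher_overlap(gl("u", *shared), gl("s", *shared), universe)
        assert t.k == 5 and t.a == 5 and t.b == 5 and t.N == 20
        assert t.p_raw == pytest.approx(1 / 15504, rel=1e-12)

    def test_brute_force_sum_example(self):
        # N=10, a=4, b=5, k=4: p = C(5,4)*C(5,0)/C(10,4) = 5/210
        universe = {f"G{i}" for i in range(10)}
        ordered = sorted(universe)
        t = fisher_overlap(gl("u", *ordered[:4]), gl("s", *ordered[:5]), universe)
        assert t.k == 4
        assert t.p_raw == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_is_p_one(self):
        universe = {f"G{i}" for i in range(30)}
        ordered = sorted(universe)
        t = fisher_overlap(gl("u", *ordered[:6]), gl("s", *ordered[6:12]), universe)
        assert t.k == 0 and t.p_raw == 1.0

    def test_genes_outside_universe_dropped(self):
        t = fisher_overlap(gl("u", "A", "B", "ZZZ"), gl("s", "A", "C"), set("ABCDEF"))
        assert t.a == 2 and t.b == 2 and t.k == 1 and t.overlap_genes == ("A",)

    def test_empty_after_restriction_is_degenerate(self):
        t = fisher_overlap(gl("u", "X", "Y"), gl("s", "A"), set("ABC"))
        assert t.degenerate and t.k == 0 and t.p_raw == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(DataError):
            fisher_overlap(gl("u", "A"), gl("s", "A"), set())

    def test_agrees_with_scipy_fisher_exact(self):
        # cross-check against the 2x2 contingency-table route
        universe = {f"G{i}" for i in range(50)}
        ordered = sorted(universe)
        user, libset = gl("u", *ordered[:12]), gl("s", *ordered[8:25])
        t = fisher_overlap(user, libset, universe)
        table = [[t.k, t.a - t.k], [t.b - t.k, t.N - t.a - t.b + t.k]]
        assert t.p_raw == pytest.approx(fisher_exact(table, alternative="greater")[1], rel=1e-9)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_exact_rational_oracle(self, data):
        N = data.draw(st.integers(2, 60))
        a = data.draw(st.integers(1, N))
        b = data.draw(st.integers(1, N))
        k_max = min(a, b)
        k_min = max(0, a + b - N)  # overlap is forced when a+b > N
        k = data.draw(st.integers(max(1, k_min), k_max))
        universe = [f"G{i:03d}" for i in range(N)]
        user = universe[:k] + universe[b : b + (a - k)]
        libset = universe[:b]
        t = fisher_overlap(gl("u", *user), gl("s", *libset), set(universe))
        assert t.k == k
        expected = float(hypergeom_upper_tail(k, a, b, N))
        assert t.p_raw == pytest.approx(expected, rel=1e-9)

    def test_monotone_nonincreasing_in_k(self):
        N, a, b = 40, 10, 15
        universe = [f"G{i:03d}" for i in range(N)]
        libset = gl("s", *universe[:b])
        prev = 1.1
        for k in range(max(0, a + b - N), min(a, b) + 1):
            user = gl("u", *(universe[:k] + universe[b : b + (a - k)]))
            p = fisher_overlap(user, libset, set(universe)).p_raw
            assert p <= prev + 1e-15
            prev = p


class TestCorrections:
    def test_bonferroni_multiplies_and_caps(self):
        assert bonferroni([0.01, 0.30]).tolist() == pytest.approx([0.02, 0.60])
        assert bonferroni([0.70, 0.90]).tolist() == [1.0, 1.0]
        assert bonferroni([0.05]).tolist() == [0.05]

    def test_bh_worked_example(self):
        out = benjamini_hochberg([0.005, 0.011, 0.02, 0.04])
        assert out == pytest.approx([0.02, 0.022, 0.0267, 0.04], rel=1e-2)

    def test_bh_singleton_and_constant_vectors(self):
        assert benjamini_hochberg([0.5]).tolist() == [0.5]
        assert benjamini_hochberg([0.3] * 5) == pytest.approx([0.3] * 5)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [-0.1], [float("nan")]])
    def test_out_of_range_pvalues_rejected(self, bad):
        with pytest.raises(DataError):
            bonferroni(bad)
        with pytest.raises(DataError):
            benjamini_hochberg(bad)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=60))
    def test_bh_matches_independent_step_up(self, pvals):
        ours = benjamini_hochberg(pvals)
        ref = bh_step_up(pvals)
        assert ours == pytest.approx(ref, rel=1e-9)
        bonf = bonferroni(pvals)
        assert np.all(ours >= np.asarray(pvals) - 1e-12)
        assert np.all(ours <= bonf + 1e-12)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30), st.randoms(use_true_random=False))
    def test_bh_order_equivariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        base = benjamini_hochberg(pvals)
        shuffled = benjamini_hochberg([pvals[i] for i in perm])
        assert shuffled == pytest.approx([base[i] for i in perm], rel=1e-12)


class TestOverlapMatrix:
    def test_shape_and_shared_universe(self, small_library):
        users = [gl("u1", "A", "B"), gl("u2", "C", "F")]
        m = overlap_matrix(users, small_library)
        assert m.p_raw.shape == (3, 2)
        assert len(m.cells) == 6
        assert {c.N for c in m.cells.values()} == {len(small_library.universe)}
        assert m.p_bonferroni.shape == m.p_bh.shape == (3, 2)

    def test_identical_list_is_column_minimum(self, small_library):
        users = [gl("u1", "C", "D", "E")]  # identical to S2
        m = overlap_matrix(users, small_library)
        cell = m.cells[("S2", "u1")]
        assert cell.k == cell.a == cell.b == 3
        assert m.p_raw["u1"].idxmin() == "S2"

    def test_disjoint_user_list_gets_all_ones(self, small_library):
        m = overlap_matrix([gl("u1", "ZZ1", "ZZ2")], small_library, universe_policy="union")
        assert (m.p_raw["u1"] == 1.0).all()

    def test_corrected_ge_raw_and_le_one(self, small_library):
        m = overlap_matrix([gl("u1", "A", "C", "E"), gl("u2", "B", "F")], small_library)
        assert ((m.p_bonferroni >= m.p_raw - 1e-15).all()).all()
        assert ((m.p_bh >= m.p_raw - 1e-15).all()).all()
        assert ((m.p_bonferroni <= 1.0).all()).all() and ((m.p_bh <= 1.0).all()).all()

    def test_union_policy_adds_user_genes_to_N(self, small_library):
        users = [gl("u1", "A", "NOVEL1", "NOVEL2")]
        m_lib = overlap_matrix(users, small_library, universe_policy="library")
        m_union = overlap_matrix(users, small_library, universe_policy="union")
        assert len(m_union.universe) == len(m_lib.universe) + 2
        assert m_lib.dropped_user_genes["u1"] == 2
        assert m_union.dropped_user_genes["u1"] == 0

    def test_empty_custom_universe_rejected(self, small_library):
        with pytest.raises(DataError):
            overlap_matrix([gl("u1", "A")], small_library, universe_policy="custom", universe=[])

    def test_matrix_scope_corrects_over_all_cells(self, small_library):
        users = [gl("u1", "A", "B", "C", "D"), gl("u2", "F", "G")]
        col = overlap_matrix(users, small_library, correction_scope="column")
        mat = overlap_matrix(users, small_library, correction_scope="matrix")
        assert (mat.p_bonferroni.to_numpy() >= col.p_bonferroni.to_numpy() - 1e-15).all()


class TestRankTerms:
    def test_sorted_by_p_raw(self, small_library):
        m = overlap_matrix([gl("u1", "A", "B", "C", "D")], small_library)
        table = rank_terms(m, "u1")
        assert list(table["p_raw"]) == sorted(table["p_raw"])
        assert table.iloc[0]["term"] == "S1"

    def test_tie_break_by_descending_k_then_label(self):
        lib = GeneSetLibrary(
            "lib",
            [gl("T_b", "X1"), gl("T_a", "X2"), gl("BIG", "A", "B", "C")],
        )
        m = overlap_matrix(
            [gl("u", "A", "B", "C")], lib, universe_policy="union"
        )
        table = rank_terms(m, "u")
        # BIG overlaps (k=3); T_a and T_b tie at p=1, k=0 -> label order
        assert list(table["term"]) == ["BIG", "T_a", "T_b"]

    def test_unknown_column_rejected(self, small_library):
        m = overlap_matrix([gl("u1", "A")], small_library)
        with pytest.raises(DataError):
            rank_terms(m, "nope")
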