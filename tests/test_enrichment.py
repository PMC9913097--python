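import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import coextree as ct
from oracles import bh_stepup, hypergeom_upper_tail_exact


class TestHypergeomPvalue:
    def test_zero_hits_gives_one(self):
        assert ct.hypergeom_pvalue(100, 10, 20, 0) == 1.0

    def test_enumerated_example(self):
        # draws of 5 from 10 with 4 special: only C(4,4)*C(6,1)=6 of C(10,5)=252
        # draws contain all four
        assert ct.hypergeom_pvalue(10, 4, 5, 4) == pytest.approx(6 / 252, abs=1e-12)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            ct.hypergeom_pvalue(10, 4, 5, 5)
        with pytest.raises(ValueError, match="invalid sizes"):
            ct.hypergeom_pvalue(10, 11, 5, 1)

    def test_matches_enumeration_for_small_universes(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        exact = float(hypergeom_upper_tail_exact(N, K, n, k))
                        assert ct.hypergeom_pvalue(N, K, n, k) == pytest.approx(
                            exact, abs=1e-12
                        )

    def test_monotone_decreasing_in_k(self):
        ps = [ct.hypergeom_pvalue(50, 12, 20, k) for k in range(13)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.2], [0.2]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.005, 0.009, 0.05, 0.5], [0.018, 0.018, 0.05 * 4 / 3, 0.5]),
        ],
    )
    def test_hand_executed_step_up(self, p, expected):
        np.testing.assert_allclose(ct.bh_fdr(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ct.bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1,
                 max_size=30)
    )
    def test_matches_literal_step_up_and_dominates_p(self, p):
        adj = ct.bh_fdr(p)
        np.testing.assert_allclose(adj, bh_stepup(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()

    @given(st.permutations(list(range(6))))
    def test_invariant_to_input_order(self, perm):
        p = [0.001, 0.02, 0.3, 0.04, 0.9, 0.11]
        shuffled = [p[i] for i in perm]
        adj_ref = ct.bh_fdr(p)
        adj = ct.bh_fdr(shuffled)
        np.testing.assert_allclose([adj_ref[i] for i in perm], adj, atol=1e-15)


class TestEnrich:
    def universe(self, n):
        return [f"U{i:04d}" for i in range(n)]

    def test_reporting_statistics_arithmetic(self):
        # N=100, K=10, n=20, k=8 -> expected 2, over-representation 4, hit 80%
        uni = self.universe(100)
        term_genes = uni[:10]
        clade = uni[:8] + uni[50:62]  # 8 hits, clade size 20
        lib = ct.TermLibrary("t", {"T1": ("term one", frozenset(term_genes))})
        rows = ct.enrich(clade, lib, uni)
        (row,) = rows
        assert (row.k, row.n, row.K, row.N) == (8, 20, 10, 100)
        assert row.expected == pytest.approx(2.0)
        assert row.over_representation == pytest.approx(4.0)
        assert row.hit_percent == pytest.approx(80.0)
        assert row.p == pytest.approx(ct.hypergeom_pvalue(100, 10, 20, 8))

    def test_hit_percent_at_published_scale(self):
        # a term describing 387 universe genes, 180 of which fall in the clade
        uni = self.universe(14000)
        term_genes = uni[:387]
        clade = uni[:180] + uni[1000:1218]  # clade of 398 genes
        lib = ct.TermLibrary("t", {"T": ("big term", frozenset(term_genes))})
        (row,) = ct.enrich(clade, lib, uni)
        assert row.k == 180 and row.K == 387
        assert round(row.hit_percent, 1) == 46.5

    def test_no_hits_anywhere_gives_empty_result(self):
        uni = self.universe(50)
        lib = ct.TermLibrary("t", {"T": ("d", frozenset(uni[40:45]))})
        assert ct.enrich(uni[:5], lib, uni) == []

    def test_insignificant_terms_filtered_by_adjusted_p(self):
        uni = self.universe(100)
        lib = ct.TermLibrary("t", {"T": ("d", frozenset(uni[:50]))})
        rows = ct.enrich(uni[:2] + uni[98:], lib, uni)  # 2/4 hits of a 50% term
        assert rows == []

    def test_versioned_ids_match_stable_ids(self):
        uni = [f"ENSG{i:04d}" for i in range(40)]
        lib = ct.TermLibrary("t", {"T": ("d", frozenset(uni[:5]))})
        clade = [f"{g}.7" for g in uni[:5]]
        (row,) = ct.enrich(clade, lib, uni)
        assert row.k == 5

    def test_clade_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            ct.enrich(["X"], ct.TermLibrary("t", {"T": ("d", frozenset(["U1"]))}),
                      ["U1"])

    def test_planted_module_term_ranks_first(self, module_data):
        m, modules = module_data
        t = ct.build_coexpression_tree(m)
        driver = modules["MOD1"][0]
        c = ct.default_clade(t, driver)
        lib = ct.make_term_library(modules, m.gene_ids, n_decoys=6, seed=3)
        rows = ct.enrich(c.gene_ids, lib, t.leaf_names())
        assert rows[0].term_id == "TERM_MOD1"


def test_gmt_round_trip(tmp_path):
    lib = ct.TermLibrary(
        "cat",
        {
            "T1": ("first term", frozenset({"G1", "G2"})),
            "T2": ("second term", frozenset({"G3"})),
        },
    )
    path = tmp_path / "lib.gmt"
    ct.write_gmt(lib, path)
    back = ct.read_gmt(path, "cat")
    assert back.terms == lib.terms


def test_gmt_malformed_line_rejected(tmp_path):
    path = tmp_path / "bad.gmt"
    path.write_text("ONLY_TWO\tfields\n")
    with pytest.raises(ValueError, match="line 1"):
        ct.read_gmt(path)
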