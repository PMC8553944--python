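"""Differentiation and diversity statistics against direct-formula oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import diversity_bruteforce, wc_fst_bruteforce
from conftest import make_genotypes
from rangeshift import popgen
from rangeshift._utils import adjust_pvalues
from rangeshift.datatypes import PairwiseStatMatrix
from rangeshift.simulate import GenotypeSimSpec, simulate_genotypes


def _random_table(rng, n_pops=2):
    n_per = int(rng.integers(5, 12))
    n_loci = int(rng.integers(3, 9))
    blocks, sites = [], []
    for k in range(n_pops):
        p = rng.uniform(0.1, 0.9, n_loci)
        b = rng.binomial(2, p, size=(n_per, n_loci)).astype(np.int8)
        miss = rng.random(b.shape) < 0.1
        b[miss] = -1
        blocks.append(b)
        sites += [f"p{k}"] * n_per
    return np.vstack(blocks), sites, blocks


class TestWeirCockerham:
    def test_matches_bruteforce_oracle_on_random_tables(self, rng):
        for _ in range(100):
            calls, sites, blocks = _random_table(rng, n_pops=int(rng.integers(2, 4)))
            g = make_genotypes(calls, sites)
            masks = g.site_masks()
            _, n, p, h = popgen.pop_locus_stats(g, masks)
            a, b, c = popgen.wc_components(n, p, h)
            ours = popgen.wc_multilocus(a, b, c)
            oracle = wc_fst_bruteforce(blocks)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_identical_populations_give_near_zero(self, rng):
        # two samples from one panmictic population: E[theta] = 0
        p = rng.uniform(0.2, 0.8, 500)
        a = rng.binomial(2, p, size=(50, 500)).astype(np.int8)
        b = rng.binomial(2, p, size=(50, 500)).astype(np.int8)
        g = make_genotypes(np.vstack([a, b]), ["a"] * 50 + ["b"] * 50)
        m = popgen.pairwise_fst(g, n_boot=500, seed=0)
        assert abs(m.estimates[0, 1]) < 0.02
        assert m.ci_lo[0, 1] <= 0 <= m.ci_hi[0, 1]

    def test_fixed_differences_give_one(self):
        calls = np.vstack([np.zeros((10, 5)), np.full((10, 5), 2)]).astype(np.int8)
        g = make_genotypes(calls, ["a"] * 10 + ["b"] * 10)
        m = popgen.pairwise_fst(g, n_boot=100, seed=0)
        assert m.estimates[0, 1] == pytest.approx(1.0, abs=1e-12)


class TestDiversity:
    def test_fixed_population_has_zero_diversity(self):
        calls = np.zeros((10, 5), dtype=np.int8)
        calls[:, 0] = [0] * 9 + [1]  # one locus barely polymorphic overall
        g = make_genotypes(np.vstack([calls, calls]), ["a"] * 10 + ["b"] * 10)
        # population 'a' restricted to its fixed loci
        div = popgen.diversity_stats(g, n_perm=20, seed=0)
        assert div.loc["a", "Ho"] < 0.06 and div.loc["a", "He"] < 0.1
        assert 1.0 <= div.loc["a", "allelic_richness"] <= 2.0

    def test_hwe_locus_half_frequency(self):
        # p = 0.5 under perfect HWE proportions (5, 10, 5): He = 0.5 exactly
        col = np.array([0] * 5 + [1] * 10 + [2] * 5, dtype=np.int8)
        calls = np.stack([col, col], axis=1)
        calls = np.vstack([calls, calls])  # two populations of 20
        g = make_genotypes(calls, ["a"] * 20 + ["b"] * 20)
        div = popgen.diversity_stats(g, n_perm=20, seed=0)
        assert div.loc["a", "He"] == pytest.approx(0.5, abs=1e-12)
        assert div.loc["a", "Ho"] == pytest.approx(0.5, abs=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        calls, sites, blocks = _random_table(rng, n_pops=3)
        g = make_genotypes(calls, sites)
        div = popgen.diversity_stats(g, n_perm=10, seed=0)
        for k, block in enumerate(blocks):
            ho, he = diversity_bruteforce(block)
            assert div.loc[f"p{k}", "Ho"] == pytest.approx(ho, abs=1e-12)
            assert div.loc[f"p{k}", "He"] == pytest.approx(he, abs=1e-12)

    def test_single_individual_population_excluded(self, rng):
        calls, sites, _ = _random_table(rng)
        sites[-1] = "lonely"
        g = make_genotypes(calls, sites)
        with pytest.warns(UserWarning, match="excluded"):
            div = popgen.diversity_stats(g, n_perm=10, seed=0)
        assert "lonely" not in div.index


class TestGstJostD:
    def _two_pop_table(self):
        # exact frequencies 0.2 and 0.8 at every locus (10 diploids each)
        pa = [1, 1, 1, 1] + [0] * 6  # 4/20 minor alleles
        pb = [2, 2, 2, 2, 2, 2, 2, 1, 1, 0]  # 16/20
        calls = np.vstack([np.column_stack([pa, pa]), np.column_stack([pb, pb])])
        return make_genotypes(calls.astype(np.int8), ["a"] * 10 + ["b"] * 10)

    def test_hand_computed_gst_and_d(self):
        # H_S = 0.32, H_T = 0.5 -> G_st = 0.36, D = (0.18/0.68)*2
        g = self._two_pop_table()
        gst, d = popgen.pairwise_gst_jostd(g, n_iter=50, seed=0)
        assert gst.estimates[0, 1] == pytest.approx(0.36, abs=1e-12)
        assert d.estimates[0, 1] == pytest.approx(0.18 / 0.68 * 2, abs=1e-12)

    def test_identical_populations_give_zero(self, rng):
        block = rng.binomial(2, rng.uniform(0.3, 0.7, 10), size=(12, 10)).astype(np.int8)
        g = make_genotypes(np.vstack([block, block]), ["a"] * 12 + ["b"] * 12)
        gst, d = popgen.pairwise_gst_jostd(g, n_iter=50, seed=0)
        assert gst.estimates[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d.estimates[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_gst_bounded_by_one(self, rng):
        for _ in range(10):
            calls, sites, _ = _random_table(rng, n_pops=2)
            g = make_genotypes(calls, sites)
            gst, _ = popgen.pairwise_gst_jostd(g, n_iter=10, seed=0)
            assert gst.estimates[0, 1] <= 1.0 + 1e-12


class TestShiftNonnegative:
    def _matrix(self, vals):
        k = vals.shape[0]
        return PairwiseStatMatrix(statistic="F_st", sites=[f"s{i}" for i in range(k)],
                                  estimates=vals)

    def test_negative_minimum_shifted_to_zero(self):
        vals = np.array([[0, -0.003, 0.01], [-0.003, 0, 0.02], [0.01, 0.02, 0]])
        out = popgen.shift_nonnegative(self._matrix(vals))
        iu = np.triu_indices(3, 1)
        assert out.estimates[iu].min() == pytest.approx(0.0, abs=1e-15)
        assert out.shift_constant == pytest.approx(0.003)

    def test_nonnegative_matrix_unchanged(self):
        vals = np.array([[0, 0.01], [0.01, 0]])
        out = popgen.shift_nonnegative(self._matrix(vals))
        assert out.shift_constant == 0.0
        assert np.array_equal(out.estimates, vals)

    def test_pair_ordering_preserved(self, rng):
        vals = rng.normal(0, 0.01, (4, 4))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        m = self._matrix(vals)
        out = popgen.shift_nonnegative(m)
        iu = np.triu_indices(4, 1)
        assert np.array_equal(np.argsort(m.estimates[iu]), np.argsort(out.estimates[iu]))


class TestMantel:
    def _stat(self, vals, sites):
        return PairwiseStatMatrix(statistic="F_st", sites=sites, estimates=vals)

    def test_three_site_hand_example(self):
        sites = ["a", "b", "c"]
        fst = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        d = np.array([[0, 10.0, 30.0], [10, 0, 45.0], [30, 45, 0]])
        lin = fst[np.triu_indices(3, 1)] / (1 - fst[np.triu_indices(3, 1)])
        expected_r = np.corrcoef(lin, d[np.triu_indices(3, 1)])[0, 1]
        res = popgen.mantel_ibd(self._stat(fst, sites), pd.DataFrame(d, index=sites, columns=sites),
                                n_perm=100, seed=0)
        assert res.r == pytest.approx(expected_r, abs=1e-12)

    def test_proportional_matrices_give_r_one_and_floor_p(self, rng):
        k = 7
        sites = [f"s{i}" for i in range(k)]
        fst = rng.uniform(0.01, 0.3, (k, k))
        fst = (fst + fst.T) / 2
        np.fill_diagonal(fst, 0)
        d = 1000 * fst / (1 - fst)
        res = popgen.mantel_ibd(self._stat(fst, sites), pd.DataFrame(d, index=sites, columns=sites),
                                n_perm=999, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p >= 1 / (999 + 1)
        assert res.p < 0.02

    def test_fst_of_one_excluded_with_warning(self):
        sites = ["a", "b", "c"]
        fst = np.array([[0, 1.0, 0.2], [1.0, 0, 0.3], [0.2, 0.3, 0]])
        d = np.array([[0, 10.0, 30.0], [10, 0, 45.0], [30, 45, 0]])
        with pytest.warns(UserWarning, match="excluded"):
            res = popgen.mantel_ibd(self._stat(fst, sites),
                                    pd.DataFrame(d, index=sites, columns=sites),
                                    n_perm=50, seed=0)
        assert res.n_excluded == 1


class TestMultipleTesting:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=30))
    def test_by_adjustment_monotone_and_at_least_raw(self, pvals):
        p = np.array(pvals)
        adj = adjust_pvalues(p, "BY")
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def test_balding_nichols_fst_tracks_target():
    # E[multilocus estimate] follows the generating F (coarse grid here;
    # the full sweep runs in the acceptance suite)
    for f in (0.05, 0.2):
        ests = []
        for seed in range(5):
            g = simulate_genotypes(GenotypeSimSpec(n_loci=1000, target_fst=f, seed=seed))
            _, n, p, h = popgen.pop_locus_stats(g, g.site_masks())
            ests.append(popgen.wc_multilocus(*popgen.wc_components(n, p, h)))
        assert np.mean(ests) == pytest.approx(f, abs=0.02)
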