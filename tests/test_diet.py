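"""OTU curation rules and community statistics against hand examples,
planted truth, and an independent reference implementation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from oracles import bray_curtis_bruteforce
from conftest import make_otu_table
from rangeshift import diet
from rangeshift.simulate import OTUSimSpec, simulate_otu_table


def _groups(n_per, names=("ga", "gb")):
    out = {}
    for name in names:
        for i in range(n_per):
            out[f"{name}{i}"] = name
    return out


class TestNormalizeDepth:
    def test_columns_sum_to_depth(self):
        t = simulate_otu_table(OTUSimSpec(n_otus=50, read_depth_range=(40000, 50000), seed=1))
        out = diet.normalize_depth(t, depth=30000, seed=2)
        sums = out.counts[out.biological_samples()].sum()
        assert set(sums) == {30000}

    def test_sample_exactly_at_depth_unchanged(self):
        groups = {"s1": "g", "s2": "g"}
        counts = {"o1": {"s1": 20000, "s2": 500}, "o2": {"s1": 10000, "s2": 40000}}
        t = make_otu_table(counts, groups)
        out = diet.normalize_depth(t, depth=30000, seed=0)
        assert out.counts["s1"].tolist() == [20000, 10000]

    def test_shallow_samples_dropped_with_warning(self):
        groups = {"s1": "g", "s2": "g"}
        counts = {"o1": {"s1": 40000, "s2": 10}, "o2": {"s1": 100, "s2": 5}}
        t = make_otu_table(counts, groups)
        with pytest.warns(UserWarning, match="dropped"):
            out = diet.normalize_depth(t, depth=30000, seed=0)
        assert "s2" not in out.counts.columns

    def test_proportions_preserved_in_expectation(self):
        groups = {"s1": "g", "s2": "g"}
        counts = {"o1": {"s1": 30000, "s2": 30000}, "o2": {"s1": 70000, "s2": 70000}}
        t = make_otu_table(counts, groups)
        fracs = []
        for seed in range(100):
            out = diet.normalize_depth(t, depth=30000, seed=seed)
            fracs.append(out.counts.loc["o1", "s1"] / 30000)
        # hypergeometric mean 0.3, SE of the mean over 100 draws ~ 0.0002
        assert np.mean(fracs) == pytest.approx(0.3, abs=0.002)

    def test_error_when_everything_shallow(self):
        t = make_otu_table({"o1": {"s1": 5}}, {"s1": "g"})
        with pytest.raises(ValueError, match="below the normalization depth"):
            diet.normalize_depth(t, depth=30000, seed=0)


class TestLulu:
    def test_planted_daughter_merged(self):
        groups = _groups(4)
        counts = {
            "parent": {s: 100 for s in groups},
            "child": {s: 10 for s in groups},
            "other": {s: 50 for s in groups},
        }
        t = make_otu_table(counts, groups, match_rows=[("child", "parent", 99.0)])
        out, log = diet.lulu_curate(t)
        assert list(log.daughter) == ["child"]
        assert "child" not in out.counts.index
        assert out.counts.loc["parent"].eq(110).all()

    def test_empty_match_list_is_identity(self):
        groups = _groups(3)
        counts = {"a": {s: 10 for s in groups}, "b": {s: 20 for s in groups}}
        t = make_otu_table(counts, groups)
        out, log = diet.lulu_curate(t)
        assert log.empty
        assert out.counts.equals(t.counts)

    def test_non_cooccurring_similar_pair_retained(self):
        groups = _groups(4)
        samples = list(groups)
        counts = {
            "x": {s: (30 if i < 4 else 0) for i, s in enumerate(samples)},
            "y": {s: (0 if i < 4 else 30) for i, s in enumerate(samples)},
        }
        t = make_otu_table(counts, groups, match_rows=[("x", "y", 95.0)])
        out, log = diet.lulu_curate(t)
        assert log.empty
        assert set(out.counts.index) == {"x", "y"}

    def test_below_identity_threshold_ignored(self):
        groups = _groups(3)
        counts = {"parent": {s: 100 for s in groups}, "child": {s: 10 for s in groups}}
        t = make_otu_table(counts, groups, match_rows=[("child", "parent", 80.0)])
        out, log = diet.lulu_curate(t, min_match=84)
        assert log.empty


class TestControlRemoval:
    def _table(self, control_count):
        groups = {"s1": "g", "s2": "g", "ctrl": "control"}
        counts = {
            "real": {"s1": 100, "s2": 80, "ctrl": 0},
            "contam": {"s1": 5, "s2": 3, "ctrl": control_count},
        }
        return make_otu_table(counts, groups, controls=("ctrl",))

    def test_single_control_read_retained(self):
        out, removed = diet.remove_control_otus(self._table(1))
        assert removed == []
        assert "contam" in out.counts.index

    def test_two_control_reads_removed(self):
        out, removed = diet.remove_control_otus(self._table(2))
        assert removed == ["contam"]
        assert "ctrl" not in out.counts.columns

    def test_planted_contaminants_all_removed(self):
        t = simulate_otu_table(OTUSimSpec(n_otus=80, control_contaminant_ids=5, seed=4))
        out, removed = diet.remove_control_otus(t)
        assert sorted(removed) == sorted(t.truth["contaminants"])

    def test_no_controls_warns_and_is_noop(self):
        t = make_otu_table({"a": {"s1": 5, "s2": 2}}, {"s1": "g", "s2": "g"})
        with pytest.warns(UserWarning, match="no control samples"):
            out, removed = diet.remove_control_otus(t)
        assert removed == [] and out.counts.equals(t.counts)


class TestMinReadFilter:
    def test_threshold_boundary(self):
        groups = {"s1": "g", "s2": "g"}
        t = make_otu_table({"nine": {"s1": 4, "s2": 5}, "ten": {"s1": 5, "s2": 5}}, groups)
        out = diet.min_read_filter(t, min_total=10)
        assert list(out.counts.index) == ["ten"]

    def test_random_table_matches_bruteforce(self, rng):
        groups = _groups(5)
        counts = {f"o{i}": {s: int(rng.integers(0, 8)) for s in groups} for i in range(40)}
        t = make_otu_table(counts, groups)
        out = diet.min_read_filter(t, min_total=10)
        expected = {o for o, row in counts.items() if sum(row.values()) >= 10}
        assert set(out.counts.index) == expected

    def test_empty_table_passes_through(self):
        t = make_otu_table({"a": {"s1": 0, "s2": 0}}, {"s1": "g", "s2": "g"})
        out = diet.min_read_filter(t)
        assert out.counts.empty


class TestBrayCurtis:
    def test_identical_and_disjoint_samples(self):
        groups = {"s1": "g", "s2": "g", "s3": "g"}
        counts = {"a": {"s1": 10, "s2": 10, "s3": 0}, "b": {"s1": 5, "s2": 5, "s3": 7}}
        d = diet.bray_curtis(make_otu_table(counts, groups))
        assert d.loc["s1", "s2"] == pytest.approx(0.0, abs=1e-12)
        assert d.loc["s1", "s1"] == 0.0

    def test_fully_disjoint_gives_one(self):
        groups = {"s1": "g", "s2": "g"}
        counts = {"a": {"s1": 10, "s2": 0}, "b": {"s1": 0, "s2": 20}}
        d = diet.bray_curtis(make_otu_table(counts, groups))
        assert d.loc["s1", "s2"] == pytest.approx(1.0, abs=1e-12)

    def test_two_otu_hand_example(self):
        # proportions (0.75, 0.25) vs (0.25, 0.75) -> BC = 0.5
        groups = {"s1": "g", "s2": "g"}
        counts = {"a": {"s1": 3, "s2": 1}, "b": {"s1": 1, "s2": 3}}
        d = diet.bray_curtis(make_otu_table(counts, groups))
        assert d.loc["s1", "s2"] == pytest.approx(0.5, abs=1e-12)
        assert d.loc["s1", "s2"] == pytest.approx(
            bray_curtis_bruteforce([3, 1], [1, 3]), abs=1e-12
        )

    def test_valid_dissimilarity_on_random_tables(self, rng):
        groups = _groups(6)
        counts = {f"o{i}": {s: int(rng.integers(0, 50)) + 1 for s in groups} for i in range(20)}
        d = diet.bray_curtis(make_otu_table(counts, groups)).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()


class TestNMDS:
    def test_planar_configuration_recovered(self, rng):
        pts = rng.normal(size=(12, 2))
        d = pd.DataFrame(squareform(pdist(pts)))
        coords, stress = diet.nmds(d, n_starts=20, seed=0)
        assert stress < 0.01

    def test_stress_invariant_to_rotation_of_input(self, rng):
        pts = rng.normal(size=(10, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        d1 = pd.DataFrame(squareform(pdist(pts)))
        d2 = pd.DataFrame(squareform(pdist(pts @ R.T)))
        _, s1 = diet.nmds(d1, n_starts=10, seed=1)
        _, s2 = diet.nmds(d2, n_starts=10, seed=1)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_dimension_bound(self):
        d = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            diet.nmds(d, k=3)


class TestPermanovaPermdisp:
    def _clustered(self, rng, sep=0.0, n_per=6):
        X = rng.normal(size=(2 * n_per, 4))
        X[n_per:, 0] += sep
        d = pd.DataFrame(squareform(pdist(X)))
        groups = pd.Series(["a"] * n_per + ["b"] * n_per)
        return d, groups

    def test_disjoint_groups_maximal_separation(self):
        groups = _groups(5)
        samples = list(groups)
        counts = {
            "a": {s: (50 if g == "ga" else 0) for s, g in groups.items()},
            "b": {s: (0 if g == "ga" else 50) for s, g in groups.items()},
        }
        d = diet.bray_curtis(make_otu_table(counts, groups))
        res = diet.permanova(d, pd.Series(groups), n_perm=999, seed=0)
        # only permutations reproducing the exact partition tie with the
        # observed statistic: minimum attainable region ~ 2/C(10,5)
        assert res.p < 0.02
        assert res.p >= 1 / 1000
        assert res.r2 > 0.9

    def test_matches_reference_implementation(self, rng):
        import skbio

        d, groups = self._clustered(rng, sep=1.5)
        res = diet.permanova(d, groups, n_perm=99, seed=0)
        dm = skbio.DistanceMatrix(d.to_numpy())
        ref = skbio.stats.distance.permanova(dm, groups.to_numpy(), permutations=99)
        assert res.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_permdisp_statistic_matches_reference(self, rng):
        import skbio

        d, groups = self._clustered(rng, sep=0.0)
        res = diet.permdisp(d, groups, n_perm=99, seed=0, center="centroid")
        dm = skbio.DistanceMatrix(d.to_numpy())
        ref = skbio.stats.distance.permdisp(dm, groups.to_numpy(), permutations=99,
                                            test="centroid")
        assert res.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-6)

    def test_permdisp_detects_planted_dispersion_difference(self, rng):
        tight = np.tile(rng.normal(size=(1, 4)), (8, 1)) + rng.normal(scale=0.01, size=(8, 4))
        loose = rng.normal(scale=3.0, size=(8, 4))
        d = pd.DataFrame(squareform(pdist(np.vstack([tight, loose]))))
        groups = pd.Series(["t"] * 8 + ["l"] * 8)
        res = diet.permdisp(d, groups, n_perm=999, seed=0)
        assert res.p < 0.01

    def test_single_group_errors(self, rng):
        d, _ = self._clustered(rng)
        with pytest.raises(ValueError):
            diet.permdisp(d, pd.Series(["a"] * 12), n_perm=9, seed=0)
        with pytest.raises(ValueError):
            diet.permanova(d, pd.Series(["a"] * 11 + ["b"]), n_perm=9, seed=0)


class TestIndval:
    def test_perfect_indicator_scores_one(self):
        groups = _groups(4)
        counts = {
            "ind": {s: (30 if g == "ga" else 0) for s, g in groups.items()},
            "bg": {s: 10 for s in groups},
        }
        res = diet.indval(make_otu_table(counts, groups), n_perm=199, seed=0)
        assert res.loc["ind", "indval"] == pytest.approx(1.0, abs=1e-12)
        assert res.loc["ind", "best_combination"] == "ga"

    def test_uniform_otu_in_two_groups(self):
        # equal abundance, full occurrence: single-group IndVal sqrt(0.5),
        # two-group combination scores 1.0 and is reported as best
        groups = _groups(2)
        counts = {"u": {s: 10 for s in groups}}
        t = make_otu_table(counts, groups)
        res = diet.indval(t, n_perm=99, seed=0)
        assert res.loc["u", "best_combination"] == "ga+gb"
        assert res.loc["u", "indval"] == pytest.approx(1.0, abs=1e-9)
        single = diet.indval(t, combinations=False, n_perm=99, seed=0)
        assert single.loc["u", "indval"] == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_absent_otu_flagged_zero(self):
        groups = _groups(3)
        counts = {"gone": {s: 0 for s in groups}, "there": {s: 5 for s in groups}}
        res = diet.indval(make_otu_table(counts, groups), n_perm=49, seed=0)
        assert res.loc["gone", "indval"] == 0.0
        assert bool(res.loc["gone", "absent_everywhere"])

    def test_planted_indicator_map_recovered(self):
        spec = OTUSimSpec(
            n_otus=80,
            indicator_map={
                "OTU_00001": ("tropical_A",),
                "OTU_00002": ("temperate",),
                "OTU_00003": ("tropical_A", "tropical_B"),
            },
            seed=13,
        )
        t = simulate_otu_table(spec)
        res = diet.indval(t, n_perm=199, seed=1)
        for otu, combo in spec.indicator_map.items():
            assert set(res.loc[otu, "best_combination"].split("+")) == set(combo)
            assert res.loc[otu, "indval"] > 0.95


def test_end_to_end_planted_artifacts_never_survive():
    spec = OTUSimSpec(
        n_otus=150, n_daughter_errors=10, control_contaminant_ids=5,
        n_decoy_pairs=3, n_low_read_otus=6,
        indicator_map={"OTU_00001": ("tropical_A",)},
        seed=21,
    )
    t = simulate_otu_table(spec)
    out, merge_log, removed = diet.curate(t, depth=30000, seed=22)
    final = set(out.counts.index)
    assert not final & set(t.truth["merges"])  # daughters merged away
    assert not final & set(t.truth["contaminants"])
    assert not final & set(t.truth["low_read"])
    assert "OTU_00001" in final  # planted indicator survives
    for a, b in t.truth["decoy_pairs"]:
        assert a in final and b in final
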