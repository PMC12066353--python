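from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mufunlab import trait_space as tsp
from mufunlab.core_io import TraitTable
from mufunlab.synthetic_data import (ScenarioConfig, gen_traits,
                                     target_species, true_groups)
from conftest import make_binary_traits


class TestGower:
    def test_identical_rows_distance_zero(self):
        tt = make_binary_traits({"A": [1, 0, 1], "B": [1, 0, 1],
                                 "C": [0, 1, 0]})
        d = tsp.gower_matrix(tt)
        assert d.loc["A", "B"] == 0.0
        assert d.loc["A", "C"] == 1.0

    def test_single_binary_mismatch_of_ten_traits(self):
        tt = make_binary_traits({"A": [1] + [0] * 9, "B": [0] * 10})
        d = tsp.gower_matrix(tt)
        assert d.loc["A", "B"] == pytest.approx(0.1)

    def test_mixed_table_matches_hand_computation(self, tiny_traits):
        d = tsp.gower_matrix(tiny_traits)
        # size range = 2; contributions averaged over 3 traits
        assert d.loc["A", "B"] == pytest.approx(2 / 3, abs=1e-12)
        assert d.loc["A", "C"] == pytest.approx(0.5, abs=1e-12)
        assert d.loc["B", "C"] == pytest.approx(2.5 / 3, abs=1e-12)

    def test_symmetric_zero_diagonal_unit_range(self, dataset):
        d = tsp.gower_matrix(dataset.traits).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 1 + 1e-12

    def test_zero_range_numeric_trait_excluded_with_warning(self):
        df = pd.DataFrame({"c1": [2.0, 2.0, 2.0], "b1": [1, 0, 1]},
                          index=pd.Index(list("ABC"), name="species"))
        tt = TraitTable(df, {"c1": "continuous", "b1": "binary"},
                        pd.Series(0.5, index=df.index),
                        pd.Series(False, index=df.index))
        with pytest.warns(UserWarning, match="zero range"):
            d = tsp.gower_matrix(tt)
        assert d.loc["A", "B"] == 1.0     # only the varying trait remains

    def test_all_constant_traits_error(self):
        tt = make_binary_traits({"A": [1, 1], "B": [1, 1]})
        with pytest.raises(tsp.TraitSpaceError):
            tsp.gower_matrix(tt)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_triangle_inequality_binary_continuous(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "c1": rng.normal(size=4), "c2": rng.normal(size=4),
            "b1": rng.integers(0, 2, 4), "b2": rng.integers(0, 2, 4)},
            index=pd.Index(list("ABCD"), name="species"))
        types = {"c1": "continuous", "c2": "continuous",
                 "b1": "binary", "b2": "binary"}
        tt = TraitTable(df, types, pd.Series(0.5, index=df.index),
                        pd.Series(False, index=df.index))
        d = tsp.gower_matrix(tt).to_numpy()
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestPCoA:
    def test_collinear_points_put_all_variance_on_axis_one(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]),
                         index=list("ABCD"), columns=list("ABCD"))
        res = tsp.pcoa(d)
        assert res.var_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_equilateral_triangle_two_equal_eigenvalues(self):
        d = pd.DataFrame(1 - np.eye(3), index=list("ABC"), columns=list("ABC"))
        res = tsp.pcoa(d)
        assert res.eigvals[0] == pytest.approx(res.eigvals[1], rel=1e-10)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(6, 3))
        from scipy.spatial.distance import squareform, pdist
        d = pd.DataFrame(squareform(pdist(pts)), index=list("ABCDEF"),
                         columns=list("ABCDEF"))
        res = tsp.pcoa(d)
        rec = squareform(pdist(res.coords.to_numpy()))
        assert np.allclose(rec, d.to_numpy(), atol=1e-8)
        assert res.correction == 0.0

    def test_matches_skbio_on_unweighted_input(self):
        """Independent oracle: scikit-bio's PCoA on the same matrix."""
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 4))
        from scipy.spatial.distance import squareform, pdist
        dm = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(7)]
        d = pd.DataFrame(dm, index=ids, columns=ids)
        ours = tsp.pcoa(d)
        ref = skbio_pcoa(DistanceMatrix(dm, ids), number_of_dimensions=4)
        assert np.allclose(ours.eigvals[:4], ref.eigvals.to_numpy()[:4],
                           atol=1e-8)
        assert np.allclose(
            ours.var_explained[:4],
            ref.proportion_explained.to_numpy()[:4], atol=1e-8)

    def test_incidence_weighting_shifts_origin(self, dataset):
        d = tsp.gower_matrix(dataset.traits)
        w = dataset.traits.incidence
        weighted = tsp.pcoa(d, weights=w)
        unweighted = tsp.pcoa(d)
        # weighted mean of coords is the origin under incidence weighting
        wn = (w / w.sum()).to_numpy()
        centroid = wn @ weighted.coords.to_numpy()
        assert np.allclose(centroid, 0.0, atol=1e-8)
        assert not np.allclose(weighted.eigvals[0], unweighted.eigvals[0])

    def test_negative_eigenvalues_trigger_cailliez(self, dataset):
        res = tsp.pcoa(tsp.gower_matrix(dataset.traits))
        assert res.correction > 0            # Gower is non-Euclidean here
        assert (res.eigvals > 0).all()
        assert np.all(np.diff(res.var_explained) <= 1e-12)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(tsp.TraitSpaceError):
            tsp.pcoa(d)


def _best_agreement(true, pred, k):
    return max(((pred.map(lambda g: perm[g]) == true).mean()
                for perm in permutations(range(k))))


class TestClustering:
    def test_planted_groups_recovered(self):
        scores = []
        for seed in range(8):
            cfg = ScenarioConfig(seed=seed, group_separation=3.0)
            tt = gen_traits(cfg)
            g = tsp.cluster_trait_groups(tsp.gower_matrix(tt), 5, seed=0)
            scores.append(_best_agreement(true_groups(cfg), g, 5))
        assert np.mean(scores) >= 0.9

    def test_zero_separation_recovers_at_chance(self):
        scores = []
        for seed in range(5):
            cfg = ScenarioConfig(seed=seed, group_separation=0.0)
            tt = gen_traits(cfg)
            g = tsp.cluster_trait_groups(tsp.gower_matrix(tt), 5, seed=0)
            scores.append(_best_agreement(true_groups(cfg), g, 5))
        assert np.mean(scores) < 0.8          # well below separated recovery

    def test_k_equals_n_gives_singletons(self, tiny_traits):
        g = tsp.cluster_trait_groups(tsp.gower_matrix(tiny_traits), 3)
        assert g.nunique() == 3

    def test_k_one_single_group(self, tiny_traits):
        g = tsp.cluster_trait_groups(tsp.gower_matrix(tiny_traits), 1)
        assert g.nunique() == 1

    def test_invalid_k_rejected(self, tiny_traits):
        with pytest.raises(tsp.TraitSpaceError):
            tsp.cluster_trait_groups(tsp.gower_matrix(tiny_traits), 0)


class TestDominants:
    def test_highest_incidence_wins(self):
        groups = pd.Series([0, 0], index=["A", "B"])
        inc = pd.Series({"A": 0.9, "B": 0.3})
        dom, ties = tsp.select_dominants(groups, inc)
        assert dom[0] == "A" and not ties

    def test_tie_breaks_lexicographically_with_flag(self):
        groups = pd.Series([0, 0], index=["B", "A"])
        inc = pd.Series({"A": 0.5, "B": 0.5})
        dom, ties = tsp.select_dominants(groups, inc)
        assert dom[0] == "A"
        assert ties[0] == ["A", "B"]

    def test_planted_targets_recovered(self):
        hits = total = 0
        for seed in range(6):
            cfg = ScenarioConfig(seed=seed, group_separation=3.0)
            tt = gen_traits(cfg)
            ts = tsp.build_trait_space(tt, k_groups=5, seed=0)
            targets = set(target_species(cfg))
            hits += len(targets & set(ts.dominants))
            total += len(targets)
        assert hits / total >= 0.8


class TestFDMetrics:
    def test_triangle_area(self):
        coords = pd.DataFrame([[0, 0], [1, 0], [0, 1]], index=list("ABC"),
                              columns=["PCo1", "PCo2"])
        ab = pd.Series([1, 1, 1], index=list("ABC"))
        assert tsp.fric(ab, coords) == pytest.approx(0.5)

    def test_interior_point_leaves_hull_unchanged(self):
        coords = pd.DataFrame([[0, 0], [1, 0], [0, 1], [0.2, 0.2]],
                              index=list("ABCD"), columns=["PCo1", "PCo2"])
        full = tsp.fric(pd.Series([1, 1, 1, 1], index=list("ABCD")), coords)
        tri = tsp.fric(pd.Series([1, 1, 1, 0], index=list("ABCD")), coords)
        assert full == pytest.approx(tri)

    def test_matches_shapely_hull_area(self):
        """Independent oracle: shapely's convex hull on random points."""
        from shapely import MultiPoint
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(8, 2))
        ids = [f"s{i}" for i in range(8)]
        coords = pd.DataFrame(pts, index=ids, columns=["PCo1", "PCo2"])
        ours = tsp.fric(pd.Series(1, index=ids), coords)
        ref = MultiPoint(pts).convex_hull.area
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_too_few_or_collinear_points_give_zero(self):
        coords = pd.DataFrame([[0, 0], [1, 1], [2, 2]], index=list("ABC"),
                              columns=["PCo1", "PCo2"])
        assert tsp.fric(pd.Series([1, 1, 0], index=list("ABC")), coords) == 0.0
        assert tsp.fric(pd.Series([1, 1, 1], index=list("ABC")), coords) == 0.0

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_fric_monotone_under_species_addition(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(7)]
        coords = pd.DataFrame(rng.normal(size=(7, 2)), index=ids,
                              columns=["PCo1", "PCo2"])
        present = rng.integers(0, 2, 7)
        a = pd.Series(present, index=ids, dtype=float)
        b = a.copy()
        b.iloc[int(rng.integers(0, 7))] = 1.0
        assert tsp.fric(b, coords) >= tsp.fric(a, coords) - 1e-12

    def test_fdis_single_species_zero(self):
        coords = pd.DataFrame([[1.0, 2.0]], index=["A"],
                              columns=["PCo1", "PCo2"])
        assert tsp.fdis(pd.Series([5], index=["A"]), coords) == 0.0

    def test_fdis_two_equal_species_half_distance(self):
        coords = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["A", "B"],
                              columns=["PCo1", "PCo2"])
        assert tsp.fdis(pd.Series([2, 2], index=["A", "B"]),
                        coords) == pytest.approx(2.5)

    def test_fdis_weighted_hand_case(self):
        # 1-D coords 0,1,2,4 with abundances 1,2,3,4: centroid 2.4,
        # weighted mean distance (2.4 + 2*1.4 + 3*0.4 + 4*1.6)/10 = 1.28
        coords = pd.DataFrame({"PCo1": [0.0, 1.0, 2.0, 4.0]},
                              index=list("ABCD"))
        ab = pd.Series([1, 2, 3, 4], index=list("ABCD"))
        assert tsp.fdis(ab, coords) == pytest.approx(1.28)

    def test_fdis_all_zero_abundance_is_nan(self):
        coords = pd.DataFrame({"PCo1": [0.0, 1.0]}, index=["A", "B"])
        assert np.isnan(tsp.fdis(pd.Series([0, 0], index=["A", "B"]), coords))
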