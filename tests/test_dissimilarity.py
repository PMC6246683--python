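import io

import numpy as np
import pandas as pd
import pytest
import skbio

from estuarynet.dissimilarity import (DistanceMatrix, bray_curtis, euclidean,
                                      geographic_distance,
                                      single_factor_distance, unifrac)
from estuarynet.io_tables import AbundanceTable, EnvTable, ValidationError


def _env(df, **kw):
    return EnvTable(pd.DataFrame(df), **kw)


def _tab(rows, index, columns):
    return AbundanceTable(pd.DataFrame(rows, index=index, columns=columns,
                                       dtype=float))


class TestEuclidean:
    def test_three_four_five_triangle(self):
        env = _env({"x": [0.0, 3.0], "y": [0.0, 4.0]})
        d = euclidean(env, standardize=False)
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_identical_rows_are_zero(self):
        env = _env({"x": [1.0, 1.0, 2.0], "y": [3.0, 3.0, 1.0]})
        d = euclidean(env, standardize=False)
        assert d.values[0, 1] == 0.0

    def test_matches_brute_force_loop(self, scenario):
        env = scenario["env"]
        d = euclidean(env, standardize=True)
        mat = env.factor_matrix()
        z = (mat - mat.mean()) / mat.std(ddof=1)
        for i in range(0, 12, 5):
            for j in range(1, 12, 4):
                expect = np.sqrt(((z.iloc[i] - z.iloc[j]) ** 2).sum())
                assert d.values[i, j] == pytest.approx(expect, abs=1e-10)

    def test_zero_variance_factor_named(self):
        env = _env({"flat": [1.0, 1.0, 1.0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError, match="flat"):
            euclidean(env, standardize=True)

    def test_coordinates_excluded(self):
        env = _env({"x": [0.0, 1.0], "Latitude": [0.0, 50.0],
                    "Longitude": [0.0, 50.0]})
        d = euclidean(env, standardize=False)
        assert d.values[0, 1] == pytest.approx(1.0)


class TestBrayCurtis:
    def test_hand_evaluated_formula(self):
        tab = _tab([[1, 2, 0], [3, 0, 0]], ["a", "b"], ["f1", "f2", "f3"])
        d = bray_curtis(tab, relative=False)
        assert d.values[0, 1] == pytest.approx(4 / 6)

    def test_identical_samples_zero(self):
        tab = _tab([[1, 2, 3], [1, 2, 3]], ["a", "b"], ["f1", "f2", "f3"])
        assert bray_curtis(tab).values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        tab = _tab([[5, 0], [0, 7]], ["a", "b"], ["f1", "f2"])
        assert bray_curtis(tab).values[0, 1] == pytest.approx(1.0)

    def test_sorensen_equals_bray_on_binarized(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5, size=(6, 20))
        ids = [f"s{i}" for i in range(6)]
        cols = [f"f{i}" for i in range(20)]
        tab = _tab(counts, ids, cols)
        binary = _tab((counts > 0).astype(float), ids, cols)
        np.testing.assert_allclose(bray_curtis(tab, binarize=True).values,
                                   bray_curtis(binary, relative=False).values)

    def test_all_zero_sample_rejected(self):
        tab = _tab([[0, 0], [1, 2]], ["a", "b"], ["f1", "f2"])
        with pytest.raises(ValidationError, match="'a'"):
            bray_curtis(tab)


class TestUniFrac:
    tree = skbio.TreeNode.read(io.StringIO("((L1:1,L2:1):1,L3:1):0;"))

    def test_identical_communities_zero(self):
        tab = _tab([[1, 2, 3], [1, 2, 3]], ["a", "b"], ["L1", "L2", "L3"])
        for weighted in (False, True):
            d = unifrac(tab, self.tree, weighted=weighted)
            assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_unweighted_hand_enumeration(self):
        # A = {L1}, B = {L2}: unique branches L1+L2 (length 2) over the
        # union's covered branches L1+L2+shared internal (length 3)
        tab = _tab([[1, 0, 0], [0, 1, 0]], ["a", "b"], ["L1", "L2", "L3"])
        d = unifrac(tab, self.tree, weighted=False)
        assert d.values[0, 1] == pytest.approx(2 / 3)

    def test_disjoint_subtrees_give_one(self):
        tree = skbio.TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1):0;"))
        tab = _tab([[1, 1, 0, 0], [0, 0, 1, 1]], ["a", "b"],
                   ["A", "B", "C", "D"])
        assert unifrac(tab, tree).values[0, 1] == pytest.approx(1.0)

    def test_weighted_scale_invariance(self):
        tab = _tab([[1, 2, 3], [2, 4, 6]], ["a", "b"], ["L1", "L2", "L3"])
        d = unifrac(tab, self.tree, weighted=True)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_missing_leaf_named(self):
        tab = _tab([[1, 1], [1, 1]], ["a", "b"], ["L1", "LX"])
        with pytest.raises(ValidationError, match="LX"):
            unifrac(tab, self.tree)


class TestGeographic:
    def test_antipodal_equator_points(self):
        env = _env({"Latitude": [0.0, 0.0], "Longitude": [0.0, 180.0]})
        d = geographic_distance(env)
        assert d.values[0, 1] == pytest.approx(np.pi * 6371.0, rel=1e-6)

    def test_one_degree_longitude_on_equator(self):
        env = _env({"Latitude": [0.0, 0.0], "Longitude": [10.0, 11.0]})
        d = geographic_distance(env)
        assert d.values[0, 1] == pytest.approx(2 * np.pi * 6371.0 / 360,
                                               rel=1e-6)

    def test_same_point_zero(self):
        env = _env({"Latitude": [30.0, 30.0], "Longitude": [121.0, 121.0]})
        assert geographic_distance(env).values[0, 1] == 0.0


class TestSingleFactor:
    def test_absolute_differences(self):
        env = _env({"x": [1.0, 4.0, 6.0]})
        d = single_factor_distance(env, "x")
        assert d.values[0, 1] == 3.0
        assert d.values[0, 2] == 5.0
        assert d.values[1, 2] == 2.0

    def test_constant_factor_all_zero(self):
        env = _env({"x": [2.0, 2.0, 2.0]})
        assert single_factor_distance(env, "x").values.sum() == 0.0

    def test_agrees_with_one_column_euclidean(self):
        env = _env({"x": [1.0, 4.0, 6.0]})
        np.testing.assert_allclose(
            single_factor_distance(env, "x").values,
            euclidean(env, standardize=False).values)

    def test_unknown_factor(self):
        with pytest.raises(ValidationError, match="nope"):
            single_factor_distance(_env({"x": [1.0, 2.0]}), "nope")


def test_metrics_invariant_to_sample_permutation(scenario):
    otus, env = scenario["otus"], scenario["env"]
    perm = list(reversed(otus.sample_ids))
    d1 = bray_curtis(otus).reorder(perm)
    shuffled = AbundanceTable(otus.data.loc[perm])
    d2 = bray_curtis(shuffled)
    np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)


def test_distance_matrix_validates_structure():
    bad = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["a", "b"],
                       columns=["a", "b"])
    with pytest.raises(ValidationError, match="symmetric"):
        DistanceMatrix(bad)
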