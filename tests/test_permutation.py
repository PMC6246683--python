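from itertools import permutations as iperm

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from estuarynet.dissimilarity import DistanceMatrix
from estuarynet.io_tables import ValidationError
from estuarynet.permutation import (adonis, anosim, mantel, mrpp,
                                    partial_mantel)


def _dm(values, ids):
    return DistanceMatrix(pd.DataFrame(values, index=ids, columns=ids))


def _random_dm(rng, n, shift=0.0, k=3):
    x = rng.standard_normal((n, k))
    x[n // 2:] += shift
    ids = [f"s{i}" for i in range(n)]
    return _dm(squareform(pdist(x)), ids), pd.Series(
        ["a"] * (n // 2) + ["b"] * (n - n // 2), index=ids)


class TestMrpp:
    def test_delta_equals_hand_weighted_within_means(self, toy_distance):
        d, groups = toy_distance
        res = mrpp(d, groups, n_perm=9, seed=0)
        sq = d.values
        xi_a = np.mean([sq[0, 1], sq[0, 2], sq[1, 2]])
        xi_b = np.mean([sq[3, 4], sq[3, 5], sq[4, 5]])
        assert res.statistic == pytest.approx(0.5 * xi_a + 0.5 * xi_b)

    def test_planted_separation_hits_minimal_p(self, toy_distance):
        d, groups = toy_distance
        res = mrpp(d, groups, n_perm=999, seed=1)
        # n=6 -> 720 permutations, enumerated exhaustively; exactly the
        # 3!*3!*2 = 72 partition-preserving ones tie the observed delta
        assert res.p_value == pytest.approx(72 / 720)
        assert res.extra["A"] > 0

    def test_chance_corrected_a_uses_exact_expectation(self, toy_distance):
        d, groups = toy_distance
        res = mrpp(d, groups, n_perm=9, seed=0)
        assert res.extra["A"] == pytest.approx(
            1 - res.statistic / d.condensed().mean())

    def test_singleton_group_rejected(self, toy_distance):
        d, _ = toy_distance
        groups = pd.Series(["a"] + ["b"] * 5, index=d.sample_ids)
        with pytest.raises(ValidationError, match="fewer than 2"):
            mrpp(d, groups)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self, toy_distance):
        d, groups = toy_distance
        res = anosim(d, groups, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_brute_force_rank_oracle(self):
        rng = np.random.default_rng(3)
        d, groups = _random_dm(rng, 7, shift=1.0)
        res = anosim(d, groups, n_perm=9, seed=0)
        ranks = rankdata(d.condensed())
        n = 7
        iu = np.triu_indices(n, k=1)
        same = (groups.values[:, None] == groups.values[None, :])[iu]
        expect = (ranks[~same].mean() - ranks[same].mean()) / (n * (n - 1) / 4)
        assert res.statistic == pytest.approx(expect)

    def test_matches_skbio(self):
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(11)
        d, groups = _random_dm(rng, 9, shift=0.5)
        res = anosim(d, groups, n_perm=99, seed=0)
        sk = sk_anosim(d.to_skbio(), groups.values, permutations=0)
        assert res.statistic == pytest.approx(sk["test statistic"])


class TestAdonis:
    def test_pseudo_f_equals_direct_sums_of_squares(self, toy_distance):
        d, groups = toy_distance
        res = adonis(d, groups, n_perm=9, seed=0)
        sq2 = d.values ** 2
        iu = np.triu_indices(6, k=1)
        ss_t = sq2[iu].sum() / 6
        ss_w = (sq2[:3, :3][np.triu_indices(3, 1)].sum() / 3
                + sq2[3:, 3:][np.triu_indices(3, 1)].sum() / 3)
        expect = ((ss_t - ss_w) / 1) / (ss_w / 4)
        assert res.statistic == pytest.approx(expect)
        assert res.extra["R2"] == pytest.approx((ss_t - ss_w) / ss_t)

    def test_matches_skbio_permanova(self):
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(8)
        d, groups = _random_dm(rng, 10, shift=0.8)
        res = adonis(d, groups, n_perm=99, seed=0)
        sk = sk_permanova(d.to_skbio(), groups.values, permutations=0)
        assert res.statistic == pytest.approx(sk["test statistic"])

    def test_separated_clusters_give_large_f(self, toy_distance):
        d, groups = toy_distance
        res = adonis(d, groups, n_perm=999, seed=2)
        assert res.statistic > 10
        assert res.p_value == pytest.approx(72 / 720)  # exhaustive floor


class TestMantel:
    def test_self_correlation_is_one(self, toy_distance):
        d, _ = toy_distance
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exhaustive_p_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        ids = list("abcde")
        da = _dm(squareform(pdist(rng.standard_normal((5, 3)))), ids)
        db = _dm(squareform(pdist(rng.standard_normal((5, 3)))), ids)
        res = mantel(da, db, n_perm=999, seed=0)
        assert res.n_perm == 120
        iu = np.triu_indices(5, k=1)
        a = da.values[iu]
        count = total = 0
        for p in iperm(range(5)):
            b = db.values[np.ix_(p, p)][iu]
            total += 1
            count += np.corrcoef(a, b)[0, 1] >= res.r - 1e-12
        assert res.p_value == pytest.approx(count / total)

    def test_matches_skbio_statistic(self):
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(21)
        ids = [f"s{i}" for i in range(8)]
        da = _dm(squareform(pdist(rng.standard_normal((8, 3)))), ids)
        db = _dm(squareform(pdist(rng.standard_normal((8, 3)))), ids)
        r_sk = sk_mantel(da.to_skbio(), db.to_skbio(), permutations=0)[0]
        assert mantel(da, db, n_perm=9, seed=0).r == pytest.approx(r_sk)

    def test_mismatched_labels_rejected(self, toy_distance):
        d, _ = toy_distance
        other = _dm(d.data.values, [f"x{i}" for i in range(6)])
        with pytest.raises(ValidationError, match="different samples"):
            mantel(d, other)


class TestPartialMantel:
    def _triple(self, seed, n=7):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        mats = [_dm(squareform(pdist(rng.standard_normal((n, 3)))), ids)
                for _ in range(3)]
        return mats

    def test_controlling_b_by_itself_gives_zero(self):
        da, db, _ = self._triple(4)
        res = partial_mantel(da, db, db, n_perm=9, seed=0)
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_uncorrelated_control_leaves_r_nearly_unchanged(self):
        da, db, dc = self._triple(6)
        plain = mantel(da, db, n_perm=9, seed=0).r
        part = partial_mantel(da, db, dc, n_perm=9, seed=0).r
        assert abs(part - plain) < 0.2

    def test_equals_residual_correlation_oracle(self):
        da, db, dc = self._triple(7, n=6)
        res = partial_mantel(da, db, dc, n_perm=9, seed=0)
        iu = np.triu_indices(6, k=1)
        a, b, c = da.values[iu], db.values[iu], dc.values[iu]
        ra = a - np.polyval(np.polyfit(c, a, 1), c)
        rb = b - np.polyval(np.polyfit(c, b, 1), c)
        assert res.r == pytest.approx(np.corrcoef(ra, rb)[0, 1], abs=1e-10)


class TestPValueContract:
    def test_p_never_zero_and_bounded(self):
        rng = np.random.default_rng(5)
        d, groups = _random_dm(rng, 12, shift=50.0)
        for fn in (mrpp, anosim, adonis):
            p = fn(d, groups, n_perm=99, seed=0).p_value
            assert 0 < p <= 1
            assert p >= 1 / 100

    def test_fixed_seed_is_bit_identical(self):
        rng = np.random.default_rng(9)
        d, groups = _random_dm(rng, 12)
        a = anosim(d, groups, n_perm=199, seed=7)
        b = anosim(d, groups, n_perm=199, seed=7)
        assert (a.statistic, a.p_value) == (b.statistic, b.p_value)
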