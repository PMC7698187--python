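"""Density operators and the self-organising cloud partitioner."""

import numpy as np
import pytest

from efnn import eda_sof as es
from efnn.eda_sof import SampleMatrix


def brute_cumulative_proximity(X, metric="euclidean"):
    K = X.shape[0]
    return np.array([sum(es.sq_distance(X[i], X[j], metric) for j in range(K))
                     for i in range(K)])


def brute_unimodal(X, metric="euclidean"):
    pi = brute_cumulative_proximity(X, metric)
    return pi.sum() / (2 * X.shape[0] * pi)


class TestDistances:
    @pytest.mark.parametrize("a, b, metric, expected", [
        ((1, 2), (1, 2), "euclidean", 0.0),
        ((0,), (3,), "euclidean", 9.0),
        ((1, 0), (0, 1), "cosine", 2.0),
        ((2, 0), (6, 0), "cosine", 0.0),   # collinear same direction
    ])
    def test_known_values(self, a, b, metric, expected):
        assert es.sq_distance(a, b, metric) == pytest.approx(expected)

    def test_symmetric(self, rng):
        a, b = rng.normal(size=(2, 4))
        for metric in ("euclidean", "cosine"):
            assert es.sq_distance(a, b, metric) == pytest.approx(
                es.sq_distance(b, a, metric))

    def test_zero_vector_cosine_warns(self):
        with pytest.warns(UserWarning):
            d = es.sq_distance((0.0, 0.0), (3.0, 0.0), "cosine")
        assert d == pytest.approx(1.0)  # squared distance origin -> unit vector


class TestDensities:
    def test_cumulative_proximity_line(self):
        assert np.allclose(es.cumulative_proximity(np.array([[0.], [1.], [2.]])),
                           [5, 2, 5])

    def test_single_sample(self):
        assert es.cumulative_proximity(np.array([[4.0]])) == pytest.approx([0.0])

    def test_duplicates_zero(self):
        X = np.array([[2.0, 3.0], [2.0, 3.0]])
        assert np.allclose(es.cumulative_proximity(X), [0, 0])

    def test_unimodal_line(self):
        assert np.allclose(es.unimodal_density(np.array([[0.], [1.], [2.]])),
                           [0.4, 1.0, 0.4])

    def test_unimodal_symmetric_pair(self):
        assert np.allclose(es.unimodal_density(np.array([[-1.], [1.]])), [0.5, 0.5])

    def test_unimodal_identical_fallback(self):
        with pytest.warns(UserWarning):
            D = es.unimodal_density(np.ones((4, 2)))
        assert np.allclose(D, 1.0)

    @pytest.mark.parametrize("metric", ["euclidean", "cosine"])
    def test_matches_brute_force(self, rng, metric):
        X = rng.normal(size=(50, 5)) + 1.0
        assert np.allclose(es.cumulative_proximity(X, metric),
                           brute_cumulative_proximity(X, metric), atol=1e-10)
        assert np.allclose(es.unimodal_density(X, metric),
                           brute_unimodal(X, metric), atol=1e-10)

    def test_multimodal_duplicated_point(self):
        X = np.array([[0.], [0.], [1.]])
        t = es.unique_table(X)
        assert np.allclose(t.uniques.ravel(), [0, 1])
        assert np.array_equal(t.freqs, [2, 1])
        assert np.allclose(es.multimodal_density(t, X), [4 / 3, 1 / 3])

    def test_multimodal_reduces_to_unimodal(self, rng):
        X = rng.normal(size=(20, 3))
        t = es.unique_table(X)
        assert np.all(t.freqs == 1)
        assert np.allclose(es.multimodal_density(t, X), es.unimodal_density(X),
                           atol=1e-12)

    def test_duplication_preserves_argmax(self, rng):
        base = rng.normal(size=(15, 2))
        X2 = np.repeat(base, 2, axis=0)
        t1, t2 = es.unique_table(base), es.unique_table(X2)
        d1 = es.multimodal_density(t1, base)
        d2 = es.multimodal_density(t2, X2)
        assert np.argmax(d1) == np.argmax(d2)


class TestRankingAndPrototypes:
    def test_chain_from_stated_head(self):
        # force the head by passing densities directly
        t = es.UniquePointTable(uniques=np.array([[0.], [10.], [1.]]),
                                freqs=np.ones(3, dtype=int))
        r = es.rank_by_density(t, np.array([3.0, 1.0, 2.0]))
        assert r.tolist() == [0, 2, 1]

    def test_single_point(self):
        t = es.UniquePointTable(uniques=np.array([[5.0]]), freqs=np.array([1]))
        assert es.rank_by_density(t, np.array([1.0])).tolist() == [0]

    def test_tie_breaks_lowest_index(self):
        t = es.UniquePointTable(uniques=np.array([[0.], [1.], [-1.]]),
                                freqs=np.ones(3, dtype=int))
        r = es.rank_by_density(t, np.array([1.0, 1.0, 1.0]))
        assert r[0] == 0      # density tie -> lowest index head
        assert r[1] == 1      # distance tie (1 vs -1) -> lowest index next

    def test_local_maxima(self):
        r = np.arange(4)
        protos = es.identify_prototypes(r, np.array([3.0, 1.0, 2.0, 1.0]))
        assert protos.tolist() == [0, 2]

    def test_monotone_chain_head_only(self):
        protos = es.identify_prototypes(np.arange(5), np.array([5.0, 4, 3, 2, 1]))
        assert protos.tolist() == [0]

    def test_single_unique_is_prototype(self):
        assert es.identify_prototypes(np.array([0]), np.array([2.0])).tolist() == [0]


class TestClouds:
    def test_assignment(self):
        X = np.array([[0.], [1.], [9.], [10.]])
        clouds = es.form_clouds(X, np.array([[0.5], [9.5]]))
        assert [c.support for c in clouds] == [2, 2]
        assert np.allclose([c.center[0] for c in clouds], [0.5, 9.5])

    def test_single_prototype_grand_mean(self, rng):
        X = rng.normal(size=(10, 3))
        clouds = es.form_clouds(X, X[:1])
        assert len(clouds) == 1
        assert clouds[0].support == 10
        assert np.allclose(clouds[0].center, X.mean(axis=0))

    def test_equidistant_lowest_index_wins(self):
        clouds = es.form_clouds(np.array([[0.5]]), np.array([[0.], [1.]]))
        assert len(clouds) == 1
        assert np.allclose(clouds[0].prototype, [0.0])

    def test_member_spread_is_sample_std(self):
        clouds = es.form_clouds(np.array([[1.], [2.], [3.]]), np.array([[2.]]))
        assert clouds[0].member_spread[0] == pytest.approx(1.0)


class TestInfluenceRadius:
    def test_pair(self):
        assert es.influence_radius(np.array([[0.], [1.]]), 1) == pytest.approx(1.0)

    def test_equal_distances_constant_in_level(self):
        # equilateral triangle: all pairwise distances equal -> early stop
        X = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        g1 = es.influence_radius(X, 1)
        assert es.influence_radius(X, 5) == pytest.approx(g1)

    def test_nonincreasing_in_level(self, rng):
        X = rng.normal(size=(30, 3))
        radii = [es.influence_radius(X, lvl) for lvl in range(1, 8)]
        assert all(a >= b for a, b in zip(radii, radii[1:]))

    def test_undefined_below_two_samples(self):
        with pytest.raises(ValueError):
            es.influence_radius(np.array([[1.0, 2.0]]), 1)


class TestRepresentatives:
    def _clouds(self, centers):
        return [es.Cloud(prototype=np.array(c), center=np.array(c), support=1)
                for c in centers]

    def test_denser_neighbour_wins(self):
        clouds = self._clouds([[0.0], [0.1]])
        kept = es.select_representatives(clouds, np.array([5.0, 3.0]), G=1.0)
        assert len(kept) == 1 and kept[0] is clouds[0]

    def test_isolated_all_kept(self):
        clouds = self._clouds([[0.0], [100.0]])
        kept = es.select_representatives(clouds, np.array([5.0, 3.0]), G=1.0)
        assert len(kept) == 2

    def test_tied_neighbours_keep_lower_index(self):
        clouds = self._clouds([[0.0], [0.1]])
        kept = es.select_representatives(clouds, np.array([4.0, 4.0]), G=1.0)
        assert len(kept) == 1 and kept[0] is clouds[0]


class TestFitOffline:
    def test_recovers_two_blobs_per_class(self, four_blob_stream):
        off = SampleMatrix(four_blob_stream.values[:200],
                           four_blob_stream.labels[:200])
        parts = es.fit_offline(off, level=1, metric="euclidean")
        assert [p.n_clouds for p in parts] == [2, 2]

    def test_single_point_class(self):
        X = SampleMatrix(np.array([[0.0, 0.0], [1.0, 1.0], [1.1, 0.9]]),
                         np.array([0, 1, 1]))
        parts = es.fit_offline(X, level=1)
        p0 = parts[0]
        assert p0.n_clouds == 1 and p0.clouds[0].support == 1
        assert p0.radius is not None and p0.radius > 0   # global fallback

    def test_support_conservation_and_local_max(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.zeros(60, dtype=int)
        parts = es.fit_offline(SampleMatrix(X, y), level=3, metric="euclidean")
        assert sum(c.support for c in parts[0].clouds) == 60
        assert parts[0].n_clouds >= 1

    def test_batch_stats(self, rng):
        X = rng.normal(size=(40, 3))
        parts = es.fit_offline(SampleMatrix(X, np.zeros(40, dtype=int)), level=2)
        p = parts[0]
        assert np.allclose(p.mean, X.mean(axis=0))
        assert np.allclose(p.scatter, np.cov(X, rowvar=False, ddof=1), atol=1e-10)


class TestUpdateOnline:
    def test_far_sample_founds_cloud(self):
        X = SampleMatrix(np.array([[0.], [1.], [0.2], [0.9]]), np.zeros(4, dtype=int))
        part = es.fit_offline(X, level=1)[0]
        part.radius = 0.5
        n = part.n_clouds
        es.update_online(part, np.array([100.0]))
        assert part.n_clouds == n + 1
        assert part.clouds[-1].support == 1

    def test_sample_at_prototype_increments_support(self):
        X = SampleMatrix(np.array([[0.], [1.], [0.2], [0.9]]), np.zeros(4, dtype=int))
        part = es.fit_offline(X, level=1)[0]
        # a point exactly at a prototype has density between the extremes of a
        # multi-prototype partition only if it is not the densest/sparsest;
        # use the fixed point of the shift rule instead: absorb twice
        target = part.clouds[0]
        p_before = target.prototype.copy()
        s_before = target.support
        target.absorb(p_before.copy())
        assert target.support == s_before + 1
        assert np.allclose(target.prototype, p_before)

    def test_stream_matches_batch_statistics(self, rng):
        S = rng.normal(size=(100, 4))
        part = es.ClassPartition(class_id=0, clouds=[], mean=None,
                                 second_moment=None, scatter=None, radius=None,
                                 count=0, metric="euclidean")
        for x in S:
            es.update_online(part, x)
        assert np.allclose(part.mean, S.mean(axis=0), atol=1e-8)
        assert np.allclose(part.scatter, np.cov(S, rowvar=False, ddof=1), atol=1e-8)
        assert sum(c.support for c in part.clouds) == 100

    def test_dimension_mismatch(self):
        X = SampleMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), np.zeros(2, dtype=int))
        part = es.fit_offline(X, level=1)[0]
        with pytest.raises(ValueError):
            es.update_online(part, np.array([1.0, 2.0, 3.0]))


class TestGaussianProjection:
    def test_center_and_sample_std(self):
        clouds = es.form_clouds(np.array([[1.], [2.], [3.]]), np.array([[2.]]))
        part = es.ClassPartition(class_id=0, clouds=clouds, mean=np.array([2.0]),
                                 second_moment=np.array([[14 / 3]]),
                                 scatter=np.array([[1.0]]), radius=1.0, count=3)
        (center, sigma), = es.clouds_to_gaussians(part)
        assert center[0] == pytest.approx(2.0)
        assert sigma[0] == pytest.approx(1.0)

    def test_singleton_gets_floor(self):
        clouds = [es.Cloud(prototype=np.array([1.0]), center=np.array([1.0]),
                           support=1)]
        part = es.ClassPartition(class_id=0, clouds=clouds, mean=np.array([1.0]),
                                 second_moment=np.array([[1.0]]),
                                 scatter=np.array([[4.0]]), radius=1.0, count=1)
        (_, sigma), = es.clouds_to_gaussians(part)
        assert sigma[0] == pytest.approx(0.1 * 2.0)   # 10% of global spread
        assert sigma[0] > 0
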