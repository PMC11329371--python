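"""Clustering, Gaussian cluster models, confusion analysis, palette design."""

import numpy as np
import pytest
from scipy.stats import norm

from fretfluor.classify import (
    ClusterModel,
    ConfusionMatrix,
    classify_level,
    cluster_levels,
    confusion_matrix,
    fit_cluster_gaussian,
    pairwise_misclassification,
    reference_models,
    select_compatible_subset,
)


def _blobs(rng, centers, sigma=0.05, n=40):
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(rng.normal(c, sigma, (n, len(c))))
        labels.append(np.full(n, i))
    return np.vstack(pts), np.concatenate(labels)


class TestClusterLevels:
    CENTERS = [(0.0, 0.0, 0.0), (1.0, 0.0, 0.5), (0.0, 1.0, 1.0)]

    def test_fixed_k_separates_blobs(self, rng):
        x, truth = _blobs(rng, self.CENTERS)
        labels = cluster_levels(x, K=3, seed=0)
        # each true blob maps to exactly one cluster
        for t in np.unique(truth):
            assert len(np.unique(labels[truth == t])) == 1
        assert len(np.unique(labels)) == 3

    def test_auto_k_recovers_blob_count(self, rng):
        x, _ = _blobs(rng, self.CENTERS)
        labels = cluster_levels(x, K="auto", seed=0)
        assert len(np.unique(labels)) == 3

    def test_rejects_oversized_k(self, rng):
        x, _ = _blobs(rng, self.CENTERS, n=2)
        with pytest.raises(ValueError):
            cluster_levels(x, K=10, seed=0)


class TestFitClusterGaussian:
    def test_recovers_moments(self, rng):
        x, labels = _blobs(rng, [(0.0, 0.0, 0.0)], sigma=0.1, n=500)
        (model,) = fit_cluster_gaussian(x, labels)
        assert np.allclose(model.mean, 0.0, atol=0.02)
        assert np.allclose(model.sigma, 0.1, rtol=0.15)

    def test_outlier_rejected_from_moments(self, rng):
        x, labels = _blobs(rng, [(0.0, 0.0, 0.0)], sigma=0.1, n=200)
        x = np.vstack([x, [[5.0, 5.0, 5.0]]])
        labels = np.append(labels, 0)
        (model,) = fit_cluster_gaussian(x, labels)
        assert np.allclose(model.sigma, 0.1, rtol=0.2)
        # the planted outlier is gone; only a few tail points may join it
        assert 190 <= model.n_members <= 200
        assert np.all(np.abs(model.mean) < 0.05)

    def test_strict_raises_on_undersized_cluster(self, rng):
        x = rng.normal(0, 1, (3, 3))
        with pytest.raises(ValueError):
            fit_cluster_gaussian(x, np.zeros(3))

    def test_lenient_skips_undersized_cluster(self, rng):
        x, labels = _blobs(rng, [(0.0, 0.0, 0.0)], sigma=0.1, n=50)
        x = np.vstack([x, rng.normal(5.0, 0.1, (3, 3))])
        labels = np.append(labels, [1, 1, 1])
        with pytest.warns(UserWarning):
            models = fit_cluster_gaussian(x, labels, strict=False)
        assert len(models) == 1


class TestPairwiseMisclassification:
    def test_identical_clusters_are_coin_flips(self):
        a = ClusterModel("a", np.zeros(3), np.ones(3))
        b = ClusterModel("b", np.zeros(3), np.ones(3))
        res = pairwise_misclassification(a, b, n_mc=50000, seed=1)
        assert res.p == pytest.approx(0.5, abs=0.01)

    def test_distant_clusters_never_confused(self):
        a = ClusterModel("a", np.zeros(3), 0.1 * np.ones(3))
        b = ClusterModel("b", 10.0 * np.ones(3), 0.1 * np.ones(3))
        res = pairwise_misclassification(a, b, n_mc=20000, seed=1)
        assert res.p == 0.0

    def test_equal_width_pair_matches_normal_tail(self):
        # equal sigmas along one axis: p = Phi(-d / 2 sigma)
        d, sigma = 1.5, 0.5
        a = ClusterModel("a", np.array([0.0, 0, 0]), sigma * np.ones(3))
        b = ClusterModel("b", np.array([d, 0, 0]), sigma * np.ones(3))
        res = pairwise_misclassification(a, b, n_mc=200000, seed=3)
        expected = norm.cdf(-d / (2 * sigma))
        assert abs(res.p - expected) < 3 * res.se


class TestConfusionMatrix:
    def _models(self, n):
        return [ClusterModel(f"c{i}", np.array([2.0 * i, 0, 0]), 0.5 * np.ones(3))
                for i in range(n)]

    def test_offdiagonal_count(self):
        conf = confusion_matrix(self._models(5), n_mc=2000, seed=0)
        assert conf.n_offdiagonal == 20
        assert len(conf.offdiagonal()) == 20

    def test_rows_sum_to_one(self):
        conf = confusion_matrix(self._models(4), n_mc=5000, seed=0)
        assert np.allclose(conf.p.sum(axis=1), 1.0)

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            confusion_matrix(self._models(1))

    def test_frame_is_label_indexed(self):
        conf = confusion_matrix(self._models(3), n_mc=2000, seed=0)
        frame = conf.to_frame()
        assert list(frame.index) == ["c0", "c1", "c2"]
        assert list(frame.columns) == ["c0", "c1", "c2"]


class TestSelectCompatibleSubset:
    def _matrix(self, labels, bad_pairs, p_bad=0.2, p_good=0.001):
        n = len(labels)
        p = np.full((n, n), p_good)
        for i, j in bad_pairs:
            p[i, j] = p[j, i] = p_bad
        np.fill_diagonal(p, 0.0)
        np.fill_diagonal(p, 1.0 - p.sum(axis=1))
        return ConfusionMatrix(list(labels), p, np.zeros((n, n)))

    def test_excludes_confusable_pair(self):
        conf = self._matrix("abcd", [(0, 1)])
        sel = select_compatible_subset(conf, threshold=0.025)
        assert len(sel.labels) == 3
        assert not {"a", "b"} <= set(sel.labels)

    def test_tie_breaks_lexicographically(self):
        # dropping either of the bad pair gives size 3; "a..." wins
        conf = self._matrix("abcd", [(0, 1)])
        sel = select_compatible_subset(conf, threshold=0.025)
        assert sel.labels == ["a", "c", "d"]

    def test_certificate_bounds_internal_confusion(self):
        conf = self._matrix("abcde", [(0, 1), (2, 3)])
        sel = select_compatible_subset(conf, threshold=0.025)
        assert sel.certificate <= sel.threshold

    def test_all_compatible_keeps_everything(self):
        conf = self._matrix("abcd", [])
        sel = select_compatible_subset(conf, threshold=0.025)
        assert sel.labels == ["a", "b", "c", "d"]

    def test_threshold_validation(self):
        conf = self._matrix("ab", [])
        with pytest.raises(ValueError):
            select_compatible_subset(conf, threshold=0.9)


class TestClassifyLevel:
    def _models(self):
        return [
            ClusterModel("left", np.array([0.0, 0, 0]), 0.5 * np.ones(3)),
            ClusterModel("right", np.array([3.0, 0, 0]), 0.5 * np.ones(3)),
        ]

    def test_assigns_nearest_cluster(self):
        res = classify_level(np.array([0.2, 0, 0]), self._models())
        assert res.label == "left"
        assert res.posteriors["left"] > 0.99

    def test_posteriors_normalized(self):
        res = classify_level(np.array([1.5, 0, 0]), self._models())
        assert sum(res.posteriors.values()) == pytest.approx(1.0)

    def test_density_floor_yields_unassigned(self):
        res = classify_level(np.array([100.0, 0, 0]), self._models(),
                             density_floor=-50.0)
        assert res.label == "unassigned"
        assert "below_density_floor" in res.flags

    def test_exact_tie_flagged_and_deterministic(self):
        models = [
            ClusterModel("b", np.array([1.0, 0, 0]), np.ones(3)),
            ClusterModel("a", np.array([-1.0, 0, 0]), np.ones(3)),
        ]
        res = classify_level(np.array([0.0, 0, 0]), models)
        assert res.label == "a"
        assert "tie" in res.flags


class TestReferenceModels:
    def test_builds_requested_labels_with_physical_means(self, registry):
        models = reference_models(registry, labels=["AB14", "AB16"],
                                  n_levels=15, n_photons=3000, seed=1)
        by_label = {m.label: m for m in models}
        assert set(by_label) == {"AB14", "AB16"}
        for lab, m in by_label.items():
            c = registry[lab]
            assert m.mean[0] == pytest.approx(c.green_brightness, rel=0.1)
            assert m.mean[1] == pytest.approx(c.red_brightness, rel=0.1)
            assert m.mean[2] == pytest.approx(c.donor_lifetime, abs=0.1)

    def test_unfittable_lifetime_axis_dropped_consistently(self, registry):
        # AB10 transfers ~94% of excitations: at 500 photons its donor
        # channel cannot support a lifetime fit, so the axis must go for
        # every construct in the set
        with pytest.warns(UserWarning, match="lifetime axis dropped"):
            models = reference_models(registry, labels=["AB10", "AB16"],
                                      n_levels=8, n_photons=500, seed=2)
        assert all(len(m.mean) == 2 for m in models)
        assert all(np.all(np.isfinite(m.mean)) for m in models)
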