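"""Window featurization and the three unsupervised anomaly scorers.

The kNN and LOF scorers are checked against independent brute-force
implementations written here from the textbook definitions; the OCSVM
scorer is checked on its contractual properties (shifted inlier scores,
outlier dominance, degenerate nu).
"""

import numpy as np
import pytest

from phytostress.detectors import (
    KNNAnomalyDetector,
    LOFAnomalyDetector,
    OCSVMAnomalyDetector,
    ScoreSeries,
    StreamScorer,
    compare_detectors,
    knn_score,
    lof_score,
    make_windows,
    ocsvm_score,
)


def raw_matrix(X, n_reference=None):
    """WindowMatrix-like wrapper around explicit window vectors (no
    featurization), built by slicing a flat series with stride=width."""
    X = np.asarray(X, dtype=float)
    m = make_windows(X.ravel(), width=X.shape[1], stride=X.shape[1],
                     standardize=False, center_windows=False, n_reference=n_reference)
    assert np.array_equal(m.values, X)
    return m


# ---------------------------------------------------------------- oracles


def brute_knn_scores(X, k):
    """Mean distance to k nearest others (self excluded), all pairs."""
    X = np.asarray(X, dtype=float)
    out = []
    for i in range(len(X)):
        d = np.sort([np.linalg.norm(X[i] - X[j]) for j in range(len(X)) if j != i])
        out.append(d[:k].mean())
    return np.array(out)


def brute_lof_scores(X, k):
    """Textbook local outlier factor (no distance ties assumed)."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    dist = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    np.fill_diagonal(dist, np.inf)
    neighbors = np.argsort(dist, axis=1)[:, :k]
    k_dist = np.array([dist[i, neighbors[i][-1]] for i in range(n)])
    reach = lambda p, o: max(k_dist[o], dist[p, o])
    lrd = np.array([
        1.0 / np.mean([reach(i, o) for o in neighbors[i]]) for i in range(n)
    ])
    return np.array([np.mean(lrd[neighbors[i]]) / lrd[i] for i in range(n)])


# ---------------------------------------------------------------- windows


class TestMakeWindows:
    @pytest.mark.parametrize("n,width,stride,expected", [
        (5, 5, 1, 1),
        (10, 4, 2, 4),
        (100, 10, 10, 10),
        (101, 10, 10, 10),
    ])
    def test_window_count_formula(self, n, width, stride, expected):
        m = make_windows(np.arange(n, dtype=float), width=width, stride=stride)
        assert m.n_windows == expected == (n - width) // stride + 1

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            make_windows(np.arange(3, dtype=float), width=5)

    def test_reference_standardization(self, rng):
        x = rng.normal(size=400)
        m = make_windows(x, width=10, stride=5, n_reference=40, center_windows=False)
        ref = m.values[:40]
        np.testing.assert_allclose(ref.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(ref.std(axis=0), 1.0, atol=1e-12)

    def test_centering_removes_level_shift(self, rng):
        x = rng.normal(size=200)
        shifted = x + 1e4
        a = make_windows(x, width=20, stride=20)
        b = make_windows(shifted, width=20, stride=20)
        np.testing.assert_allclose(a.values, b.values, atol=1e-7)

    def test_featurize_matches_batch(self, rng):
        x = rng.normal(size=300)
        m = make_windows(x, width=30, stride=1)
        np.testing.assert_allclose(m.featurize(m.raw), m.values, atol=1e-12)


# --------------------------------------------------------------- scorers


class TestKNN:
    def test_four_windows_toy_case(self):
        m = raw_matrix(np.array([[0.0], [0.0], [0.0], [10.0]]))
        series = knn_score(m, k=2)
        np.testing.assert_allclose(series.scores, [0.0, 0.0, 0.0, 10.0])

    def test_all_identical_scores_zero(self):
        m = raw_matrix(np.full((6, 3), 2.5))
        np.testing.assert_allclose(knn_score(m, k=3).scores, 0.0)

    def test_duplicated_dataset_k1_scores_zero(self, rng):
        X = rng.normal(size=(8, 4))
        m = raw_matrix(np.repeat(X, 2, axis=0))
        np.testing.assert_allclose(knn_score(m, k=1).scores, 0.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(20, 5))
        m = raw_matrix(X)
        for k in (1, 3, 5):
            np.testing.assert_allclose(knn_score(m, k=k).scores,
                                       brute_knn_scores(X, k), atol=1e-8)

    def test_new_windows_scored_against_reference_only(self, rng):
        X = rng.normal(size=(15, 4))
        m = raw_matrix(np.vstack([X, X[0] + 100.0]), n_reference=15)
        series = knn_score(m, k=3)
        assert series.scores[-1] > series.scores[:15].max() + 50

    def test_permutation_invariance_of_reference_set(self, rng):
        X = rng.normal(size=(12, 4))
        query = rng.normal(size=(1, 4)) + 3.0
        det = KNNAnomalyDetector(k=4).fit(X)
        det_p = KNNAnomalyDetector(k=4).fit(X[rng.permutation(12)])
        assert det.anomaly_scores(query)[0] == pytest.approx(det_p.anomaly_scores(query)[0])

    def test_k_must_be_smaller_than_reference(self, rng):
        with pytest.raises(ValueError, match="k="):
            KNNAnomalyDetector(k=5).fit(rng.normal(size=(5, 2)))


class TestLOF:
    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(18, 3))
        m = raw_matrix(X)
        for k in (3, 5):
            np.testing.assert_allclose(lof_score(m, n_neighbors=k).scores,
                                       brute_lof_scores(X, k), atol=1e-8)

    def test_point_inside_uniform_cluster_scores_about_one(self, rng):
        X = rng.uniform(size=(20, 2))
        X[0] = [0.5, 0.5]
        scores = lof_score(raw_matrix(X), n_neighbors=5).scores
        assert scores[0] == pytest.approx(1.0, abs=0.35)

    def test_isolated_far_point_scores_much_greater_than_one(self, rng):
        X = np.vstack([rng.normal(scale=0.1, size=(19, 2)), [[50.0, 50.0]]])
        scores = lof_score(raw_matrix(X), n_neighbors=5).scores
        assert scores[-1] > 10.0

    def test_all_identical_windows_score_finite_one(self):
        m = raw_matrix(np.full((10, 2), 3.0))
        scores = lof_score(m, n_neighbors=4).scores
        assert np.isfinite(scores).all()
        np.testing.assert_allclose(scores, 1.0)


class TestOCSVM:
    def test_training_median_score_is_zero(self, rng):
        X = rng.normal(size=(40, 3))
        series = ocsvm_score(raw_matrix(X), nu=0.05)
        # clipping at 0 leaves the median halfway between 0 and the smallest
        # positive score, i.e. ~0 relative to the score spread
        assert np.median(series.scores) <= 0.05 * series.scores.max()
        assert (series.scores >= 0).all()

    def test_far_outlier_beats_every_training_score(self, rng):
        X = rng.normal(size=(20, 2))
        det = OCSVMAnomalyDetector(nu=0.1).fit(X)
        outlier = det.anomaly_scores(np.full((1, 2), 100.0))[0]
        assert outlier > det.reference_scores_.max()

    def test_nu_one_degenerate_still_finite(self, rng):
        X = rng.normal(size=(15, 2))
        series = ocsvm_score(raw_matrix(X), nu=1.0)
        assert np.isfinite(series.scores).all()

    def test_invalid_nu_rejected(self, rng):
        with pytest.raises(ValueError, match="nu"):
            OCSVMAnomalyDetector(nu=0.0).fit(rng.normal(size=(10, 2)))


class TestCompare:
    def build(self, scores, threshold, method):
        return ScoreSeries(method=method, scores=np.asarray(scores, dtype=float),
                           threshold=threshold, starts=np.arange(len(scores)))

    def test_identical_inputs_give_unit_resolving_power(self, rng):
        segs = {m: self.build(rng.uniform(1, 2, 30), 1.5, m) for m in ("knn", "lof", "ocsvm")}
        report = compare_detectors(segs, segs)
        for stats in report["methods"].values():
            assert stats["resolving_power"] == pytest.approx(1.0)

    def test_infinite_threshold_zeroes_both_rates(self, rng):
        normal = {m: self.build(rng.uniform(0, 5, 20), np.inf, m) for m in ("knn", "lof")}
        stressed = {m: self.build(rng.uniform(0, 50, 20), np.inf, m) for m in ("knn", "lof")}
        report = compare_detectors(normal, stressed)
        for stats in report["methods"].values():
            assert stats["sensitivity"] == 0.0
            assert stats["false_score_rate"] == 0.0

    def test_mismatched_methods_rejected(self):
        a = {"knn": self.build([1.0], 1.0, "knn")}
        b = {"lof": self.build([1.0], 1.0, "lof")}
        with pytest.raises(ValueError):
            compare_detectors(a, b)


class TestStreaming:
    def test_no_score_until_buffer_full(self, rng):
        series = rng.normal(size=200)
        scorer = StreamScorer.from_reference(series, method="knn", width=50, k=3)
        for v in series[:49]:
            assert scorer.push(v) is None
        assert scorer.push(series[49]) is not None

    @pytest.mark.parametrize("method", ["knn", "lof", "ocsvm"])
    def test_stream_equals_batch_on_reference_series(self, method, rng):
        series = np.sin(np.linspace(0, 20, 300)) + 0.1 * rng.normal(size=300)
        scorer = StreamScorer.from_reference(series, method=method, width=60)
        streamed = scorer.score_stream(series)
        batch = scorer.detector.anomaly_scores(scorer.matrix.values)
        np.testing.assert_allclose(streamed, batch, atol=1e-10)

    def test_spike_triggers_immediate_score_jump(self, rng):
        series = np.sin(np.linspace(0, 30, 400)) + 0.05 * rng.normal(size=400)
        scorer = StreamScorer.from_reference(series, method="knn", width=40, k=3)
        pre = scorer.score_stream(series)
        spike_scores = [scorer.push(v) for v in [series[-1] + 25.0] * 5]
        assert min(spike_scores) > max(pre)
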