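"""Unsupervised window-based anomaly scoring of resistance streams.

The screening-stage analytics: fixed-width sliding windows are cut from one
plant's resistance series, each window is mean-centered (so the slow
nutrient-depletion trend does not register as an anomaly) and
z-standardized per position using statistics of a reference (assumed
normal) segment, and three detectors score every window against that
reference set:

* k-nearest-neighbour distance — mean Euclidean distance to the k closest
  reference windows;
* local outlier factor — the classic density-ratio score (~1 for inliers);
* one-class SVM — RBF boundary around the reference windows, scores shifted
  so typical reference windows sit at ~0.

Larger scores mean more anomalous everywhere. Each detector's stress
threshold defaults to the 99th percentile of its own reference-segment
scores. A streaming scorer replays the same computation one sample at a
time for live tracking.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator
from sklearn.neighbors import LocalOutlierFactor, NearestNeighbors
from sklearn.svm import OneClassSVM
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "WindowMatrix",
    "ScoreSeries",
    "make_windows",
    "KNNAnomalyDetector",
    "LOFAnomalyDetector",
    "OCSVMAnomalyDetector",
    "knn_score",
    "lof_score",
    "ocsvm_score",
    "compare_detectors",
    "StreamScorer",
    "DETECTOR_CLASSES",
]

DEFAULT_WIDTH = 90
DEFAULT_STRIDE = 10
DEFAULT_THRESHOLD_QUANTILE = 0.99


@dataclass
class WindowMatrix:
    """Sliding windows from one series, with their featurization recorded.

    ``values`` holds the featurized windows actually scored; ``raw`` the
    untouched ones.  ``n_reference`` marks how many leading windows form the
    reference (normal) segment whose statistics defined the featurization.
    """

    values: np.ndarray
    raw: np.ndarray
    starts: np.ndarray
    width: int
    stride: int
    center: np.ndarray
    scale: np.ndarray
    centered: bool
    n_reference: int

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def reference(self) -> np.ndarray:
        return self.values[: self.n_reference]

    def featurize(self, raw_windows: np.ndarray) -> np.ndarray:
        """Apply this matrix's recorded featurization to new raw windows."""
        w = np.asarray(raw_windows, dtype=float)
        if self.centered:
            w = w - w.mean(axis=1, keepdims=True)
        return (w - self.center) / self.scale


def make_windows(
    series,
    width: int = DEFAULT_WIDTH,
    stride: int = DEFAULT_STRIDE,
    standardize: bool = True,
    center_windows: bool = True,
    n_reference: int | None = None,
) -> WindowMatrix:
    """Cut sliding windows from a 1-d series.

    Window count is ``floor((n - width)/stride) + 1``. When ``standardize``
    the per-position center/scale come from the first ``n_reference``
    windows only (default: all), so later data cannot leak into the
    featurization.
    """
    x = np.asarray(series, dtype=float).ravel()
    if width < 1 or stride < 1:
        raise ValueError("width and stride must be >= 1")
    if x.size < width:
        raise ValueError(f"series of length {x.size} is shorter than window width {width}")
    raw = sliding_window_view(x, width)[::stride].copy()
    starts = np.arange(0, x.size - width + 1, stride)
    n_ref = raw.shape[0] if n_reference is None else int(n_reference)
    if not 1 <= n_ref <= raw.shape[0]:
        raise ValueError(f"n_reference must be in [1, {raw.shape[0]}], got {n_ref}")
    work = raw - raw.mean(axis=1, keepdims=True) if center_windows else raw
    if standardize:
        center = work[:n_ref].mean(axis=0)
        scale = work[:n_ref].std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
    else:
        center = np.zeros(width)
        scale = np.ones(width)
    values = (work - center) / scale
    return WindowMatrix(
        values=values,
        raw=raw,
        starts=starts,
        width=width,
        stride=stride,
        center=center,
        scale=scale,
        centered=center_windows,
        n_reference=n_ref,
    )


@dataclass
class ScoreSeries:
    """Per-window decision scores from one detector."""

    method: str
    scores: np.ndarray
    threshold: float
    starts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def flags(self) -> np.ndarray:
        return self.scores > self.threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"window_start": self.starts, "score": self.scores, "flag": self.flags}
        )


class _WindowDetector(BaseEstimator):
    """Shared fit/score plumbing for the three window detectors."""

    method = "base"

    def __init__(self, threshold_quantile: float = DEFAULT_THRESHOLD_QUANTILE):
        self.threshold_quantile = threshold_quantile

    def _fit_model(self, X: np.ndarray) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def _score_new(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def _score_reference(self) -> np.ndarray:
        """Scores of the fitted reference windows, self-excluded."""
        raise NotImplementedError

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("expected a 2-d window matrix with at least 2 reference windows")
        self.reference_ = X
        self._fit_model(X)
        self.reference_scores_ = self._score_reference()
        self.threshold_ = float(
            np.quantile(self.reference_scores_, self.threshold_quantile)
        )
        return self

    def anomaly_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "reference_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._score_new(X)

    def predict_flags(self, X) -> np.ndarray:
        return self.anomaly_scores(X) > self.threshold_

    def score_series(self, matrix: WindowMatrix) -> ScoreSeries:
        """Score every window of ``matrix`` against its reference portion,
        fitting on the reference windows if not already fitted there."""
        self.fit(matrix.reference)
        scores = np.concatenate(
            [self.reference_scores_, self._score_new(matrix.values[matrix.n_reference:])]
            if matrix.n_windows > matrix.n_reference
            else [self.reference_scores_]
        )
        return ScoreSeries(
            method=self.method, scores=scores, threshold=self.threshold_, starts=matrix.starts
        )


class KNNAnomalyDetector(_WindowDetector):
    """Mean distance to the k nearest reference windows.

    Reference windows are scored with themselves excluded, so a duplicated
    reference set scores 0 everywhere.
    """

    method = "knn"

    def __init__(self, k: int = 5, threshold_quantile: float = DEFAULT_THRESHOLD_QUANTILE):
        super().__init__(threshold_quantile=threshold_quantile)
        self.k = k

    def _fit_model(self, X):
        if not self.k < X.shape[0]:
            raise ValueError(f"k={self.k} must be smaller than the {X.shape[0]} reference windows")
        self.nn_ = NearestNeighbors(n_neighbors=min(self.k + 1, X.shape[0])).fit(X)

    def _score_new(self, X):
        dist, _ = self.nn_.kneighbors(X, n_neighbors=self.k)
        return dist.mean(axis=1)

    def _score_reference(self):
        X = self.reference_
        dist, idx = self.nn_.kneighbors(X, n_neighbors=self.k + 1)
        scores = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            self_pos = np.nonzero(idx[i] == i)[0]
            keep = np.delete(dist[i], self_pos[0]) if self_pos.size else dist[i][:-1]
            scores[i] = keep[: self.k].mean()
        return scores


class LOFAnomalyDetector(_WindowDetector):
    """Local outlier factor against the reference set (~1 means inlier).

    Degenerate ties (identical windows, zero distances) are scored 1, the
    limit of identical local densities.
    """

    method = "lof"

    def __init__(self, n_neighbors: int = 20,
                 threshold_quantile: float = DEFAULT_THRESHOLD_QUANTILE):
        super().__init__(threshold_quantile=threshold_quantile)
        self.n_neighbors = n_neighbors

    def _effective_neighbors(self, n_ref: int) -> int:
        return min(self.n_neighbors, n_ref - 1)

    def _fit_model(self, X):
        k = self._effective_neighbors(X.shape[0])
        self.lof_ = LocalOutlierFactor(n_neighbors=k, novelty=True).fit(X)
        self.lof_insample_ = LocalOutlierFactor(n_neighbors=k, novelty=False).fit(X)

    @staticmethod
    def _clean(scores: np.ndarray) -> np.ndarray:
        return np.where(np.isfinite(scores), scores, 1.0)

    def _score_new(self, X):
        return self._clean(-self.lof_.score_samples(X))

    def _score_reference(self):
        return self._clean(-self.lof_insample_.negative_outlier_factor_)


class OCSVMAnomalyDetector(_WindowDetector):
    """One-class SVM with RBF kernel on the reference windows.

    Scores are the negated decision function shifted by the reference
    median and clipped at 0, so typical reference windows score ~0 and
    anything outside the boundary scores positive.
    """

    method = "ocsvm"

    def __init__(self, nu: float = 0.05, gamma="scale",
                 threshold_quantile: float = DEFAULT_THRESHOLD_QUANTILE):
        super().__init__(threshold_quantile=threshold_quantile)
        self.nu = nu
        self.gamma = gamma

    def _fit_model(self, X):
        if not 0 < self.nu <= 1:
            raise ValueError(f"nu must be in (0, 1], got {self.nu}")
        # nu = 1 (every training point a boundary/outlier) is a degenerate
        # limit the solver cannot represent exactly; evaluate it just inside
        nu = min(self.nu, 1.0 - 1e-9)
        self.svm_ = OneClassSVM(kernel="rbf", nu=nu, gamma=self.gamma).fit(X)
        self.shift_ = float(np.median(self.svm_.decision_function(X)))

    def _score_new(self, X):
        return np.clip(self.shift_ - self.svm_.decision_function(X), 0.0, None)

    def _score_reference(self):
        return self._score_new(self.reference_)


DETECTOR_CLASSES = {
    "knn": KNNAnomalyDetector,
    "lof": LOFAnomalyDetector,
    "ocsvm": OCSVMAnomalyDetector,
}


def knn_score(matrix: WindowMatrix, k: int = 5, **kwargs) -> ScoreSeries:
    return KNNAnomalyDetector(k=k, **kwargs).score_series(matrix)


def lof_score(matrix: WindowMatrix, n_neighbors: int = 20, **kwargs) -> ScoreSeries:
    return LOFAnomalyDetector(n_neighbors=n_neighbors, **kwargs).score_series(matrix)


def ocsvm_score(matrix: WindowMatrix, nu: float = 0.05, gamma="scale", **kwargs) -> ScoreSeries:
    return OCSVMAnomalyDetector(nu=nu, gamma=gamma, **kwargs).score_series(matrix)


def _median_ratio(stressed: np.ndarray, normal: np.ndarray) -> float:
    ms, mn = float(np.median(stressed)), float(np.median(normal))
    if ms == mn:
        return 1.0
    if mn == 0:
        return float("inf")
    return ms / mn


def compare_detectors(
    normal: dict[str, ScoreSeries], stressed: dict[str, ScoreSeries]
) -> dict:
    """Three-way comparison of detectors on matched normal/stressed segments.

    Per method: ``resolving_power`` = median stressed / median normal score,
    ``false_score_rate`` = fraction of normal windows above the method's
    threshold, ``sensitivity`` = fraction of stressed windows above it.
    Also ranks methods (best first) on each criterion.
    """
    if set(normal) != set(stressed):
        raise ValueError("normal and stressed segments must cover the same methods")
    per_method = {}
    for method in normal:
        ns, ss = normal[method], stressed[method]
        thr = ss.threshold
        per_method[method] = {
            "resolving_power": _median_ratio(ss.scores, ns.scores),
            "false_score_rate": float(np.mean(ns.scores > thr)) if ns.scores.size else 0.0,
            "sensitivity": float(np.mean(ss.scores > thr)) if ss.scores.size else 0.0,
            "threshold": thr,
        }
    rank = lambda key, best_high: sorted(
        per_method, key=lambda m: per_method[m][key], reverse=best_high
    )
    return {
        "methods": per_method,
        "ranking": {
            "resolving_power": rank("resolving_power", True),
            "sensitivity": rank("sensitivity", True),
            "false_score_rate": rank("false_score_rate", False),
        },
    }


class StreamScorer:
    """Live per-sample anomaly scoring with a rolling window buffer.

    Wraps a fitted detector and the featurization of the reference
    :class:`WindowMatrix` it was fitted on. Each pushed sample advances the
    buffer by one; once ``width`` samples have arrived, every push emits the
    score of the current window — identical to batch scoring the same
    (stride-1) windows.
    """

    def __init__(self, detector: _WindowDetector, matrix: WindowMatrix):
        check_is_fitted(detector, "reference_")
        self.detector = detector
        self.matrix = matrix
        self.width = matrix.width
        self._buffer: deque = deque(maxlen=matrix.width)

    @classmethod
    def from_reference(cls, reference_series, method: str = "knn",
                       width: int = DEFAULT_WIDTH, **detector_params) -> "StreamScorer":
        """Fit a detector on stride-1 windows of a reference series and
        return a scorer ready for live samples."""
        matrix = make_windows(reference_series, width=width, stride=1)
        detector = DETECTOR_CLASSES[method](**detector_params)
        detector.fit(matrix.reference)
        return cls(detector, matrix)

    def push(self, value: float) -> float | None:
        """Feed one sample; returns the latest score, or None while the
        buffer is still filling."""
        self._buffer.append(float(value))
        if len(self._buffer) < self.width:
            return None
        window = self.matrix.featurize(np.array(self._buffer)[None, :])
        return float(self.detector.anomaly_scores(window)[0])

    def score_stream(self, values) -> list[float]:
        """Push a whole sequence; returns the emitted scores (buffer-filling
        samples emit nothing)."""
        out = []
        for v in values:
            s = self.push(v)
            if s is not None:
                out.append(s)
        return out
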