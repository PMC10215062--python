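"""Reconstructional-autoencoder stress forecasting on carrier-change series.

The forecasting stage: a series of relative carrier-concentration
changes is split at a boundary day into an anomaly-scarce training half and
a test half.  Windows of 45 consecutive samples (one channel) are min-max
normalized with training statistics and fed to a reconstructional
autoencoder trained to reproduce its input under mean-absolute-error loss.
The anomaly threshold is the exact maximum MAE the trained model attains on
its own training windows — by construction the training period raises zero
flags — and any test window whose reconstruction MAE exceeds it is flagged
as an unlearnt pattern, i.e. stress.

The network here is a compact fully-connected encoder-decoder
(45 -> 64 -> 32 -> 64 -> 45, tanh hidden units, linear output) trained with
Adam in pure numpy; it is small enough to train in seconds on a CPU and is
deterministic given its seed.  A linear trend fitted on the training half
is removed before windowing, so the slow nutrient-depletion drift is
modelled separately from the diurnal/noise structure the autoencoder
learns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .detectors import make_windows

__all__ = [
    "DEFAULT_WIDTH",
    "split_train_test",
    "WindowAutoencoder",
    "train_autoencoder",
    "reconstruction_mae",
    "calibrate_threshold",
    "detect_anomalies",
    "ReconstructionReport",
    "AutoencoderStressDetector",
]

DEFAULT_WIDTH = 45


def split_train_test(series: pd.DataFrame, boundary_day: int):
    """Split a timestamped series at the midnight ``boundary_day`` days after
    the first sample's calendar day.

    The split is disjoint, exhaustive and order-preserving; a boundary at or
    beyond the series end yields an empty test half.
    """
    if len(series) == 0:
        raise ValueError("cannot split an empty series")
    ts = pd.to_datetime(series["timestamp"])
    first_day = ts.iloc[0].floor("D")
    cut = first_day + pd.Timedelta(days=boundary_day)
    if boundary_day <= 0:
        raise ValueError("boundary day must be positive")
    train = series.loc[(ts < cut).to_numpy()].reset_index(drop=True)
    test = series.loc[(ts >= cut).to_numpy()].reset_index(drop=True)
    return train, test


class WindowAutoencoder(BaseEstimator):
    """Dense reconstructional autoencoder over fixed-width windows.

    Encoder ``width -> hidden[0] -> hidden[1]``, mirrored decoder, tanh
    hidden activations, linear output, mean-absolute-error loss minimized
    with Adam.  Training shuffling and weight initialization are driven by
    ``random_state`` only, so identical seeds give bit-identical models.

    Fitted attributes: ``weights_``, ``biases_``, ``loss_curve_`` (full-set
    MAE after each epoch), ``n_features_in_``.
    """

    def __init__(self, hidden=(64, 32), epochs: int = 30, batch_size: int = 64,
                 learning_rate: float = 3e-3, lr_decay: float = 0.9,
                 tol: float = 1e-5, patience: int = 5,
                 min_windows_factor: int = 10, random_state: int = 0):
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.tol = tol
        self.patience = patience
        self.min_windows_factor = min_windows_factor
        self.random_state = random_state

    def _init_params(self, sizes, rng):
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return weights, biases

    def _forward(self, X, weights, biases):
        activations = [X]
        a = X
        last = len(weights) - 1
        for i, (W, b) in enumerate(zip(weights, biases)):
            z = a @ W + b
            a = z if i == last else np.tanh(z)
            activations.append(a)
        return activations

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-d window matrix")
        n, width = X.shape
        required = self.min_windows_factor * width
        if n < required:
            raise ValueError(
                f"too few training windows: {n} < required minimum {required} "
                f"({self.min_windows_factor} x width {width})"
            )
        rng = np.random.default_rng(self.random_state)
        sizes = [width, *self.hidden, *reversed(self.hidden[:-1]), width]
        weights, biases = self._init_params(sizes, rng)
        mW = [np.zeros_like(w) for w in weights]
        vW = [np.zeros_like(w) for w in weights]
        mB = [np.zeros_like(b) for b in biases]
        vB = [np.zeros_like(b) for b in biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        loss_curve = []
        best = np.inf
        stall = 0
        for epoch in range(self.epochs):
            # MAE gradients are sign-scaled, so Adam dithers at ~the learning
            # rate; decaying it per epoch lets the fit settle
            lr = self.learning_rate * self.lr_decay**epoch
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                batch = X[order[lo:lo + self.batch_size]]
                acts = self._forward(batch, weights, biases)
                out = acts[-1]
                delta = np.sign(out - batch) / out.size
                gW = [None] * len(weights)
                gB = [None] * len(weights)
                for i in range(len(weights) - 1, -1, -1):
                    gW[i] = acts[i].T @ delta
                    gB[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = (delta @ weights[i].T) * (1.0 - acts[i] ** 2)
                step += 1
                corr1 = 1.0 - beta1**step
                corr2 = 1.0 - beta2**step
                for i in range(len(weights)):
                    mW[i] = beta1 * mW[i] + (1 - beta1) * gW[i]
                    vW[i] = beta2 * vW[i] + (1 - beta2) * gW[i] ** 2
                    weights[i] -= lr * (mW[i] / corr1) / (
                        np.sqrt(vW[i] / corr2) + eps
                    )
                    mB[i] = beta1 * mB[i] + (1 - beta1) * gB[i]
                    vB[i] = beta2 * vB[i] + (1 - beta2) * gB[i] ** 2
                    biases[i] -= lr * (mB[i] / corr1) / (
                        np.sqrt(vB[i] / corr2) + eps
                    )
            epoch_loss = float(
                np.mean(np.abs(self._forward(X, weights, biases)[-1] - X))
            )
            loss_curve.append(epoch_loss)
            if best - epoch_loss > self.tol:
                best = epoch_loss
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        self.weights_ = weights
        self.biases_ = biases
        self.loss_curve_ = loss_curve
        self.final_loss_ = loss_curve[-1]
        self.n_features_in_ = width
        return self

    def reconstruct(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._forward(X, self.weights_, self.biases_)[-1]

    def window_mae(self, X) -> np.ndarray:
        """Per-window mean absolute reconstruction error."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return reconstruction_mae(self, X)


def train_autoencoder(train_windows, epochs: int = 30, seed: int = 0,
                      **params) -> WindowAutoencoder:
    """Train a :class:`WindowAutoencoder` on prepared training windows."""
    return WindowAutoencoder(epochs=epochs, random_state=seed, **params).fit(train_windows)


def reconstruction_mae(model, windows) -> np.ndarray:
    """MAE_w = mean over window positions of |input - reconstruction|."""
    W = np.atleast_2d(np.asarray(windows, dtype=float))
    recon = np.atleast_2d(np.asarray(model.reconstruct(W), dtype=float))
    return np.mean(np.abs(W - recon), axis=1)


def calibrate_threshold(train_maes) -> float:
    """Anomaly threshold = the exact maximum training-window MAE."""
    maes = np.asarray(train_maes, dtype=float)
    if maes.size == 0:
        raise ValueError("cannot calibrate a threshold from an empty MAE series")
    return float(maes.max())


@dataclass
class ReconstructionReport:
    """Per-window reconstruction errors with their anomaly calls."""

    window_starts: np.ndarray
    mae: np.ndarray
    threshold: float
    flags: np.ndarray
    onset_estimate: object  # earliest flagged window start, or None
    severity: np.ndarray  # MAE / threshold
    boundary: object = None  # train/test boundary timestamp, if known
    train_max_mae: float | None = None
    empty_test: bool = False

    @property
    def flag_rate(self) -> float:
        return float(np.mean(self.flags)) if self.flags.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start": self.window_starts,
                "mae": self.mae,
                "severity": self.severity,
                "flag": self.flags,
            }
        )


def detect_anomalies(model, threshold: float, windows, window_starts=None) -> ReconstructionReport:
    """Flag windows whose reconstruction MAE exceeds ``threshold``."""
    W = np.atleast_2d(np.asarray(windows, dtype=float))
    maes = reconstruction_mae(model, W)
    flags = maes > threshold
    if window_starts is None:
        window_starts = np.arange(W.shape[0])
    window_starts = np.asarray(window_starts)
    onset = window_starts[flags][0] if flags.any() else None
    severity = maes / threshold if np.isfinite(threshold) and threshold > 0 else np.zeros_like(maes)
    return ReconstructionReport(
        window_starts=window_starts,
        mae=maes,
        threshold=float(threshold),
        flags=flags,
        onset_estimate=onset,
        severity=severity,
        empty_test=W.shape[0] == 0,
    )


class AutoencoderStressDetector(BaseEstimator):
    """End-to-end forecasting-stage detector on a carrier-change series.

    ``fit`` consumes the training half of a series (columns ``timestamp,
    relative_change``): it removes a linear trend fitted on that half,
    min-max normalizes the residual with training statistics, cuts
    stride-``train_stride`` windows of ``width`` samples, trains the
    autoencoder and calibrates the threshold as the maximum training MAE
    (optionally inflated by ``threshold_inflation``; default off).
    ``detect`` applies the same trend and normalization to the test half
    and reports non-overlapping-by-default windows whose MAE exceeds the
    threshold.
    """

    def __init__(self, width: int = DEFAULT_WIDTH, train_stride: int = 1,
                 detect_stride: int | None = None, detrend: bool = True,
                 threshold_inflation: float = 1.0, hidden=(64, 32),
                 epochs: int = 30, batch_size: int = 64, learning_rate: float = 3e-3,
                 min_windows_factor: int = 10, random_state: int = 0):
        self.width = width
        self.train_stride = train_stride
        self.detect_stride = detect_stride
        self.detrend = detrend
        self.threshold_inflation = threshold_inflation
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.min_windows_factor = min_windows_factor
        self.random_state = random_state

    def _days(self, series: pd.DataFrame) -> np.ndarray:
        ts = pd.to_datetime(series["timestamp"])
        return (ts - self.origin_).dt.total_seconds().to_numpy() / 86400.0

    def _normalize(self, series: pd.DataFrame) -> np.ndarray:
        values = series["relative_change"].to_numpy(dtype=float)
        if self.detrend:
            values = values - np.polyval(self.trend_coef_, self._days(series))
        return (values - self.min_) / self.scale_

    def fit(self, train_series: pd.DataFrame, y=None):
        if len(train_series) < self.width:
            raise ValueError("training series shorter than one window")
        self.origin_ = pd.to_datetime(train_series["timestamp"]).iloc[0]
        t = self._days(train_series)
        values = train_series["relative_change"].to_numpy(dtype=float)
        self.trend_coef_ = (
            np.polyfit(t, values, 1) if self.detrend else np.array([0.0, 0.0])
        )
        resid = values - np.polyval(self.trend_coef_, t) if self.detrend else values
        lo, hi = float(resid.min()), float(resid.max())
        self.min_ = lo
        self.scale_ = (hi - lo) if hi > lo else 1.0
        norm = (resid - self.min_) / self.scale_
        matrix = make_windows(norm, width=self.width, stride=self.train_stride,
                              standardize=False, center_windows=False)
        self.model_ = WindowAutoencoder(
            hidden=self.hidden, epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, min_windows_factor=self.min_windows_factor,
            random_state=self.random_state,
        ).fit(matrix.raw)
        self.train_maes_ = self.model_.window_mae(matrix.raw)
        self.train_max_mae_ = calibrate_threshold(self.train_maes_)
        self.threshold_ = self.train_max_mae_ * self.threshold_inflation
        # the training period can never raise a flag at this threshold
        assert not np.any(self.train_maes_ > self.threshold_ + 1e-15)
        return self

    def detect(self, test_series: pd.DataFrame) -> ReconstructionReport:
        check_is_fitted(self, "model_")
        stride = self.detect_stride if self.detect_stride is not None else self.width
        if len(test_series) < self.width:
            report = ReconstructionReport(
                window_starts=np.array([], dtype=object), mae=np.array([]),
                threshold=self.threshold_, flags=np.array([], dtype=bool),
                onset_estimate=None, severity=np.array([]), empty_test=True,
                train_max_mae=self.train_max_mae_,
            )
            return report
        norm = self._normalize(test_series)
        matrix = make_windows(norm, width=self.width, stride=stride,
                              standardize=False, center_windows=False)
        starts = pd.to_datetime(test_series["timestamp"]).to_numpy()[matrix.starts]
        report = detect_anomalies(self.model_, self.threshold_, matrix.raw, starts)
        report.train_max_mae = self.train_max_mae_
        report.boundary = pd.to_datetime(test_series["timestamp"]).iloc[0]
        return report
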