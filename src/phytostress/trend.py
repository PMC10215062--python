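"""Linear-trend stress screening and daily candlestick aggregation.

A healthy bottle shows a steady, near-linear rise of resistance as the
plant depletes nutrients, with the diurnal swing riding on top.  Divergence
from that line flags likely stress: the screen fits resistance on elapsed
time by ordinary least squares and compares the R-squared of the fit
against a threshold (default 0.65).  Daily OHLC candles summarize the
within-day range; a day whose high-low range blows out against the series
median is flagged as abnormal, the way a starred candle marks anomalous
behaviour on a chart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sklearn.base import BaseEstimator

__all__ = [
    "DEFAULT_R2_THRESHOLD",
    "FitReport",
    "fit_linear_trend",
    "LinearTrendScreen",
    "daily_candles",
    "moving_average",
    "flag_abnormal_range",
]

DEFAULT_R2_THRESHOLD = 0.65


@dataclass(frozen=True)
class FitReport:
    plant_id: int | None
    slope_ohm_per_day: float
    intercept_ohm: float
    r_squared: float
    stressed: bool
    threshold: float

    def to_dict(self) -> dict:
        return {
            "plant_id": self.plant_id,
            "slope_ohm_per_day": self.slope_ohm_per_day,
            "intercept_ohm": self.intercept_ohm,
            "r_squared": self.r_squared,
            "stressed": self.stressed,
            "threshold": self.threshold,
        }


def _elapsed_days(timestamps: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(timestamps)
    return (ts - ts.iloc[0]).dt.total_seconds().to_numpy() / 86400.0


def fit_linear_trend(
    samples: pd.DataFrame, r2_threshold: float = DEFAULT_R2_THRESHOLD
) -> FitReport:
    """OLS fit of resistance on elapsed time, with R-squared stress screen.

    A perfectly constant resistance series is reported as r_squared = 1 with
    slope 0 (a horizontal line is a perfect fit), so stable reference
    bottles are never screened as stressed.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to fit a trend")
    t = _elapsed_days(samples["timestamp"])
    y = samples["resistance_ohm"].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("constant time axis: all samples share one timestamp")
    if np.ptp(y) == 0:
        slope, intercept, r2 = 0.0, float(y[0]), 1.0
    else:
        res = stats.linregress(t, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    plant_ids = samples["plant_id"].unique() if "plant_id" in samples else []
    plant_id = int(plant_ids[0]) if len(plant_ids) == 1 else None
    return FitReport(
        plant_id=plant_id,
        slope_ohm_per_day=slope,
        intercept_ohm=intercept,
        r_squared=r2,
        stressed=bool(r2 < r2_threshold),
        threshold=float(r2_threshold),
    )


class LinearTrendScreen(BaseEstimator):
    """Sklearn-style wrapper around :func:`fit_linear_trend`.

    Fitted attributes: ``slope_``, ``intercept_``, ``r_squared_``,
    ``stressed_``, ``report_``.
    """

    def __init__(self, r2_threshold: float = DEFAULT_R2_THRESHOLD):
        self.r2_threshold = r2_threshold

    def fit(self, X: pd.DataFrame, y=None):
        report = fit_linear_trend(X, r2_threshold=self.r2_threshold)
        self.report_ = report
        self.slope_ = report.slope_ohm_per_day
        self.intercept_ = report.intercept_ohm
        self.r_squared_ = report.r_squared
        self.stressed_ = report.stressed
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Trend-line resistance at the timestamps of ``X`` (days measured
        from the first fitted timestamp are not retained; prediction uses
        elapsed time within ``X``)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "slope_")
        return self.intercept_ + self.slope_ * _elapsed_days(X["timestamp"])


def daily_candles(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-calendar-day OHLC summary of one plant's resistance.

    Day boundaries fall at local midnight; open/close are the first/last
    samples of each day, high/low the extremes. Columns:
    ``day, open, high, low, close, n_samples``.
    """
    if len(samples) == 0:
        return pd.DataFrame(columns=["day", "open", "high", "low", "close", "n_samples"])
    df = samples.sort_values("timestamp", kind="mergesort")
    day = pd.to_datetime(df["timestamp"]).dt.floor("D")
    grouped = df.groupby(day.values)["resistance_ohm"]
    out = grouped.agg(open="first", high="max", low="min", close="last", n_samples="size")
    out = out.reset_index().rename(columns={"index": "day"})
    out["n_samples"] = out["n_samples"].astype(np.int64)
    return out


def moving_average(candles: pd.DataFrame, window: int) -> pd.DataFrame:
    """Trailing simple moving average of the daily close over ``window`` days.

    The first ``window - 1`` days have no defined average and are omitted.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sma = candles["close"].rolling(window).mean()
    out = pd.DataFrame({"day": candles["day"], "sma": sma})
    return out.dropna().reset_index(drop=True)


def flag_abnormal_range(candles: pd.DataFrame, kappa: float = 3.0) -> pd.DataFrame:
    """Flag days whose high-low range exceeds ``kappa`` times the series median range.

    Returns columns ``day, range_ohm, flagged``.
    """
    if len(candles) < 2:
        raise ValueError("need at least 2 candles to judge an abnormal range")
    rng = (candles["high"] - candles["low"]).to_numpy(dtype=float)
    med = float(np.median(rng))
    return pd.DataFrame(
        {"day": candles["day"], "range_ohm": rng, "flagged": rng > kappa * med}
    )
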