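"""Temperature-compensated Drude transform for ionic growth media.

The medium conducts through its dissolved nutrient ions, so its resistance
is inversely proportional to the charge-carrier concentration ``n`` with a
linear temperature correction,

    R ~ 1 / ( n * [1 + alpha * (T - T0)] ),

with alpha = 0.0141/degC for agarose.  Anchoring the proportionality at a
reference state (R0, T0) gives the relative carrier change

    (n - n0)/n0 = R0 / ( R * [1 + alpha * (T - T0)] ) - 1,

the package's stress proxy: a sudden rise means ions dumped into the medium
(allelochemical release), a faster-than-trend fall means surging nutrient
uptake.  Humidity never enters the relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DrudeDomainError

__all__ = [
    "DEFAULT_ALPHA",
    "ReferenceState",
    "relative_carrier_change",
    "compensated_resistance",
    "series_carrier_change",
    "CarrierChangeTransformer",
]

#: Temperature compensation factor for agarose, per degC.
DEFAULT_ALPHA = 0.0141


@dataclass(frozen=True)
class ReferenceState:
    """The (R0, T0) anchor of the Drude transform.

    Any bottle's initial state may serve; only the ratio (n - n0)/n0 is ever
    computed, so n0 itself never appears.
    """

    r0: float
    t0: float
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self):
        if not self.r0 > 0:
            raise DrudeDomainError(f"reference resistance must be > 0, got {self.r0}")

    def compensation(self, temperature_c):
        """1 + alpha * (T - T0); must stay positive wherever it is applied."""
        return 1.0 + self.alpha * (np.asarray(temperature_c, dtype=float) - self.t0)


def _check_domain(resistance_ohm, comp):
    if np.any(np.asarray(resistance_ohm) <= 0):
        raise DrudeDomainError("resistance must be > 0")
    if np.any(np.asarray(comp) <= 0):
        raise DrudeDomainError(
            "temperature compensation factor 1 + alpha*(T - T0) must be > 0"
        )


def relative_carrier_change(resistance_ohm, temperature_c, ref: ReferenceState):
    """Relative carrier-concentration change (n - n0)/n0, dimensionless.

    Evaluates ``R0 / (R * [1 + alpha*(T - T0)]) - 1`` elementwise. Always
    greater than -1 for valid inputs (concentration cannot go negative).
    """
    comp = ref.compensation(temperature_c)
    _check_domain(resistance_ohm, comp)
    out = ref.r0 / (np.asarray(resistance_ohm, dtype=float) * comp) - 1.0
    if np.isscalar(resistance_ohm) and np.isscalar(temperature_c):
        return float(out)
    return out


def compensated_resistance(resistance_ohm, temperature_c, ref: ReferenceState):
    """Resistance referred to the reference temperature: R * [1 + alpha*(T - T0)]."""
    comp = ref.compensation(temperature_c)
    _check_domain(resistance_ohm, comp)
    out = np.asarray(resistance_ohm, dtype=float) * comp
    if np.isscalar(resistance_ohm) and np.isscalar(temperature_c):
        return float(out)
    return out


def _resolve_reference(samples: pd.DataFrame, ref, alpha: float) -> ReferenceState:
    if ref == "auto":
        first = samples.iloc[0]
        return ReferenceState(
            r0=float(first["resistance_ohm"]), t0=float(first["temperature_c"]), alpha=alpha
        )
    if isinstance(ref, ReferenceState):
        return ref
    raise TypeError("ref must be a ReferenceState or 'auto'")


def series_carrier_change(
    samples: pd.DataFrame, ref: ReferenceState | str = "auto", alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Carrier-change series for one plant's time-ordered samples.

    With ``ref='auto'`` the reference (R0, T0) is the first sample, so the
    first point is exactly 0. Returns columns ``timestamp, relative_change``.
    """
    if len(samples) == 0:
        return pd.DataFrame({"timestamp": pd.Series([], dtype="datetime64[ns]"),
                             "relative_change": pd.Series([], dtype=float)})
    if samples["plant_id"].nunique() > 1:
        raise ValueError(
            f"series spans multiple plant_ids {sorted(samples['plant_id'].unique())}; "
            "transform one plant at a time"
        )
    reference = _resolve_reference(samples, ref, alpha)
    change = relative_carrier_change(
        samples["resistance_ohm"].to_numpy(), samples["temperature_c"].to_numpy(), reference
    )
    return pd.DataFrame({"timestamp": samples["timestamp"].to_numpy(), "relative_change": change})


class CarrierChangeTransformer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer from sample tables to carrier-change series.

    Parameters
    ----------
    r0, t0 : float or None
        Reference resistance (ohm) and temperature (degC). If either is
        None, both are taken from the first sample seen at fit time.
    alpha : float
        Temperature compensation factor per degC.
    """

    def __init__(self, r0: float | None = None, t0: float | None = None,
                 alpha: float = DEFAULT_ALPHA):
        self.r0 = r0
        self.t0 = t0
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y=None):
        if self.r0 is not None and self.t0 is not None:
            self.reference_ = ReferenceState(self.r0, self.t0, self.alpha)
        else:
            if len(X) == 0:
                raise ValueError("cannot infer a reference state from an empty table")
            self.reference_ = _resolve_reference(X, "auto", self.alpha)
        self.r0_ = self.reference_.r0
        self.t0_ = self.reference_.t0
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "reference_")
        return series_carrier_change(X, ref=self.reference_)
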