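"""Synthetic growth-media resistance experiments.

Emulates the bottle experiments the analysis pipeline was designed for:
eight borosilicate bottles of agarose growth medium, measured sequentially
by one multimeter at 10 s intervals, so each bottle is sampled every
``n_plants * 10`` s.  The medium behaves as a concentrated ionic suspension:
its resistance is inversely proportional to the charge-carrier (nutrient
ion) concentration ``n`` and carries a linear temperature correction,

    R(t) = R0 / [ (n(t)/n0) * (1 + alpha * (T(t) - T0)) ] + noise.

The carrier trajectory ``n(t)/n0`` declines linearly as the plant takes up
nutrients; stress events perturb it (allelochemical release raises the
ionic content stepwise, an uptake surge amplifies the local excursions and
steepens depletion, death freezes the trajectory).  Temperature follows a
diurnal sinusoid, which is what produces the reported morning-high /
late-afternoon-low resistance pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SchemaError, UnknownEventKindError

__all__ = [
    "COLUMNS",
    "ROLES",
    "EVENT_KINDS",
    "StressEvent",
    "ScenarioSpec",
    "default_roles",
    "simulate_temperature",
    "simulate_humidity",
    "carrier_trajectory",
    "simulate_experiment",
    "write_samples",
    "read_samples",
    "single_plant",
]

COLUMNS = ["timestamp", "plant_id", "resistance_ohm", "temperature_c", "humidity_pct"]

#: Bottle roles, following the experimental arrangement: seeded bottles in a
#: controlled (air-filtered) or uncontrolled environment, unseeded reference
#: bottles, and one sealed agarose-only bottle.
ROLES = frozenset({"seed+filter", "seed+no-filter", "reference-no-seed", "sealed"})
SEEDED_ROLES = frozenset({"seed+filter", "seed+no-filter"})

EVENT_KINDS = frozenset({"allelochemical_release", "uptake_surge", "death"})

_SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class StressEvent:
    """A parameterized perturbation of one plant's carrier trajectory.

    kind
        ``allelochemical_release`` — stressed roots dump ions into the
        medium: the carrier level steps up by ``magnitude`` (fraction of the
        pre-event level) for ``duration_days``, so resistance drops suddenly.
        ``uptake_surge`` — stress-driven nutrient uptake: local resistance
        excursions are amplified ``magnitude``-fold and depletion steepens by
        the same factor for the duration.
        ``death`` — the plant stops responding; the carrier trajectory is
        frozen at its onset value (magnitude is ignored but must be positive).
    symptom_lag_days
        Optional delay until a visual symptom would appear on the plant,
        used by validation reports that compare detection time against
        symptom time.
    """

    plant_id: int
    onset_day: float
    kind: str
    magnitude: float
    duration_days: float
    symptom_lag_days: float | None = None

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise UnknownEventKindError(
                f"unknown stress event kind {self.kind!r}; expected one of {sorted(EVENT_KINDS)}"
            )
        if not self.magnitude > 0:
            raise ValueError("event magnitude must be > 0")
        if not self.duration_days > 0:
            raise ValueError("event duration must be > 0")

    @property
    def symptom_day(self) -> float | None:
        if self.symptom_lag_days is None:
            return None
        return self.onset_day + self.symptom_lag_days


def default_roles(n_plants: int) -> dict[int, str]:
    """Bottle-role mapping. For 8 bottles this is the canonical arrangement:
    1-3 seeded with air filter, 4-5 seeded without, 6-7 unseeded reference,
    8 sealed. Other counts default to all seeded+filter."""
    if n_plants == 8:
        return {1: "seed+filter", 2: "seed+filter", 3: "seed+filter",
                4: "seed+no-filter", 5: "seed+no-filter",
                6: "reference-no-seed", 7: "reference-no-seed", 8: "sealed"}
    return {i: "seed+filter" for i in range(1, n_plants + 1)}


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of a simulated experiment.

    Defaults replay the reference experiment: 8 bottles measured
    round-robin at 10 s steps (80 s per-plant cadence), baseline
    R0 = 22015 ohm at T0 = 14.98 degC with alpha = 0.0141/degC, a diurnal
    temperature swing of +/-3.4 degC peaking at 16:30 (which yields the
    +/-1 kOhm normal resistance band, lowest between 4 and 5 p.m.), and a
    nutrient depletion rate of 0.010/day.
    """

    n_plants: int = 8
    duration_days: float = 20.0
    cadence_s: float | None = None  # per-plant spacing; default n_plants * 10 s
    roles: dict[int, str] | None = None
    r0: float = 22015.0
    t0: float = 14.98
    alpha: float = 0.0141
    depletion_per_day: float = 0.010
    diurnal_amp_c: float = 3.4
    diurnal_phase_hour: float = 16.5
    noise_ohm: float = 60.0
    humidity_mean: float = 55.0
    humidity_amp: float = 10.0
    events: tuple[StressEvent, ...] = field(default_factory=tuple)
    seed: int = 0
    start: str = "2020-01-01T00:00:00"

    def __post_init__(self):
        if not self.duration_days > 0:
            raise ValueError("duration must be > 0")
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if self.cadence_s is not None and not self.cadence_s > 0:
            raise ValueError("cadence must be > 0")
        if self.depletion_per_day < 0:
            raise ValueError("depletion rate must be >= 0")
        if not self.r0 > 0:
            raise ValueError("baseline resistance must be > 0")
        object.__setattr__(self, "events", tuple(self.events))
        for ev in self.events:
            if not (0.0 <= ev.onset_day <= self.duration_days):
                raise ValueError(
                    f"event onset day {ev.onset_day} outside run span [0, {self.duration_days}]"
                )
        if self.roles is not None:
            bad = set(self.roles.values()) - ROLES
            if bad:
                raise ValueError(f"unknown bottle roles: {sorted(bad)}")

    @property
    def cadence(self) -> float:
        return self.cadence_s if self.cadence_s is not None else self.n_plants * 10.0

    @property
    def role_map(self) -> dict[int, str]:
        if self.roles is not None:
            return dict(self.roles)
        return default_roles(self.n_plants)

    def role(self, plant_id: int) -> str:
        try:
            return self.role_map[plant_id]
        except KeyError:
            raise KeyError(f"plant_id {plant_id} has no configured bottle role") from None

    def events_for(self, plant_id: int) -> tuple[StressEvent, ...]:
        return tuple(ev for ev in self.events if ev.plant_id == plant_id)

    def without_events(self) -> "ScenarioSpec":
        """Event-free twin of this scenario (same seed and parameters)."""
        return replace(self, events=())


def _phase_cos(t_days, phase_hour: float):
    """cos term peaking at ``phase_hour`` each day (runs start at midnight)."""
    hour = (np.asarray(t_days, dtype=float) % 1.0) * 24.0
    return np.cos(2.0 * np.pi * (hour - phase_hour) / 24.0)


def simulate_temperature(spec: ScenarioSpec, t_days):
    """Deterministic diurnal temperature (degC) at time ``t_days`` into the run."""
    return spec.t0 + spec.diurnal_amp_c * _phase_cos(t_days, spec.diurnal_phase_hour)


def simulate_humidity(spec: ScenarioSpec, t_days):
    """Relative humidity (%%RH), anti-phase with temperature; noise is added
    by :func:`simulate_experiment`.  Purely schema-filling: humidity does not
    enter the resistance model."""
    return spec.humidity_mean - spec.humidity_amp * _phase_cos(t_days, spec.diurnal_phase_hour)


def carrier_trajectory(spec: ScenarioSpec, plant_id: int, t_days) -> np.ndarray:
    """Relative carrier level ``n(t)/n0`` for one plant at the given times.

    Unseeded (reference/sealed) bottles hold a constant level of 1. Seeded
    bottles deplete linearly; stress events modify the trajectory as
    documented on :class:`StressEvent`. The level is floored at 0.05 (the
    medium never fully loses its ionic content).
    """
    t = np.atleast_1d(np.asarray(t_days, dtype=float))
    role = spec.role(plant_id)
    if role not in SEEDED_ROLES:
        return np.ones_like(t)

    events = spec.events_for(plant_id)
    deaths = [ev for ev in events if ev.kind == "death"]
    death_day = min((ev.onset_day for ev in deaths), default=None)

    level = 1.0 - spec.depletion_per_day * t
    for ev in events:
        if ev.kind == "uptake_surge":
            # steepened depletion: extra carrier loss accumulated over the
            # overlap of [onset, onset+duration] with [0, t]
            overlap = np.clip(t - ev.onset_day, 0.0, ev.duration_days)
            level = level - spec.depletion_per_day * (ev.magnitude - 1.0) * overlap
    for ev in events:
        active = (t >= ev.onset_day) & (t < ev.onset_day + ev.duration_days)
        if ev.kind == "allelochemical_release":
            level = np.where(active, level * (1.0 + ev.magnitude), level)
        elif ev.kind == "uptake_surge":
            # carrier-side diurnal modulation that amplifies the resistance
            # excursion band ~magnitude-fold while the surge lasts
            mod = (ev.magnitude - 1.0) * spec.alpha * spec.diurnal_amp_c
            level = np.where(
                active, level * (1.0 + mod * _phase_cos(t, spec.diurnal_phase_hour)), level
            )

    if death_day is not None:
        # no further response after death: freeze at the onset value
        frozen_spec = replace(
            spec,
            events=tuple(ev for ev in events if ev.kind != "death"),
        )
        frozen = carrier_trajectory(frozen_spec, plant_id, np.array([death_day]))[0]
        level = np.where(t >= death_day, frozen, level)

    return np.clip(level, 0.05, None)


def _plant_times_s(spec: ScenarioSpec, plant_index: int) -> np.ndarray:
    """Sample times (seconds from start) for the plant at sorted position
    ``plant_index``; the multimeter visits plants round-robin, one every
    ``cadence / n_plants`` seconds."""
    step = spec.cadence
    offset = plant_index * step / spec.n_plants
    dur_s = spec.duration_days * _SECONDS_PER_DAY
    n = int(np.ceil((dur_s - offset) / step))
    return offset + step * np.arange(max(n, 0))


def simulate_experiment(spec: ScenarioSpec) -> pd.DataFrame:
    """Simulate the full acquisition schedule for every bottle.

    Returns a long-format frame with columns
    ``timestamp, plant_id, resistance_ohm, temperature_c, humidity_pct``,
    interleaved in acquisition order. Identical specs (including seed)
    produce identical output.
    """
    start = pd.Timestamp(spec.start)
    frames = []
    for idx, plant_id in enumerate(sorted(spec.role_map)):
        t_s = _plant_times_s(spec, idx)
        t_days = t_s / _SECONDS_PER_DAY
        temp = simulate_temperature(spec, t_days)
        level = carrier_trajectory(spec, plant_id, t_days)
        comp = 1.0 + spec.alpha * (temp - spec.t0)
        resistance = spec.r0 / (level * comp)
        rng = np.random.default_rng([spec.seed, plant_id])
        if spec.noise_ohm > 0:
            resistance = resistance + spec.noise_ohm * rng.standard_normal(t_s.size)
        humidity = simulate_humidity(spec, t_days) + 0.5 * rng.standard_normal(t_s.size)
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": start + pd.to_timedelta(t_s, unit="s"),
                    "plant_id": np.full(t_s.size, plant_id, dtype=np.int64),
                    "resistance_ohm": resistance,
                    "temperature_c": temp,
                    "humidity_pct": np.clip(humidity, 0.0, 100.0),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["timestamp", "plant_id"], kind="mergesort").reset_index(drop=True)
    return out


def single_plant(samples: pd.DataFrame, plant_id: int) -> pd.DataFrame:
    """One plant's stream, time-ordered, index reset."""
    out = samples.loc[samples["plant_id"] == plant_id]
    return out.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def write_samples(samples: pd.DataFrame, path) -> None:
    """Write a sample table as UTF-8 CSV with ISO-8601 timestamps."""
    out = samples.loc[:, COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_samples(path) -> pd.DataFrame:
    """Read and validate a sample table written by :func:`write_samples`.

    Raises :class:`SchemaError` naming the first offending row for missing
    columns, unparseable timestamps, non-positive resistance, out-of-range
    humidity, or non-increasing per-plant timestamps.
    """
    raw = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    ts = pd.to_datetime(raw["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        raise SchemaError("unparseable timestamp", row=int(ts.isna().idxmax()))
    raw = raw.assign(timestamp=ts)
    res = pd.to_numeric(raw["resistance_ohm"], errors="coerce")
    if res.isna().any():
        raise SchemaError("non-numeric resistance", row=int(res.isna().idxmax()))
    bad = res <= 0
    if bad.any():
        raise SchemaError("non-positive resistance", row=int(bad.idxmax()))
    hum = pd.to_numeric(raw["humidity_pct"], errors="coerce")
    bad = hum.isna() | (hum < 0) | (hum > 100)
    if bad.any():
        raise SchemaError("humidity outside [0, 100]", row=int(bad.idxmax()))
    for plant_id, grp in raw.groupby("plant_id"):
        dts = grp["timestamp"].diff().dropna()
        if (dts <= pd.Timedelta(0)).any():
            row = int(dts.index[(dts <= pd.Timedelta(0)).to_numpy().argmax()])
            raise SchemaError(
                f"timestamps not strictly increasing for plant {plant_id}", row=row
            )
    raw["plant_id"] = raw["plant_id"].astype(np.int64)
    return raw.loc[:, COLUMNS]
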