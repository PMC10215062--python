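"""Packaged benchmark scenarios and their runners.

These fix the study conditions used throughout the test-suite and the
reproduction script:

* ``first_run_scenario`` — the 20-day, 8-bottle acquisition schedule
  (sequential measurement at 10 s steps).
* ``stress_benchmark_scenario`` — a single-bottle 12-day run whose plant
  suffers an uptake surge (excursions amplified 6x) from day 5 to day 11;
  days 1-3 are the normal reference, days 3-5 the held-out normal segment.
* ``carrier_benchmark_scenario`` — a single-bottle 60-day run sampled every
  480 s (about 10k samples), with an optional allelochemical-release event
  (carrier jump +0.35, the stressed-state shift) on day 45 of the run,
  i.e. in the test half of a day-30 train/test split; visual symptoms are
  marked 2 days after onset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import detectors as det
from .autoencoder import AutoencoderStressDetector, split_train_test
from .drude import ReferenceState, series_carrier_change
from .simulate import ScenarioSpec, StressEvent, simulate_experiment, single_plant

__all__ = [
    "first_run_scenario",
    "stress_benchmark_scenario",
    "carrier_benchmark_scenario",
    "run_detector_comparison",
    "run_autoencoder_benchmark",
]

SURGE_MAGNITUDE = 6.0
RELEASE_MAGNITUDE = 0.35
SYMPTOM_LAG_DAYS = 2.0


def first_run_scenario(seed: int = 0) -> ScenarioSpec:
    """The 20-day 8-bottle schedule with the canonical bottle arrangement."""
    return ScenarioSpec(seed=seed)


def stress_benchmark_scenario(seed: int = 0, stressed: bool = True,
                              surge_magnitude: float = SURGE_MAGNITUDE) -> ScenarioSpec:
    events = ()
    if stressed:
        events = (
            StressEvent(plant_id=1, onset_day=5.0, kind="uptake_surge",
                        magnitude=surge_magnitude, duration_days=6.0,
                        symptom_lag_days=SYMPTOM_LAG_DAYS),
        )
    return ScenarioSpec(
        n_plants=1, duration_days=12.0, cadence_s=80.0,
        roles={1: "seed+filter"}, events=events, seed=seed,
    )


def carrier_benchmark_scenario(seed: int = 0, event: bool = True,
                               release_magnitude: float = RELEASE_MAGNITUDE,
                               onset_day: float = 45.0) -> ScenarioSpec:
    events = ()
    if event:
        events = (
            StressEvent(plant_id=1, onset_day=onset_day, kind="allelochemical_release",
                        magnitude=release_magnitude, duration_days=60.0 - onset_day,
                        symptom_lag_days=SYMPTOM_LAG_DAYS),
        )
    return ScenarioSpec(
        n_plants=1, duration_days=60.0, cadence_s=480.0,
        roles={1: "seed+filter"}, events=events, seed=seed,
    )


def _segment(series: det.ScoreSeries, mask: np.ndarray) -> det.ScoreSeries:
    return det.ScoreSeries(method=series.method, scores=series.scores[mask],
                           threshold=series.threshold, starts=series.starts[mask])


def run_detector_comparison(
    seed: int = 0,
    width: int = det.DEFAULT_WIDTH,
    stride: int = det.DEFAULT_STRIDE,
    reference_days: float = 3.0,
    normal_days: tuple[float, float] = (3.0, 5.0),
    stressed_days: tuple[float, float] = (5.0, 11.0),
    detector_params: dict | None = None,
) -> dict:
    """Score the stressed benchmark with all three detectors and compare them.

    Windows are cut from the resistance stream; the reference segment is the
    windows wholly inside the first ``reference_days`` days. Returns the
    comparison report plus per-method score series and first-flag days.
    """
    spec = stress_benchmark_scenario(seed=seed)
    samples = single_plant(simulate_experiment(spec), 1)
    resistance = samples["resistance_ohm"].to_numpy()
    t_days = (
        (samples["timestamp"] - samples["timestamp"].iloc[0]).dt.total_seconds().to_numpy()
        / 86400.0
    )
    samples_per_day = int(round(86400.0 / spec.cadence))
    n_ref = (int(reference_days * samples_per_day) - width) // stride + 1
    matrix = det.make_windows(resistance, width=width, stride=stride, n_reference=n_ref)
    start_days = t_days[matrix.starts]

    params = detector_params or {}
    results, normal_seg, stressed_seg, first_flag_day = {}, {}, {}, {}
    for method, cls in det.DETECTOR_CLASSES.items():
        scorer = cls(**params.get(method, {}))
        series = scorer.score_series(matrix)
        results[method] = series
        normal_mask = (start_days >= normal_days[0]) & (start_days < normal_days[1])
        stressed_mask = (start_days >= stressed_days[0]) & (start_days < stressed_days[1])
        normal_seg[method] = _segment(series, normal_mask)
        stressed_seg[method] = _segment(series, stressed_mask)
        flagged = series.flags & (start_days >= normal_days[0])
        first_flag_day[method] = float(start_days[flagged][0]) if flagged.any() else None

    event = spec.events[0] if spec.events else None
    return {
        "spec": spec,
        "comparison": det.compare_detectors(normal_seg, stressed_seg),
        "scores": results,
        "start_days": start_days,
        "first_flag_day": first_flag_day,
        "event_onset_day": event.onset_day if event else None,
        "symptom_day": event.symptom_day if event else None,
    }


def run_autoencoder_benchmark(
    seed: int = 0,
    event: bool = True,
    boundary_day: int = 30,
    epochs: int = 30,
    detector_params: dict | None = None,
) -> dict:
    """Train the autoencoder on the first half of the 60-day carrier series
    and detect anomalies in the second half.

    Also scores the same (raw, un-detrended) carrier windows with the
    screening-stage kNN detector for the cross-stage comparison. Returns the
    reconstruction report, flag statistics relative to the event onset, and
    the kNN false-flag rate on the pre-event test windows.
    """
    spec = carrier_benchmark_scenario(seed=seed, event=event)
    samples = single_plant(simulate_experiment(spec), 1)
    ref = ReferenceState(spec.r0, spec.t0, spec.alpha)
    carrier = series_carrier_change(samples, ref=ref)
    train, test = split_train_test(carrier, boundary_day)

    params = dict(random_state=seed, epochs=epochs)
    params.update(detector_params or {})
    ae = AutoencoderStressDetector(**params).fit(train)
    report = ae.detect(test)

    ev = spec.events[0] if spec.events else None
    onset_ts = symptom_ts = None
    detection_delay_days = None
    if ev is not None:
        start = pd.Timestamp(spec.start)
        onset_ts = start + pd.Timedelta(days=ev.onset_day)
        symptom_ts = start + pd.Timedelta(days=ev.symptom_day)
        if report.onset_estimate is not None:
            detection_delay_days = (
                (pd.Timestamp(report.onset_estimate) - onset_ts).total_seconds() / 86400.0
            )

    # screening-stage kNN on the same carrier series, raw windows, reference =
    # the training half -- the configuration that fails on drifting data
    values = carrier["relative_change"].to_numpy()
    n_ref = (len(train) - ae.width) // ae.width + 1
    matrix = det.make_windows(values, width=ae.width, stride=ae.width,
                              center_windows=False, n_reference=n_ref)
    knn = det.KNNAnomalyDetector().score_series(matrix)
    test_mask = matrix.starts >= len(train)
    if ev is not None:
        pre_event = test_mask & (matrix.starts < np.searchsorted(
            samples["timestamp"].to_numpy(), np.datetime64(onset_ts)))
    else:
        pre_event = test_mask
    knn_false_rate = float(np.mean(knn.flags[pre_event])) if pre_event.any() else 0.0

    return {
        "spec": spec,
        "detector": ae,
        "report": report,
        "event_onset": onset_ts,
        "symptom_time": symptom_ts,
        "detection_delay_days": detection_delay_days,
        "test_flag_rate": report.flag_rate,
        "knn_false_rate_pre_event": knn_false_rate,
        "knn_scores": knn,
        "knn_test_mask": test_mask,
    }
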