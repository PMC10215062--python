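"""Simulator: diurnal forcing, carrier trajectories, schedule, and CSV I/O."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from phytostress.errors import SchemaError, UnknownEventKindError
from phytostress.simulate import (
    ScenarioSpec,
    StressEvent,
    carrier_trajectory,
    read_samples,
    simulate_experiment,
    simulate_temperature,
    single_plant,
    write_samples,
)


def spec1(**kw):
    base = dict(n_plants=1, duration_days=10.0, roles={1: "seed+filter"})
    base.update(kw)
    return ScenarioSpec(**base)


class TestTemperature:
    def test_zero_amplitude_is_constant(self):
        spec = spec1(diurnal_amp_c=0.0)
        t = np.linspace(0, 2, 101)
        assert np.allclose(simulate_temperature(spec, t), spec.t0)

    def test_sinusoid_symmetry(self):
        # max at the phase hour; the antipodal hour sits a full swing below
        spec = spec1(diurnal_phase_hour=15.0, diurnal_amp_c=5.0)
        t_peak, t_trough = 15 / 24, 3 / 24
        assert simulate_temperature(spec, t_peak) - simulate_temperature(spec, t_trough) == pytest.approx(10.0)

    def test_default_resistance_minimum_in_late_afternoon(self):
        """Temperature peaks in the afternoon, so the zero-noise resistance
        minimum of a day falls in the 4-5 p.m. window."""
        spec = spec1(noise_ohm=0.0, duration_days=2.0)
        series = single_plant(simulate_experiment(spec), 1)
        day1 = series[series["timestamp"] < "2020-01-02"]
        t_min = day1.loc[day1["resistance_ohm"].idxmin(), "timestamp"]
        assert 16 <= t_min.hour < 17


class TestCarrierTrajectory:
    def test_no_depletion_no_events_is_flat(self):
        spec = spec1(depletion_per_day=0.0)
        t = np.linspace(0, 10, 50)
        assert np.allclose(carrier_trajectory(spec, 1, t), 1.0)

    def test_reference_bottle_is_flat_despite_depletion(self):
        spec = ScenarioSpec(n_plants=2, duration_days=5.0,
                            roles={1: "seed+filter", 2: "reference-no-seed"})
        assert np.allclose(carrier_trajectory(spec, 2, np.linspace(0, 5, 20)), 1.0)

    def test_release_steps_carrier_up_by_fraction_of_pre_event_level(self):
        ev = StressEvent(plant_id=1, onset_day=3.0, kind="allelochemical_release",
                         magnitude=0.3, duration_days=5.0)
        spec = spec1(events=(ev,))
        before = carrier_trajectory(spec, 1, np.array([3.0 - 1e-9]))[0]
        after = carrier_trajectory(spec, 1, np.array([3.0]))[0]
        assert after == pytest.approx(1.3 * before, rel=1e-6)

    def test_death_freezes_trajectory(self):
        ev = StressEvent(plant_id=1, onset_day=2.0, kind="death",
                         magnitude=1.0, duration_days=8.0)
        spec = spec1(events=(ev,))
        t = np.array([2.0, 4.0, 9.0])
        levels = carrier_trajectory(spec, 1, t)
        assert levels[0] == levels[1] == levels[2]
        assert levels[0] == pytest.approx(1 - 2 * spec.depletion_per_day)

    def test_surge_amplifies_resistance_excursions_about_sixfold(self):
        """A magnitude-6 uptake surge widens the daily resistance band to
        roughly six times the normal +/-1 kOhm temperature band."""
        ev = StressEvent(plant_id=1, onset_day=4.0, kind="uptake_surge",
                         magnitude=6.0, duration_days=4.0)
        spec = spec1(events=(ev,), noise_ohm=0.0, depletion_per_day=0.0)
        series = single_plant(simulate_experiment(spec), 1)
        days = (series["timestamp"] - series["timestamp"].iloc[0]).dt.total_seconds() / 86400
        normal = series[(days >= 1) & (days < 2)]["resistance_ohm"]
        surged = series[(days >= 5) & (days < 6)]["resistance_ohm"]
        ratio = (surged.max() - surged.min()) / (normal.max() - normal.min())
        assert 4.5 < ratio < 7.5

    def test_unknown_event_kind_rejected(self):
        with pytest.raises(UnknownEventKindError):
            StressEvent(plant_id=1, onset_day=1.0, kind="sunspots",
                        magnitude=1.0, duration_days=1.0)

    def test_event_outside_run_span_rejected(self):
        ev = StressEvent(plant_id=1, onset_day=30.0, kind="death",
                         magnitude=1.0, duration_days=1.0)
        with pytest.raises(ValueError, match="onset"):
            spec1(events=(ev,))

    def test_monotone_coupling_depletion_vs_resistance(self):
        """At fixed temperature, a faster depletion rate never yields lower
        resistance at any later time (noise off)."""
        base = dict(n_plants=1, duration_days=10.0, roles={1: "seed+filter"},
                    noise_ohm=0.0, diurnal_amp_c=0.0)
        slow = single_plant(simulate_experiment(ScenarioSpec(depletion_per_day=0.005, **base)), 1)
        fast = single_plant(simulate_experiment(ScenarioSpec(depletion_per_day=0.02, **base)), 1)
        assert (fast["resistance_ohm"] >= slow["resistance_ohm"] - 1e-9).all()


class TestSchedule:
    def test_twenty_day_run_yields_21600_samples_per_bottle(self):
        samples = simulate_experiment(ScenarioSpec())
        counts = samples.groupby("plant_id").size()
        assert (counts == 21600).all()
        assert (counts > 20000).all()

    def test_per_plant_spacing_is_n_plants_times_ten_seconds(self):
        samples = simulate_experiment(ScenarioSpec(duration_days=0.5))
        for plant_id in range(1, 9):
            spacing = single_plant(samples, plant_id)["timestamp"].diff().dropna()
            assert (spacing == pd.Timedelta(seconds=80)).all()

    def test_round_robin_interleaving(self):
        samples = simulate_experiment(ScenarioSpec(duration_days=0.01))
        head = samples.head(8)
        assert list(head["plant_id"]) == list(range(1, 9))
        assert (head["timestamp"].diff().dropna() == pd.Timedelta(seconds=10)).all()

    def test_seed_determinism(self):
        spec = spec1(seed=42)
        a = simulate_experiment(spec)
        b = simulate_experiment(dataclasses.replace(spec))
        pd.testing.assert_frame_equal(a, b)

    def test_constant_carrier_reference_temperature_no_noise_gives_r0(self):
        spec = spec1(noise_ohm=0.0, diurnal_amp_c=0.0, depletion_per_day=0.0)
        series = single_plant(simulate_experiment(spec), 1)
        assert np.allclose(series["resistance_ohm"], spec.r0)

    def test_ten_degree_rise_drops_resistance_by_drude_factor(self):
        # alpha * 10 degC = 0.141
        spec = spec1(noise_ohm=0.0, depletion_per_day=0.0, diurnal_amp_c=10.0,
                     diurnal_phase_hour=0.0)
        series = single_plant(simulate_experiment(spec), 1)
        at_peak = series[series["timestamp"] == "2020-01-01T00:00:00"]["resistance_ohm"].iloc[0]
        assert at_peak == pytest.approx(spec.r0 / 1.141, rel=1e-12)


class TestSampleIO:
    def test_round_trip(self, tmp_path, one_plant_series):
        path = tmp_path / "samples.csv"
        write_samples(one_plant_series.head(10), path)
        back = read_samples(path)
        assert len(back) == 10
        pd.testing.assert_series_equal(back["timestamp"], one_plant_series["timestamp"].head(10))
        np.testing.assert_allclose(back["resistance_ohm"],
                                   one_plant_series["resistance_ohm"].head(10))

    def test_empty_round_trip(self, tmp_path, one_plant_series):
        path = tmp_path / "empty.csv"
        write_samples(one_plant_series.head(0), path)
        assert len(read_samples(path)) == 0

    def test_negative_resistance_names_row(self, tmp_path, one_plant_series):
        path = tmp_path / "bad.csv"
        df = one_plant_series.head(5).copy()
        df.loc[3, "resistance_ohm"] = -5.0
        write_samples(df, path)
        with pytest.raises(SchemaError, match="row 3"):
            read_samples(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("timestamp,plant_id\n2020-01-01T00:00:00,1\n")
        with pytest.raises(SchemaError, match="missing"):
            read_samples(path)

    def test_unparseable_timestamp_names_row(self, tmp_path, one_plant_series):
        path = tmp_path / "ts.csv"
        write_samples(one_plant_series.head(3), path)
        lines = path.read_text().splitlines()
        lines[2] = lines[2].replace("2020", "not-a-date")
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SchemaError, match="row 1"):
            read_samples(path)
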