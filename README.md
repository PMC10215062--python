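# phytostress

Unsupervised stress phenotyping for plants grown in an ionic medium, from
continuous electrical-resistance measurements of the medium itself.

When a plant is stressed — by pathogens, by its neighbours' warning
signals, or by the climate around it — its nutrient exchange with the
growth medium changes days before any visual symptom appears: stressed
roots surge their uptake of macro-nutrients (K⁺ in particular) and dump
allelochemicals back into the medium. Both move the medium's ionic
charge-carrier concentration *n*, and hence its electrical resistance *R*.
`phytostress` implements the full analysis chain for such experiments:
bottles of agarose medium measured sequentially by one multimeter every
10 s, with temperature and humidity logged alongside.

## The model

The medium behaves as a concentrated ionic suspension whose resistance
follows a temperature-compensated Drude relation,

```
R ∝ 1 / ( n · [1 + α (T − T₀)] ),          α = 0.0141 /°C for agarose
```

Anchoring at a reference state (R₀, T₀) gives the stress proxy used
throughout, the **relative carrier change**

```
(n − n₀)/n₀ = R₀ / ( R · [1 + α (T − T₀)] ) − 1 .
```

Normal diurnal temperature swings move R by about ±1 kΩ around
R₀ = 22015 Ω but compensate away to a carrier change within 5%
(max ≈ 4.76%); a stressed decline of six normal excursions corresponds to
a carrier shift of ≈ 37.5%, past the reported 35% stressed-state level.

Four screening methods sit on top of the transform:

* **R² trend screen** — healthy bottles deplete nutrients at a steady
  rate, so resistance rises near-linearly; an ordinary least-squares fit
  with R² below 0.65 flags likely stress.
* **Daily candles** — per-day open/high/low/close resistance, with a
  simple moving average for the trend and a κ×median rule for abnormal
  daily ranges.
* **Window anomaly detectors** — k-nearest-neighbour distance, local
  outlier factor and one-class SVM score sliding resistance windows
  against a reference (normal) segment, batch or streaming.
* **Reconstructional autoencoder** — trained on an anomaly-scarce period
  of the carrier-change series (45-sample windows); the anomaly threshold
  is the exact maximum training reconstruction MAE, so any test window it
  cannot reproduce that well is an unlearnt — stressed — pattern.

Because raw data of this kind is rarely deposited, the package includes a
first-class simulator that replays the acquisition schedule (8 bottles,
round-robin, 10 s steps), the diurnal forcing, nutrient depletion, and
parameterized stress events (allelochemical release, uptake surge, death).

## Worked example

Simulate one bottle for 12 days with a six-fold uptake surge starting on
day 5, then screen and score it:

```python
import numpy as np
from phytostress import (ScenarioSpec, StressEvent, simulate_experiment,
                         single_plant, ReferenceState, series_carrier_change,
                         fit_linear_trend, make_windows, KNNAnomalyDetector)

event = StressEvent(plant_id=1, onset_day=5.0, kind="uptake_surge",
                    magnitude=6.0, duration_days=6.0)
spec = ScenarioSpec(n_plants=1, duration_days=12.0, cadence_s=80.0,
                    roles={1: "seed+filter"}, events=(event,), seed=0)
samples = single_plant(simulate_experiment(spec), 1)

report = fit_linear_trend(samples)
print(f"R^2 = {report.r_squared:.3f}  stressed = {report.stressed}")

carrier = series_carrier_change(samples, ref=ReferenceState(spec.r0, spec.t0))
print(f"max |dn/n0| = {carrier['relative_change'].abs().max():.3f}")

matrix = make_windows(samples["resistance_ohm"].to_numpy(), width=90, stride=10,
                      n_reference=(3 * 1080 - 90) // 10 + 1)   # days 1-3 = normal
scores = KNNAnomalyDetector(k=5).score_series(matrix)
t_days = matrix.starts / 1080
print(f"median kNN score days 1-3: {np.median(scores.scores[t_days < 3]):.2f}")
print(f"median kNN score days 5-11: {np.median(scores.scores[(t_days >= 5) & (t_days < 11)]):.2f}")
strong = scores.scores > 2 * scores.threshold
print(f"first strong flag at day {t_days[strong][0]:.2f}")
```

prints

```
R^2 = 0.535  stressed = True
max |dn/n0| = 0.516
median kNN score days 1-3: 7.25
median kNN score days 5-11: 48.68
first strong flag at day 4.93
```

The surge breaks the linear rise (R² = 0.54 < 0.65), pushes the carrier
change far past the 5% normal band, and the kNN decision score separates
stressed from normal days by ~7×, crossing twice its calibration threshold
within two hours of the surge onset — two days before visual symptoms
would be expected.

The same stages are available from a shell:

```
phytostress simulate --out samples.csv --seed 0
phytostress transform --in samples.csv --plant 1 --out carrier.csv
phytostress screen   --in samples.csv --plant 1 --out report.json
phytostress score    --in samples.csv --plant 1 --method knn --out scores.csv
phytostress forecast --in carrier.csv --boundary-day 30 --out forecast.json
phytostress run      --config run.yaml --outdir runs/demo
```

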