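# Methods

This note documents the models the package implements, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not establish about real data.

## Resistance model and the Drude transform

The growth medium is treated as a concentrated ionic suspension: its
resistance is inversely proportional to the charge-carrier (nutrient ion)
concentration, with a linear temperature correction characterized by the
agarose compensation factor α = 0.0141/°C,

    R(t) = R₀ / [ (n(t)/n₀) · (1 + α (T(t) − T₀)) ] .

Inverting at a reference state (R₀, T₀) gives the relative carrier change
(n − n₀)/n₀ = R₀/(R·[1 + α(T − T₀)]) − 1, the package's stress proxy. The
transform is exact by construction: resistance variation caused purely by
temperature maps back to zero carrier change to machine precision, which
is asserted as a property test. The reference state defaults to the
"first sample" policy (`ref="auto"`); any bottle can anchor it, and the
canonical values R₀ = 22015 Ω, T₀ = 14.98 °C are used throughout the
benchmarks. α is configurable but constant within a series; humidity is
recorded for completeness and never enters the transform.

## What the simulator emulates

One multimeter visits `n_plants` bottles round-robin at 10 s steps, so
each bottle is sampled every `n_plants × 10` s; a 20-day, 8-bottle run
gives exactly 21 600 samples per bottle. Temperature is a deterministic
diurnal sinusoid around T₀ with amplitude 3.4 °C peaking at 16:30 —
chosen so the induced resistance band is the characteristic ±1 kΩ around
R₀ and the daily resistance minimum falls between 4 and 5 p.m. Seeded
bottles deplete carriers linearly at 0.010/day, a rate chosen so a 20-day
normal run fits a line with R² ≈ 0.77 (the middle of the healthy-bottle
range) while a few-day normal stretch keeps |Δn/n₀| under 5%. Unseeded
reference bottles hold a constant carrier level. Measurement noise is
additive Gaussian on resistance (60 Ω default); the diurnal forcing is
collapsed into temperature alone, which reproduces the morning-high /
late-afternoon-low resistance pattern but shifts the morning resistance
peak earlier (≈4:30 a.m. plus trend) than a plant with endogenous rhythm
would show.

Stress events perturb the carrier trajectory:

* **allelochemical_release** — the level steps up by `magnitude` × the
  pre-event level for the event duration (resistance drops suddenly);
* **uptake_surge** — depletion steepens `magnitude`-fold and a
  carrier-side diurnal modulation amplifies the local resistance
  excursions ≈ `magnitude`-fold (the six-fold stressed band);
* **death** — the trajectory freezes at its onset value; a dead bottle
  keeps its diurnal temperature response but shows no further nutrient
  response, so none of the screens call it.

Events may carry a `symptom_lag_days` marker (default 2 days in the
benchmarks) representing when visual symptoms would appear; validation
tests require every method's first flag to precede it.

The simulator does **not** model electrode polarization, microbial growth
kinetics, evaporation (which makes real reference bottles drift), sensor
dropout or acquisition gaps — the full schedule is always emitted.
Passing tests on this generator therefore demonstrate correctness of the
analysis chain under the stated statistical structure, not robustness to
every artifact of a physical rig.

## Trend screen and candles

The screen is an ordinary least-squares fit of resistance on elapsed days
with R² = 1 − SS_res/SS_tot and a stress flag at R² < 0.65 (configurable;
the threshold was derived from a single experiment and should be
recalibrated per installation). A perfectly constant series is defined as
R² = 1 with slope 0 — a horizontal line is a perfect fit, and a dead but
stable bottle must not screen as stressed. Daily candles use local
midnight boundaries with no partial-day exclusion; the abnormal-range rule
flags days with (high − low) > κ × median range, κ = 3 by default, since
no quantitative rule accompanies the starred-candle convention.

## Window detectors

The detectors consume sliding windows of the resistance channel, width 90
samples (~2 h at the 80 s cadence — long enough to span several diurnal
sub-patterns, short enough to react within hours), stride 10. Each window
is mean-centered before the per-position z-standardization computed on the
reference segment (first 3 days by default). Centering is deliberate: the
depletion trend moves every later window's level away from the reference,
and without it all three detectors flag normal drift wholesale; with it,
shape anomalies (sudden declines, amplified excursions) remain fully
visible. The kNN score is the mean Euclidean distance to the k = 5 nearest
reference windows, self-excluded when scoring the reference itself; LOF
uses n_neighbors = 20 with degenerate ties defined as score 1; the
one-class SVM (ν = 0.05, RBF, scale-type γ) reports the negated decision
function shifted by the reference median and clipped at zero. ν = 1 is
evaluated at the nearest representable interior value, since the exact
boundary case has no finite solution. Each detector's threshold is the
99th percentile of its reference scores — score units are featurized
distances, so absolute decision-score scales from other rigs do not carry
over; only orderings and separations do.

Streaming scoring keeps a rolling width-sample buffer and reuses the
fitted featurization and detector, so its scores are exactly the batch
scores of the same stride-1 windows.

On the packaged surge benchmark the comparison reproduces the expected
qualitative ordering: kNN out-resolves LOF (median-ratio resolving power)
and OCSVM raises several-fold more false scores on normal segments. One
caveat: because the OCSVM score shift pins its inlier median near zero,
its median-ratio "resolving power" is numerically enormous rather than
low; its weakness shows in the false-score rate, not in that ratio.

## Autoencoder forecasting

The forecasting-stage detector runs on the carrier-change series. A linear
trend fitted on the training half is subtracted first (slow depletion is
modelled separately; without this the whole test half drifts outside the
training regime), the residual is min-max normalized with training
statistics only, and 45-sample single-channel windows (stride 1 for
training, non-overlapping for reporting) feed a dense reconstructional
autoencoder: 45 → 64 → 32 → 64 → 45, tanh hidden units, linear output,
MAE loss, Adam with per-epoch learning-rate decay (3·10⁻³ × 0.9^epoch —
MAE gradients are sign-scaled, so the fit dithers at the learning-rate
scale unless it decays), batch 64, ≤30 epochs with early stop on a 1e-5
plateau. All randomness flows from a single seed and training is plain
numpy, so identical seeds give bit-identical models. Training requires at
least 10× width windows.

The anomaly threshold is the exact maximum training-window MAE, so the
training period can never raise a flag (asserted on every fit). An
optional inflation factor (threshold × 1.10) is exposed but off by
default. On the 60-day benchmark the detector flags a +0.35 carrier
release in the test half within one day of onset (typically the first
window containing the jump) while event-free runs flag ~0% of test
windows; a kNN detector fed the same raw, un-detrended carrier windows
flags nearly the entire drifting test half and cannot localize the event
— the behaviour that motivated moving to reconstruction error in the
first place. Reported MAE values are in normalized units and depend on
the normalization span; they are not comparable across data sets.

## Pipeline verdicts

A detector `StressCall` requires at least 3 consecutive windows above 2×
the detector threshold. Both parts are needed: overlapping windows make
scores autocorrelated, so marginal threshold crossings (measured at
1.02–1.07× threshold in event-free runs) arrive in runs, while genuine
events score ≥6× threshold. The R²-screen call requires the stressed flag
*and* at least one abnormal-range day, because over short runs diurnal
variance alone can push a healthy bottle's R² below threshold, and
flat-but-noisy reference bottles never fit a rising line. Individual
window flags are still reported unfiltered in the score tables.
Stress-onset estimates are the start of the earliest qualifying
window/day; severity is the score-to-threshold (or MAE-to-threshold)
ratio.

## Problem sizes

The packaged benchmarks are sized for a desk-scale single-CPU run: the
surge benchmark uses one bottle at 80 s cadence for 12 days
(12 960 samples, ~1 290 windows), the autoencoder benchmark one bottle at
480 s cadence for 60 days (10 800 samples, ~5 356 training windows), each
across 20 seeds. The full 8-bottle 20-day schedule (172 800 records) is
exercised directly for the schedule-fidelity checks.

## Known limitations

* The R² threshold, detector score scales and MAE magnitudes from any
  particular physical experiment are not reproducible without that
  experiment's raw data; the package carries over the decision rules and
  orderings, not the absolute numbers.
* The depletion trend is linear in the simulator; real media deplete
  saturably and evaporate, so the trend-removal steps (window centering,
  training-half detrend) should be revisited for long real deployments.
* The pipeline reports calls; it implements no alarm debouncing policy
  beyond the persistence rule above.
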