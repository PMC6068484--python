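# Methods

## Problem and model

The estimand is the continuous position within a walking gait cycle — the
*gait percent* `y ∈ [0, 1)`, where 0 is initial contact (heel strike) and the
value grows linearly to the next heel strike of the same foot. The estimator
sees only the six channels of one shank-mounted IMU (gyroscope deg/s,
accelerometer g) sampled every 10 ms; two force-sensitive resistors under
heel and toe serve exclusively as the ground-truth contact reference during
dataset construction and are never model input.

**Segmentation.** Heel strikes are rising crossings of a force threshold on
the heel FSR (default: 50 % of the channel maximum) with a 500 ms refractory
period; cycles are the half-open intervals between consecutive strikes, with
0-based in-cycle indexing. Sample `i` of an `n`-sample cycle is labelled
`y = i/n`, so labels are strictly increasing within a cycle, start at 0 and
never reach 1. A `quantize` flag snaps labels down to the 1 % grid for a hard
1 %-bin discretisation; the continuous ramp is the default because it is
strictly more informative. Cycles shorter than 0.5 s or longer than 2.5 s are
discarded as detection outliers. The native 10 ms sampling is kept — cycles
are *not* resampled onto a fixed 100-point grid, so rows per cycle vary with
cadence.

**Delay embedding.** For anchor sample `t` the full delayed row holds
`X[t−d..t]` per channel (depth `d = 16` samples, i.e. 160 ms) and the target
row holds the next `f` labels `y[t+1..t+f]` (`f = 1` by default — a strict
one-step forecast, 10 ms ahead, which is what removes actuation delay). The
exponential window keeps only the lags `{round(b^k) : k = 0..δ}` plus lag 0;
with base `b = 1.6` and `δ = 5` that is `{0, 1, 2, 3, 4, 7, 10}` — seven lags
per channel, 42 features in all. Non-integer powers are rounded to the sample
grid and deduplicated. `d = 16` is chosen so the largest exponential lag (10)
fits with margin; the window must satisfy `round(b^δ) ≤ d`. Windows may span
a cycle boundary — the model has to learn the sawtooth reset — with an
option to drop boundary-spanning rows for ablations.

**Network.** One branch per sensor: the gyroscope branch sees the 21 windowed
gyro features, the accelerometer branch its own 21. Each branch is
`Linear(21→6) → ReLU → Linear(6→6) → ReLU`; the branch outputs are
concatenated (12 units) and a single linear head maps them to the `f`
outputs. The output activation is the identity (this is regression);
forecasts are clamped to `[0, 1)` only at prediction/evaluation time.
Training minimises the half-MSE cost `(1/2N) Σ ‖h(x_i) − y_i‖²` by exact
backpropagation with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), learning rate
1e-3, 200 epochs, shuffled minibatches of 256 — all configurable, plain
gradient descent available. Weights are initialised uniform in
`±1/√fan_in`, seeded; inputs are standardised per sensor channel (one
mean/std shared by all lags of a channel) using training-split statistics
stored with the model. All parameters live in one flat vector with per-layer
views, which keeps the minibatch loop cheap and makes finite-difference
gradient checking direct.

**Metrics.** Reported MSE is the plain mean of squared residuals — *without*
the training cost's ½ factor — so reported magnitudes are comparable across
tools; MAE and R² = 1 − SS_res/SS_tot follow their standard definitions, and
×100 converts MSE/MAE onto the percent-of-cycle scale. R² is undefined
(raised as an error) when the ground truth is constant. Evaluation clamps
predictions to `[0, 1)` by default (switchable). Splits are 80/20 by whole
gait cycles, seeded; the repeated-run protocol trains one model per seed and
reports per-run metrics plus mean ± std (the numeric content of a violin
plot). A diverging run is recorded, not fatal.

## Synthetic generator

Real walking IMU signals are periodic, phase-informative and subject-varying;
those are the only properties the estimator exploits, so the generator uses
sums of 2–4 sinusoidal harmonics per channel rather than biomechanical
simulation — exact morphology is irrelevant to the algorithm under test. The
sagittal gyro channel carries a dominant `−cos` bump peaking near 70 % of the
cycle (the swing-phase shank rotation). Contact structure follows the
classical 60/40 stance–swing division: the heel FSR is active on the first
25 % of the cycle (heel-contact onset *defines* percent 0), the toe FSR on
10–60 % (toe off at 60 %), so some FSR is loaded for exactly the first 60 %.
FSR pulses are square and noiseless — they are the reference instrument — so
threshold detection recovers the true onsets exactly, an invariant the tests
rely on. A one-sample stub of the next cycle's heel contact is appended so
the final cycle is bounded by a detectable strike.

Per-cycle durations are drawn from `N(cadence_mean, cadence_std)` clipped to
0.55–2.45 s; IMU noise is seeded Gaussian with standard deviation
`noise_std ×` the channel's peak amplitude. Defaults — 2 % noise, 5 % cadence
jitter, 250 cycles per subject — define the benchmark difficulty and are not
tuned per experiment. The multi-subject benchmark uses 8 subjects with
cadences spread over 0.9–1.2 s, per-channel gains drawn in [0.7, 1.3], the
last two subjects on a 15° incline (modelled as a mild gain/offset
perturbation — no signal-level incline model is attempted), speeds cycling
through 2.2–3.8 m/s as metadata.

What passing tests on this generator do **not** show: robustness to real IMU
artefacts (drift, soft-tissue wobble, sensor re-mounting), to pathological or
amputee gait asymmetry, to treadmill-vs-overground differences, or to FSR
degradation. They do show that the pipeline — segmentation, labelling,
embedding, the branched network and the metric/protocol layer — is correct
and that the architecture learns the percent map to well inside the intended
error regime when its assumptions hold.

## Benchmark experiments and problem sizes

The repeated-run experiments train 10 seeds per benchmark: a single subject
with 250 cycles (~25 k samples) and the joined 8-subject set (~2000 cycles,
~210 k samples), 200 epochs each. On one CPU a single-subject run takes ~4 s
and a joined run ~40 s; `scripts/acceptance.py` completes in about 8 minutes.
Seed-averaged results land at validation MSE ≈ 2–7 × 10⁻⁴ (single subject)
and ≈ 7 × 10⁻⁴ with R² ≈ 0.99 (joined) — the joined set is consistently
harder than a single subject at matched data volume because the network must
absorb inter-subject signal differences.

## Numerical choices and edge cases

- Rising-edge convention: a series starting at/above threshold crosses at
  index 0; detection on an empty series returns an empty result, not an error.
- Half-open cycle intervals guarantee `y < 1` and non-overlap; a cycle of
  fewer than 2 samples is a degenerate-cycle error.
- The eight classical phase intervals (IC 0–8 %, … terminal swing 85–100 %)
  are treated half-open `[lo, hi)` so `percent_to_phase` partitions `[0, 1)`.
- Offsets are deduplicated after rounding, so small `b`/large `δ` never
  produce repeated lags; gaps between consecutive lags are non-decreasing.
- Standard-deviation guards: a constant feature channel gets σ = 1 instead of
  a division by ~0.
- Determinism: one integer seed fixes generation, the cycle-level split,
  weight initialisation and batch shuffling; identical seeds give bitwise
  identical learning curves and reports.

## Known limitations

Offline only — no streaming event detection or embedded-target deployment.
No recurrent baselines. The forecast horizon trades resolution for no-delay
control but was only exercised at small `f`. The generator's speed parameter
is metadata, not a signal model.
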