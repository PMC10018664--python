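# Methods

## Scope and data model

The package predicts a single scalar breathing-amplitude channel (mm,
nominally 26 Hz) a short horizon ahead, emulating the predictor stage of a
robotic tumor-tracking system. The correlation model that maps external
markers to internal tumor position, X-ray image handling, and online weight
updates during treatment are out of scope: predictors are fitted once on
the early part of a trace and then frozen.

## Breathing simulator

Clinical traces are not redistributable, so the synthetic cohort stands in
for them. A trace is

    y(t) = baseline + drift·t + A_k · cos^{2n}(π (t − t_k) / T_k) + ε(t)

where cycle k starts at `t_k`, has period `T_k` and depth `A_k`, and
`ε ~ N(0, σ²)` is sensor noise. The `cos^{2n}` (Lujan-type) profile is the
standard analytic respiratory surrogate; n = 2 gives the characteristic
end-exhale dwell. Per-cycle period and depth are drawn as
`T_k = T·(1 + η·ξ_k)` with fractional jitter η (clipped to keep `T_k > 0`),
so cycles stay individually smooth and the phase is continuous across
boundaries (every boundary is an inhale peak). The cycle-jitter and noise
random streams are independent children of the seed, so the same seed with
`noise_sd_mm = 0` reproduces the identical noiseless trace — which is how
the tests verify the noise level by residual.

Five presets encode the qualitative regimes of free breathing:

| regime        | period (s) | depth (mm) | jitter (period/depth) | drift (mm/min) | noise SD (mm) |
|---------------|-----------:|-----------:|----------------------:|---------------:|--------------:|
| steady        | 4.0        | 10         | 0 / 0                 | 0              | 0             |
| slow_deep     | 6.0        | 15         | 0.08 / 0.10           | 0.3            | 0.15          |
| slow_shallow  | 6.0        | 5          | 0.08 / 0.10           | 0.2            | 0.15          |
| rapid_deep    | 2.5        | 15         | 0.08 / 0.10           | 0.3            | 0.15          |
| rapid_shallow | 2.5        | 5          | 0.08 / 0.10           | 0.2            | 0.15          |

Periods bracket adult respiratory rates (~6 vs ~24 breaths/min), depths
bracket typical thoraco-abdominal excursions, and "steady" is jitter-free
by definition. Cohort durations default to 23–60 min, the range of
single-fraction recordings; the test suite and acceptance script use
1–5 min traces so runs stay desk-sized.

What the simulator does **not** model: cardiac or mixed-frequency
components, hysteresis and 3-D trajectories, coughs/apnoea, or
patient-specific spectra. Passing tests therefore demonstrate that the
pipeline is correct and that the models learn quasi-periodic dynamics with
realistic cycle variability — not that clinical error levels are
reproduced. Trained on smooth synthetic cycles, absolute RMSE values here
are optimistic relative to patient data.

## Preprocessing and windowing

- **Split:** chronological 35% / 5% / 60% (train/validation/test). Segment
  lengths are `floor(frac·L)` for train and validation with the remainder
  to test, so the partition is exact and deterministic; empty segments on
  tiny inputs warn rather than fail.
- **Normalization:** affine min-max to [0, 1], fitted on the training
  segment only and reused downstream (no leakage). Out-of-range test
  values are extended affinely, never clipped — clipping would bias the
  millimetre metrics after the inverse map.
- **Windows:** pair *i* is `(samples[i : i+W], samples[i+W+h−1 : i+W+h−1+O])`,
  giving `L − W − h − O + 2` pairs. The horizon h is expressed in samples;
  `latency_to_samples` converts hardware latency (115 ms at 26 Hz → 3
  samples, minimum 1). Windows never cross split boundaries. The tuning
  table's latency values {1, 5, 10, 15} are read as sample horizons — the
  only reading consistent with the windowing framework; both the selected
  value 1 and the 115 ms bridge (3) are supported rather than asserting
  either as canonical.

## Models

Seven architectures: simple RNN, LSTM, GRU, their bidirectional wrappers
(forward and time-reversed passes concatenated), and CNN-LSTM. Cells follow
the common gated formulations with logistic gates and a configurable
hidden activation in the candidate/state slot; the LSTM forget bias starts
at 1. Design points the architecture names leave open were fixed as
follows: no dropout; the CNN stage is one 1-D convolution (kernel 3,
filters = units) plus max-pool 2 ahead of the LSTM stack, and `n_layers`
counts the recurrent layers after it; "number of layers" excludes the
output projection. Two multistep heads are provided: a **vector** head
(one dense projection to all O outputs) and an **encoder–decoder** head
(encoder summary repeated O times into a decoder cell of the same family,
one dense output per step). Initialization is Glorot-uniform from an
explicit seed, so builds and training runs are bit-reproducible.

The engine is a compact NumPy implementation with hand-derived
backpropagation through time; every architecture/head combination is
verified against central finite differences in the test suite (relative
error ≲ 1e-6). Training uses per-epoch shuffled mini-batches, runs exactly
the configured number of epochs (no early stopping), and records one
train/validation loss per epoch. A non-finite loss marks the run diverged
and stops it; sweeps score such trials +∞ instead of aborting.

Recommended per-architecture configurations (depth, width, optimizer,
learning rate, activations, epochs, batch, loss; all with W = 50, O = 1,
h = 1 and the encoder–decoder head) are shipped as presets; the GRU preset
is 3 layers × 10 units, Adam at 0.005, ELU hidden / linear output, MSE,
batch 200, 1000 epochs.

## Hyperparameter search

The thirteen tunable-parameter domains (depth, width, optimizer, learning
rate, hidden and output activation, epochs, latency, batch size, loss,
input/output window, multistep head) would form a full factorial of
hundreds of millions of combinations. The grouped search instead resolves
ordered groups of 1–3 correlated parameters: A `loss × optimizer` (grid),
B `optimizer × learning rate` (random), C `layers × units` (grid), then
`epochs × learning rate`, `batch × optimizer`, `latency × input window`,
`hidden activation × optimizer`, `multistep × epochs`, and singleton sweeps
of output activation and output window. Winners are carried forward and
**frozen**: a parameter resolved by an earlier group is dropped from later
groups rather than re-searched. Each configuration is evaluated once per
seed (default 10 repeats) and scored by seed-averaged validation RMSE in
mm — the only leak-free objective given that test data must stay untouched.
Random groups sample distinct combinations without replacement from a
seeded generator; ties break by enumeration order of the domains. The
learning-rate candidate list is printed with a repeated 0.005 in the source
tuning table; the package deduplicates it to six unique values and keeps a
constant recording the raw list.

For separable objectives the grouped search provably returns the global
optimum whenever each parameter's optimum is reachable in its group; the
tests confirm this exhaustively on rigged analytic objectives.

## Metrics

RMSE, MAE and NRMSE as defined in the README; NRMSE divides by the
ground-truth range of the evaluated segment, making it scale-free
(affine-invariant), which the tests verify as an algebraic property. All
metrics are computed in millimetres after inverting the normalization. The
F-test is read as a two-sample variance-ratio test between the real and
predicted series (sample variances, n−1 degrees of freedom each, two-sided
p): this is the conventional F-test applicable to two paired series, and a
good forecast yields F ≈ 1 — no significant variance difference. For a
constant (zero-variance) series the ratio is undefined and the report
carries NaN. Box statistics use inclusive linear-interpolation quartiles
(the convention is stated because quartiles are convention-dependent),
whiskers at the most extreme non-outlier points, and flag outliers beyond
2.7 standard deviations of the mean. Cohort tables report mean ± SD of
each metric over per-signal reports.

## Problem sizes and numerical choices

- Heavy checks are sized for a single CPU: the tuned-GRU accuracy check
  uses 5-minute steady traces, 100 epochs, 3 seeds (normalized test RMSE
  ≈ 0.003 against a 0.02 bound); the latency sweep uses five jittered
  80–100 s signals, 20 epochs, horizons 1 vs 15 (degradation ratio ≈ 3);
  the end-to-end pipeline check trains all seven architectures for 30
  epochs on two 60–80 s signals.
- Huber delta is 1.0 (signals are normalized to unit range before
  training). Optimizer smoothing constants are the conventional defaults;
  Adagrad/FTRL accumulators start at 0.1.
- All randomness flows from explicit seeds through independent child
  streams (cycle jitter vs noise; weight init vs batch shuffling), so every
  result in the tests and the acceptance script is exactly reproducible.

## Known limitations

- Synthetic-only validation; no patient-trace ingestion beyond the generic
  CSV dialect (vendor log formats are proprietary).
- The grouped search explores only the documented pairings; interactions
  outside them (e.g. loss × latency) are not revisited, and a parameter
  frozen by an early group cannot be overturned later.
- Single-channel, single-horizon-at-a-time prediction; no probabilistic
  forecasts or confidence intervals on RMSE.
- The NumPy engine favors clarity and exact reproducibility over speed;
  epoch counts in the thousands on hour-long traces are possible but slow,
  which is why experiment configs expose an epoch override.
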