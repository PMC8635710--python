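# Methods

This note documents the models, defaults and numerical choices behind
`emgforce`, and what the synthetic benchmark does and does not establish.

## Synthetic recordings

The simulator emulates the statistical structure of an isometric
sine-tracking acquisition session rather than its physiology. Per task, one
force gauge follows the rectified target
`mvc_fraction · mvc_level · |sin(2π·0.1·t)|` for `n_periods` cycles; the
signed sinusoid is exposed as the tracking cue, whose sign separates the
two movement phases of the DoF (e.g. flexion vs. extension). Realized force
is the target plus *tracking error* — white noise low-passed at 1 Hz and
rescaled to `tracking_error_sd` — so it deviates smoothly from the cue the
way a human tracker does. Off-task gauges carry tracking noise only; the
acquisition protocol exercises one DoF at a time, and the force off the
active DoF is assumed near zero.

EMG is amplitude-modulated interference noise. For channel k,

    emg_k(t) = Σ_j crosstalk[k, j] · (env_j(t) / f_ref)^α · n_kj(t)
               + noise_floor_sd · w_k(t),

where `env_j` is the phase-specific rectified force envelope of matching j
(gated by cue sign), `f_ref = mvc_fraction · mvc_level` keeps the
modulation gain O(1) in any force unit, α is a monotone nonlinearity
(α = 1 linear; α ≠ 1 makes window amplitude a curved function of force),
and `n_kj`, `w_k` are independent unit-variance Gaussian noises confined to
`carrier_band`. The carrier filter is a deliberately steep order-10
Butterworth in second-order sections so that out-of-band power stays below
5 % of the total; a gentler filter leaks about 10 % into the transition
bands, which would blur the band-limitation property the preprocessing
relies on. Everything derives from one `numpy` generator seeded from the
configuration, so identical configurations give bit-identical recordings.

What the simulator does **not** model: motor-unit action potentials and
their rate/recruitment coding, electrode placement and impedance, muscle
synergies and co-contraction, fatigue, and nonstationarity across a
session. Consequently, passing the synthetic benchmark shows that the
pipeline recovers amplitude-coded force under crosstalk and nonlinearity —
it does not certify performance on clinical recordings.

## Preprocessing

All stages are causal so the chain can run online: filters are single-pass
IIR (`lfilter`, zero initial state), and the clipping bounds and
normalization statistics are estimated on the training periods only, then
applied unchanged everywhere. Fixed order of operations: clip → low-pass →
decimate → phase-split/rectify → pair → window → split → normalize.

- **Clipping** at the 1st/99th percentiles of the training-period portion
  of each EMG channel (linear-interpolation percentile convention). The
  reference choice matters: an online system cannot use future data, so
  per-recording percentiles are not an option.
- **Filters**: 2nd-order Butterworth low-pass, 500 Hz for EMG and 10 Hz for
  force at the native 10 240 Hz. The −3 dB point sits exactly at the cutoff
  (bilinear design with prewarping); the analog magnitude formula
  `1/√(1+(f/fc)^(2n))` describes the digital filter only while
  fc ≪ Nyquist, which is why the stop-band spot check uses the 10 Hz
  configuration.
- **Decimation** keeps every 10th sample. No additional anti-alias filter
  is applied because the 500 Hz low-pass already sits below the new 512 Hz
  Nyquist.
- **Phase splitting**: positive channel = |force| where cue > 0, negative
  channel = |force| where cue < 0; cue = 0 samples belong to neither.
- **Pairing** selects, per EMG channel, its matched phase-specific force
  channel; unmatched force channels are discarded, EMG channels without a
  matching are dropped with a warning, and samples from tasks actuating no
  matched channel are removed entirely.
- **Windowing** never lets a window straddle a task boundary or a
  discontinuity introduced by sample removal; a window's target and period
  index are read at its *last* sample, because that is the instant the
  online system would act on. Per contiguous segment of length L the count
  is `floor((L − width)/step) + 1`.
- **Splits** by sinusoid period: 7/1/2 of 10 for train/val/test; other
  period counts use the same 70/10/20 proportions (minimum one period
  each), e.g. 3/1/1 of 5.
- **Normalization**: EMG per-channel z-score with training statistics;
  force targets divided by the training SD without mean subtraction, since
  rectified targets have a meaningful zero.

## Networks and training

The three strategies share one topology and differ only in the
convolution's input width and the head's output width; that shared
skeleton — Conv1D(64 filters, kernel 21, same padding), leaky ReLU (slope
0.2), layer normalization, dropout 0.2, LSTM(64) read at the final step,
the same activation/norm/dropout block, FC 64→32, FC 32→out — yields
exactly 36 801 parameters for the 1-input/1-output network and 43 521 for
the 6-input/1-output one. The hidden FC width of 32 and the placement of
learnable layer norms (after conv and after the LSTM output vector only)
are the unique completion consistent with both of those counts, which is
why they are fixed here. The same arithmetic gives 43 686 for the
6-input/6-output network: a 6-wide head replaces the 33-parameter 1-wide
head with 32·6+6 = 198, so a published figure of 43 653 for this variant
cannot be produced by any architecture that yields the other two counts —
it is treated as a bookkeeping slip and 43 686 is the count this package
reports and tests.

The engine is written in NumPy: im2col convolution, explicit
backpropagation through time, layer-norm and dropout gradients by hand, and
AdamW with decoupled decay (`p ← p − lr·(m̂/(√v̂+ε) + λ·p)`). Finite
-difference checks in the test suite hold every gradient to ~1e-6 relative.
Weight initialization: Glorot-uniform conv/FC/input-to-hidden weights,
orthogonal recurrent blocks (per gate), zero biases except the forget gate
at 1 — the contemporaneous framework defaults, fixed by seed. Dropout and
minibatch shuffling draw from a per-model generator, so a (data, config,
seed) triple reproduces the training trace bit-for-bit.

Training defaults: AdamW η = 1e-4, β = (0.9, 0.999), λ = 1e-9, batch 32,
early stopping on raw validation loss with patience 25 / max 250 epochs,
last partial minibatch used, validation evaluated with dropout off, and the
best-validation weights restored at the end (the stopping rule alone leaves
unspecified which weights are returned; restoring the best epoch is the
better-defined contract). Multi-output loss is the plain MSE mean over
batch and channels.

## Metrics and statistics

RMSE normalizes the per-window channel-RMS error by the *global* test-set
maximum of the ground truth (`y_max`); a per-channel variant exists behind
a flag but the global reading matches the singular "maximum of the
regressand across the test set". VAF uses sample variances (ddof = 1);
the ratio is invariant to that convention. A constant predictor scores
VAF = 0 because targets are rectified, not centered.

The comparison ladder mirrors standard practice for within-subject method
comparisons: Shapiro–Wilk per method; if none rejects at α = 0.05, a
one-way repeated-measures ANOVA (statsmodels `AnovaRM`) with paired
t-tests post hoc and means as summaries; otherwise Friedman with Wilcoxon
signed-rank post hoc (exact null where the tie structure allows, normal
approximation otherwise) and medians as summaries. All C(4,2) = 6 post hoc
p-values are Bonferroni-multiplied and clamped at 1.

## The desk-scale benchmark

The `presets.demo_*` configuration is the package's own scaled study:
4 single-DoF tasks × 5 periods at 2048 Hz, 4 EMG channels matched
one-to-one to the 4 gauges (positive phase), crosstalk matrix with unit
diagonal and 0.3 off-diagonal, α = 1.6, carrier 20–100 Hz, noise floor
0.1, tracking error 0.01 (forces in MVC units, mvc_level = 1). The EMG
low-pass moves to 100 Hz and decimation to ×8 (256 Hz) to respect the new
Nyquist; windows are 64 samples (250 ms) with step 64; networks shrink to
32 conv filters / 32 LSTM units / 16 FC with lr 5e-3 and ≤ 30 epochs.
These sizes were chosen once to make the full three-seed, four-method
comparison run in minutes on a single core while preserving the phenomena
under study: crosstalk that only multichannel models can disambiguate
(during any task, every channel sees the active source; only their joint
pattern identifies it) and a nonlinearity that defeats an affine map of
MAV. The expected outcome, asserted by the acceptance tests, is the
ranking All-to-All ≤ All-to-One < One-to-One < linear on mean test RMSE
with all network strategies above 50 % VAF.

## Known limitations

- The NumPy engine is single-threaded BLAS-bound; full-scale (512-step,
  64-unit) training is feasible but slow, so the shipped benchmarks run the
  reduced geometry. Architecture accounting, by contrast, is always done at
  full scale.
- The simulator's stationarity and exact channel symmetry make the
  synthetic task easier than clinical data; reported synthetic VAF values
  are not comparable to values on real recordings.
- The adapter for the original public database is a documented layout
  mapping only (`emgforce.io` bundle format); it is not exercised by tests.
- Wilcoxon p-values with 16 recordings are granular; with heavy ties the
  normal approximation is used, as in common practice.
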