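# Methods

This note documents the models, defaults and numerical choices behind
semgrip, and what the synthetic-data experiments do and do not demonstrate.

## Packet protocol

The transfer format fixes field *sizes* (2-byte header, 4-byte frame
header, 6-byte MAC, 50 × 2-byte samples, 2-byte end flag, 2-byte trailer =
116 bytes) but not magic values or endianness, which are radio-firmware
details. The codec therefore declares configurable defaults: header
`AA 55`, end-of-data `FF FF`, trailer `0D 0A`, little-endian 16-bit samples,
and the 4-byte frame header read as a little-endian unsigned frame counter.
These are conventions, not values inferred from hardware; any deployment
can override them on `ProtocolConfig`. Stream reconstruction groups packets
by MAC, sorts by frame sequence, keeps the first copy of a duplicated frame
and reports missing frames as inclusive gap ranges — gaps are never filled,
because silent interpolation would corrupt downstream amplitude features.

ADC mapping divides by `2^bits − 1` (4095) so that full scale lands exactly
on the 3.3 V reference; the alternative divisor 4096 is off by one LSB and
can never reach the reference. Code 0 ↔ −1.65 V, code 4095 ↔ +1.65 V after
baseline removal.

## Preprocessing

* **Filter.** 4th-order Butterworth band-pass, 20–490 Hz at 1000 Hz,
  realized as second-order sections for numerical stability and applied
  forward–backward (zero phase) with odd-reflection padding of
  3 × (order + 1) = 15 samples. Because the filter runs twice, the
  effective amplitude response is the squared magnitude of the one-pass
  design; tests verify tones against exactly that analytic response.
  "4th order" names the band-pass prototype before the forward–backward
  doubling, matching common EMG practice.
* **Rectification** is the elementwise absolute value, applied after
  filtering.
* **MVC normalization.** The reference `sEMG_MVC` is the maximum sample of
  the rectified, filtered MVC trial, per subject and channel, with no
  smoothing before the maximum; several MVC trials are pooled by taking the
  maximum over all of them. This stage choice makes the normalized ratio
  non-negative and lets the MVC trial itself peak at exactly 100 %.
* Segments are half-open `[start, end)` spans with 0-based sample indices.
  Both the rectified-normalized and the filtered-unrectified version of
  each segment are retained: spectral features must not see the rectified
  signal, whose folded spectrum concentrates mass at low frequencies.
* An amplitude-threshold onset detector is included as optional plumbing
  only; the primary segmentation path is manual annotation.

## Features

Windows are 256 ms advanced by 56 ms (256/56 samples at 1000 Hz); a
trailing span shorter than one window is dropped, so a segment of L samples
yields `floor((L − 256)/56) + 1` windows. Time-domain features (iEMG, RMS,
WL, Shannon entropy) read the normalized stage; spectral features (MF, MPF)
read the filtered stage of the same span.

* **iEMG** is implemented with its 1/N factor, i.e. as the mean rectified
  amplitude. As printed the quantity is per-unit-time rather than a raw
  sum; the 1/N version is kept because it is scale-consistent across window
  lengths.
* **Entropy** needs a discretization of the continuous amplitudes: an
  equal-width histogram over `[min, max]` with 64 bins by default
  (configurable), log base 2, `0·log 0 := 0`. A constant window has zero
  entropy by construction.
* **Spectrum.** Single Hann-tapered periodogram, one-sided, resolution
  `rate/N` ≈ 3.9 Hz. Welch averaging inside a 256-sample window would
  destroy resolution for no variance benefit at this length.
* **Median frequency** is computed as the frequency splitting the
  cumulative spectral power in half, with linear interpolation between
  bins. A literal reading of the usual shorthand formula
  (`MF = ½∫PSD df`) evaluates to half the total *power* — units of power,
  not Hz — so the standard definition the shorthand abbreviates is
  implemented instead.
* **Waveform length** sums `|x_{i+1} − x_i|` to `i = N − 1` (an upper index
  of N would address a nonexistent sample).

## Bald eagle search

A population metaheuristic with three phases per iteration — select space,
search prey (trigonometric spiral), swoop (hyperbolic spiral) — exactly as
described in the module docstring. Choices that the verbal description
leaves open, fixed here:

* **Acceptance.** Candidates replace an eagle only if they improve its
  fitness (greedy). This yields elitism and a provably non-increasing
  best-so-far history, which the tests rely on.
* **Defaults** within the admissible ranges: α = 2, a = 10, R = 1.5,
  c1 = c2 = 2 (the aggressive end of each range, pinned for
  reproducibility and exposed in `BESConfig`).
* **Neighbor term.** The search-prey update references "the next" eagle;
  it is read as the (i+1)-th member of the population array with cyclic
  wrap-around. With a single eagle the phase is the identity.
* **Bounds** are enforced by hard clipping — the simplest deterministic
  repair.
* **Randomness.** One `numpy` generator seeded once; draws are phase-major
  then eagle-major (select: one uniform per eagle; search: angles then
  radii; swoop: angles then the position blend), so trajectories are
  bit-identical per seed.

On the 2-D sphere benchmark with the best-observed setting (population 10,
30 iterations) the optimizer reaches ~1e-76, far below the 1e-2 test bound;
on 1-D quadratics it matches a 1e-3-step grid minimum within 1e-2 for 20/20
test seeds.

## Grip-force model

* The 70/30 split is row-wise over windows with a seeded shuffle; subject
  stratification is available by flag but off by default (windows of one
  session can land on both sides — the documented alternative treats whole
  subjects as units).
* The tuning fitness is `MSE_train + MSE_test` of a forest fitted with the
  candidate `(n_estimators, min_samples_leaf)`. This deliberately feeds the
  test split into tuning, which leaks information; it is implemented as the
  method prescribes, and a cross-validated fitness (`cv_folds`) is provided
  for leakage-free tuning, off by default.
* BES runs on the continuous relaxation of the integer box
  (`n_estimators ∈ [10, 500]`, `min_samples_leaf ∈ [1, 20]` by default,
  bounds configurable); positions are rounded half-up at evaluation, and
  fitness values are cached per integer pair so revisits are free.
* Forest internals are delegated to scikit-learn with a fixed
  `random_state`; the package's contribution is the codec, features,
  optimizer, fitness, metrics and pipeline.
* Metrics follow the formulas in the README; R² is undefined (error) for a
  constant truth vector.

## Synthetic data

The generator emulates the study conditions so the chain runs without the
(unavailable) recorded data: two channels at 1000 Hz; one MVC trial plus
contractions at 80/60/40 %MVC, each 3 s (protocol minimum 2 s) with 200 ms
onset/offset ramps; 12-bit quantization about the 1.65 V baseline;
packetization into the transfer protocol, one emulated MAC per channel.

The signal model is the standard stochastic sEMG surrogate:
amplitude-modulated Gaussian noise confined to 20–490 Hz by FFT masking,
with activation `A(level) = (level/100)^γ`, γ = 1.5 — between a linear and
a strongly nonlinear force–amplitude relationship, and configurable to
probe robustness. A broadband noise floor (2 % of MVC amplitude) is always
present; an optional 50 Hz line component is off by default. The MVC-level
analog RMS amplitude is 0.30 V so the waveform exercises most of the ADC
span with rare clipping. Rest gaps contain only baseline plus the noise
floor and default to 1 s: their content is inert and annotation-driven
segmentation never reads them, so the physiological 20 s anti-fatigue rest
is not reproduced.

What the generator does *not* emulate: motor-unit firing statistics,
inter-muscle crosstalk, electrode-skin impedance drift, movement artifact,
or inter-subject variability in activation shape. Passing end-to-end tests
therefore demonstrates that the software chain is correct and that the
model can recover a monotone force–amplitude relationship from quantized,
packetized signals — not that the reported accuracy transfers to real
muscles.

## Problem sizes and determinism

The test suite and the acceptance script run desk-scale configurations
chosen as the package's own defaults for quick, single-CPU verification:
two synthetic sessions (≈400 windows, 12 features) for the end-to-end
check, one session for the ten-seed tuned-vs-default comparison, and a
reduced BES budget (population 5, 5–6 iterations over
`n_estimators ∈ [10, 200]`) with per-pair fitness caching. Library defaults
keep the full study setting (population 10, 30 iterations,
`n_estimators ∈ [10, 500]`). All randomness flows from explicit integer
seeds; every CLI run writes a manifest (command, config hash, package
version) sufficient to replay it.

## Known limitations

* The protocol magic bytes and frame-header semantics are declared
  conventions; interoperating with real firmware requires configuring them.
* The tuning fitness's test-set leakage is faithful to the prescribed
  procedure but optimistic; use `cv_folds` for honest model selection.
* Windows overlap (256/56 ms), so adjacent rows are correlated; a row-wise
  random split slightly flatters held-out scores relative to a
  contraction- or subject-level split.
* Entropy depends on the histogram bin count; 64 bins is a convention, not
  an estimate of optimal binning.
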