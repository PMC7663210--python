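# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `soilspec`, in the spirit of a model-description
appendix: what is computed, under which assumptions, and what the bundled
tests do and do not establish.

## Data model and containers

A `SpectrumSet` holds a strictly ascending wavelength axis (nm) and an
n × C intensity matrix, either reflectance fractions in (0, 1] or unitless
absorbance. Reflectance is converted with A = −log₁₀(R), the Beer–Lambert
convention for diffuse-reflectance spectra. Attribute tables are joined to
spectra **by sample ID only**, never by row order; an unmatched ID is an
error rather than a silent drop.

Dataset splitting assigns each non-train partition ⌈ratio·n⌉ samples and
gives the remainder to train, after a seeded uniform shuffle and contiguous
slicing. This rule is exact and total: with n = 19,036 and ratios
(0.6, 0.2, 0.2) it yields 11,420/3,808/3,808, and with n = 180 at 7:3 it
yields 126/54. Survey reports occasionally quote split counts (e.g. 125/55
for 180 at "7:3") that no deterministic rounding rule reproduces; we do not
attempt to match such counts.

## Preprocessing

Three transforms, composable in a fixed canonical order sg → msc → center:

- **Savitzky–Golay smoothing** (`scipy.signal.savgol_filter`, mirror
  padding): sliding-window least-squares polynomial fit; defaults window 11,
  polynomial order 2. The window/order are not critical for the smooth
  synthetic bands and are exposed in the pipeline config.
- **MSC**: each spectrum is regressed on a reference by OLS over
  wavelengths, x ≈ a + b·ref, and corrected to (x − a)/b. The reference is
  the **training-set mean spectrum** (median references are out of scope).
  |b| ≤ 1e−8 is reported as a per-sample correction error with the sample ID.
- **Centering**: subtraction of the per-wavelength training mean.
  "Per-wavelength across samples" (the regression convention) rather than
  per-spectrum; centering a training set therefore zeroes its column means
  exactly, while applying the frozen train mean to new data does not (and
  is deliberately not idempotent).

Pipelines are **fit on the training partition only** and applied with frozen
state everywhere else; a leakage test asserts the fitted state is
byte-identical after transforming unseen data. Each fit statistic is
computed on the output of the preceding steps, matching how the pipeline is
later applied.

## Spectrogram construction

The wavelength axis is treated as a time axis. A spectrum is framed
(frame length F, overlap V, hop F − V, trailing remainder dropped), each
frame is multiplied by a symmetric Hamming window
w(k) = 0.54 − 0.46·cos(2πk/(N−1)), and an F-point real FFT magnitude is
taken, giving an (F/2 + 1) × n_frames grid. Stock parameterizations:
F = 50, V = 20 for 750-channel spectra (26 × 24 grid) and F = 100, V = 50
for 4200-channel spectra (51 × 83 grid).

The raw grid is not square, so it is rendered to the target size
(default 64 × 64) by log1p compression (toggleable), bilinear resize
(`scipy.ndimage.zoom`, grid mode) and per-image min–max normalization to
[0, 1]. The resize step is the one place where the published image size
cannot be derived from the STFT arithmetic alone; bilinear interpolation is
our choice and is flagged as such. A constant grid maps to the all-zero
image (min = max convention), with a relative-epsilon guard against resize
round-off. Images are computed from the **raw** spectra; the 1-D branch is
the one that consumes preprocessed sequences. No zero padding, no phase,
single channel.

## Network architectures

Implemented on an in-package numpy layer core (channels-last, explicit
forward/backward, finite-difference-verified gradients; no external deep
learning framework is used).

**Single-input (`Multi_CNN_1D` style):**
Conv1D(64, k3, weight-normalized, ReLU) → BatchNorm → MaxPool1D(5) →
Conv1D(128, k3, ReLU) → residual block → Conv1D(64, k3, ReLU) → flatten →
FC(128, ReLU) → FC(64, ReLU) → T linear heads FC(1). The residual block is
TCN-style: dilated Conv1D(64, k3, d=2, WN, ReLU) → Dropout →
dilated Conv1D(64, k3, d=4, WN, ReLU) → Dropout, summed with a parallel
plain Conv1D(64, k3) skip projection, then ReLU. Its receptive half-width
is 1·2 + 1·4 = 6 positions, asserted by perturbation analysis.

**Dual-stream:** the same 1-D branch up to its flatten, plus
Conv2D(64, 5×5, ReLU) → MaxPool2D(2) → Conv2D(128, 3×3, ReLU) → MaxPool2D(2)
→ Conv2D(256, 3×3, ReLU) → MaxPool2D(2) → flatten on the spectrogram image;
branch features are fused by concatenation and share one FC trunk and the
per-attribute heads.

Choices made where the reference layout is under-specified:

- **Non-causal dilated convolutions.** TCNs are causal for genuine time
  series; a wavelength axis has no direction, so all convolutions use
  symmetric "same" padding and sequence lengths are controlled only by
  pooling.
- **ReLU on every convolution**, weight normalization on the first 1-D
  convolution and the dilated pair; batch norm only after the first 1-D
  convolution; dropout rate 0.1 (unstated upstream; any value in [0, 0.3)
  behaves similarly here).
- **Skip path** realized as a k=3 "same" convolution (the fifth 1-D conv
  row of the layout) rather than a 1×1 projection.
- **Fusion by concatenation**, with a single shared trunk after the merge.
- Glorot-uniform initialization from an explicit seed; two builds with the
  same config and seed are bit-identical.

**Adaptive input selection**: single input when n_samples < 1000 or
n_channels < 1000 (both thresholds configurable), dual input otherwise,
with an explicit override. Rationale: the dual model roughly triples the
parameter count and overfits small surveys.

## Training and evaluation

Loss is equal-weight summed per-task MSE on **per-attribute standardized
targets** (train statistics only, inverted inside `predict`), so tasks with
different units (g/kg vs mg/kg) contribute comparably. Optimizer Adam at
1e−3, batch 32, seeded shuffling; 200 fixed epochs when no validation
partition exists, otherwise early stopping on validation loss with
patience 20 and best-weight restoration. Training state is float32 (Adam
moments in float64); runs are exactly reproducible for a given seed on a
given BLAS. NaN loss aborts with a diagnostic.

Metrics: R² = 1 − SSres/SStot with the evaluation-set mean in the
denominator (NaN sentinel when the targets have zero variance);
RMSE = √mean((y−ŷ)²); RPD = SD(y_test, ddof = n−1)/RMSEP (infinite with a
warning when RMSEP = 0). RPD·RMSEP equals the test-set SD identically.
All metrics are reported in raw target units.

## Synthetic data

Each sample draws non-negative band depths d (truncated normal, mean 1,
SD 0.3) over K = 6 Gaussian absorption bands spread over the inner 80% of
the wavelength range (width = span/20). The clean absorbance is
A(λ) = Σₖ dₖ·exp(−(λ−μₖ)²/2σₖ²); the observed spectrum is
m·A + offset + slope·u + ε with per-sample multiplicative scatter
m ~ U(0.7, 1.3), additive offset U(−0.05, 0.05) plus baseline intercept
U(0, 0.2), linear drift slope U(−0.1, 0.1) over normalized wavelength, and
iid Gaussian noise applied **after** scatter (so scatter correction cannot
remove it). Targets are affine in the depths, y = c + G·M·d with a full-row-rank
3 × 6 map M and per-attribute gains chosen so the defaults mimic a soil
survey (TC mean 6.21 g/kg SD 3.42; TN 0.80/0.46; AN 69.51/33.18 mg/kg).
The generator returns the full ground truth (depths, scatter factors, clean
spectra, effective map) for oracle tests.

**Identifiability and the level direction.** With targets affine in the
depths, a spectrum m·A(d) is observationally equivalent to 1·A(m·d): the
overall depth scale and the scatter factor are confounded, and no
preprocessing can separate them. Scatter correction is nevertheless
standard practice because real scatter moves the overall level and slope
while chemistry moves the band structure. The generator makes this
assumption explicit: the iid depth deviations are shrunk along the
*spectral-level direction* — the depth-space direction that changes a
spectrum's OLS slope against the mean spectrum — to a configurable fraction
(`level_variation`, default 0.1) of their iid spread. Chemistry then lives
almost entirely in scatter-separable directions, MSC-corrected spectra
correlate with the clean ground truth at r > 0.99 per sample, and the
depth-to-target map remains exactly recoverable by OLS because the retained
level-direction variance keeps the depth design full rank. The per-target
scaling accounts for the shrunken covariance
σ²(I − (1 − ε²)·ĉĉᵀ) analytically.

**What the synthetic data does not emulate**: nonlinear detector response,
wavelength-dependent (chromatic) scatter, correlated noise, water-vapor
artifacts, target measurement error, and real soil compositional
covariance. Passing the recovery tests therefore shows the pipeline and
optimizer are correct and that preprocessing removes the corruptions it
targets — not that comparable R² would be reached on any particular field
dataset.

## Problem sizes used in the bundled checks

The recovery check trains the single-input network on 500 samples × 750
channels (7:3 split, noise at 5% of clean-signal SD, 200 epochs) and asks
for held-out R² ≥ 0.9 on all three attributes; typical results are ≈ 0.97.
The preprocessing ablation uses 50 independent trials of 120 × 300 with a
ridge readout; the determinism check trains twice for 10 epochs at 60 × 300
and compares metric JSON byte-for-byte. These sizes were chosen as the
smallest at which the effects of interest are unambiguous.

## Known limitations

- The numpy core is single-threaded BLAS-bound; it is meant for
  verification-scale experiments (10²–10⁴ samples), not for training on
  full continental libraries.
- Bit-exact reproducibility holds for a fixed BLAS/platform; across
  platforms, float32 accumulation order may differ.
- The spectrogram resize is an interpolation choice, not a derived
  quantity; alternative renderings (nearest, area) would change the 2-D
  branch's input slightly.
- `select_mode` thresholds are heuristics calibrated to "small survey vs
  continental library" scales, not learned.
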