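# Methods

`nirquant` implements a deep-learning calibration workflow for quantifying
solid adulterants (corn flour, tapioca starch) in coconut milk from
near-infrared spectra, together with a synthetic-data generator that emulates
the two-instrument study design the workflow targets. This note records the
models, the defaults and the design choices, and what the synthetic data can
and cannot show.

## The calibration problem

A spectrum is a vector of absorbance values (log 1/R) on a fixed instrument
grid; the target is the adulterant mass fraction in % w/w. Two grids are
built in: a benchtop FT-NIR grid of 1102 evenly spaced wavenumbers over
4000–12,500 cm⁻¹ (spacing ≈ 7.72 cm⁻¹) and a portable Micro-NIR grid of 125
evenly spaced wavelengths over 908–1676 nm (spacing ≈ 6.19 nm). The stated
8 cm⁻¹ FT-NIR resolution does not arithmetically yield 1102 points over that
range; the feature count is authoritative, so the grid is defined as 1102
evenly spaced points. Axes are stored ascending in their native unit and
every report prints both units (ν[cm⁻¹]·λ[nm] = 10⁷).

## Synthetic spectra

No measured spectra ship with the package, so the generator must supply
spectra with the study's design and qualitative structure:

* **Design**: 15 adulteration levels (1–10, 15, 20, 30, 40, 50 %), 10
  physical samples per level, 3 scans per sample → 450 spectra per
  instrument–adulterant pair, 1800 in the full 2×2 study. Levels are exact
  integers so targets are deterministic.
* **Pure components** are sums of Gaussian bands. Band *centers* sit at the
  standard NIR assignments (water OH combination 1932 nm / 5176 cm⁻¹ and
  first overtone 1452 nm / 6889 cm⁻¹; fat CH second overtone 1210 nm and
  first overtones 1728/1764 nm; starch OH 1540 nm; glucose region 1400 nm).
  Band widths (15–50 nm) and amplitudes (water bands dominating at 0.7–1.0
  absorbance, starch bands 0.2–0.55) are simulator defaults chosen to look
  like smooth, heavily overlapped NIR spectra; they are configuration, not
  measured values, and nothing downstream depends on their exact numbers.
* **Mixing model**: at adulterant mass fraction c the noise-free absorbance
  is `A(λ) = (1−c)·A_milk(λ)·(1−γc) + c·A_adulterant(λ)`. The attenuation
  γ (default 0.3) models moisture equilibration — a solid adulterant binds
  the milk's free water, so milk-band peak absorbance falls faster than
  linear dilution alone. This makes the expectation quadratic in c (affine
  when γ = 0) and strictly decreasing in c at the water bands over the whole
  design range, the qualitative trend a solid-in-liquid adulteration series
  shows.
* **Measurement effects**: per-sample multiplicative gain U(0.9, 1.1) and
  baseline offset U(−0.02, 0.02) shared by a sample's three scans (these are
  exactly the distortions SNV removes), plus per-scan white noise
  (SD 0.003 absorbance) and a per-scan scalar baseline jitter (SD 0.001).
* **Seeds**: one master seed; each instrument–adulterant stream derives its
  own sub-seed (< 2³¹) by hashing the pair's tags with the master seed, so
  any single dataset is reproducible without generating the other three.

What the generator does **not** emulate: physically calibrated
absorptivities, temperature/humidity drift, scattering theory, instrument
line-shape differences, or the between-batch variability of real coconut
milk. Passing tests therefore demonstrate that the pipeline recovers a known
mixing signal under realistic scatter and noise — not field performance on
real adulterated samples.

## Preprocessing

Standard normal variate: each spectrum is centered and scaled to unit sample
standard deviation (n−1 convention; the constant factor relative to the
population form is absorbed by the scale-free models downstream). SNV is
per-row and fit-free, so it is applied before splitting without leakage.
Constant spectra are rejected as degenerate.

## Splitting

A plain uniform random permutation keyed to a seed (default 42) with
|train| = floor(0.70·n): 450 → 315/135. Replicate scans are split at the
spectrum level, so one sample's scans may straddle train and test; this
mirrors the target study's bookkeeping and is noted as a leakage caveat
rather than "fixed". The split is not stratified by level.

## The four regressors

All four architectures are one-dimensional, end in a single linear unit, and
train on raw percent targets (no clipping — slightly negative predictions
are legitimate outputs). Exact layer recipes:

| arch | body |
|---|---|
| `simple_cnn` | Conv(32,k7) → MaxPool2 → Conv(64,k5) → MaxPool2 → Flatten → Dense(64) → Dense(1) |
| `s_alexnet` | Conv(48,k11,s4) → Conv(128,k5) → Conv(192,k3) → Conv(192,k3) → Conv(128,k3), max-pools after convs 1, 2, 5, then Dense(256) → Dense(128) → Dense(1) |
| `resnet` | Conv(32,k7,s2) stem → four pre-activation residual blocks (channels 32,32,64,64; two k3 convs + batch-norm each; identity shortcut, 1×1 projection on channel change) → BN → GAP → Dense(1) |
| `googlenet` | Conv(32,k7,s2) stem → MaxPool2 → two inception modules (parallel k1/k3/k5/pool-k1 branches; channel splits 16-32-8-8 then 32-48-12-12) → GAP → Dense(1) |

ReLU activations throughout. Residual blocks are pre-activation so an
identity-shortcut block with zeroed convolutions is an exact identity —
this keeps the residual mechanism testable. The sizes preserve each
family's defining mechanism (depth, shortcut, multi-scale branches) at a
capacity trainable on ~300 spectra.

The engine is a self-contained float64 numpy implementation (im2col
convolutions, explicit backward passes, Adam); every layer's gradient is
validated against central finite differences in the test suite. Running in
float64 end-to-end means the interpretation module's 10⁻⁶ perturbation step
is well above numeric resolution. Weights initialize from the uniform
fan-in scheme U(−1/√fan_in, 1/√fan_in) keyed to the run seed; bit-exact
reproducibility across BLAS builds is not promised, within one environment
runs are deterministic.

## Training protocol

Adam with MSE loss. Per-architecture defaults (batch, max epochs, learning
rate, patience): simple_cnn (128, 1000, 5·10⁻³, 200); s_alexnet (16, 300,
10⁻⁵, 300); resnet and googlenet (160, 1000, 10⁻⁵, 200). The validation set
is the trailing `n − floor(0.9·n)` rows after one seeded shuffle of the
training rows — 32 spectra at n = 315. Early stopping restores the best
validation weights. The default protocol repeats training 11 times with
fresh initializations, keeps the repeat with the lowest best validation
loss, and reports epochs cumulatively across repeats (so a reported epoch
count of several thousand reflects repeats of ≤1000-epoch runs). A NaN loss
aborts with the epoch index.

Whether training-set metrics include the 32 validation spectra is
convention; this package evaluates "training" metrics over all 315 training
rows (validation included), the plain reading of a train/test report table.

## Evaluation

R² = 1 − Σ(E−P)²/Σ(E−Ē)², RMSE, Bias = mean(E−P) (positive = model
under-predicts), RPD = 1/√(1−R²) computed from the unrounded R². The RPD
form is the reciprocal square root: it is the algebraic link consistent
with the banding convention and with published R²–RPD pairings in this
application area (R² 0.886 ↔ RPD ≈ 2.96). Bands: < 3.1 poor, 3.1–5.0 fair,
5.0–6.5 good, 6.5–8.1 very good, > 8.1 excellent; values in the
conventionally unlisted gaps (e.g. 3.05) fall to the lower band. Test-set
R² uses the test-set mean for Ē.

## Interpretation

The "regression coefficient" of a trained network on spectrum x is the
one-at-a-time forward finite difference `w_j = [f(x + ε·e_j) − f(x)]/ε`
(ε default 10⁻⁶, configurable; a warning recommends a larger ε if every
difference underflows to zero). Per-spectrum vectors are averaged
element-wise over all training spectra — a nonlinear model has a different
coefficient vector per spectrum, and the mean profile is what gets
thresholded. Important wavelengths are those with mean weight ≥ 50% of the
profile maximum or ≤ 50% of the profile minimum (signed cutoffs, not 50% of
|w̄|); contiguous selected grid runs are merged and labelled in both nm and
cm⁻¹. Coefficients are defined with respect to SNV-scaled inputs, so
rescaling raw absorbance leaves the profile unchanged.

## Numerical choices and degenerate inputs

* Sample (n−1) SD throughout (SNV, summary statistics).
* Constant spectra, constant reference vectors, all-equal coefficient
  profiles and empty selections raise typed errors instead of propagating
  NaNs.
* RPD of a perfect predictor (R² = 1) is reported as infinite with the
  "excellent" band by convention.
* Ties in the best-regressor report break by lower test RMSE, then
  lexicographic architecture name.
* Axis conversion rejects non-positive values (it is a reciprocal map).

## Problem sizes used in the shipped checks

The test suite and the acceptance script regenerate everything they need at
run time. The parameter-recovery check trains the Simple CNN on the full
450-spectrum Micro-NIR corn-flour design with the published protocol and a
single repeat; architecture capacity and protocol-mechanics checks use a
noise-free 30-spectrum design and reduced epoch budgets, which is where
those properties are cheapest to demonstrate. The heavier FT-NIR grid and
the 11-repeat protocol run through the same code paths and remain available
through the configuration surface.

## Known limitations

* Synthetic band amplitudes/widths cannot be validated against measured
  spectra; they are exposed as configuration and documented as defaults.
* The low-learning-rate protocols (10⁻⁵) are faithful to their published
  budgets but converge slowly by construction; on the synthetic task the
  Simple CNN protocol is the fast, reliable reference point.
* Only SNV preprocessing is provided (no MSC, derivatives or detrending),
  matching the workflow's scope.
* No JCAMP-DX/SPC or vendor binary spectral formats; the interchange format
  is the wide CSV + JSON sidecar pair.
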