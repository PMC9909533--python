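# Methods

This note records the models, parameter choices and numerical policies
behind `leafspec`, and what the synthetic study conditions do and do
not demonstrate.

## The measurement model

A leaf sprayed with a pesticide solution carries surface residue `c`
(mg/kg, determined by reference LC-MS/MS chemistry). Its reflectance
spectrum R(λ) over 320–1100 nm differs from an untreated leaf's mainly
in a narrow absorption region; the workflow assumes that the
absorbance proxy A(λ) = log₁₀(1/R(λ)) is, at some band λ*, approximately
linear in `c`. Stage one finds λ*; stage two regresses `c` on image
statistics captured under λ* illumination.

## Synthetic data generator

No public dataset accompanies this problem, so the generator encodes
the structure the method assumes and every claim in the test suite is
relative to it.

**Spectra.** Each sample is

    R(λ) = [ B(λ) − c · η · G(λ; λ*, σ) ] · (1 + a) + b + ε(λ),  clipped to [0, 1]

* `B(λ)`: a fixed green-leaf baseline — low visible reflectance, a
  green bump at 550 nm, a sigmoid red edge centred at 715 nm rising to
  an NIR plateau, and a shallow 970 nm water dip. It is hard-coded so
  the planted band (default λ* = 709 nm) sits on a realistic red-edge
  slope.
* `η` (`effect_size`, default 0.04 reflectance units per mg/kg) scales a
  Gaussian absorption `G` of width σ = 15 nm. Over the default 0–2.5
  mg/kg range this produces maximum correlation |r| ≈ 0.9 at the band,
  matching the regime the method is designed for. `η = 0` is the null
  model.
* `a ~ N(0, 0.05)`, `b ~ N(0, 0.01)`: per-sample multiplicative and
  additive scatter (the effects MSC removes); `ε ~ N(0, 0.005)` per
  channel.

**Concentrations.** Four spray groups emulate the experimental design
(water control and three dilutions): defaults 0.0, 0.8, 1.5 and
2.5 mg/kg — chosen once as plausible residues under the 3 mg/kg
Chinese maximum-residue limit, since no measured per-group values are
published — plus N(0, 0.1 mg/kg) leaf-to-leaf jitter truncated at
zero, mimicking spray and uptake variability. A uniform-range mode is
available.

**Images.** A rasterized disk (default radius 20.5 px in a 64×64
frame) on a dark background (level 12); foreground channel means are
`clip(base + slope·c)` with base (90, 140, 70), slopes (28, 16, 9)
intensity per mg/kg, and N(0, 4) pixel noise, quantized to 8 bits. The
half-integer radius makes the rasterized disk invariant under the 3×3
morphological cleanup, so noise-free segmentation is exactly
invertible — integer radii leave one-pixel protrusions at the four
cardinal extremes that an opening removes.

**What this does not show.** The generator has no wavelength-correlated
noise, no leaf-shape or texture variability, no specular highlights or
illumination gradients, no disease spots, and a perfectly linear
concentration–signal link. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes, not that the assumptions
hold on real leaves.

## Preprocessing

Eight schemes are implemented behind one dispatcher: raw, per-spectrum
min-max normalization, MSC, plain first derivative, SG smoothing, SG
first/second convolution derivatives, and column mean centering.

* **Savitzky–Golay.** The window of n = 2m+1 points is fitted by a
  degree-k polynomial; the smoother is the orthogonal projection
  B = X(XᵀX)⁻¹Xᵀ built from the Vandermonde design on offsets −m…m,
  and the value (or d-th derivative, scaled by d!/h^d for grid step h)
  of the fit at the window centre gives the convolution weights.
  Defaults: window 11, order 3 — a common chemometrics choice; the
  window must satisfy n ≥ k + 2.
* **Edge policy.** Smoothing copies the first/last m points through
  unchanged (simplest auditable policy); derivative filters repeat the
  nearest interior value, since copying the signal itself would mix
  units.
* **MSC** regresses each spectrum on the calibration-set mean and
  inverts the fitted affine map. As sklearn transformers, all
  data-dependent schemes learn their statistics from the calibration
  rows only and apply them unchanged to prediction rows.
* **"Standard normalization"** is the per-spectrum min-max map; it
  rejects constant input, where the map is undefined.

## Wavelength selection

Spectra are floored at 10⁻⁶ and transformed to log₁₀(1/R). (The
transform acts on reflectance: a log of the wavelength axis itself
would be identical across samples and could not correlate with
residue.) Two evidence curves are computed:

1. Pearson r(λ) between the transformed column and `c` (constant
   columns get r = 0 with a warning);
2. PCA scoring coefficients: loadings of the first q = 3 components of
   the column-standardized matrix, with explained-variance ratios.

The screening score is `unit(r²) · unit(L)` where
`L(λ) = max_k |loading_k(λ)|` over the retained components and
`unit(·)` rescales to [0, 1] (a constant curve is treated as neutral).
Using the maximum over retained components rather than the first
component alone is deliberate: with multiplicative scatter the leading
component is the common scatter factor, whose loading is *depressed*
at the analyte band (the band column is the one column carrying large
scatter-independent variance), while the concentration factor appears
as a later retained component. Scoring by |loading₁| alone
systematically displaces the primary band off the planted wavelength;
the maximum over the retained components restores the intended
"highest correlation and highest scoring coefficient" conjunction.

Candidate bands are local maxima of the score (plateau-tolerant,
endpoints allowed), taken greedily in score order subject to a minimum
separation (default 30 nm — small enough to admit close pairs such as
680/709 nm); the primary band is the retained peak with the highest
score, ties broken toward larger r². If fewer separated peaks exist
than requested, the selector returns what exists with a warning; a
low `max_r_squared` in the output flags null-like data.

## PLS calibration

`PLS1Regression` is NIPALS PLS1: for a single response the weight
vector per component is the normalised covariance Xᵀy, followed by
score projection and rank-one deflation; coefficients are recovered as
W(PᵀW)⁻¹q and mapped back to the original predictor scale. Predictors
are centred (unit-scaling optional); the algorithm is deterministic
given row order, and components that find no remaining covariance
truncate the model with a warning.

Metrics follow the chemometric convention: Rc/Rp are Pearson
correlations of observed vs fitted on the calibration/prediction sets,
SEC/SEP the root mean squared residuals with the population divisor n
(no degrees-of-freedom correction; documented here because conventions
differ). Comparison workflows use a seeded random 8:2 split — the only
split ratio the training protocol specifies — and default to 5
components, capped by data rank.

## Image chain

Grayscale uses ITU-R BT.601 weights (0.299, 0.587, 0.114), rounded to
8-bit. Segmentation thresholds the gray image (configurable to a
single channel) by Otsu's method, takes the brighter side as leaf,
applies 3×3 closing then opening, and keeps the largest connected
component; an image without contrast or with an empty cleaned
foreground raises a segmentation error (batch mode skips and logs such
images). Background pixels are zeroed in all channels before feature
computation. The 10 features — average gray over the de-backgrounded
mask, plus per-channel mean, population SD, and CV = SD/mean (0 with a
warning for a zero-mean channel) — are computed over foreground pixels
only, which makes them invariant to background content by
construction.

## Residue network

The feature vector is standardized with training-set statistics and
embedded row-major into cells 0–9 of a 6×6 single-channel grid (zeros
elsewhere — the simplest deterministic embedding of 10 values in 36
cells). Architecture: conv 2×2×16 ('same' padding, bottom/right for
the even kernel) → ReLU → maxpool 2×2 stride 2 → conv 2×2×32 ('same')
→ ReLU → flatten (3·3·32 = 288) → dense 512 → ReLU → dense 1; weights
initialized N(0, 0.1), biases 0.1. The dense width of 512 is fixed by
the protocol even though the flattened convolutional output is 288.
150,641 parameters in total.

Training minimises MSE by plain gradient descent at learning rate 0.01
for 10,000 iterations (Adam available behind a flag), with the
training loss logged every 100 iterations and an internal seeded 8:2
train/test split. Two numerical choices:

* **Label standardization.** Labels are z-scored internally and
  inverted at prediction; losses are reported in mg/kg². This keeps
  the fixed learning rate well-conditioned across label scales.
* **Mini-batches.** Batches of 128 drawn by seeded permutation sweeps
  (full batch when the training set is smaller). Problem sizes here
  make full-batch descent needlessly expensive at 10,000 iterations;
  seeded mini-batching preserves exact run-to-run reproducibility.

The network is implemented directly in NumPy (float32; im2col
convolutions, argmax-routed pooling gradients, hand-derived
backpropagation); at this size a dense formulation is fast, dependency
free and bit-reproducible under a fixed seed. Divergence (non-finite
loss) raises an explicit error. Models persist as versioned `.npz`
archives carrying the config echo, feature/label statistics and
weights; `load(save(m))` reproduces predictions exactly.

## Evaluation

PRESS is the plain residual sum of squares Σ(y−ŷ)² on the stated
split, so press = n·rmse² holds by construction. R² is the coefficient
of determination (can be negative); the squared-Pearson form is
exposed separately because published tables mix the two conventions.
Units are mg/kg throughout.

## Problem sizes and defaults used in checks

The automated checks run the generator at the study scale: 200-sample
spectra sets across 20 seeds for band recovery (with a null control),
120-sample sets for the calibration comparisons, and the full
1,200-sample image set (the enlarged sample design: 120 leaves × 10
portions) for network training, with a shuffled-label control.
Byte-level reproducibility is verified by running the training stage
twice from one config.

## Known limitations

* The screening score is a heuristic conjunction; it has no optimality
  guarantee and is sensitive to the PCA depth q on data whose analyte
  factor falls outside the retained components.
* SG edge handling (copy-through) biases the first/last m points;
  derivative edges are constant-extrapolated.
* The CNN protocol (fixed lr, fixed iterations, no early stopping or
  regularisation) is faithful to its source but is not a tuned modern
  training recipe; on the clean synthetic link it overfits benignly.
* Single-leaf scenes only; no illumination correction or lesion
  handling.
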