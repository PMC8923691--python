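# Methods

This note records the models, parameter choices and numerical conventions
behind `renaltlco`, and what the synthetic evaluation does and does not
demonstrate.

## Renal-function targets

eGFR is computed with the Japanese-cohort serum-creatinine equation,
eGFR = 194 · Cr^(−1.094) · age^(−0.287) mL/min/1.73 m², multiplied by
0.739 for women.  Both exponents make eGFR strictly decreasing in
creatinine and age; the equation is inverted algebraically when the
phantom generator needs a creatinine value consistent with a planted eGFR.

Per-subject regression targets come from an ordinary least-squares line of
eGFR against time.  Time is fractional years since the first observation
at 365.25 days per year; the paperwork of calendars (leap days, visit
cadence) then cancels out of the slope.  The line is evaluated at the
imaging date for `egfr_at_imaging`; its slope, signed as fitted, is the
annual eGFR slope (decline negative).  R² of the fit is reported only when
three or more observations constrain it.

## Twelve-layer parcellation (TLCO)

The kidney parenchyma is divided into 12 concentric shells by geodesic
depth.  The seed is the mask's outer boundary — every mask pixel
8-adjacent to background — so depth grows inward and layer 1 is the outer
(cortical) shell; a user-supplied seed image overrides this.  Distance is
the 8-connected chamfer metric (axial step 1, diagonal step √2), computed
with a minimum-cost-path search constrained to the mask; paths must go
around concavities such as the hilum, which is exactly why geodesic rather
than Euclidean depth is used.  Binning is

    layer(p) = min(12, floor(12 · d(p)/d_max) + 1),

so d = 0 maps to layer 1 and d = d_max to layer 12.  The chamfer metric
overestimates Euclidean distance by at most ≈ 8% (worst at 22.5°); since
the map is normalised by d_max, that bias largely cancels and the test
suite checks a ≤ 9% depth error against an exact Euclidean transform on a
disk.  Masks too small or thin to populate all 12 layers raise an error
and the subject is flagged and excluded from layer-wise features.

Layer statistics follow the layered-analysis convention: cortical mean =
mean of layer means 1–3, medullary mean = layers 8–10, and the
corticomedullary gradient = OLS slope of layer mean against % depth over
layers 4–7, with layer k placed at its shell midpoint 100·(k−0.5)/12.

## Segmentation

The 3-class convention is kidney / kidney boundary / other tissue.  The
boundary class is the dilation-minus-erosion band of the binary mask (3×3
square element, one iteration each, ≈ 2 px wide); this keeps the class
rare, which is the point — it forces the network to learn the contour.
Class weights default to inverse pixel frequency renormalised to mean 1.

The U-net is implemented directly in NumPy (im2col convolutions with
hand-written backward passes, verified against finite differences): two
3×3 conv + ReLU pairs per level, max-pool encoder, nearest-upsample
decoder with skip concatenation, softmax head with weighted cross-entropy,
Adam at learning rate 1e-4.  Default geometry is 3 encoder levels and
64×64 patches with 8 base channels.  Training patches tile each slice at
stride patch/2; inference slides the same grid and averages class
probabilities over overlaps.  All randomness (init, batch order) flows
from one seed, so training is bit-reproducible.  Dice is 2TP/(2TP+FP+FN)
with the both-empty case defined as 1 to keep the metric total.

## Morphological cleanup

Components are labeled in 3D with 26-connectivity (8-connectivity in 2D);
maximal connectivity avoids splitting a kidney across thin slice bridges.
Components of 2500 pixels or fewer are removed — the threshold is
inclusive, matching the clinical false-positive filter.  The analysis
kidney is the largest surviving 3D component, analysed at its largest-area
slice; exact size ties break toward the smaller centroid column
(deterministic).  Pooling features over all slices is a possible extension
but the single-slice convention is what the rest of the pipeline assumes.

## Registration

All subjects are mapped onto one canonical target mask so that a single
precomputed layer map indexes every warped image; transforms map
target-grid points into the moving image (the resampling direction).

*Affine stage.*  Binary masks are smoothed with a Gaussian (σ = 2 px) to
give the mean-squared-error metric usable gradients, then registered over
a 3-level pyramid (shrink 4/2/1, smoothing 2/1/0) with dense metric
sampling and regular-step gradient descent — fully deterministic.  On
planted transforms this recovers translations to well under 0.5 px and
scale factors to under 1%.

*Demons stage.*  A symmetric-forces demons field (Gaussian field
smoothing σ = 1.5 px, 100 iterations per level, 3 pyramid levels) refines
the affine alignment.  The field is driven by the smoothed masks, not by
the intensity pattern: deformation should carry shape only, because
warping intensities toward a fixed reference image would distort the very
corticomedullary signal being measured, and a generic target mask carries
no intensity.  Two guards apply before the field is accepted: the Jacobian
determinant must be positive on ≥ 99% of target-mask pixels (no folding),
and the warped-mask Dice must not fall below the affine-only Dice.  Either
failure falls back to affine alone with a warning.  Intensities are
resampled linearly, masks nearest-neighbour; pixels outside the warped
mask are NaN and excluded from all statistics.

The target mask is configurable; for phantom studies it is a noiseless
healthy phantom (the analogue of choosing a well-sized reference kidney),
with its layer map and intensity attached.

## Feature scheme

1998 = 3 variants × (4 + 12 + 50 + 600).  The variants are the registered
image and its once- and twice-median-filtered versions; the median filter
is 3×3 and sees only in-mask pixels (NaN-median), so background zeros
never bleed into the kidney.  Histograms have 50 equal-width bins over a
per-subject range — the min–max of the unfiltered masked intensities,
shared by all 13 histograms of all three variants of that subject — and
hold relative frequencies, so neither uncalibrated MR intensity scales nor
kidney size leak into the features.  Kurtosis is excess kurtosis;
zero-variance samples define skewness and kurtosis as 0.  Feature names
(`<variant>/<block>/<index>`) are a stable contract, asserted at import.

## Regression and evaluation

The RSVM uses an RBF kernel with box constraint C = iqr(y)/1.349 (a
robust SD estimate of the response) and tube width ε = iqr(y)/13.49, both
computed on training-fold responses only; a degenerate iqr of 0 floors
both at 1e-3 · mean|y| with a warning.  The kernel width σ is the median
pairwise Euclidean distance over a seeded subsample of ≤ 256 standardized
training rows (γ = 1/2σ²).  Features are standardized with training-fold
mean/SD for the RSVM and left raw for the 300-tree random forest.

Forward stepwise selection greedily adds the feature minimising
cross-validated RMSE.  Plateau steps — improvement below 1e-3 × iqr(y) —
are tolerated for up to 3 consecutive steps and trimmed from the result if
never improved upon; selection also stops at 50 features.  Inside the
subject-based 5-fold evaluation, candidates are first pre-screened to the
64 strongest univariate correlations *within the training fold*; the
screen is a cost control (a full greedy scan over 1998 candidates per step
is quadratic waste) and, living inside the fold, leaks nothing.  A
`leakage_free=False` switch reproduces the optimistic global-selection
variant; the test suite asserts the leakage-free estimate is the smaller
one on null data.  Out-of-fold predictions are pooled for RMSE and
Pearson r (sample formula, N−1 normalisation).

The comparison baseline is OLS on the 12 per-layer mean intensities under
the same grouped folds, with a pseudo-inverse fall-back on rank-deficient
designs.

## Phantom generator

The phantom plants a known truth behind every quantity the pipeline
estimates.  The kidney is an ellipse bent along its major axis (the bend
creates the hilum concavity that separates geodesic from Euclidean
depth), scaled per slice to mimic a through-plane profile, with a default
central slice of ≈ 2000–3400 px so cohort kidneys clear the 2500-px
filter in 3D.  Intensity inside the mask is base + g · 12 · depth, with
depth the normalised geodesic depth and the per-layer step g linked to
the planted eGFR linearly, g = 6.0 · eGFR/90 — the simplest monotone link
for the observation that corticomedullary contrast tracks renal function.
Nuisances are drawn independently per subject: baseline intensity
U[90, 110], additive Gaussian noise σ ∈ U[8, 12], atrophy U[0.8, 1.0],
bend U[0.15, 0.45], and 0–3 dark cysts (discs of zero intensity in the
deep zone).  Cohort images default to 96×96 with semi-axes (34, 20) —
desk-scale sizes; nothing in the pipeline depends on them.  Each subject
also gets a creatinine series from inverting the eGFR equation along a
linear course (visits every 3–6 months over ~2 years, slope U[−5, 1]
clipped to keep eGFR above 5), so the clinical module is exercised
end-to-end; planted values are recovered to the day-rounding error of
visit dates.

What the phantoms do *not* emulate: MR physics (bias fields, coil
profiles, Dixon reconstruction), anatomical texture, inter-observer mask
variability, and any image correlate of the eGFR *slope* — the slope is
planted only in the creatinine series, so image-based slope prediction is
null by construction and slope recovery is validated through the clinical
trajectory fit instead.  Passing the synthetic suite therefore shows the
machinery is correct and the planted signal recoverable; it does not
certify clinical accuracy on patient images.

## Problem sizes and numerical notes

The standard evaluation uses 150 phantom subjects (eGFR ~ U[10, 110]) for
the regression path, 200 random connected masks ≤ 50×50 for exact
layer-map oracle equivalence, and 100 slices at 96×96 for a 10-epoch
U-net run — sizes chosen so the whole suite runs on one CPU in minutes.
Geodesic distances are float64 and the layer binning uses the literal
floor formula; ties at bin edges are resolved identically by
implementation and oracle.  Registration is deterministic (dense metric
sampling, fixed pyramid); SVR and random-forest fits are seeded.  The
demons Dice-monotonicity guarantee is enforced by construction (fallback),
not assumed.
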