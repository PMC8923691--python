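# renaltlco

Automated twelve-layer concentric-object (TLCO) analysis of kidney MRI
water images, for estimating renal function — the estimated glomerular
filtration rate (eGFR) at the time of imaging and its annual slope — from
image structure alone.

Nephrologists read renal MRI qualitatively: a damaged kidney is smaller,
its surface irregular, and the cortex–medulla contrast washed out.  This
package quantifies that reading.  It is aimed at medical-image-analysis
researchers who want a fully automatic, reproducible pipeline from coronal
water-image slices to a cross-validated renal-function estimate, plus a
synthetic phantom generator so every stage can be developed and tested
without patient data.

## Method

Given a subject's slice stack and kidney mask (from the built-in 3-class
U-net or supplied ground truth), the pipeline:

1. **Cleans the segmentation** by 3D connected-component labeling
   (26-connectivity) and removal of components of ≤ 2500 pixels, then picks
   the larger kidney at its largest-area slice.
2. **Registers** that kidney onto a canonical target mask: an affine
   transform (translation/rotation/scale/shear) minimising the
   mean-squared difference of smoothed masks, refined by a demons-style
   displacement field with fold control and a Dice-monotonicity guarantee.
3. **Parcellates** the target mask once into 12 concentric layers by
   normalised geodesic depth: with d(p) the shortest within-mask path
   length to the outer boundary and d_max its maximum,

       layer(p) = min(12, ⌊12 · d(p)/d_max⌋ + 1),

   so layer 1 is the outer cortex and layer 12 the inner medulla.
4. **Extracts 1998 features** per subject: for the registered image and
   its once- and twice-median-filtered variants, the mask-wide mean /
   kurtosis / skewness / median (4), per-layer medians (12), a 50-bin
   mask histogram, and a 50-bin histogram per layer (600) — 3 × 666.
5. **Regresses** the target with an RBF support-vector machine
   (C = iqr(y)/1.349, ε = iqr(y)/13.49, kernel width from a median
   pairwise-distance heuristic), with forward stepwise feature selection
   re-run inside every training fold of a subject-based 5-fold
   cross-validation.  RMSE and Pearson r are reported against a
   12-layer-mean OLS baseline and a 300-tree regression random forest.

Clinical targets come from longitudinal serum creatinine via the
Japanese-cohort equation eGFR = 194 · Cr^(−1.094) · age^(−0.287)
(× 0.739 if female) and an OLS line of eGFR against time in years.

## Worked example

`examples/cohort_regression.py` generates 40 phantoms with planted eGFR
values, runs the full imaging pipeline, and cross-validates the estimator:

```
n = 40 subjects, true eGFR ~ U[10, 110]
stepwise + RSVM : RMSE   8.27   r 0.967
12-layer-mean OLS: RMSE  14.58   r 0.909
features selected (first fold): ['med2/layer_median/12', 'med1/hist/40',
                                 'med2/layer_median/11', 'orig/layer_hist/4_39']
```

RMSE is in mL/min/1.73 m²; r is the pooled out-of-fold Pearson
correlation between estimated and planted eGFR.  The layered-histogram
features beat the plain layer-mean baseline because cysts and noise
distort means more than medians and histogram shapes.  The other examples
cover the clinical trajectory fit, the layer map and corticomedullary
statistics, single-subject registration, and U-net training.

A command-line interface mirrors the pipeline
(`renaltlco simulate | clean-mask | tlco | train-seg | segment | run-all`).

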