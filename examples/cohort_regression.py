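"""Small end-to-end cohort study: phantoms -> features -> cross-validated eGFR.

Generates 40 phantom subjects with planted eGFR values, runs the imaging
pipeline (mask bypass), and compares the stepwise + RSVM estimator against
the 12-layer-mean OLS baseline under subject-based 5-fold CV.
"""

from renaltlco import make_target_mask
from renaltlco.modeling import CvConfig, multiple_regression_baseline, subject_cv_evaluate
from renaltlco.phantom import generate_cohort
from renaltlco.pipeline import extract_cohort_features

subjects = generate_cohort(40, rng_seed=5)
target = make_target_mask(image_size=(96, 96), kidney_axes=(34.0, 20.0), bend=0.3)
features, layer_means, targets = extract_cohort_features(subjects, target)
y = targets["egfr_at_imaging"]

report = subject_cv_evaluate(features, y, CvConfig(rng_seed=5))
baseline = multiple_regression_baseline(layer_means.to_numpy(), y.to_numpy(), rng_seed=5)

print(f"n = {report.n} subjects, true eGFR ~ U[10, 110]")
print(f"stepwise + RSVM : RMSE {report.rmse:6.2f}   r {report.pearson_r:.3f}")
print(f"12-layer-mean OLS: RMSE {baseline.rmse:6.2f}   r {baseline.pearson_r:.3f}")
print(f"features selected (first fold): {report.per_fold[0]['selected']}")
print(
    "\nRMSE is in mL/min/1.73 m^2; the richer layered-histogram features beat\n"
    "the layer-mean baseline because cysts and noise distort plain means."
)
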