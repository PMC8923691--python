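"""End-to-end orchestration: images -> features -> cross-validated report.

The stages mirror the clinical workflow: (optional) segmentation, 3D
labeling + size filtering, selection of the analysis kidney, registration
onto the canonical target mask, feature extraction against the target's
precomputed 12-layer map, and subject-based cross-validated regression.
Segmentation may be bypassed with ground-truth masks so the geometric and
statistical stages are testable without a trained network.

Every run is reproducible from one master seed plus the serialized config;
all stage randomness is derived from it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphology
from .clinical import fit_trajectory
from .features import N_FEATURES, extract_features, feature_names
from .image_io import TargetMask, read_manifest, read_mask, read_volume
from .modeling import CvConfig, EvaluationReport, multiple_regression_baseline, subject_cv_evaluate
from .phantom import CohortSubject, generate_cohort, make_target_mask
from .registration import register_subject
from .tlco import layer_statistics

__all__ = ["PipelineConfig", "SubjectFeatures", "extract_cohort_features", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One file of knobs for a full run (serialized into the run directory)."""

    out_dir: str = "runs/run0"
    input_dir: str | None = None  # None -> simulate a phantom cohort
    n_subjects: int = 150
    seed: int = 0
    target_variable: str = "egfr"  # "egfr" | "slope"
    model: str = "rsvm"  # "rsvm" | "rrf"
    use_demons: bool = True
    mask_bypass: bool = True  # use ground-truth masks instead of the U-net
    size_threshold: int = morphology.SIZE_THRESHOLD
    n_folds: int = 5

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SubjectFeatures:
    """Per-subject products of the imaging stages."""

    subject_id: str
    features: np.ndarray  # (1998,)
    layer_means: np.ndarray  # (12,)
    dice_affine: float
    dice_final: float
    analysis_slice: int
    side: str


def process_subject(
    subject_id: str,
    volume_slices: np.ndarray,
    binary_mask: np.ndarray,
    target: TargetMask,
    use_demons: bool = True,
    size_threshold: int = morphology.SIZE_THRESHOLD,
) -> SubjectFeatures:
    """Morphology -> registration -> features for one subject volume."""
    cleaned = morphology.clean_mask(binary_mask, threshold=size_threshold)
    slice_mask, slice_idx, side = morphology.select_analysis_kidney(cleaned)
    intensity = volume_slices[slice_idx]
    registered = register_subject(intensity, slice_mask, target, use_demons=use_demons)
    if target.layers is None:
        raise ValueError("target mask must carry a precomputed layer map")
    image = np.where(registered.mask, registered.image, 0.0)
    vec = extract_features(image, registered.mask, target.layers)
    stats = layer_statistics(
        np.where(registered.mask, image, np.nan),
        np.where(registered.mask, target.layers, 0),
    )
    return SubjectFeatures(
        subject_id=subject_id,
        features=vec,
        layer_means=stats.per_layer_means,
        dice_affine=registered.dice_affine,
        dice_final=registered.dice_final,
        analysis_slice=slice_idx,
        side=side,
    )


def extract_cohort_features(
    subjects: list[CohortSubject],
    target: TargetMask,
    use_demons: bool = True,
    size_threshold: int = morphology.SIZE_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the imaging stages over a cohort (mask bypass).

    Returns (features, layer_means, targets) DataFrames indexed by subject
    id.  Subjects whose warped kidney leaves a layer empty are flagged and
    excluded (the small-kidney policy) with a log message.
    """
    feats, layers, targets = {}, {}, {}
    for s in subjects:
        sid = s.record.subject_id
        try:
            sf = process_subject(
                sid, s.phantom.volume.slices, s.phantom.mask.binary, target,
                use_demons=use_demons, size_threshold=size_threshold,
            )
        except ValueError as exc:
            log.warning("subject %s excluded: %s", sid, exc)
            continue
        feats[sid] = sf.features
        layers[sid] = sf.layer_means
        fitted = fit_trajectory(s.record)
        targets[sid] = {
            "egfr_at_imaging": fitted.egfr_at_imaging,
            "egfr_slope": fitted.egfr_slope,
            "true_egfr": s.target.egfr_at_imaging,
            "true_slope": s.target.egfr_slope,
            "dice_final": sf.dice_final,
        }
    features_df = pd.DataFrame.from_dict(feats, orient="index", columns=feature_names())
    layer_df = pd.DataFrame.from_dict(
        layers, orient="index", columns=[f"layer_mean/{k}" for k in range(1, 13)]
    )
    targets_df = pd.DataFrame.from_dict(targets, orient="index")
    return features_df, layer_df, targets_df


def _load_subjects(input_dir: Path) -> list[CohortSubject]:
    from .phantom import Phantom, PhantomSpec  # layout matches write_cohort

    records = read_manifest(input_dir / "manifest.csv")
    subjects = []
    for record in records:
        sid = record.subject_id
        volume = read_volume(input_dir / f"{sid}_water.nii.gz", sid)
        mask = read_mask(input_dir / f"{sid}_mask.nii.gz", sid)
        ph = Phantom(volume, mask, seed=np.zeros(volume.slices.shape[1:], bool),
                     depth=np.full(volume.slices.shape, np.nan),
                     analysis_slice=0, spec=PhantomSpec(subject_id=sid))
        subjects.append(CohortSubject(ph, record, fit_trajectory(record)))
    return subjects


def run_pipeline(config: PipelineConfig) -> EvaluationReport:
    """Execute the full pipeline and write artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if config.input_dir is not None:
        input_dir = Path(config.input_dir)
        if not input_dir.exists():
            raise FileNotFoundError(f"input directory {input_dir} does not exist")
        subjects = _load_subjects(input_dir)
    else:
        subjects = generate_cohort(config.n_subjects, rng_seed=config.seed)
    log.info("stage=cohort n=%d elapsed=%.1fs", len(subjects), time.time() - t0)

    target = make_target_mask(image_size=subjects[0].phantom.volume.slices.shape[1:])
    features_df, layer_df, targets_df = extract_cohort_features(
        subjects, target, use_demons=config.use_demons, size_threshold=config.size_threshold
    )
    log.info("stage=features n=%d elapsed=%.1fs", len(features_df), time.time() - t0)

    column = "egfr_at_imaging" if config.target_variable == "egfr" else "egfr_slope"
    y = targets_df[column]
    report = subject_cv_evaluate(
        features_df, y,
        CvConfig(n_folds=config.n_folds, rng_seed=config.seed, model=config.model),
    )
    baseline = None
    if len(y) > 13:  # OLS on 12 layer means needs n > parameters
        baseline = multiple_regression_baseline(
            layer_df.to_numpy(), y.to_numpy(), n_folds=config.n_folds, rng_seed=config.seed
        )
    log.info("stage=model rmse=%.3f r=%.3f elapsed=%.1fs", report.rmse, report.pearson_r, time.time() - t0)

    features_df.to_csv(out / "features.csv")
    targets_df.to_csv(out / "targets.csv")
    summary = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_subjects": int(report.n),
        "rmse": report.rmse,
        "pearson_r": report.pearson_r,
        "baseline_ols12_rmse": baseline.rmse if baseline else None,
        "baseline_ols12_r": baseline.pearson_r if baseline else None,
        "selected_features": report.selected_features,
        "per_fold": report.per_fold,
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2))
    return report
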