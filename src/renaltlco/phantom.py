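"""Synthetic kidney phantoms with a known ("planted") renal function.

Real water images show the kidney parenchyma bright against suppressed fat,
with a cortex-to-medulla intensity gradient that fades as chronic damage
progresses.  The phantom emulates exactly that mechanism: a bean-shaped mask
(an ellipse bent along its major axis, so the hilum concavity makes geodesic
depth differ from Euclidean depth), an intensity ramp along true concentric
depth whose steepness encodes a chosen "true eGFR" through a linear link

    gradient_per_layer = g0 * true_egfr / 90,

plus the nuisances clinical images carry: atrophy (smaller kidneys), dark
cysts, a varying baseline intensity, and additive Gaussian noise.  A matched
creatinine time series is produced by inverting the eGFR equation at each
visit date, so the clinical module can be exercised end-to-end.

The phantom does not attempt physical MR realism (coil profiles, bias
fields, Dixon reconstruction); it is a testbed for the geometric and
statistical machinery, not a signal simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .clinical import RenalFunctionTarget, SubjectRecord, invert_egfr
from .image_io import MaskVolume, TargetMask, VolumeImage, write_manifest, write_mask, write_volume
from .tlco import compute_layer_map, geodesic_distance, outer_boundary

__all__ = [
    "PhantomSpec",
    "Phantom",
    "CohortSubject",
    "generate_phantom",
    "generate_cohort",
    "make_target_mask",
    "write_cohort",
]

#: intensity increase per concentric layer for a healthy (eGFR 90) kidney
GRADIENT_AT_90 = 6.0
#: reference eGFR of the linear gradient link
EGFR_REF = 90.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic kidney image volume."""

    subject_id: str = "phantom"
    true_egfr: float = 90.0  # mL/min/1.73 m^2
    image_size: tuple[int, int] = (128, 128)
    kidney_axes: tuple[float, float] = (42.0, 26.0)  # semi-axes, pixels
    bend: float = 0.35  # hilum curvature, 0 = plain ellipse
    atrophy: float = 1.0  # linear shrink factor in (0, 1]
    cyst_count: int = 0
    noise_sigma: float = 0.0  # additive Gaussian, intensity units
    base_intensity: float = 100.0
    gradient_scale: float = GRADIENT_AT_90  # g0 of the eGFR link
    slice_count: int = 3
    rng_seed: int = 0

    @property
    def gradient_per_layer(self) -> float:
        """Planted per-layer intensity step (the monotone eGFR link)."""
        return self.gradient_scale * self.true_egfr / EGFR_REF


@dataclass
class Phantom:
    """A rendered phantom plus its ground truth."""

    volume: VolumeImage
    mask: MaskVolume
    seed: np.ndarray  # outer-boundary seed of the analysis slice
    depth: np.ndarray  # noiseless normalised depth in [0,1], NaN outside mask
    analysis_slice: int
    spec: PhantomSpec


@dataclass
class CohortSubject:
    phantom: Phantom
    record: SubjectRecord
    target: RenalFunctionTarget


def _bean_mask(shape, axes, bend, scale=1.0) -> np.ndarray:
    """Ellipse of semi-axes ``axes`` bent along the major (row) axis."""
    a, b = axes[0] * scale, axes[1] * scale
    rows, cols = shape
    r = (np.arange(rows) - (rows - 1) / 2.0)[:, None]
    c = (np.arange(cols) - (cols - 1) / 2.0)[None, :]
    u = r / a
    v = (c - bend * b * (r / a) ** 2) / b
    return (u**2 + v**2) <= 1.0


def _slice_scales(n: int) -> np.ndarray:
    """Through-plane size profile: largest at the central slice."""
    if n == 1:
        return np.array([1.0])
    pos = (np.arange(n) - (n - 1) / 2.0) / ((n + 1) / 2.0)
    return np.sqrt(np.maximum(0.25, 1.0 - pos**2))


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render one phantom volume, mask, seed and ground-truth depth field."""
    if not (0 < spec.atrophy <= 1):
        raise ValueError("atrophy must lie in (0, 1]")
    if spec.slice_count < 1:
        raise ValueError("slice_count must be >= 1")
    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.image_size
    scales = _slice_scales(spec.slice_count) * spec.atrophy
    masks = np.stack([_bean_mask(shape, spec.kidney_axes, spec.bend, s) for s in scales])
    mid = int(np.argmax(scales))

    occupied = np.argwhere(masks.any(axis=0))
    if occupied.size == 0:
        raise ValueError("kidney mask is empty; axes/atrophy too small")
    lo, hi = occupied.min(axis=0), occupied.max(axis=0)
    if (lo < 4).any() or (hi >= np.array(shape) - 4).any():
        raise ValueError("kidney does not fit inside the image with a 4-pixel margin")

    depth = np.full(masks.shape, np.nan)
    intensity = np.zeros(masks.shape)
    for s in range(spec.slice_count):
        m = masks[s]
        if not m.any():
            continue
        d = geodesic_distance(m, outer_boundary(m))[m]
        dn = d / max(float(d.max()), 1.0)
        depth[s][m] = dn
        intensity[s][m] = spec.base_intensity + spec.gradient_per_layer * 12.0 * dn

    # cysts: dark discs planted in the deep (medullary) zone of every slice
    if spec.cyst_count:
        deep = np.argwhere(np.nan_to_num(depth[mid], nan=-1) > 0.35)
        rr = np.arange(shape[0])[:, None]
        cc = np.arange(shape[1])[None, :]
        for _ in range(spec.cyst_count):
            if deep.size == 0:
                break
            cy, cx = deep[rng.integers(len(deep))]
            radius = rng.uniform(2.0, max(2.5, 0.12 * min(spec.kidney_axes) * spec.atrophy))
            disc = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
            intensity[:, disc] = np.where(masks[:, disc], 0.0, intensity[:, disc])

    if spec.noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sigma, size=intensity.shape)

    volume = VolumeImage(spec.subject_id, intensity)
    mask = MaskVolume(spec.subject_id, masks.astype(np.int16))
    seed = outer_boundary(masks[mid])
    return Phantom(volume, mask, seed, depth, mid, spec)


def make_target_mask(
    image_size=(128, 128), kidney_axes=(42.0, 26.0), bend=0.35
) -> TargetMask:
    """Canonical registration target: a noiseless healthy phantom.

    Mirrors the clinical choice of a well-sized reference kidney; carries the
    precomputed 12-layer map so one parcellation indexes every warped
    subject, and the noiseless intensity image for intensity-driven
    refinement.
    """
    spec = PhantomSpec(
        subject_id="target",
        true_egfr=EGFR_REF,
        image_size=image_size,
        kidney_axes=kidney_axes,
        bend=bend,
        slice_count=1,
    )
    ph = generate_phantom(spec)
    mask2d = ph.mask.labels[0] > 0
    return TargetMask(
        mask=mask2d,
        seed=outer_boundary(mask2d),
        layers=compute_layer_map(mask2d),
        intensity=ph.volume.slices[0],
    )


_IMAGING_DATE = date(2021, 6, 1)


def _creatinine_series(
    rng: np.random.Generator, true_egfr: float, slope: float, age: float, sex: str
) -> tuple[list[tuple[date, float]], float]:
    """Visit dates + creatinine exactly consistent with a linear eGFR course.

    Visits every 3-6 months over ~2 years around imaging (the clinical
    sampling cadence); the slope is clipped so eGFR stays above 5 over the
    window.
    """
    offsets = [-1.5]
    while offsets[-1] < 0.5:
        offsets.append(offsets[-1] + rng.uniform(0.25, 0.5))
    offsets = np.array(offsets)
    span = max(abs(offsets.min()), abs(offsets.max()))
    if true_egfr + slope * span < 5.0 or true_egfr - slope * span < 5.0:
        slope = float(np.sign(slope)) * (true_egfr - 5.0) / span
    obs = []
    for t in offsets:
        egfr_t = true_egfr + slope * t
        d = _IMAGING_DATE + timedelta(days=round(t * 365.25))
        obs.append((d, invert_egfr(egfr_t, age, sex)))
    return obs, slope


def generate_cohort(
    n: int,
    egfr_range: tuple[float, float] = (10.0, 110.0),
    rng_seed: int = 0,
    image_size: tuple[int, int] = (96, 96),
    kidney_axes: tuple[float, float] = (34.0, 20.0),
    bend_range: tuple[float, float] = (0.15, 0.45),
    atrophy_range: tuple[float, float] = (0.8, 1.0),
    cyst_counts: tuple[int, ...] = (0, 1, 2, 3),
    noise_sigma_range: tuple[float, float] = (8.0, 12.0),
    base_intensity_range: tuple[float, float] = (90.0, 110.0),
    slope_range: tuple[float, float] = (-5.0, 1.0),
) -> list[CohortSubject]:
    """Draw a cohort of phantoms with planted eGFR and eGFR-slope targets.

    ``true_egfr`` is uniform over ``egfr_range``; every nuisance (size,
    bend, atrophy, cysts, noise, baseline) is drawn independently so no
    single confounder encodes the response.  Each subject also carries a
    synthetic creatinine series whose trajectory line passes exactly through
    (imaging date, true eGFR) with the drawn annual slope.
    """
    if n < 2:
        raise ValueError("cohort size must be >= 2")
    for name, rng_pair in [("egfr_range", egfr_range), ("noise_sigma_range", noise_sigma_range)]:
        if rng_pair[1] < rng_pair[0]:
            raise ValueError(f"empty {name}")
    rng = np.random.default_rng(rng_seed)
    subjects = []
    for i in range(n):
        true_egfr = float(rng.uniform(*egfr_range))
        spec = PhantomSpec(
            subject_id=f"S{i:04d}",
            true_egfr=true_egfr,
            image_size=image_size,
            kidney_axes=kidney_axes,
            bend=float(rng.uniform(*bend_range)),
            atrophy=float(rng.uniform(*atrophy_range)),
            cyst_count=int(rng.choice(cyst_counts)),
            noise_sigma=float(rng.uniform(*noise_sigma_range)),
            base_intensity=float(rng.uniform(*base_intensity_range)),
            rng_seed=int(rng.integers(2**31)),
        )
        phantom = generate_phantom(spec)
        age = float(rng.integers(30, 81))
        sex = "female" if rng.random() < 0.4 else "male"
        obs, slope = _creatinine_series(rng, true_egfr, float(rng.uniform(*slope_range)), age, sex)
        record = SubjectRecord(
            subject_id=spec.subject_id,
            sex=sex,
            age=age,
            imaging_date=_IMAGING_DATE,
            observations=obs,
        )
        target = RenalFunctionTarget(egfr_at_imaging=true_egfr, egfr_slope=slope)
        subjects.append(CohortSubject(phantom, record, target))
    return subjects


def write_cohort(subjects: list[CohortSubject], outdir: str | Path) -> None:
    """Materialise a cohort in the NIfTI + manifest layout ``image_io`` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        sid = s.record.subject_id
        write_volume(s.phantom.volume, outdir / f"{sid}_water.nii.gz")
        write_mask(s.phantom.mask, outdir / f"{sid}_mask.nii.gz")
    write_manifest([s.record for s in subjects], outdir / "manifest.csv")
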