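"""Reading and writing image volumes, masks, and subject manifests.

On-disk conventions
-------------------
Volumes and masks are stored as NIfTI (``.nii``/``.nii.gz``) with the array
laid out ``(slice, row, col)``.  Stacks of equally sized PNG/TIFF slices are
also accepted on read (lexicographic file order defines slice order), because
the phantom generator can emit them.  Manifests are long-format CSV with one
creatinine observation per row::

    subject_id,sex,age,imaging_date,obs_date,creatinine

Intensities are never rescaled on read; normalisation is an explicit
feature-extraction step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "VolumeImage",
    "MaskVolume",
    "TargetMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_manifest",
    "write_manifest",
]

_SLICE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class VolumeImage:
    """A subject's stack of coronal grayscale slices.

    ``slices`` has axes ``(slice, row, col)`` and holds raw MR-style
    intensities as floats; ``pixel_spacing_mm`` is (row, col) spacing.
    """

    subject_id: str
    slices: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a 3D (slice, row, col) array")
        if not (1 <= self.slices.shape[0] <= 64):
            raise ValueError("slice count must be in [1, 64]")
        if min(self.slices.shape[1:]) < 16:
            raise ValueError("row/col extents must be >= 16")
        if not np.all(np.isfinite(self.slices)):
            raise ValueError("intensities must be finite")
        if min(self.pixel_spacing_mm) <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def slice_count(self) -> int:
        return int(self.slices.shape[0])


@dataclass
class MaskVolume:
    """Integer label volume paired with a :class:`VolumeImage`.

    Labels are 0 (other tissue), 1 (kidney) and, for the 3-class
    segmentation convention, 2 (kidney boundary).
    """

    subject_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer) and labels.dtype != bool:
            raise ValueError("mask labels must be integer-valued")
        labels = labels.astype(np.int16, copy=False)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3D (slice, row, col) array")
        if not np.isin(np.unique(labels), (0, 1, 2)).all():
            raise ValueError("mask label values must be a subset of {0, 1, 2}")
        self.labels = labels

    @property
    def binary(self) -> np.ndarray:
        """Kidney support (labels 1 and 2 merged)."""
        return self.labels > 0


@dataclass
class TargetMask:
    """Canonical kidney mask every subject is registered onto.

    ``seed`` marks the origin of the geodesic layering (by default the outer
    boundary of ``mask``); ``layers`` caches the 12-layer parcellation so one
    layer map indexes every warped subject.  ``intensity`` optionally carries
    the canonical image the mask was taken from.
    """

    mask: np.ndarray
    seed: np.ndarray | None = None
    layers: np.ndarray | None = None
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("target mask must be 2D")
        if self.seed is not None:
            self.seed = np.asarray(self.seed).astype(bool)
            if self.seed.shape != self.mask.shape:
                raise ValueError("seed shape must match mask shape")


def _read_slice_dir(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES
    )
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF slices under {path}")
    slices = [np.asarray(Image.open(f), dtype=np.float64) for f in files]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"ragged slice shapes under {path}: {sorted(shapes)}")
    if slices[0].ndim != 2:
        raise ValueError("slice images must be single-channel grayscale")
    return np.stack(slices)


def read_volume(path: str | Path, subject_id: str | None = None) -> VolumeImage:
    """Read a NIfTI volume or a directory of grayscale slices."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        data = _read_slice_dir(path)
        spacing = (1.0, 1.0)
    else:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim == 2:
            data = data[None]
        zooms = img.header.get_zooms()
        spacing = (float(zooms[1]), float(zooms[2])) if len(zooms) >= 3 else (1.0, 1.0)
    return VolumeImage(subject_id or path.stem.split(".")[0], data, spacing)


def write_volume(volume: VolumeImage, path: str | Path) -> None:
    """Write a volume as NIfTI, (slice, row, col) layout, float64."""
    path = Path(path)
    affine = np.diag([1.0, volume.pixel_spacing_mm[0], volume.pixel_spacing_mm[1], 1.0])
    nib.save(nib.Nifti1Image(volume.slices.astype(np.float64), affine), str(path))


def read_mask(path: str | Path, subject_id: str | None = None) -> MaskVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.all(data == np.round(data)):
        raise ValueError(f"mask file {path} holds non-integer values")
    data = np.round(data).astype(np.int16)
    if data.ndim == 2:
        data = data[None]
    return MaskVolume(subject_id or path.stem.split(".")[0], data)


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), np.eye(4)), str(Path(path)))


def _parse_date(value: str) -> date:
    return datetime.strptime(str(value).strip(), "%Y-%m-%d").date()


def read_manifest(path: str | Path) -> list["SubjectRecord"]:
    """Read a long-format manifest CSV into per-subject records.

    Rows sharing a ``subject_id`` are merged into one record; observations
    are sorted by date.  Raises ``ValueError`` naming the offending row for
    non-numeric creatinine.
    """
    from .clinical import SubjectRecord

    df = pd.read_csv(path, dtype={"subject_id": str, "sex": str})
    required = {"subject_id", "sex", "age", "imaging_date", "obs_date", "creatinine"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    cr = pd.to_numeric(df["creatinine"], errors="coerce")
    if cr.isna().any():
        bad = int(np.flatnonzero(cr.isna().to_numpy())[0])
        raise ValueError(f"non-numeric creatinine in manifest row {bad}")
    records = []
    for sid, grp in df.groupby("subject_id", sort=True):
        obs = sorted(
            (_parse_date(d), float(c))
            for d, c in zip(grp["obs_date"], pd.to_numeric(grp["creatinine"]))
        )
        records.append(
            SubjectRecord(
                subject_id=str(sid),
                sex=str(grp["sex"].iloc[0]).strip().lower(),
                age=float(grp["age"].iloc[0]),
                imaging_date=_parse_date(grp["imaging_date"].iloc[0]),
                observations=obs,
            )
        )
    return records


def write_manifest(records: list["SubjectRecord"], path: str | Path) -> None:
    rows = []
    for r in records:
        for d, c in r.observations:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "sex": r.sex,
                    "age": r.age,
                    "imaging_date": r.imaging_date.isoformat(),
                    "obs_date": d.isoformat(),
                    "creatinine": c,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
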