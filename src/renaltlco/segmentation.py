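"""3-class kidney segmentation (kidney / kidney boundary / other tissue).

A U-net is trained on square patches of water-image slices with a weighted
cross-entropy loss: the boundary class is a thin morphological band, so its
pixel frequency is tiny and inverse-frequency class weights compensate for
the imbalance.  Full-slice inference assembles sliding-window patch
predictions with probability averaging over overlaps.

The whole pipeline also accepts ground-truth masks in place of model output
(the "mask bypass"), so downstream stages stay testable without a trained
model.  The network itself lives in :mod:`renaltlco._unet` and runs on
plain NumPy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._unet import UNet, adam_step, softmax_weighted_ce
from .image_io import MaskVolume, VolumeImage

__all__ = [
    "UnetConfig",
    "UnetModel",
    "SegmentationResult",
    "make_boundary_class",
    "train_unet",
    "segment",
    "dice_coefficient",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


def make_boundary_class(mask: MaskVolume) -> MaskVolume:
    """Binary kidney mask -> 3-class labels with a thin boundary band.

    The boundary (class 2) is the dilation-minus-erosion band of the kidney
    with a 3x3 square element, one iteration each (about 2 px wide, one
    inside and one outside the contour).  Class 1 is the kidney interior
    minus the band; class 0 the rest.  The classes partition every slice.
    """
    out = np.zeros_like(mask.labels)
    for s in range(mask.labels.shape[0]):
        binary = mask.labels[s] > 0
        dil = ndimage.binary_dilation(binary, structure=_SQUARE3)
        ero = ndimage.binary_erosion(binary, structure=_SQUARE3, border_value=0)
        band = dil & ~ero
        out[s][ero] = 1
        out[s][band] = 2
    return MaskVolume(mask.subject_id, out)


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice = 2TP / (2TP + FP + FN); two empty masks agree perfectly (1)."""
    pred = np.asarray(pred) > 0
    truth = np.asarray(truth) > 0
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    tp = int((pred & truth).sum())
    denom = 2 * tp + int((pred & ~truth).sum()) + int((~pred & truth).sum())
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


@dataclass
class UnetConfig:
    """Training configuration; defaults follow the 3-level / 64x64 setup."""

    depth: int = 3
    patch_size: int = 64
    classes: int = 3
    learning_rate: float = 1e-4
    epochs: int = 50
    class_weights: np.ndarray | None = None  # default: inverse frequency
    base_channels: int = 8
    batch_size: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.depth <= 4:
            raise ValueError("depth must be 2, 3, or 4")
        if self.patch_size % (2**self.depth) != 0:
            raise ValueError("patch_size must be divisible by 2**depth")
        if self.class_weights is not None:
            cw = np.asarray(self.class_weights, dtype=float)
            if cw.shape != (self.classes,) or not np.all(np.isfinite(cw)) or (cw <= 0).any():
                raise ValueError("class_weights must be positive, finite, one per class")
            self.class_weights = cw


@dataclass
class UnetModel:
    """Trained network plus its config and per-epoch loss trace."""

    net: UNet
    config: UnetConfig
    class_weights: np.ndarray
    loss_trace: list[float]
    intensity_scale: float  # training-set normalisation divisor


@dataclass
class SegmentationResult:
    labels: np.ndarray  # (slice, H, W) argmax classes
    probabilities: np.ndarray  # (slice, classes, H, W), summing to 1 per pixel

    @property
    def kidney_mask(self) -> np.ndarray:
        """Kidney support: kidney class plus boundary class."""
        return (self.labels == 1) | (self.labels == 2)


def _patch_grid(extent: int, patch: int, stride: int) -> list[int]:
    """Window origins covering [0, extent) including a flush last window."""
    pos = list(range(0, extent - patch + 1, stride))
    if pos[-1] != extent - patch:
        pos.append(extent - patch)
    return pos


def _extract_patches(slices, labels, patch, stride):
    xs, ys = [], []
    for img, lab in zip(slices, labels):
        for r in _patch_grid(img.shape[0], patch, stride):
            for c in _patch_grid(img.shape[1], patch, stride):
                xs.append(img[r : r + patch, c : c + patch])
                ys.append(lab[r : r + patch, c : c + patch])
    return np.stack(xs), np.stack(ys)


def train_unet(
    images: list[VolumeImage], labels: list[MaskVolume], config: UnetConfig | None = None
) -> UnetModel:
    """Train the 3-class U-net on all slices of the given volumes.

    Deterministic for a fixed ``config.rng_seed``.  Labels must already
    carry the 3-class convention (see :func:`make_boundary_class`).
    """
    config = config or UnetConfig()
    all_slices = [s for v in images for s in v.slices]
    all_labels = [s for m in labels for s in m.labels]
    if not all_slices:
        raise ValueError("at least one labelled slice is required")
    if any(min(s.shape) < config.patch_size for s in all_slices):
        raise ValueError("patch_size exceeds a training slice")

    scale = float(max(np.abs(s).max() for s in all_slices)) or 1.0
    x, y = _extract_patches(
        [s / scale for s in all_slices], all_labels, config.patch_size, config.patch_size // 2
    )
    y = y.astype(np.int64)

    if config.class_weights is None:
        freq = np.bincount(y.ravel(), minlength=config.classes) / y.size
        inv = 1.0 / np.maximum(freq, 1e-6)
        weights = inv / inv.mean()
    else:
        weights = config.class_weights

    rng = np.random.default_rng(config.rng_seed)
    net = UNet(
        depth=config.depth, in_ch=1, classes=config.classes,
        base_channels=config.base_channels, rng_seed=config.rng_seed,
    )
    opt = adam_step(net, lr=config.learning_rate)
    trace = []
    for _ in range(config.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = net.forward(x[idx][:, None])
            loss, dlogits = softmax_weighted_ce(logits, y[idx], weights)
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return UnetModel(net, config, weights, trace, scale)


def segment(model: UnetModel, volume: VolumeImage) -> SegmentationResult:
    """Full-slice 3-class prediction by overlapping sliding windows."""
    if not isinstance(model, UnetModel):
        raise TypeError("segment() needs a trained UnetModel")
    patch = model.config.patch_size
    stride = patch // 2
    if min(volume.slices.shape[1:]) < patch:
        raise ValueError("slice dimensions are smaller than the patch size")
    probs_out = []
    for img in volume.slices:
        acc = np.zeros((model.config.classes, *img.shape))
        cnt = np.zeros(img.shape)
        scaled = img / model.intensity_scale
        for r in _patch_grid(img.shape[0], patch, stride):
            for c in _patch_grid(img.shape[1], patch, stride):
                p = model.net.predict_proba(scaled[None, None, r : r + patch, c : c + patch])[0]
                acc[:, r : r + patch, c : c + patch] += p
                cnt[r : r + patch, c : c + patch] += 1
        probs_out.append(acc / cnt)
    probs = np.stack(probs_out)
    return SegmentationResult(labels=probs.argmax(axis=1).astype(np.int16), probabilities=probs)
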