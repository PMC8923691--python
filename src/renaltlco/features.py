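"""The 1998-dimensional layered-histogram feature scheme.

Per subject, three image variants are analysed: the registered water image
and the same image median-filtered once and twice (3x3 kernel, restricted to
the kidney mask).  For each variant the features are

==================  =====  ==============================================
block               count  definition
==================  =====  ==============================================
stats                   4  mean, excess kurtosis, skewness, median (mask)
layer_median           12  median intensity of each concentric layer
hist                   50  50-bin relative-frequency histogram of the mask
layer_hist            600  50-bin histogram of each of the 12 layers
==================  =====  ==============================================

3 * (4 + 12 + 50 + 600) = 1998 values.  Histograms share one per-subject
min-max range (taken over the unfiltered masked image) and are relative
frequencies, so kidney size does not leak into the features.  Feature names
follow ``<variant>/<block>/<index>`` with variants ``orig``, ``med1``,
``med2`` and are a stable contract.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from .tlco import N_LAYERS

__all__ = [
    "N_FEATURES",
    "N_BINS",
    "VARIANTS",
    "feature_names",
    "median_variants",
    "histogram_features",
    "extract_features",
]

N_BINS = 50
VARIANTS = ("orig", "med1", "med2")
_BLOCK_SIZES = {"stats": 4, "layer_median": N_LAYERS, "hist": N_BINS, "layer_hist": N_LAYERS * N_BINS}
N_FEATURES = len(VARIANTS) * sum(_BLOCK_SIZES.values())
assert N_FEATURES == 1998, "feature scheme arithmetic changed"

_STAT_NAMES = ("mean", "kurtosis", "skewness", "median")


def feature_names() -> list[str]:
    """The 1998 feature names, in extraction order."""
    names = []
    for variant in VARIANTS:
        names += [f"{variant}/stats/{s}" for s in _STAT_NAMES]
        names += [f"{variant}/layer_median/{k}" for k in range(1, N_LAYERS + 1)]
        names += [f"{variant}/hist/{b}" for b in range(N_BINS)]
        names += [
            f"{variant}/layer_hist/{k}_{b}"
            for k in range(1, N_LAYERS + 1)
            for b in range(N_BINS)
        ]
    return names


def _masked_median_filter(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """3x3 median filter that only sees in-mask pixels.

    Outside-mask neighbours are ignored (NaN-median over the 3x3 window);
    pixels outside the mask pass through unchanged.
    """
    padded = np.full((image.shape[0] + 2, image.shape[1] + 2), np.nan)
    padded[1:-1, 1:-1] = np.where(mask, image, np.nan)
    windows = np.stack(
        [padded[dr : dr + image.shape[0], dc : dc + image.shape[1]] for dr in range(3) for dc in range(3)]
    )
    filtered = image.copy()
    filtered[mask] = np.nanmedian(windows[:, mask], axis=0)
    return filtered


def median_variants(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(original, median-filtered once, median-filtered twice)."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    med1 = _masked_median_filter(image, mask)
    med2 = _masked_median_filter(med1, mask)
    return image, med1, med2


def histogram_features(values: np.ndarray, hist_range: tuple[float, float], bins: int = N_BINS) -> np.ndarray:
    """Equal-width relative-frequency histogram over a declared range.

    Values outside the range fall into the nearest edge bin so frequencies
    always sum to 1.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("empty sample")
    lo, hi = hist_range
    if not hi > lo:
        # degenerate range (constant subject): all mass in the first bin
        out = np.zeros(bins)
        out[0] = 1.0
        return out
    counts, _ = np.histogram(np.clip(values, lo, hi), bins=bins, range=(lo, hi))
    return counts / values.size


def _moment_stats(values: np.ndarray) -> np.ndarray:
    """mean, excess kurtosis, skewness, median; zero-variance -> kurt/skew 0."""
    if np.ptp(values) == 0:
        return np.array([values[0], 0.0, 0.0, values[0]])
    return np.array(
        [
            values.mean(),
            sstats.kurtosis(values, fisher=True, bias=True),
            sstats.skew(values, bias=True),
            np.median(values),
        ]
    )


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    layers: np.ndarray,
    hist_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """The full 1998-value feature vector of one registered subject.

    ``layers`` is the (target-space) 12-layer map; every layer must be
    nonempty over ``mask``.  ``hist_range`` defaults to the per-subject
    min-max of the unfiltered masked intensities.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    layers = np.asarray(layers)
    if not mask.any():
        raise ValueError("empty mask")
    layer_sel = [(layers == k) & mask for k in range(1, N_LAYERS + 1)]
    empty = [k + 1 for k, sel in enumerate(layer_sel) if not sel.any()]
    if empty:
        raise ValueError(f"empty layers over the warped mask: {empty}")
    if hist_range is None:
        inside = image[mask]
        hist_range = (float(inside.min()), float(inside.max()))

    out = []
    for variant in median_variants(image, mask):
        inside = variant[mask]
        out.append(_moment_stats(inside))
        out.append(np.array([np.median(variant[sel]) for sel in layer_sel]))
        out.append(histogram_features(inside, hist_range))
        out.append(np.concatenate([histogram_features(variant[sel], hist_range) for sel in layer_sel]))
    vec = np.concatenate(out)
    assert vec.shape == (N_FEATURES,)
    return vec
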