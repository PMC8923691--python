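"""Twelve-layer concentric-object (TLCO) parcellation by geodesic distance.

The kidney mask is carved into 12 concentric shells: each in-mask pixel gets
the length of the shortest 8-connected path (axial step 1, diagonal step
sqrt(2)) that stays inside the mask and reaches the seed set — by default the
mask's outer boundary, so depth grows inward.  Distances are normalised by
the mask's maximum depth and binned::

    layer(p) = min(12, floor(12 * d(p) / d_max) + 1)

giving layer 1 at the outer (cortical) rim and layer 12 at the core
(medullary side).  Geodesic rather than Euclidean distance matters for
bean-shaped kidneys: depth follows the parenchyma around the hilum instead
of cutting across the concavity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.graph import MCP_Geometric

__all__ = [
    "LayerStatistics",
    "outer_boundary",
    "geodesic_distance",
    "compute_layer_map",
    "layer_statistics",
    "N_LAYERS",
    "layer_depth_percent",
]

N_LAYERS = 12

_EIGHT = np.ones((3, 3), dtype=bool)


def outer_boundary(mask: np.ndarray) -> np.ndarray:
    """Mask pixels 8-adjacent to background (the default layering seed)."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_EIGHT, border_value=0)
    return mask & ~eroded


def geodesic_distance(mask: np.ndarray, seed: np.ndarray) -> np.ndarray:
    """Within-mask shortest-path distance (pixels) to the nearest seed pixel.

    Returns an array shaped like ``mask`` with distances on the mask support
    and ``inf`` outside.  Seed pixels outside the mask are still usable as
    path origins but only in-mask steps are allowed.

    Raises
    ------
    ValueError
        if the seed is empty or some mask pixel cannot be reached (the mask
        is not connected to the seed).
    """
    mask = np.asarray(mask, dtype=bool)
    seed = np.asarray(seed, dtype=bool)
    if mask.shape != seed.shape:
        raise ValueError("mask and seed shapes differ")
    if not seed.any():
        raise ValueError("seed is empty")
    costs = np.where(mask | seed, 1.0, np.inf)
    mcp = MCP_Geometric(costs, fully_connected=True)
    starts = np.argwhere(seed)
    cum, _ = mcp.find_costs(starts)
    dist = np.where(mask | seed, cum, np.inf)
    if not np.isfinite(dist[mask]).all():
        raise ValueError("mask has pixels unreachable from the seed (disconnected)")
    return dist


def compute_layer_map(mask: np.ndarray, seed: np.ndarray | None = None) -> np.ndarray:
    """Concentric layer labels 1..12 over ``mask`` (0 outside).

    ``seed`` defaults to the mask's outer boundary so that layer 1 is the
    outermost shell.  Raises on a degenerate mask whose maximum geodesic
    depth is zero (mask contained in the seed).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if seed is None:
        seed = outer_boundary(mask)
    dist = geodesic_distance(mask, seed)
    d = dist[mask]
    d_max = float(d.max())
    if d_max <= 0:
        raise ValueError("degenerate mask: maximum geodesic depth is 0")
    layers = np.zeros(mask.shape, dtype=np.int16)
    layers[mask] = np.minimum(
        N_LAYERS, np.floor(N_LAYERS * d / d_max).astype(np.int16) + 1
    )
    return layers


def layer_depth_percent(layer: int) -> float:
    """Depth abscissa (% of full depth) of a layer: its shell midpoint."""
    return 100.0 * (layer - 0.5) / N_LAYERS


@dataclass
class LayerStatistics:
    """Corticomedullary summary of a layered intensity image.

    ``cortical_mean`` averages the three superficial layer means (1-3),
    ``medullary_mean`` the deep layers (8-10), and ``gradient`` is the OLS
    slope of layer-mean intensity against % depth fitted on layers 4-7 —
    the corticomedullary contrast that fades with chronic damage.
    """

    per_layer_means: np.ndarray  # shape (12,)
    cortical_mean: float
    medullary_mean: float
    gradient: float  # intensity units per % depth


def layer_statistics(image: np.ndarray, layers: np.ndarray) -> LayerStatistics:
    image = np.asarray(image, dtype=np.float64)
    layers = np.asarray(layers)
    if image.shape != layers.shape:
        raise ValueError("image and layer map shapes differ")
    means = np.empty(N_LAYERS)
    for k in range(1, N_LAYERS + 1):
        sel = layers == k
        if not sel.any():
            raise ValueError(f"layer {k} is empty")
        means[k - 1] = image[sel].mean()
    grad_layers = np.arange(4, 8)
    x = np.array([layer_depth_percent(k) for k in grad_layers])
    y = means[grad_layers - 1]
    slope = np.polyfit(x, y, 1)[0]
    return LayerStatistics(
        per_layer_means=means,
        cortical_mean=float(means[0:3].mean()),
        medullary_mean=float(means[7:10].mean()),
        gradient=float(slope),
    )
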