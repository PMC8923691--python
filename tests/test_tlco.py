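"""Geodesic distances, layer binning, and corticomedullary statistics."""

import heapq

import numpy as np
import pytest
from scipy import ndimage

from conftest import random_connected_mask
from renaltlco.tlco import (
    N_LAYERS,
    compute_layer_map,
    geodesic_distance,
    layer_statistics,
    outer_boundary,
)

SQRT2 = np.sqrt(2.0)


def dijkstra_geodesic(mask: np.ndarray, seed: np.ndarray) -> np.ndarray:
    """Brute-force chamfer-geodesic oracle (heap-based shortest path)."""
    dist = np.full(mask.shape, np.inf)
    heap = []
    for r, c in np.argwhere(seed):
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))
    allowed = mask | seed
    h, w = mask.shape
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and allowed[nr, nc]:
                    nd = d + (SQRT2 if dr and dc else 1.0)
                    if nd < dist[nr, nc] - 1e-12:
                        dist[nr, nc] = nd
                        heapq.heappush(heap, (nd, nr, nc))
    return dist


def test_corridor_distances_are_integers():
    mask = np.zeros((3, 12), dtype=bool)
    mask[1, 1:11] = True
    seed = np.zeros_like(mask)
    seed[1, 1] = True
    d = geodesic_distance(mask, seed)
    assert np.allclose(d[1, 1:11], np.arange(10))


def test_c_shape_geodesic_exceeds_euclidean():
    mask = np.zeros((30, 30), dtype=bool)
    mask[5:25, 5:9] = True  # left arm
    mask[5:9, 5:25] = True  # top arm
    mask[5:25, 21:25] = True  # right arm
    seed = np.zeros_like(mask)
    seed[24, 6] = True  # bottom of left arm
    d = geodesic_distance(mask, seed)
    tip = (24, 23)  # bottom of right arm
    euclid = np.hypot(tip[0] - 24, tip[1] - 6)
    assert d[tip] > euclid + 5
    oracle = dijkstra_geodesic(mask, seed)
    assert np.allclose(d[mask], oracle[mask], atol=1e-9)


def test_disk_boundary_seed_approximates_euclidean_depth():
    yy, xx = np.mgrid[:101, :101]
    mask = (yy - 50) ** 2 + (xx - 50) ** 2 <= 45**2
    d = geodesic_distance(mask, outer_boundary(mask))
    edt = ndimage.distance_transform_edt(
        ndimage.binary_erosion(mask, np.ones((3, 3)))
    )
    inner = edt > 3  # compare away from the discrete rim
    rel = np.abs(d[inner] - edt[inner]) / edt[inner]
    assert rel.max() <= 0.09  # chamfer metric overestimates by <= ~8%


def test_disconnected_mask_raises():
    mask = np.zeros((10, 10), dtype=bool)
    mask[1, 1], mask[8, 8] = True, True
    seed = np.zeros_like(mask)
    seed[1, 1] = True
    with pytest.raises(ValueError, match="unreachable|disconnected"):
        geodesic_distance(mask, seed)


def test_disk_layers_are_concentric_annuli():
    yy, xx = np.mgrid[:131, :131]
    mask = (yy - 65) ** 2 + (xx - 65) ** 2 <= 60**2
    layers = compute_layer_map(mask)
    assert set(np.unique(layers[mask])) == set(range(1, 13))
    assert layers[65, 65] == 12  # center is innermost
    assert layers[outer_boundary(mask)].max() == 1  # rim is layer 1
    # annuli: layer is non-increasing with radius along a ray
    ray = layers[65, 65:125]
    ray = ray[ray > 0]
    assert np.all(np.diff(ray) <= 0)


def test_corridor_24_gives_two_pixels_per_layer():
    mask = np.zeros((3, 26), dtype=bool)
    mask[1, 1:25] = True
    seed = np.zeros_like(mask)
    seed[1, 1] = True
    layers = compute_layer_map(mask, seed)
    # d = 0..23, d_max = 23; layer(p) = min(12, floor(12 d / 23) + 1)
    expect = np.minimum(12, (12 * np.arange(24) // 23) + 1)
    assert np.array_equal(layers[1, 1:25], expect)
    counts = np.bincount(layers[mask], minlength=13)[1:]
    assert counts.sum() == 24 and counts.max() == 2


def test_layer_map_scale_invariance_on_disks():
    def disk(radius, size):
        yy, xx = np.mgrid[:size, :size]
        return (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2

    small = compute_layer_map(disk(24, 60))
    big = compute_layer_map(disk(48, 120))
    # normalisation removes scale: corresponding pixels get the same layer
    # up to the +/-1 bin-edge jitter of the discrete grid
    ys, xs = np.where(disk(24, 60))
    paired = big[60 + 2 * (ys - 30), 60 + 2 * (xs - 30)]
    diff = np.abs(small[ys, xs].astype(int) - paired.astype(int))
    assert diff.max() <= 1
    assert (diff == 0).mean() > 0.8


def test_degenerate_mask_raises():
    mask = np.zeros((8, 8), dtype=bool)
    mask[3, 3] = True
    with pytest.raises(ValueError, match="degenerate|depth"):
        compute_layer_map(mask)


def test_layer_statistics_closed_form():
    # image whose intensity equals the layer index
    yy, xx = np.mgrid[:131, :131]
    mask = (yy - 65) ** 2 + (xx - 65) ** 2 <= 60**2
    layers = compute_layer_map(mask)
    stats = layer_statistics(layers.astype(float), layers)
    assert stats.cortical_mean == pytest.approx(2.0)
    assert stats.medullary_mean == pytest.approx(9.0)
    # slope of layer index vs % depth over layers 4-7: exactly 12/100
    assert stats.gradient == pytest.approx(0.12, abs=1e-12)


def test_layer_statistics_constant_and_shift():
    yy, xx = np.mgrid[:101, :101]
    mask = (yy - 50) ** 2 + (xx - 50) ** 2 <= 45**2
    layers = compute_layer_map(mask)
    const = layer_statistics(np.full(mask.shape, 7.5), layers)
    assert const.gradient == pytest.approx(0.0, abs=1e-12)
    assert const.cortical_mean == const.medullary_mean == 7.5

    rng = np.random.default_rng(5)
    img = rng.normal(size=mask.shape)
    a, b = layer_statistics(img, layers), layer_statistics(img + 3.0, layers)
    assert b.cortical_mean == pytest.approx(a.cortical_mean + 3.0)
    assert b.medullary_mean == pytest.approx(a.medullary_mean + 3.0)
    assert b.gradient == pytest.approx(a.gradient, abs=1e-10)


def test_layer_map_partitions_random_masks():
    rng = np.random.default_rng(20)
    for _ in range(25):
        mask = random_connected_mask(rng)
        try:
            layers = compute_layer_map(mask)
        except ValueError:
            continue  # degenerate blob (all boundary)
        assert np.count_nonzero(layers) == mask.sum()
        assert (layers[~mask] == 0).all()
        d = geodesic_distance(mask, outer_boundary(mask))
        oracle = dijkstra_geodesic(mask, outer_boundary(mask))
        assert np.allclose(d[mask], oracle[mask], atol=1e-9)
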