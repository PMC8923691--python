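"""3D labeling, the 2500-pixel filter, and kidney selection."""

import numpy as np
import pytest

from renaltlco.morphology import (
    clean_mask,
    label_components_3d,
    remove_small_components,
    select_analysis_kidney,
)


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """Brute-force 26-connected components by stack-based flood fill."""
    mask = mask > 0
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp, stack = set(), [start]
        seen[start] = True
        while stack:
            p = stack.pop()
            comp.add(p)
            for off in offsets:
                q = tuple(np.add(p, off))
                if all(0 <= q[i] < mask.shape[i] for i in range(3)):
                    if mask[q] and not seen[q]:
                        seen[q] = True
                        stack.append(q)
        comps.append(comp)
    return comps


def test_two_cubes_counted():
    vol = np.zeros((4, 8, 8), dtype=bool)
    vol[0:2, 0:2, 0:2] = True
    vol[2:4, 5:7, 5:7] = True
    _, sizes = label_components_3d(vol)
    assert sorted(sizes.values()) == [8, 8]


def test_empty_mask_no_components():
    _, sizes = label_components_3d(np.zeros((2, 4, 4), dtype=bool))
    assert sizes == {}


def test_diagonal_touch_merges_under_26_connectivity():
    vol = np.zeros((3, 3, 3), dtype=bool)
    vol[0, 0, 0] = True
    vol[1, 1, 1] = True  # touches only diagonally
    labeled, sizes = label_components_3d(vol)
    assert len(sizes) == 1
    assert len(flood_fill_components(vol)) == 1


def test_size_threshold_is_inclusive():
    # components of sizes 2400, 2500, 2501, 5000: only > 2500 survive
    vol = np.zeros((1, 70, 270), dtype=bool)
    col = 2
    for rows, cols in [(40, 60), (50, 50), (61, 41), (50, 100)]:  # 2400/2500/2501/5000
        vol[0, 2 : 2 + rows, col : col + cols] = True
        col += cols + 3
    labeled, sizes = label_components_3d(vol)
    assert sorted(sizes.values()) == [2400, 2500, 2501, 5000]
    out = remove_small_components(labeled, sizes, threshold=2500)
    surviving = sorted(s for s in np.bincount(labeled[out].ravel()) if s > 0)
    assert surviving == [2501, 5000]


def test_filter_can_empty_mask():
    vol = np.zeros((2, 10, 10), dtype=bool)
    vol[0, :5, :5] = True
    out = clean_mask(vol, threshold=2500)
    assert not out.any()


def test_threshold_zero_is_identity():
    rng = np.random.default_rng(3)
    vol = rng.random((4, 12, 12)) > 0.7
    assert np.array_equal(clean_mask(vol, threshold=0), vol)


def test_filter_is_idempotent_and_shrinking():
    rng = np.random.default_rng(4)
    vol = rng.random((5, 20, 20)) > 0.6
    once = clean_mask(vol, threshold=30)
    twice = clean_mask(once, threshold=30)
    assert np.array_equal(once, twice)
    assert not (once & ~vol).any()  # never adds pixels


def test_labeling_matches_flood_fill_oracle_on_random_volumes():
    rng = np.random.default_rng(7)
    for _ in range(12):
        shape = tuple(rng.integers(3, 17, size=3))
        vol = rng.random(shape) > rng.uniform(0.5, 0.8)
        labeled, sizes = label_components_3d(vol)
        oracle = flood_fill_components(vol)
        assert len(oracle) == len(sizes)
        assert sorted(len(c) for c in oracle) == sorted(sizes.values())
        # filtering equals dropping oracle components by the same rule
        thr = int(rng.integers(1, 10))
        out = clean_mask(vol, threshold=thr)
        expect = np.zeros(shape, dtype=bool)
        for comp in oracle:
            if len(comp) > thr:
                for p in comp:
                    expect[p] = True
        assert np.array_equal(out, expect)


def test_select_larger_kidney_and_slice():
    vol = np.zeros((3, 40, 60), dtype=bool)
    vol[0:3, 5:25, 5:20] = True  # left, 3 * 300 = 900 px
    vol[1, 8:28, 40:55] = True  # right, 300 px
    slice_mask, idx, side = select_analysis_kidney(vol)
    assert side == "left"
    assert slice_mask.sum() == 300 * 1  # one slice of the left block
    assert idx in (0, 1, 2)

    vol2 = np.zeros((3, 40, 60), dtype=bool)
    vol2[1, 5:25, 40:55] = True  # only a right kidney
    m2, idx2, side2 = select_analysis_kidney(vol2)
    assert side2 == "right" and idx2 == 1 and m2.sum() == 300


def test_select_tie_breaks_leftmost():
    vol = np.zeros((1, 20, 40), dtype=bool)
    vol[0, 5:10, 2:7] = True  # left block, 25 px
    vol[0, 5:10, 30:35] = True  # right block, 25 px
    _, _, side = select_analysis_kidney(vol)
    assert side == "left"


def test_select_requires_surviving_component():
    with pytest.raises(ValueError):
        select_analysis_kidney(np.zeros((2, 8, 8), dtype=bool))
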