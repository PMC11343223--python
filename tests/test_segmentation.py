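"""Pillar segmentation, external masks and the perturbation protocol."""

import imageio.v3 as iio
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pillartrack import (
    MaskPair,
    PillarMask,
    SyntheticMovieSpec,
    generate_movie,
    load_external_mask,
    perturb_mask,
    segment_pillars,
)
from pillartrack.errors import MaskError, SegmentationError


def _block_mask(size=64, block=9, side="left"):
    grid = np.zeros((size, size), dtype=bool)
    lo = (size - block) // 2
    grid[lo:lo + block, lo:lo + block] = True
    return PillarMask(raster=grid, side=side)


def test_constant_frame_fails_with_external_mask_hint():
    frame = np.full((64, 64), 100, dtype=np.uint8)
    with pytest.raises(SegmentationError, match="external"):
        segment_pillars(frame)


def test_segmentation_recovers_cap_placement(std_movie, std_masks):
    """Mask centroids fall inside the true cap boxes; sides match construction."""
    _, truth = std_movie
    for mask, true_cap in zip(std_masks, truth.cap_masks):
        r, c = mask.centroid
        rows, cols = np.nonzero(true_cap)
        assert rows.min() <= r <= rows.max()
        assert cols.min() <= c <= cols.max()
    assert std_masks.left.centroid[1] < std_masks.right.centroid[1]


def test_segmentation_jaccard_overlap(std_movie, std_masks):
    """Each mask overlaps its true cap with Jaccard >= 0.5."""
    _, truth = std_movie
    for mask, true_cap in zip(std_masks, truth.cap_masks):
        inter = (mask.raster & true_cap).sum()
        union = (mask.raster | true_cap).sum()
        assert inter / union >= 0.5


def test_segmentation_deterministic(std_movie):
    movie, _ = std_movie
    a = segment_pillars(movie.frames[0])
    b = segment_pillars(movie.frames[0])
    np.testing.assert_array_equal(a.left.raster, b.left.raster)
    np.testing.assert_array_equal(a.right.raster, b.right.raster)


def test_type2_polarity_inversion():
    """Dark pillars on a bright background segment after polarity inversion."""
    movie, truth = generate_movie(
        SyntheticMovieSpec(style="type2", noise_sd=0.01, n_beats=2, seed=21)
    )
    masks = segment_pillars(movie.frames[0], data_type="type2")
    for mask, true_cap in zip(masks, truth.cap_masks):
        inter = (mask.raster & true_cap).sum()
        union = (mask.raster | true_cap).sum()
        assert inter / union >= 0.5


def test_external_mask_text_grid(tmp_path):
    grid = np.zeros((64, 64), dtype=int)
    grid[10:15, 10:15] = 1
    path = tmp_path / "mask.txt"
    np.savetxt(path, grid, fmt="%d")
    mask = load_external_mask(path, side="left", frame_shape=(64, 64))
    assert mask.area == 25


def test_external_mask_rejects_non_binary(tmp_path):
    grid = np.zeros((8, 8), dtype=int)
    grid[2:4, 2:4] = 2
    path = tmp_path / "bad.txt"
    np.savetxt(path, grid, fmt="%d")
    with pytest.raises(MaskError, match="non-binary"):
        load_external_mask(path, side="left")


def test_external_mask_rejects_zero_area(tmp_path):
    path = tmp_path / "zero.txt"
    np.savetxt(path, np.zeros((8, 8), dtype=int), fmt="%d")
    with pytest.raises(MaskError, match="zero area"):
        load_external_mask(path, side="left")


def test_external_mask_shape_mismatch(tmp_path):
    grid = np.zeros((8, 8), dtype=int)
    grid[2:4, 2:4] = 1
    path = tmp_path / "m.txt"
    np.savetxt(path, grid, fmt="%d")
    with pytest.raises(MaskError, match="shape"):
        load_external_mask(path, side="left", frame_shape=(16, 16))


def test_external_mask_binary_png(tmp_path):
    grid = np.zeros((32, 32), dtype=np.uint8)
    grid[5:10, 5:10] = 255
    path = tmp_path / "mask.png"
    iio.imwrite(path, grid)
    mask = load_external_mask(path, side="right")
    assert mask.area == 25


def test_perturb_block_arithmetic():
    """5x5-kernel Minkowski arithmetic on a centered 9x9 block."""
    mask = _block_mask(block=9)
    assert perturb_mask(mask, "erode", 1).area == 25  # 9-4 = 5 per side
    assert perturb_mask(mask, "dilate", 1).area == 13 * 13


def test_perturb_dilation_clips_to_frame():
    grid = np.zeros((11, 11), dtype=bool)
    grid[1:10, 1:10] = True
    dilated = perturb_mask(PillarMask(raster=grid, side="left"), "dilate", 1)
    assert dilated.area == 11 * 11


def test_over_erosion_is_an_error():
    mask = _block_mask(block=5)
    with pytest.raises(MaskError, match="emptied"):
        perturb_mask(mask, "erode", 4)


@settings(max_examples=20, deadline=None)
@given(
    block=st.integers(min_value=6, max_value=20),
    row=st.integers(min_value=10, max_value=30),
    col=st.integers(min_value=10, max_value=30),
)
def test_morphological_duality(block, row, col):
    """erode(dilate(M)) ⊇ M and dilate(erode(M)) ⊆ M for the same kernel."""
    grid = np.zeros((64, 64), dtype=bool)
    grid[row:row + block, col:col + block] = True
    mask = PillarMask(raster=grid, side="left")
    closed = perturb_mask(perturb_mask(mask, "dilate", 1), "erode", 1)
    opened = perturb_mask(perturb_mask(mask, "erode", 1), "dilate", 1)
    assert np.all(closed.raster >= mask.raster)
    assert np.all(opened.raster <= mask.raster)


def test_mask_pair_invariants(std_masks):
    with pytest.raises(MaskError, match="overlap"):
        MaskPair(
            left=PillarMask(std_masks.left.raster, "left"),
            right=PillarMask(std_masks.left.raster, "right"),
        )
    with pytest.raises(MaskError, match="left"):
        MaskPair(
            left=PillarMask(std_masks.right.raster, "left"),
            right=PillarMask(std_masks.left.raster, "right"),
        )


def test_mask_requires_single_component():
    grid = np.zeros((32, 32), dtype=bool)
    grid[2:6, 2:6] = True
    grid[20:24, 20:24] = True
    with pytest.raises(MaskError, match="connected component"):
        PillarMask(raster=grid, side="left")
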