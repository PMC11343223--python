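"""Feature detection and pyramidal Lucas-Kanade tracking oracles.

The key accuracy contracts: exact zero on static movies, the shift
schedule on integer-roll movies, and <10% peak error on rendered
sub-pixel motion with realistic noise.
"""

import numpy as np
import pytest

from pillartrack import (
    FeatureParams,
    FlowParams,
    MovieFrames,
    PillarMask,
    SyntheticMovieSpec,
    auto_adjust,
    detect_features,
    generate_movie,
    make_integer_shift_movie,
    mean_displacement,
    track_markers,
)
from pillartrack.errors import TrackingError


def _center_mask(shape, size, side="left"):
    grid = np.zeros(shape, dtype=bool)
    r0 = (shape[0] - size) // 2
    c0 = (shape[1] - size) // 2
    grid[r0:r0 + size, c0:c0 + size] = True
    return PillarMask(raster=grid, side=side)


def test_uniform_patch_has_no_features():
    frame = np.full((64, 64), 128, dtype=np.uint8)
    mask = _center_mask((64, 64), 20)
    with pytest.raises(TrackingError):
        detect_features(frame, mask, FeatureParams())


def test_checkerboard_corner_count():
    """8-px checkerboard under a 40x40 mask yields at least the interior
    checker corners surviving a 5-px suppression radius."""
    r, c = np.indices((64, 64))
    frame = (((r // 8 + c // 8) % 2) * 255).astype(np.uint8)
    mask = _center_mask((64, 64), 40)
    markers = detect_features(frame, mask, FeatureParams(min_distance=5))
    assert markers.n_markers >= 9
    rounded = np.round(markers.positions).astype(int)
    assert mask.raster[rounded[:, 0], rounded[:, 1]].all()


def test_markers_always_inside_mask(std_movie, std_masks):
    movie, _ = std_movie
    for mask in std_masks:
        markers = detect_features(movie.frames[0], mask, FeatureParams())
        rounded = np.round(markers.positions).astype(int)
        assert mask.raster[rounded[:, 0], rounded[:, 1]].all()


def test_marker_count_monotone_in_quality(std_movie, std_masks):
    """Lowering quality_level never decreases the number of features."""
    movie, _ = std_movie
    counts = []
    for q in (0.4, 0.2, 0.1, 0.05, 0.01):
        counts.append(
            detect_features(
                movie.frames[0], std_masks.left, FeatureParams(quality_level=q)
            ).n_markers
        )
    assert all(b >= a for a, b in zip(counts, counts[1:]))


def test_static_movie_tracks_to_exact_zero(std_movie, std_masks):
    movie, _ = std_movie
    static = MovieFrames(
        frames=np.repeat(movie.frames[:1], 10, axis=0), bit_depth=movie.bit_depth
    )
    markers = detect_features(static.frames[0], std_masks.left, FeatureParams())
    traj = track_markers(static, markers, FlowParams())
    series = mean_displacement(traj)
    assert np.abs(series.d_abs).max() < 0.05


def test_integer_shift_recovers_schedule(std_movie, std_masks):
    """2 px/frame rightward roll for 10 frames -> 18 px at frame 9."""
    movie, _ = std_movie
    shifted = make_integer_shift_movie(movie.frames[0], (0, 2), 10)
    markers = detect_features(shifted.frames[0], std_masks.left, FeatureParams())
    traj = track_markers(shifted, markers, FlowParams())
    series = mean_displacement(traj)
    assert series.d_col[9] == pytest.approx(18.0, abs=0.2)
    assert np.abs(series.d_row).max() < 0.2


def test_subpixel_sinusoid_peak_within_ten_percent(std_movie, std_masks):
    """Rendered sub-pixel motion, 3 px amplitude, 2% noise."""
    movie, truth = std_movie
    peaks = []
    for mask in std_masks:
        fp, flp = auto_adjust(movie.frames[0], mask)
        markers = detect_features(movie.frames[0], mask, fp)
        traj = track_markers(movie, markers, flp)
        peaks.append(mean_displacement(traj).d_abs)
    peak = (0.5 * (peaks[0] + peaks[1])).max()
    assert abs(peak - truth.amplitude) / truth.amplitude < 0.10


def test_auto_adjust_keeps_defaults_on_textured_pillar(std_movie, std_masks):
    movie, _ = std_movie
    fp, flp = auto_adjust(movie.frames[0], std_masks.left)
    assert fp.quality_level == FeatureParams().quality_level
    assert flp.window_size == FlowParams().window_size


def test_auto_adjust_relaxes_quality_on_sparse_texture():
    """One dominant corner with only faint texture elsewhere: the default
    relative quality threshold finds too few features, so the schedule
    lowers it until enough markers appear."""
    rng = np.random.default_rng(16)
    frame = (8 + 2 * rng.standard_normal((64, 64))).clip(0, 255)
    frame[28:36, 28:36] += 120  # one strong block: four dominant corners
    frame = frame.clip(0, 255).astype(np.uint8)
    mask = _center_mask((64, 64), 40)
    n_default = detect_features(frame, mask, FeatureParams()).n_markers
    assert n_default < 10
    fp, _ = auto_adjust(frame, mask)
    n = detect_features(frame, mask, fp).n_markers
    assert fp.quality_level < FeatureParams().quality_level
    assert n >= 10 or fp.quality_level == pytest.approx(0.005)


def test_auto_adjust_scales_window_with_mask():
    grid = np.zeros((256, 256), dtype=bool)
    grid[50:200, 50:200] = True  # 150-px pillar: 4x the default reference
    fp_frame = np.random.default_rng(0).integers(0, 255, (256, 256)).astype(np.uint8)
    _, flp = auto_adjust(fp_frame, PillarMask(raster=grid, side="left"))
    assert flp.window_size > FlowParams().window_size
    assert flp.window_size % 2 == 1


def test_markers_leaving_frame_are_dropped(std_movie, std_masks):
    """Markers carried off the frame edge are invalidated; losing nearly
    all of them is a hard error."""
    movie, _ = std_movie
    exiting = make_integer_shift_movie(movie.frames[0], (0, -6), 16)
    markers = detect_features(exiting.frames[0], std_masks.left, FeatureParams())
    with pytest.raises(TrackingError, match="survived"):
        track_markers(exiting, markers, FlowParams())
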