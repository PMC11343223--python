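"""Shared fixtures: synthetic movies are expensive, so the canonical ones
are generated once per session and reused across test modules."""

import numpy as np
import pytest
from scipy import ndimage

from pillartrack import (
    RunConfig,
    SyntheticMovieSpec,
    generate_movie,
    segment_pillars,
)


def brute_force_cap_shift(frames, cap_mask, frame_index):
    """Independent dense-registration oracle for the renderer.

    Exhaustive sub-pixel translation search (SSD over a shift grid,
    refined to 0.02 px) of the cap-interior crop of ``frame_index``
    against frame 0.  No gradients, no pyramids — nothing shared with
    the Lucas-Kanade tracker it helps to judge.
    """
    rows, cols = np.nonzero(cap_mask)
    r0, r1 = rows.min() + 3, rows.max() - 2
    c0, c1 = cols.min() + 3, cols.max() - 2
    rr, cc = np.mgrid[r0:r1, c0:c1].astype(float)
    ref = frames[0, r0:r1, c0:c1].astype(float)
    cur = ndimage.spline_filter(frames[frame_index].astype(float), order=3)

    def ssd(dr, dc):
        sampled = ndimage.map_coordinates(
            cur, [rr + dr, cc + dc], order=3, prefilter=False, mode="nearest"
        )
        return ((sampled - ref) ** 2).mean()

    best, best_d = np.inf, (0.0, 0.0)
    for dr in np.arange(-4.0, 4.01, 0.5):
        for dc in np.arange(-4.0, 4.01, 0.5):
            v = ssd(dr, dc)
            if v < best:
                best, best_d = v, (dr, dc)
    for step in (0.1, 0.02):
        dr0, dc0 = best_d
        for dr in np.arange(dr0 - 5 * step, dr0 + 5.01 * step, step):
            for dc in np.arange(dc0 - 5 * step, dc0 + 5.01 * step, step):
                v = ssd(dr, dc)
                if v < best:
                    best, best_d = v, (dr, dc)
    return np.asarray(best_d)


@pytest.fixture(scope="session")
def std_movie():
    """Standard noisy movie: 3 px amplitude, 3 beats, 2% noise."""
    return generate_movie(SyntheticMovieSpec(amplitude=3.0, noise_sd=0.02, seed=1))


@pytest.fixture(scope="session")
def clean_movie():
    """Noiseless counterpart of the standard movie."""
    return generate_movie(SyntheticMovieSpec(amplitude=3.0, noise_sd=0.0, seed=2))


@pytest.fixture(scope="session")
def std_masks(std_movie):
    movie, _ = std_movie
    return segment_pillars(movie.frames[0], "type1")


@pytest.fixture
def type1_config():
    """The Type-1 batch settings: 30 fps, 4 μm/px, k = 2.677 μN/μm, 350 μm depth."""
    return RunConfig(
        data_type="type1",
        fps=30.0,
        length_scale=4.0,
        stiffness=2.677,
        tissue_depth=350.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
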