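"""Fiducial-marker detection and sparse optical-flow tracking.

Markers are Shi-Tomasi corners (minimum eigenvalue of the local structure
tensor) detected inside each pillar mask on the first frame, then followed
through the movie with a pyramidal iterative Lucas-Kanade tracker: at each
pyramid level, the inter-frame displacement of every marker is refined by
iterative local least squares on the spatial/temporal image gradients
inside a square window, coarse-to-fine over the pyramid.  The whole path
is deterministic — no random state anywhere.

Feature-detection and flow parameters are adjusted automatically per
movie (:func:`auto_adjust`): the corner-quality threshold is relaxed until
enough markers are found, and the flow window grows with the pillar size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.feature import corner_peaks, corner_shi_tomasi

from .errors import TrackingError
from .image_io import MovieFrames
from .segmentation import PillarMask

logger = logging.getLogger(__name__)

#: Minimum number of detected markers per pillar before the quality
#: threshold stops relaxing.
MIN_FEATURES = 10
#: Minimum number of markers that must survive tracking per pillar.
MIN_SURVIVING = 5
#: Floor of the corner quality-level relaxation schedule.
QUALITY_FLOOR = 0.005
#: Coarsest pyramid level must keep at least this many pixels per side.
MIN_PYRAMID_DIM = 16


@dataclass(frozen=True)
class FeatureParams:
    """Shi-Tomasi corner detection parameters."""

    max_corners: int = 200
    quality_level: float = 0.1  # fraction of the maximal corner response
    min_distance: int = 3  # non-maximum suppression radius, px
    block_size: int = 3  # structure-tensor integration scale, px

    def __post_init__(self) -> None:
        if not 0 < self.quality_level < 1:
            raise ValueError("quality_level must lie in (0, 1)")
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")


@dataclass(frozen=True)
class FlowParams:
    """Pyramidal Lucas-Kanade parameters."""

    window_size: int = 15  # odd; square integration window side, px
    pyramid_levels: int = 3
    max_iterations: int = 30
    epsilon: float = 0.01  # stop when the update magnitude drops below, px

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")


@dataclass
class MarkerSet:
    """Sub-pixel marker positions on the first frame of one pillar."""

    positions: np.ndarray  # (N, 2) float (row, col)
    pillar: str  # "left" or "right"

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        if self.positions.size == 0 or self.positions.shape[1] != 2:
            raise TrackingError("marker set must be a non-empty (N, 2) array")

    @property
    def n_markers(self) -> int:
        return self.positions.shape[0]


@dataclass
class TrackedTrajectories:
    """Cumulative marker positions across all frames of one pillar.

    ``coords`` has shape (M, F, 2) in sub-pixel (row, col); ``status``
    flags markers that remained valid through the whole movie.  Positions
    of invalidated markers are frozen at their last valid value and must
    be excluded via ``status``.
    """

    coords: np.ndarray
    status: np.ndarray
    pillar: str

    @property
    def n_valid(self) -> int:
        return int(self.status.sum())

    def valid_coords(self) -> np.ndarray:
        return self.coords[self.status]


def detect_features(
    frame: np.ndarray, mask: PillarMask, params: FeatureParams
) -> MarkerSet:
    """Shi-Tomasi corners inside a pillar mask.

    Candidates are scored by the minimum eigenvalue of the structure
    tensor; those below ``quality_level`` x (max masked response) are
    rejected, and greedy non-maximum suppression enforces
    ``min_distance``.  Every returned point lies on a mask pixel.
    """
    img = np.asarray(frame, dtype=np.float64)
    if img.max() > 0:
        img = img / img.max()
    response = corner_shi_tomasi(img, sigma=max(params.block_size / 3.0, 0.5))
    response[~mask.raster] = 0.0
    response[response < 0] = 0.0
    if response.max() <= 0:
        raise TrackingError(
            f"no trackable texture inside the {mask.side} pillar mask"
        )
    peaks = corner_peaks(
        response,
        min_distance=params.min_distance,
        threshold_rel=params.quality_level,
        num_peaks=params.max_corners,
        exclude_border=False,
    )
    if peaks.shape[0] == 0:
        raise TrackingError(
            f"zero features detected in the {mask.side} pillar mask "
            f"(quality_level={params.quality_level})"
        )
    return MarkerSet(positions=peaks.astype(np.float64), pillar=mask.side)


def auto_adjust(
    frame: np.ndarray, mask: PillarMask,
    feature_params: FeatureParams | None = None,
    flow_params: FlowParams | None = None,
) -> tuple[FeatureParams, FlowParams]:
    """Deterministic per-movie parameter schedule.

    Starting from the defaults, the corner quality level is halved until
    at least ``MIN_FEATURES`` markers are found (floor 0.005); if the
    floor is reached with too few markers — typically on small pillar
    masks — the non-maximum-suppression radius is reduced (3 -> 2 -> 1)
    and the quality schedule replayed.  The flow window is scaled up
    with the mask bounding box for large pillars, and pyramid levels are
    capped so the coarsest level keeps at least ``MIN_PYRAMID_DIM`` px
    per side.
    """
    fp0 = feature_params or FeatureParams()
    flp = flow_params or FlowParams()

    fp = fp0
    for min_distance in sorted({fp0.min_distance, 2, 1}, reverse=True):
        fp = replace(fp0, min_distance=min_distance)
        while True:
            try:
                n = detect_features(frame, mask, fp).n_markers
            except TrackingError:
                n = 0
            if n >= MIN_FEATURES or fp.quality_level <= QUALITY_FLOOR:
                break
            fp = replace(fp, quality_level=max(fp.quality_level * 0.5, QUALITY_FLOOR))
        if n >= MIN_FEATURES:
            break

    r0, r1, c0, c1 = mask.bbox
    bbox_extent = max(r1 - r0 + 1, c1 - c0 + 1)
    if bbox_extent > 4 * flp.window_size:
        win = int(bbox_extent // 4)
        win += 1 - win % 2  # keep it odd
        flp = replace(flp, window_size=win)

    max_levels = 1
    extent = min(frame.shape)
    while extent // 2 >= MIN_PYRAMID_DIM and max_levels < flp.pyramid_levels:
        extent //= 2
        max_levels += 1
    if max_levels < flp.pyramid_levels:
        flp = replace(flp, pyramid_levels=max_levels)
    return fp, flp


# ---------------------------------------------------------------------------
# pyramidal Lucas-Kanade core


def _build_pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    """Gaussian pyramid, level 0 = full resolution, downscale 2 per level."""
    pyr = [img]
    for _ in range(levels - 1):
        blurred = ndimage.gaussian_filter(pyr[-1], sigma=1.0, mode="nearest")
        pyr.append(blurred[::2, ::2])
    return pyr


def _sample(img: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Bilinear sampling at (N, K, 2) coordinates -> (N, K) values."""
    flat = coords.reshape(-1, 2).T
    vals = ndimage.map_coordinates(img, flat, order=1, mode="nearest")
    return vals.reshape(coords.shape[:-1])


def _lk_level(
    prev: np.ndarray,
    nxt: np.ndarray,
    pts: np.ndarray,
    guess: np.ndarray,
    params: FlowParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One Lucas-Kanade refinement at a single pyramid level.

    ``pts`` (N, 2) are marker positions in ``prev``; ``guess`` (N, 2) is
    the displacement carried down from the coarser level.  Returns the
    refined displacement and a per-marker validity flag (False where the
    structure tensor is near-singular).
    """
    half = params.window_size // 2
    dr, dc = np.mgrid[-half:half + 1, -half:half + 1]
    offsets = np.stack([dr.ravel(), dc.ravel()], axis=-1)  # (K, 2)

    coords_prev = pts[:, None, :] + offsets[None, :, :]  # (N, K, 2)
    grad_r = ndimage.sobel(prev, axis=0) / 8.0
    grad_c = ndimage.sobel(prev, axis=1) / 8.0
    iw = _sample(prev, coords_prev)
    gr = _sample(grad_r, coords_prev)
    gc = _sample(grad_c, coords_prev)

    g_rr = (gr * gr).sum(axis=1)
    g_rc = (gr * gc).sum(axis=1)
    g_cc = (gc * gc).sum(axis=1)
    det = g_rr * g_cc - g_rc**2
    valid = det > 1e-12
    det_safe = np.where(valid, det, 1.0)

    disp = guess.copy()
    active = valid.copy()
    for _ in range(params.max_iterations):
        if not active.any():
            break
        coords_next = coords_prev[active] + disp[active, None, :]
        diff = iw[active] - _sample(nxt, coords_next)
        b_r = (diff * gr[active]).sum(axis=1)
        b_c = (diff * gc[active]).sum(axis=1)
        inv_det = 1.0 / det_safe[active]
        upd_r = (g_cc[active] * b_r - g_rc[active] * b_c) * inv_det
        upd_c = (g_rr[active] * b_c - g_rc[active] * b_r) * inv_det
        disp[active, 0] += upd_r
        disp[active, 1] += upd_c
        still = np.hypot(upd_r, upd_c) >= params.epsilon
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    return disp, valid


def _flow_step(
    prev_pyr: list[np.ndarray],
    next_pyr: list[np.ndarray],
    pts: np.ndarray,
    params: FlowParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Coarse-to-fine displacement of markers between two frames."""
    disp = np.zeros_like(pts)
    valid = np.ones(pts.shape[0], dtype=bool)
    for level in range(len(prev_pyr) - 1, -1, -1):
        scale = 2.0**level
        disp, lvl_valid = _lk_level(
            prev_pyr[level], next_pyr[level], pts / scale, disp, params
        )
        valid &= lvl_valid
        if level > 0:
            disp = disp * 2.0
    return disp, valid


def track_markers(
    frames: MovieFrames, markers: MarkerSet, params: FlowParams | None = None
) -> TrackedTrajectories:
    """Track markers through all frames by pyramidal Lucas-Kanade flow.

    Trajectories are cumulative sub-pixel positions.  A marker is dropped
    (with a logged warning) when its structure tensor degenerates, its
    position leaves the frame, or its single-step displacement exceeds
    the window extent; per-pillar statistics later use survivors only.

    Raises
    ------
    TrackingError
        If fewer than ``MIN_SURVIVING`` markers survive.
    """
    params = params or FlowParams()
    stack = frames.as_float()
    n_frames = frames.n_frames
    n_markers = markers.n_markers
    coords = np.empty((n_markers, n_frames, 2), dtype=np.float64)
    coords[:, 0] = markers.positions
    status = np.ones(n_markers, dtype=bool)
    max_step = params.window_size * 2.0**params.pyramid_levels
    R, C = frames.frame_shape

    prev_pyr = _build_pyramid(stack[0], params.pyramid_levels)
    for t in range(1, n_frames):
        next_pyr = _build_pyramid(stack[t], params.pyramid_levels)
        pts = coords[:, t - 1]
        disp, valid = _flow_step(prev_pyr, next_pyr, pts, params)
        step = np.hypot(disp[:, 0], disp[:, 1])
        new_pos = pts + disp
        in_frame = (
            (new_pos[:, 0] >= 0) & (new_pos[:, 0] <= R - 1)
            & (new_pos[:, 1] >= 0) & (new_pos[:, 1] <= C - 1)
        )
        ok = valid & np.isfinite(step) & (step <= max_step) & in_frame
        lost = status & ~ok
        if lost.any():
            logger.warning(
                "%s pillar: dropping %d marker(s) at frame %d",
                markers.pillar, int(lost.sum()), t,
            )
        status &= ok
        coords[:, t] = np.where(ok[:, None], new_pos, pts)
        prev_pyr = next_pyr

    if status.sum() < MIN_SURVIVING:
        raise TrackingError(
            f"only {int(status.sum())} marker(s) survived tracking on the "
            f"{markers.pillar} pillar; need >= {MIN_SURVIVING}"
        )
    return TrackedTrajectories(coords=coords, status=status, pillar=markers.pillar)
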