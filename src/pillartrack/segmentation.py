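"""Pillar mask creation: local-Otsu segmentation, external masks, perturbation.

The two pillar caps are segmented on the first movie frame by a local Otsu
threshold (rank filter), followed by morphological cleanup and a candidate
scoring step that keeps the two largest, laterally separated regions.  If
automatic segmentation fails the error message directs the user to supply
an externally generated binary mask (0/1 text grid or binary PNG).

For the mask-sensitivity protocol, masks can be eroded or dilated with a
fixed 5x5 square kernel, applied one or more times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import measure, morphology, util
from skimage.filters import rank, threshold_otsu

from .errors import MaskError, SegmentationError

logger = logging.getLogger(__name__)

#: Structuring element for the sensitivity protocol: 5x5 square of ones.
PERTURBATION_KERNEL = np.ones((5, 5), dtype=bool)


@dataclass
class PillarMask:
    """Binary pillar mask on the movie's frame grid.

    ``raster`` is boolean with True (=1) on the pillar domain and False
    (=0) on background; ``side`` is ``"left"`` or ``"right"``.
    """

    raster: np.ndarray
    side: str

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster).astype(bool)
        if self.raster.ndim != 2:
            raise MaskError(f"mask must be 2-D, got shape {self.raster.shape}")
        if self.side not in ("left", "right"):
            raise MaskError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.area == 0:
            raise MaskError("mask has zero area")
        n_components = measure.label(self.raster, connectivity=2).max()
        if n_components != 1:
            raise MaskError(
                f"mask must have exactly one connected component, found {n_components}"
            )

    @property
    def area(self) -> int:
        return int(self.raster.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.raster)
        return float(rows.mean()), float(cols.mean())

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(row_min, row_max, col_min, col_max), inclusive."""
        rows, cols = np.nonzero(self.raster)
        return int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max())


@dataclass
class MaskPair:
    """The two pillar masks; left has the smaller centroid column."""

    left: PillarMask
    right: PillarMask

    def __post_init__(self) -> None:
        if self.left.raster.shape != self.right.raster.shape:
            raise MaskError("left and right masks are on different grids")
        if np.any(self.left.raster & self.right.raster):
            raise MaskError("pillar masks overlap")
        if self.left.centroid[1] >= self.right.centroid[1]:
            raise MaskError("left mask centroid is not left of the right mask")

    def __iter__(self):
        return iter((self.left, self.right))


_FAIL_HINT = (
    " Automatic segmentation failed; provide a manually or externally "
    "generated binary mask (0/1 text grid or binary PNG) instead."
)


def _local_otsu_binary(frame: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Local Otsu foreground map with a global-Otsu floor.

    The rank-filter Otsu adapts to uneven illumination but, in flat
    background regions, splits pure noise into foreground; the global
    Otsu floor suppresses that speckle.  Returns the binary map and the
    rescaled 8-bit image (for later threshold escalation).
    """
    img8 = util.img_as_ubyte(
        (frame.astype(np.float64) - frame.min()) / max(np.ptp(frame), 1)
    )
    local_thr = rank.otsu(img8, morphology.disk(radius))
    global_thr = threshold_otsu(img8)
    return (img8 > local_thr) & (img8 > global_thr), img8


def segment_pillars(
    first_frame: np.ndarray,
    data_type: str = "type1",
    radius: int | None = None,
    min_area_fraction: float = 0.001,
) -> MaskPair:
    """Segment the two pillar caps on the first movie frame.

    Procedure: local Otsu threshold (disk neighborhood, default radius 25
    px scaled with frame size) -> binary map -> remove small objects and
    border-touching components, fill holes -> keep the two largest
    laterally separated candidates.  For type-2 data the polarity is
    inverted when the pillars are darker than the background (decided by
    which intensity class is the minority).

    Raises
    ------
    SegmentationError
        On near-constant frames or when fewer than two valid candidate
        regions are found; the message suggests the external-mask path.
    """
    frame = np.asarray(first_frame)
    if frame.ndim != 2:
        raise SegmentationError(f"expected a 2-D frame, got shape {frame.shape}")
    if np.ptp(frame) < 0.01 * (frame.max() if frame.max() > 0 else 1) or np.ptp(frame) < 3:
        raise SegmentationError(
            "frame has little intensity variation; cannot threshold." + _FAIL_HINT
        )
    if radius is None:
        radius = max(15, min(frame.shape) // 5)

    work = frame
    if data_type == "type2":
        # pillars are the minority class; invert if the bright class dominates
        thr = threshold_otsu(frame)
        if (frame > thr).mean() > 0.5:
            work = frame.max() - frame

    binary, img8 = _local_otsu_binary(work, radius)
    min_area = max(8, int(min_area_fraction * frame.size))
    R, C = frame.shape

    # The tissue band often bridges the two caps into one component; when
    # that happens, escalate the threshold with a second Otsu restricted
    # to the current foreground (the caps are brighter than the band).
    best, labels = None, None
    for _ in range(4):
        filled = ndimage.binary_fill_holes(binary)
        labels = measure.label(filled, connectivity=2)
        candidates = []
        for p in measure.regionprops(labels):
            r0, c0, r1, c1 = p.bbox
            if r0 == 0 or c0 == 0 or r1 == R or c1 == C:
                continue  # border-touching: stage edge or clipped tissue
            if p.area < min_area:
                continue  # noise speckle
            candidates.append(p)
        candidates.sort(key=lambda p: p.area, reverse=True)
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                a, b = candidates[i], candidates[j]
                sep = abs(a.centroid[1] - b.centroid[1])
                width = max(a.bbox[3] - a.bbox[1], b.bbox[3] - b.bbox[1])
                if sep > width:
                    best = (a, b)
                    break
            if best:
                break
        if best is not None:
            break
        fg = img8[binary]
        if fg.size < 2 or np.ptp(fg) < 2:
            break
        binary = binary & (img8 > threshold_otsu(fg))
        if not binary.any():
            break
    if best is None:
        raise SegmentationError(
            "could not find two laterally separated pillar regions." + _FAIL_HINT
        )
    a, b = sorted(best, key=lambda p: p.centroid[1])
    return MaskPair(
        left=PillarMask(labels == a.label, side="left"),
        right=PillarMask(labels == b.label, side="right"),
    )


def load_external_mask(
    path: str | Path, side: str, frame_shape: tuple[int, int] | None = None
) -> PillarMask:
    """Load an externally generated binary mask.

    Accepted dialects: whitespace-delimited 0/1 text grid (one row per
    line) or a binary PNG with values {0, 255} (normalized to 0/1).
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        grid = np.asarray(iio.imread(path))
        if grid.ndim == 3:
            grid = grid[..., 0]
        values = set(np.unique(grid).tolist())
        if not values <= {0, 255} and not values <= {0, 1}:
            raise MaskError(f"PNG mask {path} is not binary (values {sorted(values)})")
        grid = (grid > 0).astype(int)
    else:
        try:
            grid = np.loadtxt(path)
        except Exception as exc:  # noqa: BLE001
            raise MaskError(f"cannot parse mask file {path}: {exc}") from exc
        values = set(np.unique(grid).tolist())
        if not values <= {0.0, 1.0}:
            raise MaskError(
                f"mask {path} contains non-binary values {sorted(values - {0.0, 1.0})}"
            )
    if grid.ndim != 2:
        raise MaskError(f"mask {path} is not 2-D")
    if frame_shape is not None and grid.shape != tuple(frame_shape):
        raise MaskError(
            f"mask {path} shape {grid.shape} does not match frame shape {tuple(frame_shape)}"
        )
    if grid.sum() == 0:
        raise MaskError(f"mask {path} has zero area")
    return PillarMask(raster=grid.astype(bool), side=side)


def perturb_mask(mask: PillarMask, op: str, iterations: int = 1) -> PillarMask:
    """Erode or dilate a mask with the fixed 5x5 kernel, ``iterations`` times.

    Raises :class:`MaskError` if erosion empties the mask.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if op == "erode":
        out = ndimage.binary_erosion(mask.raster, PERTURBATION_KERNEL, iterations=iterations)
        if not out.any():
            raise MaskError(
                f"erosion x{iterations} with a 5x5 kernel emptied the {mask.side} mask"
            )
        labels = measure.label(out, connectivity=2)
        if labels.max() > 1:
            # a ragged boundary can split under erosion; keep the main body
            logger.warning(
                "erosion split the %s mask into %d pieces; keeping the largest",
                mask.side, labels.max(),
            )
            areas = np.bincount(labels.ravel())[1:]
            out = labels == (int(areas.argmax()) + 1)
    elif op == "dilate":
        out = ndimage.binary_dilation(mask.raster, PERTURBATION_KERNEL, iterations=iterations)
    else:
        raise ValueError(f"op must be 'erode' or 'dilate', got {op!r}")
    return PillarMask(raster=out, side=mask.side)
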