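"""Frame-folder movie input and plain-text tabular output.

A movie is a folder of consecutive grayscale raster frames (TIFF or PNG,
8- or 16-bit).  Frames are ordered by *natural* (numeric-aware) filename
sort, so ``frame_2.tif`` precedes ``frame_10.tif`` whether or not the
numbers are zero-padded.  All tabular results are written as tab-delimited
text files with a single header row at full double precision.

Coordinate convention used throughout the package: 0-based ``(row, col)``,
origin at the top-left corner, row index increasing downward.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import MovieLoadError

logger = logging.getLogger(__name__)

#: Raster formats accepted inside a movie folder.
SUPPORTED_EXTENSIONS = (".tif", ".tiff", ".png")

# RGB -> luminance weights (ITU-R BT.601).
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata attached to a movie.

    Parameters
    ----------
    fps : float
        Frame rate in Hz.
    length_scale : float
        Microns per pixel.
    data_type : str
        ``"type1"`` (PDMS strain-gauge devices with bright pillar caps) or
        ``"type2"`` (fiber-matrix devices with cantilever tips).
    """

    fps: float
    length_scale: float
    data_type: str = "type1"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.length_scale <= 0:
            raise ValueError(
                f"length_scale must be positive, got {self.length_scale}"
            )
        if self.data_type not in ("type1", "type2"):
            raise ValueError(f"data_type must be 'type1' or 'type2', got {self.data_type!r}")


@dataclass
class MovieFrames:
    """Ordered stack of grayscale frames.

    Attributes
    ----------
    frames : ndarray, shape (F, R, C)
        Unsigned-integer intensities.
    bit_depth : int
        8 or 16; intensities must fit the declared depth.
    filenames : list of str, optional
        Source filenames in temporal order (empty for synthetic movies).
    """

    frames: np.ndarray
    bit_depth: int
    filenames: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise MovieLoadError(
                f"expected a (F, R, C) stack, got shape {self.frames.shape}"
            )
        if self.n_frames < 2:
            raise MovieLoadError("a movie needs at least 2 frames")
        if self.bit_depth not in (8, 16):
            raise MovieLoadError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.frames.max(initial=0) > 2**self.bit_depth - 1:
            raise MovieLoadError(
                f"intensities exceed declared {self.bit_depth}-bit range"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def dynamic_range(self) -> float:
        return float(2**self.bit_depth - 1)

    def as_float(self) -> np.ndarray:
        """Frames scaled to [0, 1] floats (the tracker's working space)."""
        return self.frames.astype(np.float64) / self.dynamic_range

    def truncated(self, start_frame: int) -> "MovieFrames":
        """A copy of the movie that begins at ``start_frame``."""
        if not 0 <= start_frame < self.n_frames - 1:
            raise ValueError(f"start_frame {start_frame} out of range")
        return MovieFrames(
            frames=self.frames[start_frame:].copy(),
            bit_depth=self.bit_depth,
            filenames=self.filenames[start_frame:],
        )


def natural_sort_key(name: str) -> tuple:
    """Sort key treating digit runs as integers: frame_2 < frame_10."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _to_grayscale(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        logger.warning("converting RGB frame %s to grayscale by luminance", path.name)
        lum = arr[..., :3].astype(np.float64) @ _LUMA
        return np.round(lum).astype(arr.dtype)
    raise MovieLoadError(f"frame {path} has unsupported shape {arr.shape}")


def load_movie(folder_path: str | Path) -> MovieFrames:
    """Read a frame folder into a :class:`MovieFrames` stack.

    Frames are sorted by natural filename order.  The bit depth is
    detected from the file dtype; RGB frames are converted to grayscale
    by luminance weighting with a logged warning.

    Raises
    ------
    MovieLoadError
        For an empty folder, mixed frame dimensions, or an unreadable
        file; the message names the offending file.
    """
    folder = Path(folder_path)
    if not folder.is_dir():
        raise MovieLoadError(f"not a directory: {folder}")
    files = sorted(
        (p for p in folder.iterdir() if p.suffix.lower() in SUPPORTED_EXTENSIONS),
        key=lambda p: natural_sort_key(p.name),
    )
    if len(files) < 2:
        raise MovieLoadError(
            f"folder {folder} contains {len(files)} readable frames; need at least 2"
        )
    frames = []
    for path in files:
        try:
            if path.suffix.lower() in (".tif", ".tiff"):
                arr = tifffile.imread(path)
            else:
                arr = iio.imread(path)
        except Exception as exc:  # noqa: BLE001 - rewrap with filename
            raise MovieLoadError(f"cannot read frame {path}: {exc}") from exc
        arr = np.asarray(arr)
        if not np.issubdtype(arr.dtype, np.integer):
            raise MovieLoadError(f"frame {path} is not integer-typed ({arr.dtype})")
        frames.append(_to_grayscale(arr, path))
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise MovieLoadError(
            f"mixed frame dimensions in {folder}: {sorted(shapes)}"
        )
    stack = np.stack(frames)
    bit_depth = 16 if stack.dtype.itemsize > 1 else 8
    return MovieFrames(
        frames=stack, bit_depth=bit_depth, filenames=[p.name for p in files]
    )


def write_movie(movie: MovieFrames, folder_path: str | Path, stem: str = "frame") -> list[Path]:
    """Write a movie as zero-padded individual TIFF frames."""
    folder = Path(folder_path)
    folder.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(movie.n_frames - 1)))
    paths = []
    for i, frame in enumerate(movie.frames):
        path = folder / f"{stem}_{i:0{width}d}.tif"
        tifffile.imwrite(path, frame)
        paths.append(path)
    return paths


def write_timeseries(
    table: Mapping[str, Sequence] | pd.DataFrame, out_path: str | Path
) -> Path:
    """Write a labeled column set as a tab-delimited text file.

    One header line, values at full double precision (`%.17g`), byte
    deterministic for a fixed table.  All columns must share one length.
    """
    if not isinstance(table, pd.DataFrame):
        lengths = {k: len(v) for k, v in table.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"columns have unequal lengths: {lengths}")
        table = pd.DataFrame(dict(table))
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_path, sep="\t", index=False, float_format="%.17g", lineterminator="\n")
    return out_path


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited table written by :func:`write_timeseries`."""
    return pd.read_csv(path, sep="\t")
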