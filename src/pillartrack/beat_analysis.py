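"""Displacement series, valley detection, drift handling, beat splitting.

The per-pillar trajectories are reduced to mean directional displacements
(Δrow, Δcol) and a mean absolute displacement |d|(t), all relative to a
baseline frame.  Valleys — frames where the tissue is fully relaxed —
are local minima of the smoothed |d| signal; consecutive valleys delimit
beats.  A movie must span at least 2 complete beats to be analyzed at
all, and at least 3 to be split into per-beat re-baselined series (the
drift correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .errors import BeatAnalysisError
from .image_io import MovieFrames
from .tracking import TrackedTrajectories

logger = logging.getLogger(__name__)

MIN_BEATS_ANALYZE = 2  # complete beats required for any analysis
MIN_BEATS_SPLIT = 3  # complete beats required for per-beat splitting

#: Default drift tolerance at valleys (px); below typical tracking noise
#: the warning would be meaningless.
DEFAULT_DRIFT_TOL_PX = 0.5

#: Irregularity thresholds: beat-period coefficient of variation and
#: per-beat peak-amplitude deviation from the median peak.
PERIOD_CV_THRESHOLD = 0.20
AMPLITUDE_DEVIATION_THRESHOLD = 0.30


@dataclass
class DisplacementSeries:
    """Mean displacement of one pillar versus frame, in pixels.

    ``d_row``/``d_col`` are means over markers of the signed displacement
    components; ``d_abs`` is the mean over markers of the per-marker
    Euclidean displacement norm (so opposing marker motions do not
    cancel).  ``d_abs[baseline] == 0`` by construction.
    """

    d_row: np.ndarray
    d_col: np.ndarray
    d_abs: np.ndarray
    pillar: str

    def __post_init__(self) -> None:
        if not (len(self.d_row) == len(self.d_col) == len(self.d_abs)):
            raise BeatAnalysisError("displacement components differ in length")

    @property
    def n_frames(self) -> int:
        return len(self.d_abs)

    def abs_um(self, length_scale: float) -> np.ndarray:
        return self.d_abs * length_scale


@dataclass
class BeatSegments:
    """Valley frames and the beats (half-open frame ranges) between them."""

    valley_frames: np.ndarray
    beats: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.valley_frames = np.asarray(self.valley_frames, dtype=int)
        if np.any(np.diff(self.valley_frames) <= 0):
            raise BeatAnalysisError("valley frames must be strictly increasing")
        for start, end in self.beats:
            if end - start < 3:
                raise BeatAnalysisError(f"beat [{start}, {end}) spans < 3 frames")

    @property
    def n_beats(self) -> int:
        return len(self.beats)

    def periods(self) -> np.ndarray:
        """Beat durations in frames."""
        return np.diff(self.valley_frames).astype(float)


@dataclass
class DriftReport:
    """Result of the valley-baseline drift check."""

    detected: bool
    valley_baselines_px: np.ndarray  # |d| at each valley after frame 0
    tolerance_px: float


def mean_displacement(
    traj: TrackedTrajectories, baseline_frame: int = 0
) -> DisplacementSeries:
    """Reduce trajectories to the pillar's mean displacement series."""
    coords = traj.valid_coords()
    if coords.shape[0] == 0:
        raise BeatAnalysisError(f"no surviving markers on the {traj.pillar} pillar")
    if not 0 <= baseline_frame < coords.shape[1]:
        raise BeatAnalysisError(f"baseline frame {baseline_frame} out of range")
    delta = coords - coords[:, baseline_frame:baseline_frame + 1, :]
    return DisplacementSeries(
        d_row=delta[..., 0].mean(axis=0),
        d_col=delta[..., 1].mean(axis=0),
        d_abs=np.linalg.norm(delta, axis=2).mean(axis=0),
        pillar=traj.pillar,
    )


def contraction_signal(
    traj_left: TrackedTrajectories, traj_right: TrackedTrajectories
) -> np.ndarray:
    """Baseline-free contraction measure: loss of inter-pillar separation.

    ``max(sep) - sep(t)`` where ``sep`` is the column distance between
    the two pillars' marker centroids.  It is zero when the tissue is
    fully relaxed and positive during contraction *regardless of the
    movie's starting phase*, unlike a displacement series baselined at
    frame 0 — which is why the pipeline segments beats on this signal.
    """
    sep = (
        traj_right.valid_coords()[:, :, 1].mean(axis=0)
        - traj_left.valid_coords()[:, :, 1].mean(axis=0)
    )
    return sep.max() - sep


def smooth_series(signal: np.ndarray, fps: float) -> np.ndarray:
    """Centered moving average over ``max(3, round(fps / 10))`` frames."""
    win = max(3, int(round(fps / 10.0)))
    kernel = np.ones(win) / win
    pad = win // 2
    padded = np.pad(signal, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="valid")
    return out[: len(signal)]


def find_valleys(
    abs_signal: np.ndarray,
    fps: float,
    prominence_fraction: float = 0.25,
    min_separation_s: float = 1.0 / 3.0,
) -> BeatSegments:
    """Locate valley frames and form beats from consecutive valleys.

    The signal is smoothed by a short moving average and detrended with a
    rolling-minimum baseline so that a drifting relaxed level does not
    mask the beats.  Beat peaks are local maxima of the detrended signal
    with prominence >= ``prominence_fraction`` of its range and
    separation >= ``min_separation_s`` seconds (default fps/3 frames,
    capping the detectable beating rate at 3 Hz); the valley frames are
    the minima of the smoothed signal between consecutive peaks, plus the
    leading minimum.  A trailing minimum is kept only when the signal
    rises again after it, so a terminal partial beat is discarded.

    Raises
    ------
    BeatAnalysisError
        When fewer than 2 complete beats are present.
    """
    signal = np.asarray(abs_signal, dtype=np.float64)
    if signal.size < 8:
        raise BeatAnalysisError("series too short for beat segmentation")
    smoothed = smooth_series(signal, fps)
    if np.ptp(smoothed) <= 0:
        raise BeatAnalysisError("flat displacement series; no beats to segment")
    distance = max(2, int(round(min_separation_s * fps)))
    baseline = ndimage.minimum_filter1d(smoothed, size=2 * distance + 1, mode="nearest")
    detrended = smoothed - ndimage.uniform_filter1d(baseline, size=distance, mode="nearest")
    rng = np.ptp(detrended)
    if rng <= 0:
        raise BeatAnalysisError("flat displacement series; no beats to segment")
    peaks, _ = find_peaks(
        detrended, prominence=prominence_fraction * rng, distance=distance
    )
    if peaks.size < 2:
        raise BeatAnalysisError(
            f"found {max(peaks.size - 1, 0)} complete beat(s); a minimum of "
            f"{MIN_BEATS_ANALYZE} complete beats is required for analysis"
        )
    valleys = [int(np.argmin(smoothed[: peaks[0] + 1]))]
    for a, b in zip(peaks[:-1], peaks[1:]):
        valleys.append(int(a + np.argmin(smoothed[a: b + 1])))
    tail_v = int(peaks[-1] + np.argmin(smoothed[peaks[-1]:]))
    if tail_v < signal.size - 1:  # interior minimum: the signal rises again
        valleys.append(tail_v)
    valleys = np.asarray(valleys, dtype=int)
    if len(valleys) < MIN_BEATS_ANALYZE + 1:
        raise BeatAnalysisError(
            f"found {max(len(valleys) - 1, 0)} complete beat(s); a minimum of "
            f"{MIN_BEATS_ANALYZE} complete beats is required for analysis"
        )
    beats = [(int(valleys[i]), int(valleys[i + 1])) for i in range(len(valleys) - 1)]
    return BeatSegments(valley_frames=valleys, beats=beats)


def adjust_start(
    frames: MovieFrames, segments: BeatSegments
) -> tuple[MovieFrames, bool]:
    """Re-anchor the movie at its first valley frame.

    If the movie already starts at a valley it is returned unchanged with
    ``retrack_needed = False``; otherwise the leading frames are dropped
    and the caller must re-run feature detection and tracking on the
    returned movie.
    """
    first_valley = int(segments.valley_frames[0])
    if first_valley == 0:
        return frames, False
    logger.info("movie does not start at a valley; re-anchoring at frame %d", first_valley)
    return frames.truncated(first_valley), True


def detect_drift(
    abs_signal: np.ndarray,
    segments: BeatSegments,
    tol_px: float = DEFAULT_DRIFT_TOL_PX,
) -> DriftReport:
    """Flag drift when the relaxed-state baseline walks away from zero.

    Drift is detected iff |d| at any valley after frame 0 exceeds
    ``tol_px``; a user-facing warning is logged when it is.
    """
    if len(segments.valley_frames) < 2:
        raise BeatAnalysisError("drift check needs at least 2 valleys")
    later = segments.valley_frames[segments.valley_frames > 0]
    baselines = np.asarray(abs_signal, dtype=float)[later]
    detected = bool(np.any(baselines > tol_px))
    if detected:
        logger.warning(
            "drift detected: valley baselines %s px exceed %.3g px; consider "
            "per-beat splitting (split=True)",
            np.array2string(baselines, precision=3), tol_px,
        )
    return DriftReport(detected=detected, valley_baselines_px=baselines, tolerance_px=tol_px)


def split_beats(
    traj: TrackedTrajectories, segments: BeatSegments
) -> list[DisplacementSeries]:
    """Per-beat displacement series, each re-baselined to its start valley.

    Uses the marker positions at the first frame of each beat as that
    beat's baseline, which removes any baseline accumulated by drift.
    Requires at least ``MIN_BEATS_SPLIT`` complete beats.
    """
    if segments.n_beats < MIN_BEATS_SPLIT:
        raise BeatAnalysisError(
            f"per-beat splitting requires at least {MIN_BEATS_SPLIT} complete "
            f"beats; found {segments.n_beats}"
        )
    coords = traj.valid_coords()
    out = []
    for start, end in segments.beats:
        delta = coords[:, start:end, :] - coords[:, start:start + 1, :]
        out.append(
            DisplacementSeries(
                d_row=delta[..., 0].mean(axis=0),
                d_col=delta[..., 1].mean(axis=0),
                d_abs=np.linalg.norm(delta, axis=2).mean(axis=0),
                pillar=traj.pillar,
            )
        )
    return out


def slice_beats(abs_signal: np.ndarray, segments: BeatSegments) -> list[np.ndarray]:
    """Whole-movie-baselined per-beat slices of an |d| series (no re-baselining)."""
    return [np.asarray(abs_signal, dtype=float)[s:e] for s, e in segments.beats]


def detect_irregular(segments: BeatSegments, abs_signal: np.ndarray) -> bool:
    """Warn about irregular beating; no further action is taken.

    A movie is flagged when the beat-period coefficient of variation
    exceeds 20% or any beat's peak amplitude deviates more than 30% from
    the median peak.
    """
    if segments.n_beats < MIN_BEATS_ANALYZE:
        raise BeatAnalysisError("irregularity check needs at least 2 beats")
    periods = segments.periods()
    cv = periods.std() / periods.mean()
    peaks = np.array([sl.max() - sl.min() for sl in slice_beats(abs_signal, segments)])
    median_peak = np.median(peaks)
    amp_dev = np.abs(peaks - median_peak) / median_peak if median_peak > 0 else peaks * 0
    irregular = bool(cv > PERIOD_CV_THRESHOLD or np.any(amp_dev > AMPLITUDE_DEVIATION_THRESHOLD))
    if irregular:
        logger.warning(
            "irregular beating detected (period CV %.1f%%, max amplitude deviation %.1f%%)",
            100 * cv, 100 * amp_dev.max(),
        )
    return irregular
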