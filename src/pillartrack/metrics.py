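"""Per-beat and whole-movie contractility metrics.

From the per-beat displacement/force series the package reports: beating
rate, peak displacement/force/stress per beat, contraction and relaxation
velocities (extrema of the displacement derivative before/after the
peak), and twitch durations FWHM and FW80M — the full widths of the beat
at 50% and 80% of its peak, found by linear interpolation of the flank
crossings.  ("FW80M" is read here as full width at 80% of maximum.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beat_analysis import BeatSegments
from .errors import MetricsError


@dataclass
class BeatMetrics:
    """Metrics of a single beat."""

    peak_displacement_um: float
    peak_force_un: float
    peak_stress_kpa: float
    contraction_velocity_um_s: float
    relaxation_velocity_um_s: float
    fwhm_s: float
    fw80m_s: float


@dataclass
class ContractilityReport:
    """Whole-movie summary: per-beat metrics plus means and SDs."""

    beating_rate_hz: float
    per_beat: list[BeatMetrics]
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    n_beats: int = 0
    single_beat: bool = False  # SD undefined, reported as 0
    irregular: bool = False
    drift_detected: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(b) for b in self.per_beat])


def beating_rate(segments: BeatSegments, fps: float) -> float:
    """Complete beats per second over the first-to-last-valley span."""
    if segments.n_beats < 2:
        raise MetricsError("beating rate needs at least 2 complete beats")
    span_s = (segments.valley_frames[-1] - segments.valley_frames[0]) / fps
    return segments.n_beats / span_s


def _crossing(t0: int, y0: float, y1: float, level: float) -> float:
    """Linear-interpolated fractional index where the signal crosses level."""
    return t0 + (level - y0) / (y1 - y0)


def width_at_fraction(beat: np.ndarray, fraction: float, fps: float) -> float:
    """Full width of a beat at ``fraction`` of its peak, in seconds.

    The beat is assumed re-baselined (starts near 0) with a single
    dominant peak; the two crossings of ``fraction * peak`` on the rising
    and falling flanks are located by linear interpolation.
    """
    if not 0 < fraction < 1:
        raise MetricsError("fraction must lie in (0, 1)")
    beat = np.asarray(beat, dtype=float)
    peak_idx = int(np.argmax(beat))
    peak = beat[peak_idx]
    if peak <= 0:
        raise MetricsError("beat peak is below resolution; cannot measure width")
    level = fraction * peak
    rising = np.flatnonzero(beat[: peak_idx + 1] < level)
    if rising.size == 0:
        raise MetricsError("no rising crossing: beat does not start below the level")
    r = rising[-1]
    t_rise = _crossing(r, beat[r], beat[r + 1], level)
    falling = np.flatnonzero(beat[peak_idx:] < level)
    if falling.size == 0:
        raise MetricsError("no falling crossing within the beat")
    f = peak_idx + falling[0]
    t_fall = _crossing(f - 1, beat[f - 1], beat[f], level)
    return (t_fall - t_rise) / fps


def beat_velocities(
    beat: np.ndarray, fps: float, length_scale: float
) -> tuple[float, float]:
    """(contraction, relaxation) velocities in μm/s.

    Central finite differences of the displacement (converted to μm);
    contraction velocity is the largest positive derivative before the
    peak, relaxation velocity the magnitude of the most negative
    derivative after it.
    """
    beat = np.asarray(beat, dtype=float)
    if beat.size < 5:
        raise MetricsError("beat too short (<5 frames) for velocity estimation")
    if np.ptp(beat) <= 0:
        raise MetricsError("flat beat; velocities undefined")
    deriv = np.gradient(beat * length_scale) * fps  # μm/s
    peak_idx = int(np.argmax(beat))
    contraction = float(deriv[: peak_idx + 1].max())
    relaxation = float(-deriv[peak_idx:].min())
    return contraction, relaxation


_METRIC_FIELDS = (
    "peak_displacement_um",
    "peak_force_un",
    "peak_stress_kpa",
    "contraction_velocity_um_s",
    "relaxation_velocity_um_s",
    "fwhm_s",
    "fw80m_s",
)


def summarize(
    per_beat: list[BeatMetrics],
    beating_rate_hz: float,
    irregular: bool = False,
    drift_detected: bool = False,
) -> ContractilityReport:
    """Mean and SD across beats for every metric.

    With a single beat the SD is undefined and reported as 0 with the
    ``single_beat`` flag set.
    """
    if not per_beat:
        raise MetricsError("no per-beat metrics to summarize")
    single = len(per_beat) == 1
    mean, sd = {}, {}
    for name in _METRIC_FIELDS:
        values = np.array([getattr(b, name) for b in per_beat], dtype=float)
        mean[name] = float(values.mean())
        sd[name] = 0.0 if single else float(values.std(ddof=1))
    return ContractilityReport(
        beating_rate_hz=beating_rate_hz,
        per_beat=per_beat,
        mean=mean,
        sd=sd,
        n_beats=len(per_beat),
        single_beat=single,
        irregular=irregular,
        drift_detected=drift_detected,
    )
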