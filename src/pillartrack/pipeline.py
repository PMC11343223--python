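"""End-to-end pipeline: movie folder in, contractility report + text files out.

The run configuration mirrors the five-parameter user contract: data
type, frame rate, length scale, pillar stiffness (or the cantilever
geometry to derive it), and tissue depth.  Everything else is automatic.

Stages: load -> segment (or external masks) -> detect/track -> valley
check -> re-anchor + re-track if the movie does not start relaxed ->
displacement -> drift check (+ optional per-beat split) -> mechanics ->
metrics.  All tabular outputs are tab-delimited ``.txt`` files; warnings
(drift, irregular beats, dropped markers) are mirrored into a
machine-readable ``warnings.txt``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import beat_analysis, mechanics, metrics as metrics_mod, tracking
from .beat_analysis import BeatSegments, DisplacementSeries
from .errors import ConfigError, MetricsError, PillarTrackError
from .image_io import AcquisitionMeta, MovieFrames, load_movie, write_timeseries
from .mechanics import (
    CircularSection,
    PillarGeometry,
    PillarStiffness,
    RectangularSection,
    TissueGeometry,
)
from .segmentation import MaskPair, load_external_mask, segment_pillars
from .tracking import TrackedTrajectories

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """User configuration for a single run or a batch.

    Exactly one of ``stiffness`` (μN/μm) or ``geometry`` must be given;
    when the geometry is given the stiffness is derived from the
    cantilever equation.
    """

    data_type: str
    fps: float
    length_scale: float
    tissue_depth: float
    stiffness: float | None = None
    geometry: PillarGeometry | None = None
    split: bool = False
    external_mask_left: Path | None = None
    external_mask_right: Path | None = None
    drift_tol_px: float = beat_analysis.DEFAULT_DRIFT_TOL_PX
    tissue_width: float | None = None  # manual override, μm

    def __post_init__(self) -> None:
        if (self.stiffness is None) == (self.geometry is None):
            raise ConfigError("exactly one of stiffness or geometry must be provided")
        for name in ("fps", "length_scale", "tissue_depth"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.stiffness is not None and self.stiffness <= 0:
            raise ConfigError("stiffness must be positive")
        if (self.external_mask_left is None) != (self.external_mask_right is None):
            raise ConfigError("external masks must be provided for both pillars or neither")

    @property
    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            fps=self.fps, length_scale=self.length_scale, data_type=self.data_type
        )

    def resolve_stiffness(self) -> PillarStiffness:
        if self.stiffness is not None:
            return PillarStiffness(k=self.stiffness, source="measured")
        return mechanics.pillar_stiffness(self.geometry)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a plain-text ``key = value`` configuration file.

        Recognized keys: data_type, fps, length_scale, tissue_depth,
        stiffness, split, drift_tol_px, tissue_width,
        external_mask_left/right, and — for geometry-derived stiffness —
        e_kpa, length, force_location, cross_section (rectangular|circular),
        width, thickness, diameter.
        """
        raw: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"cannot parse config line: {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            raw[key.lower()] = value
        try:
            kwargs: dict = {
                "data_type": raw["data_type"],
                "fps": float(raw["fps"]),
                "length_scale": float(raw["length_scale"]),
                "tissue_depth": float(raw["tissue_depth"]),
            }
        except KeyError as exc:
            raise ConfigError(f"missing required config key: {exc}") from exc
        if "stiffness" in raw:
            kwargs["stiffness"] = float(raw["stiffness"])
        elif "e_kpa" in raw:
            shape = raw.get("cross_section", "rectangular")
            if shape == "rectangular":
                section = RectangularSection(
                    w=float(raw["width"]), t=float(raw["thickness"])
                )
            elif shape == "circular":
                section = CircularSection(D=float(raw["diameter"]))
            else:
                raise ConfigError(f"unknown cross_section {shape!r}")
            kwargs["geometry"] = PillarGeometry(
                E_kpa=float(raw["e_kpa"]),
                L=float(raw["length"]),
                a=float(raw["force_location"]),
                cross_section=section,
            )
        if "split" in raw:
            kwargs["split"] = raw["split"].lower() in ("true", "1", "yes")
        if "drift_tol_px" in raw:
            kwargs["drift_tol_px"] = float(raw["drift_tol_px"])
        if "tissue_width" in raw:
            kwargs["tissue_width"] = float(raw["tissue_width"])
        if "external_mask_left" in raw:
            kwargs["external_mask_left"] = Path(raw["external_mask_left"])
        if "external_mask_right" in raw:
            kwargs["external_mask_right"] = Path(raw["external_mask_right"])
        return cls(**kwargs)


@dataclass
class RunResult:
    """Everything a single-movie run produced."""

    masks: MaskPair
    trajectories: dict[str, TrackedTrajectories]
    series: dict[str, DisplacementSeries]
    combined_abs_px: np.ndarray
    segments: BeatSegments
    drift: beat_analysis.DriftReport
    irregular: bool
    stiffness: PillarStiffness
    tissue: TissueGeometry
    force_un: dict[str, np.ndarray]  # left, right, mean
    stress_kpa: np.ndarray
    report: metrics_mod.ContractilityReport
    reanchored_at: int
    output_dir: Path | None = None
    warnings: list[str] = field(default_factory=list)


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(f"{record.name}: {record.getMessage()}")


def _track_both(
    movie: MovieFrames, masks: MaskPair
) -> dict[str, TrackedTrajectories]:
    out = {}
    frame0 = movie.frames[0]
    for mask in masks:
        fp, flp = tracking.auto_adjust(frame0, mask)
        markers = tracking.detect_features(frame0, mask, fp)
        out[mask.side] = tracking.track_markers(movie, markers, flp)
    return out


def peak_mean_absolute_displacement(movie: MovieFrames, masks: MaskPair) -> float:
    """Peak of the two-pillar mean absolute displacement, in pixels.

    The quantity used by the mask-sensitivity protocol: detect and track
    with the given masks, average the two pillars' mean absolute
    displacement series, and take its maximum over frames.
    """
    trajectories = _track_both(movie, masks)
    series = [beat_analysis.mean_displacement(t) for t in trajectories.values()]
    return float((0.5 * (series[0].d_abs + series[1].d_abs)).max())


def analyze_movie(movie: MovieFrames, config: RunConfig) -> RunResult:
    """Run the full pipeline on an in-memory movie."""
    collector = _WarningCollector()
    pkg_logger = logging.getLogger("pillartrack")
    pkg_logger.addHandler(collector)
    try:
        if config.external_mask_left is not None:
            masks = MaskPair(
                left=load_external_mask(
                    config.external_mask_left, "left", movie.frame_shape
                ),
                right=load_external_mask(
                    config.external_mask_right, "right", movie.frame_shape
                ),
            )
        else:
            masks = segment_pillars(movie.frames[0], config.data_type)

        trajectories = _track_both(movie, masks)
        # beats are segmented on the baseline-free inter-pillar separation,
        # which identifies relaxed frames whatever phase the movie starts in
        contraction = beat_analysis.contraction_signal(
            trajectories["left"], trajectories["right"]
        )
        segments = beat_analysis.find_valleys(contraction, config.fps)

        adjusted, retrack = beat_analysis.adjust_start(movie, segments)
        reanchored_at = int(segments.valley_frames[0]) if retrack else 0
        if retrack:
            movie = adjusted
            trajectories = _track_both(movie, masks)
            contraction = beat_analysis.contraction_signal(
                trajectories["left"], trajectories["right"]
            )
            segments = beat_analysis.find_valleys(contraction, config.fps)
        series = {s: beat_analysis.mean_displacement(t) for s, t in trajectories.items()}
        combined = 0.5 * (series["left"].d_abs + series["right"].d_abs)

        drift = beat_analysis.detect_drift(combined, segments, config.drift_tol_px)
        irregular = beat_analysis.detect_irregular(segments, combined)

        # mechanics
        stiffness = config.resolve_stiffness()
        if config.tissue_width is not None:
            width = config.tissue_width
        else:
            width = mechanics.measure_tissue_width(
                movie.frames[0], masks, config.length_scale
            )
        tissue = TissueGeometry(width=width, depth=config.tissue_depth)
        force = {
            s: mechanics.twitch_force(series[s], stiffness, config.length_scale)
            for s in ("left", "right")
        }
        force["mean"] = mechanics.force_pair_mean(force["left"], force["right"])
        _, stress_kpa = mechanics.tissue_stress(force["mean"], tissue)

        # per-beat metric inputs: re-baselined series when splitting is
        # requested (drift correction), whole-movie baseline otherwise
        if config.split:
            split_lr = {
                s: beat_analysis.split_beats(trajectories[s], segments)
                for s in ("left", "right")
            }
            beat_abs = [
                0.5 * (l.d_abs + r.d_abs)
                for l, r in zip(split_lr["left"], split_lr["right"])
            ]
        else:
            beat_abs = beat_analysis.slice_beats(combined, segments)

        per_beat = []
        area = tissue.area
        for i, b_abs in enumerate(beat_abs):
            b_um = b_abs * config.length_scale
            b_force = stiffness.k * b_um
            try:
                fwhm = metrics_mod.width_at_fraction(b_um, 0.5, config.fps)
                fw80m = metrics_mod.width_at_fraction(b_um, 0.8, config.fps)
            except MetricsError as exc:
                logger.warning("beat %d: width measurement failed (%s)", i, exc)
                fwhm = fw80m = float("nan")
            contraction, relaxation = metrics_mod.beat_velocities(
                b_abs, config.fps, config.length_scale
            )
            per_beat.append(
                metrics_mod.BeatMetrics(
                    peak_displacement_um=float(b_um.max()),
                    peak_force_un=float(b_force.max()),
                    peak_stress_kpa=float(b_force.max() / area * mechanics.KPA_PER_UN_PER_UM2),
                    contraction_velocity_um_s=contraction,
                    relaxation_velocity_um_s=relaxation,
                    fwhm_s=fwhm,
                    fw80m_s=fw80m,
                )
            )
        rate = metrics_mod.beating_rate(segments, config.fps)
        report = metrics_mod.summarize(
            per_beat, rate, irregular=irregular, drift_detected=drift.detected
        )
        return RunResult(
            masks=masks,
            trajectories=trajectories,
            series=series,
            combined_abs_px=combined,
            segments=segments,
            drift=drift,
            irregular=irregular,
            stiffness=stiffness,
            tissue=tissue,
            force_un=force,
            stress_kpa=stress_kpa,
            report=report,
            reanchored_at=reanchored_at,
            warnings=collector.messages,
        )
    finally:
        pkg_logger.removeHandler(collector)


def _write_outputs(result: RunResult, config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = np.arange(result.combined_abs_px.size)
    for side in ("left", "right"):
        s = result.series[side]
        write_timeseries(
            {
                "frame": frames,
                "disp_row_px": s.d_row,
                "disp_col_px": s.d_col,
                "abs_px": s.d_abs,
                "abs_um": s.abs_um(config.length_scale),
            },
            out_dir / f"displacement_{side}.txt",
        )
    write_timeseries(
        {
            "frame": frames,
            "force_left_un": result.force_un["left"],
            "force_right_un": result.force_un["right"],
            "force_mean_un": result.force_un["mean"],
            "stress_kpa": result.stress_kpa,
        },
        out_dir / "force_stress.txt",
    )
    report = result.report
    lines = [
        f"beating_rate_hz = {report.beating_rate_hz:.17g}",
        f"n_beats = {report.n_beats}",
        f"stiffness_un_per_um = {result.stiffness.k:.17g} ({result.stiffness.source})",
        f"tissue_width_um = {result.tissue.width:.17g}",
        f"tissue_depth_um = {result.tissue.depth:.17g}",
        f"drift_detected = {report.drift_detected}",
        f"irregular_beats = {report.irregular}",
        f"reanchored_at_frame = {result.reanchored_at}",
    ]
    for name in report.mean:
        lines.append(f"mean_{name} = {report.mean[name]:.17g}")
        lines.append(f"sd_{name} = {report.sd[name]:.17g}")
    (out_dir / "metrics_summary.txt").write_text("\n".join(lines) + "\n")
    write_timeseries(report.to_frame(), out_dir / "metrics_per_beat.txt")
    (out_dir / "warnings.txt").write_text(
        "\n".join(result.warnings) + ("\n" if result.warnings else "")
    )

    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    t = frames / config.fps
    for side in ("left", "right"):
        axes[0].plot(t, result.series[side].abs_um(config.length_scale), label=side)
    axes[0].plot(t, result.combined_abs_px * config.length_scale, "k--", label="mean")
    for v in result.segments.valley_frames:
        axes[0].axvline(v / config.fps, color="0.8", lw=0.5)
    axes[0].set_ylabel("displacement (μm)")
    axes[0].legend(loc="upper right", fontsize=8)
    axes[1].plot(t, result.force_un["mean"], color="C3")
    axes[1].set_ylabel("mean force (μN)")
    axes[1].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(out_dir / "timeseries.png", dpi=120)
    plt.close(fig)


def run_single(
    movie_folder: str | Path, config: RunConfig, output_dir: str | Path | None = None
) -> RunResult:
    """Analyze one frame-folder movie and write its outputs.

    Outputs land in ``output_dir`` (default: ``<movie>_results`` next to
    the movie folder).
    """
    movie_folder = Path(movie_folder)
    movie = load_movie(movie_folder)
    result = analyze_movie(movie, config)
    out_dir = (
        Path(output_dir)
        if output_dir is not None
        else movie_folder.parent / f"{movie_folder.name}_results"
    )
    _write_outputs(result, config, out_dir)
    result.output_dir = out_dir
    return result


def run_batch(
    parent_folder: str | Path,
    config: RunConfig,
    output_dir: str | Path | None = None,
) -> tuple[dict[str, RunResult], dict[str, str]]:
    """Analyze every movie folder under ``parent_folder`` with one config.

    Per-movie failures are isolated: the failing stage is logged and the
    batch continues.  An aggregate table (one row per successful movie)
    is written to ``aggregate_metrics.txt``.

    Returns (results, failures) keyed by movie name; raises if no movie
    could be processed at all.
    """
    parent = Path(parent_folder)
    movie_dirs = sorted(
        (d for d in parent.iterdir() if d.is_dir() and not d.name.endswith("_results")),
        key=lambda d: d.name,
    )
    if not movie_dirs:
        raise PillarTrackError(f"no movie folders found under {parent}")
    out_root = Path(output_dir) if output_dir is not None else parent / "batch_results"
    results: dict[str, RunResult] = {}
    failures: dict[str, str] = {}
    rows = []
    for movie_dir in movie_dirs:
        try:
            res = run_single(movie_dir, config, out_root / movie_dir.name)
        except PillarTrackError as exc:
            logger.error("movie %s failed: %s", movie_dir.name, exc)
            failures[movie_dir.name] = str(exc)
            continue
        results[movie_dir.name] = res
        row = {"movie": movie_dir.name, "beating_rate_hz": res.report.beating_rate_hz,
               "n_beats": res.report.n_beats,
               "drift_detected": int(res.report.drift_detected),
               "irregular": int(res.report.irregular)}
        for name, value in res.report.mean.items():
            row[f"mean_{name}"] = value
        rows.append(row)
    if not results:
        raise PillarTrackError(
            f"no movie under {parent} could be processed; "
            f"failures: {failures}"
        )
    import pandas as pd

    out_root.mkdir(parents=True, exist_ok=True)
    write_timeseries(pd.DataFrame(rows), out_root / "aggregate_metrics.txt")
    return results, failures
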