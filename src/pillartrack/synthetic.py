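"""Synthetic brightfield-like microbundle movies with known ground truth.

Renders two speckle-textured pillar caps joined by a tissue band, moving
toward each other with a prescribed periodic waveform.  Sub-pixel motion
is realized by cubic-spline resampling of a precomputed texture field —
never by integer rolls — so the optical-flow tracker faces realistic
interpolated inputs.  Additive Gaussian noise and an optional baseline
drift (a slow rigid translation of both caps perpendicular to the
contraction axis, emulating stage/focal drift) are applied after motion.

Every movie comes with a :class:`GroundTruth` manifest: the true per-pillar
displacement series, valley frames, cap masks and tissue-band width, which
the test suite uses as its oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image_io import MovieFrames, write_movie, write_timeseries

__all__ = [
    "SyntheticMovieSpec",
    "GroundTruth",
    "generate_movie",
    "make_integer_shift_movie",
    "render_fixture_suite",
]


@dataclass(frozen=True)
class SyntheticMovieSpec:
    """Parameters of a synthetic two-pillar movie.

    Lengths are in pixels, times in frames.  ``amplitude`` is the peak
    deflection of *each* pillar from rest; the caps move toward each
    other (left cap +col, right cap -col).  ``noise_sd`` is the standard
    deviation of the per-frame additive Gaussian noise as a fraction of
    the dynamic range.  ``drift_rate`` translates both caps along rows
    (perpendicular to the contraction axis) by ``drift_rate`` px/frame.
    """

    frame_size: tuple[int, int] = (128, 256)
    cap_size: int = 40
    cap_centers: tuple[tuple[float, float], tuple[float, float]] = ((64.0, 64.0), (64.0, 192.0))
    amplitude: float = 3.0
    period: int = 30
    n_beats: int = 3
    phase: float = 0.0
    waveform: str = "raised-cosine"  # or "triangular"
    amplitude_schedule: tuple[float, ...] | None = None
    period_schedule: tuple[int, ...] | None = None
    noise_sd: float = 0.02
    drift_rate: float = 0.0
    band_width: int = 30
    speckle_contrast: float = 0.4
    style: str = "type1"  # "type2" inverts polarity (dark caps on bright bg)
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.period < 4:
            raise ValueError("period must be >= 4 frames")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.waveform not in ("raised-cosine", "triangular"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.style not in ("type1", "type2"):
            raise ValueError(f"unknown style {self.style!r}")
        half = self.cap_size / 2
        gap = (self.cap_centers[1][1] - half) - (self.cap_centers[0][1] + half)
        max_amp = max(self.amplitude, *(self.amplitude_schedule or (0.0,)))
        if gap - 2 * max_amp < 4:
            raise ValueError(
                f"caps would overlap at peak deflection (gap {gap:.1f} px, amplitude {max_amp} px)"
            )


@dataclass
class GroundTruth:
    """Manifest of true quantities for a rendered movie."""

    disp_left: np.ndarray  # (F, 2) true (row, col) displacement of the left cap
    disp_right: np.ndarray  # (F, 2) of the right cap
    abs_displacement: np.ndarray  # (F,) |displacement| per pillar (equal by symmetry)
    valley_frames: np.ndarray  # frames where the waveform is at rest
    cap_masks: tuple[np.ndarray, np.ndarray]  # boolean masks on the frame-0 grid
    band_width_px: float
    amplitude: float
    spec: SyntheticMovieSpec = field(repr=False)


def _waveform_series(spec: SyntheticMovieSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (deflection series in px, true valley frames).

    Uniform mode uses ``amplitude``/``period``/``phase``; schedule mode
    concatenates per-beat segments with individual amplitudes/periods
    (always starting from a valley).  The movie extends a third of a
    period past the last valley, so that valley is an interior minimum
    of the series; the partial tail is what the analysis discards.
    """
    if spec.amplitude_schedule is not None or spec.period_schedule is not None:
        amps = spec.amplitude_schedule or (spec.amplitude,) * spec.n_beats
        pers = spec.period_schedule or (spec.period,) * spec.n_beats
        if len(amps) != len(pers):
            amps = tuple(amps) * len(pers) if len(amps) == 1 else amps
        segments, valleys, t0 = [], [0], 0
        for amp, per in zip(amps, pers):
            tau = np.arange(per)
            if spec.waveform == "raised-cosine":
                w = amp * (1.0 - np.cos(2 * np.pi * tau / per)) / 2.0
            else:
                w = amp * (1.0 - np.abs(tau / per * 2.0 - 1.0))
            segments.append(w)
            t0 += per
            valleys.append(t0)
        tail = np.arange(pers[-1] // 3 + 1)
        if spec.waveform == "raised-cosine":
            w_tail = amps[-1] * (1.0 - np.cos(2 * np.pi * tail / pers[-1])) / 2.0
        else:
            w_tail = amps[-1] * (1.0 - np.abs(tail / pers[-1] * 2.0 - 1.0))
        series = np.concatenate(segments + [w_tail])
        return series, np.asarray(valleys)

    n_frames = spec.n_beats * spec.period + 1 + spec.period // 3
    t = np.arange(n_frames)
    u = t / spec.period + spec.phase / (2 * np.pi)  # cycle coordinate
    if spec.waveform == "raised-cosine":
        series = spec.amplitude * (1.0 - np.cos(2 * np.pi * u)) / 2.0
    else:
        series = spec.amplitude * (1.0 - np.abs(np.mod(u, 1.0) * 2.0 - 1.0))
    # valleys sit where the cycle coordinate is integer
    first = np.ceil(u[0] - 1e-9)
    valley_t = (np.arange(first, u[-1] + 1e-9) - spec.phase / (2 * np.pi)) * spec.period
    valleys = np.round(valley_t[(valley_t > -0.5) & (valley_t < n_frames - 0.5)]).astype(int)
    return series, valleys


def _soft_box(shape: tuple[int, int], r0: float, r1: float, c0: float, c1: float,
              edge: float = 1.0) -> np.ndarray:
    """Rectangle indicator with smooth (logistic) edges of scale ``edge`` px."""
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    vr = 1.0 / (1.0 + np.exp(-(rr - r0) / edge)) * (1.0 / (1.0 + np.exp((rr - r1) / edge)))
    vc = 1.0 / (1.0 + np.exp(-(cc - c0) / edge)) * (1.0 / (1.0 + np.exp((cc - c1) / edge)))
    return vr * vc


def _speckle(shape: tuple[int, int], rng: np.random.Generator, sigma: float = 1.2) -> np.ndarray:
    """Band-limited speckle in [-1, 1]: smoothed white noise, renormalized."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return np.clip(raw / (3 * raw.std()), -1.0, 1.0)


def generate_movie(spec: SyntheticMovieSpec) -> tuple[MovieFrames, GroundTruth]:
    """Render a synthetic movie and its ground-truth manifest.

    Deterministic for a fixed spec (including seed): calling twice with
    the same spec yields bit-identical frames.
    """
    rng = np.random.default_rng(spec.seed)
    R, C = spec.frame_size
    defl, valleys = _waveform_series(spec)
    n_frames = defl.size
    t = np.arange(n_frames)
    drift = spec.drift_rate * t

    # per-pillar displacement vectors (row, col): caps move toward each other
    disp_left = np.column_stack([drift, +defl])
    disp_right = np.column_stack([drift, -defl])

    if spec.style == "type1":
        bg_base, cap_base, band_base = 0.15, 0.55, 0.38
    else:  # type2: dark cantilever tips on a brighter background
        bg_base, cap_base, band_base = 0.62, 0.22, 0.45

    background = bg_base + 0.02 * _speckle((R, C), rng, sigma=3.0)

    half = spec.cap_size / 2
    cap_fields, cap_masks = [], []
    for (cr, cc) in spec.cap_centers:
        tex = spec.speckle_contrast / 2 * _speckle((R, C), rng, sigma=1.2)
        window = _soft_box((R, C), cr - half, cr + half, cc - half, cc + half)
        cap_fields.append(((cap_base - bg_base) + tex) * window)
        rr, ccg = np.mgrid[0:R, 0:C]
        cap_masks.append(
            (np.abs(rr - cr) <= half) & (np.abs(ccg - cc) <= half)
        )
    # prefilter once for cubic-spline resampling of the moving caps
    cap_splines = [ndimage.spline_filter(f, order=3) for f in cap_fields]

    band_row = (spec.cap_centers[0][0] + spec.cap_centers[1][0]) / 2
    band_tex = 0.04 * _speckle((1, 512), rng, sigma=2.0)[0]  # stretched along the band

    rr = np.arange(R, dtype=float)[:, None]
    cc = np.arange(C, dtype=float)[None, :]
    base_coords = np.mgrid[0:R, 0:C].astype(float)

    frames = np.empty((n_frames, R, C), dtype=np.uint16 if spec.bit_depth == 16 else np.uint8)
    scale = 2**spec.bit_depth - 1
    inner_left0 = spec.cap_centers[0][1] + half
    inner_right0 = spec.cap_centers[1][1] - half

    for k in range(n_frames):
        img = background.copy()
        for fld, d in zip(cap_splines, (disp_left[k], disp_right[k])):
            coords = np.array([base_coords[0] - d[0], base_coords[1] - d[1]])
            img += ndimage.map_coordinates(fld, coords, order=3, prefilter=False, mode="nearest")
        # tissue band stretches linearly between the (moving) inner cap edges
        xl = inner_left0 + disp_left[k, 1]
        xr = inner_right0 + disp_right[k, 1]
        row_shift = drift[k]
        vr = (1.0 / (1.0 + np.exp(-(rr - (band_row + row_shift - spec.band_width / 2))))
              / (1.0 + np.exp((rr - (band_row + row_shift + spec.band_width / 2)))))
        vc = 1.0 / (1.0 + np.exp(-(cc[0] - (xl - 1.0)))) / (1.0 + np.exp(cc[0] - (xr + 1.0)))
        u = np.clip((cc[0] - xl) / max(xr - xl, 1.0), 0.0, 1.0)
        tex = np.interp(u * (band_tex.size - 1), np.arange(band_tex.size), band_tex)
        img += vr * vc[None, :] * ((band_base - bg_base) + tex[None, :])
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=(R, C))
        frames[k] = np.round(np.clip(img, 0.0, 1.0) * scale).astype(frames.dtype)

    movie = MovieFrames(frames=frames, bit_depth=spec.bit_depth)
    truth = GroundTruth(
        disp_left=disp_left,
        disp_right=disp_right,
        abs_displacement=np.hypot(defl, drift),
        valley_frames=valleys,
        cap_masks=(cap_masks[0], cap_masks[1]),
        band_width_px=float(spec.band_width),
        amplitude=float(max(defl)),
        spec=spec,
    )
    return movie, truth


def make_integer_shift_movie(
    base_frame: np.ndarray, shift_per_frame: tuple[int, int], n_frames: int, bit_depth: int = 8
) -> MovieFrames:
    """Movie built by integer-rolling a single frame — an exact-motion oracle.

    Unlike :func:`generate_movie` this moves the *whole scene*, so the
    recovered displacement equals the roll schedule with no interpolation
    error at all.
    """
    frames = np.stack(
        [np.roll(base_frame, (k * shift_per_frame[0], k * shift_per_frame[1]), axis=(0, 1))
         for k in range(n_frames)]
    )
    return MovieFrames(frames=frames, bit_depth=bit_depth)


#: Canonical fixture specs, keyed by name.  Seeds are fixed offsets so the
#: suite is reproducible; amplitudes/periods are the study conditions used
#: throughout the tests.
FIXTURE_SPECS: dict[str, SyntheticMovieSpec] = {
    "static": SyntheticMovieSpec(amplitude=0.0, n_beats=2, noise_sd=0.0, seed=11),
    "subpixel_clean": SyntheticMovieSpec(amplitude=3.0, noise_sd=0.0, seed=12),
    "subpixel_noisy": SyntheticMovieSpec(amplitude=3.0, noise_sd=0.02, seed=13),
    "drifting": SyntheticMovieSpec(amplitude=3.0, n_beats=4, drift_rate=0.05, noise_sd=0.0, seed=14),
    "irregular": SyntheticMovieSpec(
        amplitude_schedule=(3.0, 3.0, 1.5, 3.0), period_schedule=(30, 30, 30, 30),
        noise_sd=0.0, seed=15,
    ),
    "low_contrast": SyntheticMovieSpec(amplitude=3.0, speckle_contrast=0.06, noise_sd=0.01, seed=16),
    "type1_like": SyntheticMovieSpec(amplitude=3.0, noise_sd=0.02, style="type1", seed=17),
    "type2_like": SyntheticMovieSpec(amplitude=3.0, noise_sd=0.02, style="type2", seed=18),
}


def render_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Write the canonical fixture movies as TIFF frame folders + manifests.

    Idempotent for the fixed seeds above.  Each folder gets the frames, a
    ``manifest.txt`` with the true displacement series and a
    ``params.txt`` with the generating parameters.
    """
    out_dir = Path(out_dir)
    written: dict[str, Path] = {}
    for name, spec in FIXTURE_SPECS.items():
        folder = out_dir / name
        movie, truth = generate_movie(spec)
        write_movie(movie, folder)
        write_timeseries(
            {
                "frame": np.arange(movie.n_frames),
                "disp_row_left_px": truth.disp_left[:, 0],
                "disp_col_left_px": truth.disp_left[:, 1],
                "disp_row_right_px": truth.disp_right[:, 0],
                "disp_col_right_px": truth.disp_right[:, 1],
                "abs_px": truth.abs_displacement,
            },
            folder / "manifest.txt",
        )
        with open(folder / "params.txt", "w") as fh:
            for key, value in vars(spec).items():
                fh.write(f"{key}={value}\n")
        written[name] = folder
    return written
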