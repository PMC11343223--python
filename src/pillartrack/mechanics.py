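"""Beam mechanics: pillar stiffness, twitch force, tissue stress.

The pillar is a cantilever of known elastic modulus and geometry; the
tissue pulls at a point ``a`` along its length ``L``.  Twitch force
follows Hooke's law, F = k·δ, with stiffness either measured or derived
from the cantilever equation

    k = 6 E I / (a² (3L − a)),

which reduces to the classical tip-load stiffness 3EI/L³ at a = L.  The
second moment of area is I = w·t³/12 for rectangular and I = π·D⁴/64 for
circular cross sections.

Unit policy: lengths in μm, forces in μN, stiffness in μN/μm, elastic
modulus accepted in kPa and converted internally (1 kPa = 1e-3 μN/μm²);
stress is reported in both μN/μm² and kPa (1 μN/μm² = 1 MPa = 1000 kPa).

Deflection convention: the package reports the *mean of the two pillars'
deflections from rest*, not the change in inter-pillar distance.  For a
symmetric contraction the distance-change convention yields forces and
stresses exactly twice as high; both are exposed so the factor can be
audited (:func:`force_interpillar_convention`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from skimage.filters import threshold_otsu

from .beat_analysis import DisplacementSeries
from .errors import MechanicsError
from .segmentation import MaskPair

#: Pillar stiffness used for all Type-1 devices, μN/μm.
TYPE1_STIFFNESS_UN_PER_UM = 2.677

KPA_PER_UN_PER_UM2 = 1000.0  # 1 μN/μm² = 1 MPa = 1000 kPa


@dataclass(frozen=True)
class RectangularSection:
    """Rectangular cross section: width w and thickness t, μm."""

    w: float
    t: float


@dataclass(frozen=True)
class CircularSection:
    """Circular cross section of diameter D, μm."""

    D: float


CrossSection = Union[RectangularSection, CircularSection]


@dataclass(frozen=True)
class PillarGeometry:
    """Cantilever geometry for stiffness derivation.

    E_kpa : elastic modulus in kPa (PDMS is typically O(10³) kPa);
    L : cantilever length, μm; a : location of force application along
    the cantilever, μm (0 < a <= L).
    """

    E_kpa: float
    L: float
    a: float
    cross_section: CrossSection

    def __post_init__(self) -> None:
        if self.E_kpa <= 0 or self.L <= 0 or self.a <= 0:
            raise MechanicsError("E, L and a must all be positive")
        if self.a > self.L:
            raise MechanicsError(f"force location a={self.a} exceeds length L={self.L}")


@dataclass(frozen=True)
class PillarStiffness:
    """Stiffness in μN/μm, measured experimentally or derived from geometry."""

    k: float
    source: str  # "measured" | "derived"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise MechanicsError(f"stiffness must be positive, got {self.k}")


@dataclass(frozen=True)
class TissueGeometry:
    """Tissue cross section: auto-measured width x user-supplied depth, μm."""

    width: float
    depth: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.depth <= 0:
            raise MechanicsError("tissue width and depth must be positive")

    @property
    def area(self) -> float:
        return self.width * self.depth


def moment_of_inertia(section: CrossSection) -> float:
    """Second moment of area in μm⁴: w·t³/12 or π·D⁴/64."""
    if isinstance(section, RectangularSection):
        if section.w <= 0 or section.t <= 0:
            raise MechanicsError("rectangular section dimensions must be positive")
        return section.w * section.t**3 / 12.0
    if isinstance(section, CircularSection):
        if section.D <= 0:
            raise MechanicsError("diameter must be positive")
        return math.pi * section.D**4 / 64.0
    raise MechanicsError(f"unknown cross section {section!r}")


def cantilever_stiffness(E: float, I: float, L: float, a: float) -> float:
    """k = 6EI / (a²(3L − a)) in whatever consistent units E·I/L³ carries."""
    if a <= 0 or a > L:
        raise MechanicsError(f"need 0 < a <= L, got a={a}, L={L}")
    return 6.0 * E * I / (a**2 * (3.0 * L - a))


def pillar_stiffness(geom: PillarGeometry) -> PillarStiffness:
    """Derive stiffness (μN/μm) from cantilever geometry.

    E is converted from kPa to μN/μm² so that with I in μm⁴ and lengths
    in μm the stiffness emerges in μN/μm.
    """
    E_un_um2 = geom.E_kpa / KPA_PER_UN_PER_UM2
    I = moment_of_inertia(geom.cross_section)
    return PillarStiffness(
        k=cantilever_stiffness(E_un_um2, I, geom.L, geom.a), source="derived"
    )


def twitch_force(
    series: DisplacementSeries, k: PillarStiffness, length_scale: float
) -> np.ndarray:
    """Hooke's-law force series F(t) = k·δ(t) in μN for one pillar.

    δ is the pillar's mean absolute displacement converted to μm.
    """
    return k.k * series.abs_um(length_scale)


def force_pair_mean(force_left: np.ndarray, force_right: np.ndarray) -> np.ndarray:
    """The package's reported convention: mean of the two pillars' forces."""
    return 0.5 * (np.asarray(force_left) + np.asarray(force_right))


def force_interpillar_convention(
    series_left: DisplacementSeries,
    series_right: DisplacementSeries,
    k: PillarStiffness,
    length_scale: float,
) -> np.ndarray:
    """Force from the change in inter-pillar distance (δ₁ + δ₂).

    Provided for auditing only: for a symmetric contraction this reports
    forces exactly twice the per-pillar-mean convention.
    """
    delta_sum = (series_left.abs_um(length_scale) + series_right.abs_um(length_scale))
    return k.k * delta_sum


def tissue_stress(force_un: np.ndarray, tg: TissueGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Stress series σ(t) = F(t) / (width·depth): (μN/μm², kPa)."""
    sigma = np.asarray(force_un, dtype=float) / tg.area
    return sigma, sigma * KPA_PER_UN_PER_UM2


def measure_tissue_width(
    first_valley_frame: np.ndarray, masks: MaskPair, length_scale: float
) -> float:
    """Automatic tissue-width measurement on the first valley frame, μm.

    The strip between the two pillars' inner edges is examined around the
    inter-pillar midline: the column-averaged intensity profile of the
    central third of the strip is thresholded (Otsu, hence invariant to
    global intensity rescaling) and the width is the extent of the
    longest contiguous above-threshold run of rows.

    Raises
    ------
    MechanicsError
        When no tissue band is detectable between the pillars; supply the
        width manually in that case.
    """
    frame = np.asarray(first_valley_frame, dtype=np.float64)
    inner_left = masks.left.bbox[3]
    inner_right = masks.right.bbox[2]
    if inner_right - inner_left < 6:
        raise MechanicsError("no room between pillar masks to measure the tissue width")
    third = (inner_right - inner_left) // 3
    strip = frame[:, inner_left + third: inner_right - third]
    profile = strip.mean(axis=1)
    if np.ptp(profile) <= 0:
        raise MechanicsError(
            "no detectable tissue band between the pillars; supply the width manually"
        )
    thr = threshold_otsu(profile)
    above = profile > thr
    if not above.any():
        raise MechanicsError(
            "no detectable tissue band between the pillars; supply the width manually"
        )
    # longest contiguous run of above-threshold rows
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    lengths = ends - starts
    width_px = int(lengths.max())
    if width_px < 2:
        raise MechanicsError("detected tissue band is thinner than 2 px; not credible")
    return width_px * length_scale
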