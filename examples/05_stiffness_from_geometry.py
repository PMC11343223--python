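"""Derive pillar stiffness from cantilever geometry and convert to force.

When the stiffness has not been measured experimentally it follows from
beam theory, k = 6EI / (a^2 (3L - a)), with I = w t^3 / 12 (rectangular)
or pi D^4 / 64 (circular).
"""

from pillartrack import (
    PillarGeometry,
    RectangularSection,
    CircularSection,
    moment_of_inertia,
    pillar_stiffness,
)

# A PDMS pillar: E = 1.5 MPa, 400 um long, tissue attached at the tip.
geom = PillarGeometry(
    E_kpa=1500.0, L=400.0, a=400.0, cross_section=RectangularSection(w=150.0, t=150.0)
)
I = moment_of_inertia(geom.cross_section)
k = pillar_stiffness(geom)
print(f"second moment of area I = {I:.4g} um^4")
print(f"derived stiffness k = {k.k:.3f} uN/um (source: {k.source})")
print(f"a 10 um tip deflection therefore reports F = {k.k * 10:.2f} uN")

round_I = moment_of_inertia(CircularSection(D=150.0))
print(f"a circular pillar of the same diameter: I = {round_I:.4g} um^4")
# At a = L the formula reduces to the classical tip-load stiffness 3EI/L^3.
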