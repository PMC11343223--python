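"""Mask-perturbation sensitivity protocol.

Tracks the same movie with the automatic masks and with eroded/dilated
variants (5x5 kernel, applied once and four times) and reports how much
the peak mean absolute displacement moves.  Robust segmentation should
keep all changes below 10%.
"""

from pillartrack import MaskPair, SyntheticMovieSpec, generate_movie, perturb_mask, segment_pillars
from pillartrack.pipeline import peak_mean_absolute_displacement

movie, _ = generate_movie(SyntheticMovieSpec(amplitude=3.0, noise_sd=0.02, seed=17))
reference = segment_pillars(movie.frames[0], "type1")
ref_peak = peak_mean_absolute_displacement(movie, reference)
print(f"reference-mask peak displacement: {ref_peak:.3f} px")

for op in ("erode", "dilate"):
    for iterations in (1, 4):
        perturbed = MaskPair(
            left=perturb_mask(reference.left, op, iterations),
            right=perturb_mask(reference.right, op, iterations),
        )
        peak = peak_mean_absolute_displacement(movie, perturbed)
        change = 100 * abs(peak - ref_peak) / ref_peak
        print(f"{op:>6} x{iterations}: peak {peak:.3f} px, change {change:.2f}%")
# The tracked displacement is a property of the pillar texture, not of the
# exact mask outline, so modest mask errors barely move the result.
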