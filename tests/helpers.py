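"""Shared test construction helpers."""

from reefcarb.survey import BenthicTransect, Intercept


def make_transect(counts: dict[str, int], contour_m=None, planar=2.0, depth=6.0):
    """Build a transect by tiling category blocks; corals are P. lobata."""
    intercepts, pos = [], 0
    for cat, n in counts.items():
        taxon = "Porites lobata" if cat == "coral" else None
        for _ in range(n):
            intercepts.append(Intercept(pos, cat, taxon))
            pos += 1
    contour_m = contour_m if contour_m is not None else pos / 100.0
    return BenthicTransect("T", "S1", depth, planar, contour_m, intercepts)
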