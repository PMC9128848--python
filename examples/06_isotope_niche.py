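"""Isotopic niche geometry: 40% ellipse and 100% convex hull.

Simulates blood (breeding) and feather (non-breeding) d13C/d15N groups,
applies a user-supplied feather-to-blood tissue correction, and prints the
standard niche summaries per group.
"""

import birdyear as by
from birdyear import synthetic

samples = by.simulate_isotopes(
    synthetic.DEFAULT_ISOTOPE_GROUPS, synthetic.DEFAULT_ISOTOPE_COV, 15, seed=4
)
# tissue-correction offsets must come from the literature for the taxon
samples = by.apply_feather_correction(samples, d13c_offset=-1.9, d15n_offset=0.6)

for (tissue, period), g in samples.groupby(["tissue", "period"]):
    ell = by.niche_ellipse(g, coverage=0.40)
    hull = by.niche_hull(g)
    print(f"{tissue:7s} {period:13s} n={len(g)}  "
          f"centroid ({ell.centroid[0]:6.2f}, {ell.centroid[1]:5.2f}) permil  "
          f"40% ellipse {ell.area:5.2f}  hull {hull.area:6.2f} permil^2")

print(
    "\nThe 40% ellipse captures the typical core of each group's isotopic "
    "niche; the convex hull is the full spread including outliers.  The "
    "centroid shift between tissues reflects habitat/trophic change across "
    "the annual cycle."
)
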