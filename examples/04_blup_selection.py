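"""BLUP-based simultaneous selection for performance and stability:
harmonic mean of genotypic values (HMGV) and the weighted average of
absolute interaction scores (WAASB), with the four-quadrant classification.
"""

import pandas as pd

from metstab import SyntheticConfig, cell_means, generate_met
from metstab.blup import (
    composite_score,
    fit_blups,
    hmgv,
    performance_stability_quadrants,
    waasb,
)

met = generate_met(SyntheticConfig(seed=7))
cells = cell_means(met, "FRY")
blup = fit_blups(met, "FRY")
print(f"shrinkage: genotype {blup.shrinkage_g:.3f}, interaction {blup.shrinkage_ge:.3f}")

h = hmgv(blup)
w = waasb(blup)
means = pd.Series(cells.genotype_means, index=list(cells.genotypes), name="mean")
table = pd.concat(
    [means.round(2), h.round(2).add_prefix("hmgv_"), w.round(3).add_prefix("waasb_"),
     performance_stability_quadrants(w, means),
     composite_score(means, w["waasb"]).round(1)],
    axis=1,
)
print(table.to_string())
print()
print("HMGV rank 1 = best yield after penalizing instability; WAASB rank 1 =")
print("smallest interaction footprint; group 4 = above-average mean AND stable")
print("(the broad-adaptation quadrant); composite = 50/50 performance-stability blend.")
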