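"""AMMI and GGE decompositions of a simulated trial: interaction axes, the
ASV stability value, the which-won-where polygon and environment metrics.
"""

import numpy as np

from metstab import SyntheticConfig, cell_means, generate_met
from metstab.ammi import ammi_decompose, asv
from metstab.gge import environment_metrics, gge_decompose, which_won_where

met = generate_met(SyntheticConfig(seed=7))
cells = cell_means(met, "FRY")

am = ammi_decompose(cells)
print("AMMI interaction axes (% of GxE SS):",
      np.round(100 * am.ss_share[:4], 1), "...")
print("ASV (smaller = more stable):")
print(asv(am).frame.round(3).sort_values("rank").to_string())
print()

gg = gge_decompose(cells, svp="environment")
print("GGE PC1/PC2 explain", np.round(100 * gg.pc_share[:2], 1), "% of G+GxE")
www = which_won_where(gg)
print("which-won-where mega-environments (winner -> environments):")
for winner, envs in www.mega_environments:
    print(f"  {winner}: {', '.join(envs)}")
print()
em = environment_metrics(gg)
print("environment discrimination (vector length) and representativeness")
print("(cosine with the average-environment axis; 1 = fully representative):")
print(em.frame.round(3).to_string())
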