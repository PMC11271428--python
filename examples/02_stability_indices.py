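"""Compute the univariate stability/adaptability indices for every genotype
of a simulated trial and rank them.

Low Wi / Pi / S(1) / S(6) and a slope near 1 mark stable, broadly adapted
genotypes; a confidence index above 100 means the genotype reliably beats
the environment average.
"""

from metstab import SyntheticConfig, cell_means, generate_met, joint_anova
from metstab.compare import build_rank_matrix
from metstab.indices import environmental_index, stability_table

met = generate_met(SyntheticConfig(seed=7))
cells = cell_means(met, "FRY")
anova = joint_anova(met, "FRY")

table = stability_table(met, cells, "FRY", ms_error=anova.ms("residual"), reps=3)
print(table.round(2).to_string())
print()
idx = environmental_index(cells)
print("environment quality index I_j (positive = favorable environment):")
print(idx.round(2).to_string())
print()
ranks = build_rank_matrix(table)
print("display ranks (1 = best under each method's own reading):")
print(ranks.display.to_string())
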