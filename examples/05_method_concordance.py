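"""Rank concordance between stability methods on the published cassava VCU
rankings: Spearman correlations and PCA grouping into stability concepts.
"""

import pandas as pd

from metstab import datasets
from metstab.compare import (
    pca_group_methods,
    spearman_matrix,
    stability_concept_classification,
)

table = datasets.load_stability("FRY")
rank_cols = [c for c in table.columns if c.endswith("_rank")]
ranks = table[rank_cols].rename(columns=lambda c: c[:-5])
# the trait's own mean ranking joins the matrix as the performance reference
ranks["mean"] = table["mean"].rank(ascending=False).astype(int)

out = spearman_matrix(ranks)
print("Spearman correlations between published FRY rankings (excerpt):")
print(out["rho"].loc[["lig", "lid", "lif", "hmgv", "bi", "dp"],
                     ["hmgv", "dp", "mean"]].round(2).to_string())
print()

groups = pca_group_methods(out["rho"], n_groups=4)
concepts = stability_concept_classification(groups.groups, out["rho"]["mean"])
summary = pd.concat([groups.groups, concepts], axis=1)
print(f"PC1+PC2 explain {groups.explained.sum():.1f}% of the method-correlation structure")
print(summary.sort_values("group").to_string())
print()
print("methods grouped with the trait-mean ranking follow dynamic (agronomic)")
print("stability; groups uncorrelated with performance follow static stability.")
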