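"""Published reference tables from a cassava VCU multi-environment trial.

The source study evaluated 12 cassava genotypes in 12 environments (Bahia,
Brazil; three harvest years x four locations, RCBD with 3 blocks) for fresh
root yield (FRY, t/ha) and root dry matter content (DMC, %).  The plot-level
raw data were not deposited; what is public — and shipped here as small CSV
files — are the joint-ANOVA sums of squares, the variance-component /
genetic-parameter table, and the per-genotype stability-index values with
their published rankings.  These tables exercise every derived chain of the
package (EMS solving, genetic parameters, percent-SS partitions, rank
machinery, rank concordance) without access to raw plots.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..anova import AnovaTable, anova_table_from_ss

TRAITS = ("FRY", "DMC")

#: published overall trial means per trait
GRAND_MEANS = {"FRY": 26.14, "DMC": 36.22}


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_anova_ss() -> pd.DataFrame:
    """Long table of (trait, source, df, ss) from the published joint ANOVA."""
    return _read("cassava_vcu_anova.csv")


def reference_anova(trait: str) -> AnovaTable:
    """Published joint-ANOVA table for one trait as an AnovaTable.

    Interaction principal-component rows (pc1, pc2) are carried along for
    percent-share computations but take no part in EMS solving.
    """
    df = load_anova_ss()
    sub = df[df["trait"] == trait]
    if len(sub) == 0:
        raise KeyError(f"unknown trait {trait!r}; available: {TRAITS}")
    rows = [(r.source, int(r.df), float(r.ss)) for r in sub.itertuples()]
    return anova_table_from_ss(rows)


def load_genetic_parameters() -> pd.DataFrame:
    """Published variance components and genetic parameters, one column per trait."""
    return _read("cassava_vcu_genetic_parameters.csv").set_index("parameter")


def load_stability(trait: str) -> pd.DataFrame:
    """Published per-genotype stability-index values and rankings for one trait.

    Columns: genotype means with Scott-Knott letters, then for each method a
    value column and its published ``*_rank`` column.
    """
    name = {"FRY": "cassava_vcu_stability_fry.csv", "DMC": "cassava_vcu_stability_dmc.csv"}
    if trait not in name:
        raise KeyError(f"unknown trait {trait!r}; available: {TRAITS}")
    return _read(name[trait]).set_index("genotype")


#: design constants of the reference trial
DESIGN = {"n_genotypes": 12, "n_environments": 12, "n_blocks": 3}
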