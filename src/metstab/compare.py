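"""Cross-method rank concordance: rank matrix, Spearman correlations,
PCA grouping of methods, and stability-concept labels.

Each stability method orders the genotypes under its own direction rule
(ascending better, descending better, or closest to a target such as a unit
regression slope).  Ties receive average ranks; for display the averages are
rounded to the nearest integer (banker's rounding), while exact averages are
always used for inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ValidationError

# ---------------------------------------------------------------------------
# direction rules
# ---------------------------------------------------------------------------

ASCENDING = "ascending_better"
DESCENDING = "descending_better"


def closest_to_target(target: float) -> tuple[str, float]:
    return ("closest_to_target", target)


#: default rule per method column, matching how each statistic is read:
#: variance-type measures rank ascending, confidence/performance measures
#: descending, regression slopes by distance to their null value.
DEFAULT_DIRECTIONS: dict[str, object] = {
    "mean": DESCENDING,
    "dp": ASCENDING,
    "waasb": ASCENDING,
    "asv": ASCENDING,
    "gge": closest_to_target(0.0),
    "wi": ASCENDING,
    "pi": ASCENDING,
    "si1": ASCENDING,
    "si6": ASCENDING,
    "hmgv": DESCENDING,
    "er_s2di": closest_to_target(0.0),
    "er_rmse": ASCENDING,
    "er_r2": closest_to_target(1.0),
    "er_bi": closest_to_target(1.0),
    "pj_bi": closest_to_target(1.0),
    "pj_di": closest_to_target(0.0),
    "ann_li_general": DESCENDING,
    "ann_li_favorable": DESCENDING,
    "ann_li_unfavorable": DESCENDING,
    "s2x": ASCENDING,
    "composite": DESCENDING,
}


def rank_genotypes(values: pd.Series, direction: object) -> pd.DataFrame:
    """Rank one method column; returns exact (average-tie) and display ranks.

    Rank 1 is best under the rule.  Display ranks round the tied averages to
    the nearest integer.
    """
    v = values.to_numpy(dtype=float)
    if not np.isfinite(v).all():
        raise ValidationError("values must be finite")
    if direction == ASCENDING:
        key = v
    elif direction == DESCENDING:
        key = -v
    elif isinstance(direction, tuple) and direction[0] == "closest_to_target":
        key = np.abs(v - direction[1])
    else:
        raise ValidationError(f"unregistered direction rule {direction!r}")
    exact = stats.rankdata(key, method="average")
    display = np.round(exact).astype(int)  # banker's rounding of .5 averages
    return pd.DataFrame({"rank": exact, "display_rank": display}, index=values.index)


@dataclass(frozen=True)
class RankMatrix:
    """Genotype x method matrix of ranks plus the direction registry."""

    ranks: pd.DataFrame  # exact average-tie ranks
    display: pd.DataFrame  # rounded ranks, as printed in report tables
    directions: dict[str, object]


def build_rank_matrix(
    values: pd.DataFrame, directions: Mapping[str, object] | None = None
) -> RankMatrix:
    """Rank every method column of a genotype x method value table."""
    registry = dict(DEFAULT_DIRECTIONS)
    if directions:
        registry.update(directions)
    missing = [c for c in values.columns if c not in registry]
    if missing:
        raise ValidationError(f"no direction registered for method(s): {missing}")
    exact = {}
    display = {}
    for col in values.columns:
        r = rank_genotypes(values[col], registry[col])
        exact[col] = r["rank"]
        display[col] = r["display_rank"]
    return RankMatrix(
        pd.DataFrame(exact, index=values.index),
        pd.DataFrame(display, index=values.index),
        {c: registry[c] for c in values.columns},
    )


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman_matrix(ranks: pd.DataFrame) -> dict:
    """Pairwise Spearman correlations between method rank columns.

    Works on exact (average-tie) ranks.  Constant columns yield NaN with a
    warning.  Returns dict with 'rho', 'p' and 'stars' DataFrames.
    """
    if len(ranks) < 3:
        raise ValidationError("need at least 3 genotypes")
    cols = list(ranks.columns)
    m = len(cols)
    rho = np.eye(m)
    pval = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            x, y = ranks.iloc[:, a], ranks.iloc[:, b]
            if x.nunique() == 1 or y.nunique() == 1:
                warnings.warn(f"constant rank column; correlation undefined for {cols[a]}/{cols[b]}")
                r, p = np.nan, np.nan
            else:
                res = stats.spearmanr(x, y)
                r, p = float(res.statistic), float(res.pvalue)
            rho[a, b] = rho[b, a] = r
            pval[a, b] = pval[b, a] = p
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(pval, index=cols, columns=cols)
    stars = p_df.where(np.eye(m) == 0).map(
        lambda p: significance_stars(p) if np.isfinite(p) else ""
    )
    return {"rho": rho_df, "p": p_df, "stars": stars}


@dataclass(frozen=True)
class ConcordanceResult:
    spearman: pd.DataFrame
    pca_loadings: pd.DataFrame  # methods x (PC1, PC2)
    explained: np.ndarray  # percent variance of PC1, PC2
    groups: pd.Series  # method -> group id (1..n_groups)


def pca_group_methods(spearman: pd.DataFrame, n_groups: int = 4) -> ConcordanceResult:
    """Eigen-decompose the rank-correlation matrix and cluster the methods.

    Loadings are eigenvector components scaled by sqrt(eigenvalue); methods
    are grouped by Ward hierarchical clustering of their 2-D loadings.
    """
    m = len(spearman)
    if m < n_groups:
        raise ValidationError(f"cannot form {n_groups} groups from {m} methods")
    c = spearman.to_numpy(dtype=float)
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValidationError("correlation matrix must be symmetric")
    eigval, eigvec = np.linalg.eigh(c)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval_clipped = np.clip(eigval, 0.0, None)
    explained = 100.0 * eigval_clipped[:2] / eigval_clipped.sum()
    loadings = eigvec[:, :2] * np.sqrt(eigval_clipped[:2])
    # deterministic sign: largest-|.| loading positive per component
    for k in range(2):
        pivot = np.argmax(np.abs(loadings[:, k]))
        if loadings[pivot, k] < 0:
            loadings[:, k] = -loadings[:, k]
    link = linkage(loadings, method="ward")
    labels = fcluster(link, t=n_groups, criterion="maxclust")
    return ConcordanceResult(
        spearman=spearman,
        pca_loadings=pd.DataFrame(loadings, index=spearman.index, columns=["PC1", "PC2"]),
        explained=explained,
        groups=pd.Series(labels, index=spearman.index, name="group"),
    )


def stability_concept_classification(
    groups: pd.Series,
    trait_corr: pd.Series,
    trait_column: str = "mean",
    threshold: float = 0.6,
    static_band: float = 0.1,
) -> pd.Series:
    """Label each method group dynamic / static / weak.

    A group is *dynamic* when it contains the trait-mean ranking itself or
    its mean |correlation| with the trait ranking exceeds ``threshold``
    (methods that reward tracking good environments); *static* when that mean
    |correlation| is below ``static_band`` (methods indifferent to
    performance level); anything in between is *weak*.
    """
    labels = {}
    for gid in groups.unique():
        members = groups.index[groups == gid]
        if trait_column in members:
            labels[gid] = "dynamic"
            continue
        corr = trait_corr.reindex(members).abs().mean()
        if corr > threshold:
            labels[gid] = "dynamic"
        elif corr < static_band:
            labels[gid] = "static"
        else:
            labels[gid] = "weak"
    return pd.Series({m: labels[groups[m]] for m in groups.index}, name="concept")
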