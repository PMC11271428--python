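"""Univariate parametric and nonparametric stability / adaptability indices.

All statistics are computed per genotype from the genotype x environment
cell-means matrix (plot-level data are additionally needed only for the
standard deviation DP).  Conventions:

* environmental index I_j = Y.j - Y.. ; an environment is favorable when
  I_j > 0;
* joint regression (Eberhart-Russell) regresses the genotype's environment
  means on I_j; the Perkins-Jinks regression applies the same regression to
  the interaction residuals, so its slope is the Eberhart-Russell slope
  minus one;
* ecovalence W_i is the genotype's share of the interaction sum of squares;
* the superiority index P_i is the mean squared distance from the best
  genotype in each environment, divided by two;
* the confidence (reliability) index works on the percentage scale
  p_ij = 100 * Y_ij / Y.j and penalizes the mean percentage by Z_(1-alpha)
  standard deviations;
* the nonparametric rank statistics S(1) and S(6) rank genotypes within each
  environment, by default after removing genotype main effects
  (X_ij - Yi. + Y..), and summarize rank fluctuation across environments.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data import CellMeansMatrix, METTable
from .errors import ValidationError


def environmental_index(cells: CellMeansMatrix) -> pd.DataFrame:
    """Environment quality index I_j = Y.j - Y.. with a favorability flag."""
    idx = cells.environment_means - cells.grand_mean
    return pd.DataFrame(
        {"index": idx, "favorable": idx > 0}, index=list(cells.environments)
    )


def eberhart_russell(
    cells: CellMeansMatrix, ms_error: float, reps: int
) -> pd.DataFrame:
    """Joint regression on the environmental index, per genotype.

    Returns er_bi (slope), er_s2di (deviation variance, error-corrected),
    er_rmse (sqrt of mean squared deviation) and er_r2 (determination
    coefficient of the regression).
    """
    e = cells.n_environments
    if e < 3:
        raise ValidationError("joint regression needs at least 3 environments")
    if ms_error < 0:
        raise ValidationError("ms_error must be non-negative")
    ij = cells.environment_means - cells.grand_mean
    sxx = float((ij**2).sum())
    y = cells.means
    ycent = y - y.mean(axis=1, keepdims=True)
    bi = (ycent @ ij) / sxx
    fitted = np.outer(bi, ij)
    delta = ycent - fitted
    ss_dev = (delta**2).sum(axis=1)
    s2di = ss_dev / (e - 2) - ms_error / reps
    rmse = np.sqrt(ss_dev / e)
    ss_tot = (ycent**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_dev / ss_tot, np.nan)
    return pd.DataFrame(
        {"er_bi": bi, "er_s2di": s2di, "er_rmse": rmse, "er_r2": r2},
        index=list(cells.genotypes),
    )


def perkins_jinks(cells: CellMeansMatrix) -> pd.DataFrame:
    """Regression of the interaction residuals on the environmental index.

    The slope pj_bi equals the joint-regression slope minus one; pj_di is the
    deviation variance with an e-2 denominator.
    """
    e = cells.n_environments
    if e < 3:
        raise ValidationError("needs at least 3 environments")
    ij = cells.environment_means - cells.grand_mean
    sxx = float((ij**2).sum())
    z = cells.interaction_residuals()
    bi = (z @ ij) / sxx
    delta = z - np.outer(bi, ij)
    di = (delta**2).sum(axis=1) / (e - 2)
    return pd.DataFrame({"pj_bi": bi, "pj_di": di}, index=list(cells.genotypes))


def wricke_ecovalence(cells: CellMeansMatrix) -> pd.Series:
    """W_i = sum_j (Y_ij - Yi. - Y.j + Y..)^2, the genotype's interaction share."""
    z = cells.interaction_residuals()
    return pd.Series((z**2).sum(axis=1), index=list(cells.genotypes), name="wi")


def lin_binns(cells: CellMeansMatrix) -> pd.Series:
    """P_i = sum_j (Y_ij - M_j)^2 / (2e) with M_j the best value in environment j."""
    mj = cells.means.max(axis=0)
    pi = ((cells.means - mj[None, :]) ** 2).sum(axis=1) / (2 * cells.n_environments)
    return pd.Series(pi, index=list(cells.genotypes), name="pi")


def annicchiarico(cells: CellMeansMatrix, alpha: float = 0.25) -> pd.DataFrame:
    """Confidence index on the percentage scale, overall and by environment class.

    li = mean(p_ij) - Z_(1-alpha) * sd(p_ij) over all environments
    (ann_li_general) and separately over favorable / unfavorable environments
    (I_j > 0 / I_j <= 0).  A value above 100 means the genotype can be
    expected, at confidence 1-alpha, to beat the environment average.  An
    empty class yields NaN with a warning.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    z = stats.norm.ppf(1 - alpha)
    p = 100.0 * cells.means / cells.environment_means[None, :]
    fav = (cells.environment_means - cells.grand_mean) > 0

    def li(mask: np.ndarray) -> np.ndarray:
        if mask.sum() == 0:
            warnings.warn("empty environment class; confidence index reported absent")
            return np.full(cells.n_genotypes, np.nan)
        sub = p[:, mask]
        return sub.mean(axis=1) - z * sub.std(axis=1, ddof=0)

    return pd.DataFrame(
        {
            "ann_li_general": li(np.ones(cells.n_environments, dtype=bool)),
            "ann_li_favorable": li(fav),
            "ann_li_unfavorable": li(~fav),
        },
        index=list(cells.genotypes),
    )


def dispersion_measures(
    met: METTable, cells: CellMeansMatrix, trait: str
) -> pd.DataFrame:
    """DP (population SD of the genotype's plot values) and S2x (variance of
    its environment means, e-1 denominator)."""
    s2x = cells.means.var(axis=1, ddof=1)
    sub = met.subset_trait(trait)
    dp = sub.groupby("genotype", sort=False)["value"].apply(lambda v: float(np.std(v, ddof=0)))
    dp = dp.reindex(list(cells.genotypes))
    return pd.DataFrame({"dp": dp.to_numpy(), "s2x": s2x}, index=list(cells.genotypes))


def nassar_huehn(cells: CellMeansMatrix, corrected: bool = True) -> pd.DataFrame:
    """Huehn's nonparametric rank-stability statistics S(1) and S(6).

    Ranks are taken within each environment on the corrected values
    X_ij - Yi. + Y.. (genotype main effects removed) unless
    ``corrected=False``, in which case raw cell means are ranked.  Ties get
    mid-ranks.  S(1) is the mean absolute rank difference over all
    environment pairs; S(6) is the sum of absolute deviations from the
    genotype's mean rank, scaled by that mean rank.
    """
    if cells.n_environments < 2:
        raise ValidationError("needs at least 2 environments")
    x = cells.means
    if corrected:
        x = x - x.mean(axis=1, keepdims=True) + cells.grand_mean
    if any(len(np.unique(x[:, j])) < cells.n_genotypes for j in range(cells.n_environments)):
        warnings.warn("ties within an environment; mid-ranks used")
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    e = cells.n_environments
    si1 = np.zeros(cells.n_genotypes)
    for j in range(e - 1):
        for jp in range(j + 1, e):
            si1 += np.abs(ranks[:, j] - ranks[:, jp])
    si1 *= 2.0 / (e * (e - 1))
    mean_rank = ranks.mean(axis=1)
    si6 = np.abs(ranks - mean_rank[:, None]).sum(axis=1) / mean_rank
    return pd.DataFrame({"si1": si1, "si6": si6}, index=list(cells.genotypes))


def stability_table(
    met: METTable,
    cells: CellMeansMatrix,
    trait: str,
    ms_error: float,
    reps: int,
    alpha: float = 0.25,
    corrected_ranks: bool = True,
) -> pd.DataFrame:
    """All univariate indices side by side, one row per genotype."""
    parts = [
        dispersion_measures(met, cells, trait),
        pd.DataFrame({"wi": wricke_ecovalence(cells), "pi": lin_binns(cells)}),
        eberhart_russell(cells, ms_error, reps),
        perkins_jinks(cells),
        annicchiarico(cells, alpha),
        nassar_huehn(cells, corrected_ranks),
    ]
    out = pd.concat(parts, axis=1)
    out.insert(0, "mean", cells.genotype_means)
    return out
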