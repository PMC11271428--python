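"""Mixed-model BLUPs on balanced MET data and the two simultaneous
performance-stability statistics, HMGV and WAASB.

Model: y = mu + environment (fixed) + block-within-environment (fixed)
+ genotype (random, sigma_g^2) + G x E (random, sigma_ge^2) + error
(sigma_e^2).  On a balanced design the mixed-model equations have an exact
closed-form solution.  With D_g = sigma_g^2 + sigma_ge^2/e + sigma_e^2/(e r),
marginal genotype deviations m_i = Yi. - Y.. and interaction residuals
Z_ij = Y_ij - Yi. - Y.j + Y..:

    g_hat_i   = c_g * m_i,              c_g  = sigma_g^2 / D_g
    ge_hat_ij = c_ge * Z_ij + d * m_i,  c_ge = sigma_ge^2 / (sigma_ge^2 + sigma_e^2 / r)

where d = (sigma_ge^2 / e) / D_g allocates to the interaction effects their
share of the genotype-marginal contrast (the row mean of e interaction
effects is itself a random variable with variance sigma_ge^2/e, so the
marginal information splits between g and ge in proportion to their
variances).  Variance components come from the expected-mean-square solution
of the joint ANOVA (exact for balanced data).  The predicted genotypic value in
environment j is GV_ij = mu + g_hat_i + ge_hat_ij — the environment main
effect is deliberately excluded so that the harmonic mean HMGV penalizes
interaction instability, not environment quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ammi import _signed_svd
from .anova import VarianceComponents, joint_anova, variance_components
from .data import CellMeansMatrix, METTable, cell_means, validate_balance
from .errors import DegenerateError, DesignError, ValidationError


@dataclass(frozen=True)
class BLUPResult:
    grand_mean: float
    genotype_blups: np.ndarray  # g-vector, sums to ~0
    ge_blups: np.ndarray  # g x e
    genotypic_values: np.ndarray  # g x e: mu + g_hat + ge_hat
    components: VarianceComponents
    shrinkage_g: float
    shrinkage_ge: float
    genotypes: tuple[str, ...]
    environments: tuple[str, ...]

    def genotypic_values_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.genotypic_values, index=list(self.genotypes), columns=list(self.environments)
        )


def fit_blups(met: METTable, trait: str, mode: str = "component_sum") -> BLUPResult:
    """Closed-form balanced-case BLUPs for genotype and G x E effects."""
    report = validate_balance(met, trait)
    if not report.is_balanced:
        raise DesignError("BLUP fitting requires balanced complete data")
    if report.reps_per_cell < 2:
        raise DesignError("needs at least 2 blocks")
    anova = joint_anova(met, trait)
    cells = cell_means(met, trait)
    vc = variance_components(anova, report.reps_per_cell, cells.n_environments, mode)
    return blups_from_components(cells, vc, report.reps_per_cell)


def blups_from_components(
    cells: CellMeansMatrix, vc: VarianceComponents, reps: int
) -> BLUPResult:
    """Shrink fixed-effect estimates using supplied variance components."""
    e, r = cells.n_environments, reps
    denom_g = vc.var_g + vc.var_ge / e + vc.var_e / (e * r)
    denom_ge = vc.var_ge + vc.var_e / r
    if denom_g <= 0 and denom_ge <= 0:
        raise DegenerateError("zero total variance; BLUPs undefined")
    c_g = vc.var_g / denom_g if denom_g > 0 else 0.0
    c_ge = vc.var_ge / denom_ge if denom_ge > 0 else 0.0
    d = (vc.var_ge / e) / denom_g if denom_g > 0 else 0.0
    m = cells.genotype_means - cells.grand_mean
    g_hat = c_g * m
    ge_hat = c_ge * cells.interaction_residuals() + d * m[:, None]
    gv = cells.grand_mean + g_hat[:, None] + ge_hat
    return BLUPResult(
        grand_mean=cells.grand_mean,
        genotype_blups=g_hat,
        ge_blups=ge_hat,
        genotypic_values=gv,
        components=vc,
        shrinkage_g=float(c_g),
        shrinkage_ge=float(c_ge),
        genotypes=cells.genotypes,
        environments=cells.environments,
    )


def hmgv(blup: BLUPResult) -> pd.DataFrame:
    """Harmonic mean of predicted genotypic values; rank 1 = largest."""
    gv = blup.genotypic_values
    if (gv <= 0).any():
        i, j = np.argwhere(gv <= 0)[0]
        raise ValidationError(
            "harmonic mean undefined: non-positive genotypic value for "
            f"({blup.genotypes[i]}, {blup.environments[j]})"
        )
    e = gv.shape[1]
    values = e / (1.0 / gv).sum(axis=1)
    ranks = stats.rankdata(-values, method="average")
    return pd.DataFrame({"hmgv": values, "rank": ranks}, index=list(blup.genotypes))


def waasb(blup: BLUPResult) -> pd.DataFrame:
    """Weighted average of absolute IPCA scores of the G x E BLUP matrix.

    The interaction BLUP matrix is decomposed by SVD; axis k gets weight
    EP_k = lambda_k^2 / sum(lambda^2) and contributes the absolute genotype
    score |IPCA_ik|.  All min(g, e) - 1 axes are used.  Rank 1 = smallest.
    """
    z = blup.ge_blups
    g, e = z.shape
    k = min(g, e) - 1
    if not np.any(z):
        warnings.warn("all interaction BLUPs are zero; WAASB is 0 for every genotype")
        values = np.zeros(g)
    else:
        u, s, _ = _signed_svd(z, k)
        scores = np.abs(u * np.sqrt(s))
        ep = s**2 / (s**2).sum()
        values = scores @ ep  # weights already sum to 1
    ranks = stats.rankdata(values, method="average")
    return pd.DataFrame({"waasb": values, "rank": ranks}, index=list(blup.genotypes))


def performance_stability_quadrants(
    waasb_table: pd.DataFrame,
    means: pd.Series,
    pivot: str = "median",
) -> pd.Series:
    """Four-group classification crossing mean performance with WAASB.

    Group 1: below-average mean, unstable;  Group 2: above-average mean,
    unstable;  Group 3: below-average mean, stable;  Group 4: above-average
    mean, stable (broad adaptation).  The WAASB pivot is its median
    (``pivot='median'``) or mean (``pivot='mean'``); values at the pivot
    count as stable.
    """
    w = waasb_table["waasb"].reindex(means.index)
    if pivot == "median":
        cut = float(w.median())
    elif pivot == "mean":
        cut = float(w.mean())
    else:
        raise ValidationError("pivot must be 'median' or 'mean'")
    high_mean = means >= means.mean()
    stable = w <= cut
    group = np.select(
        [~high_mean & ~stable, high_mean & ~stable, ~high_mean & stable, high_mean & stable],
        [1, 2, 3, 4],
    )
    return pd.Series(group, index=means.index, name="group")


def composite_score(
    means: pd.Series, waasb_values: pd.Series, performance_weight: float = 0.5
) -> pd.Series:
    """Weighted blend of performance and stability rank positions.

    Each criterion's ranks (mean: larger better; WAASB: smaller better) are
    rescaled to 0-100 (100 = best) and averaged with the given weight on
    performance.  The default 50/50 blend is the usual equal-weights
    simultaneous-selection score.
    """
    if not 0 <= performance_weight <= 1:
        raise ValidationError("performance_weight must lie in [0, 1]")
    g = len(means)
    r_mean = stats.rankdata(-means.to_numpy(), method="average")
    r_waasb = stats.rankdata(waasb_values.reindex(means.index).to_numpy(), method="average")

    def rescale(r: np.ndarray) -> np.ndarray:
        return 100.0 * (g - r) / (g - 1) if g > 1 else np.full(g, 100.0)

    score = performance_weight * rescale(r_mean) + (1 - performance_weight) * rescale(r_waasb)
    return pd.Series(score, index=means.index, name="composite")
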