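"""Individual and joint ANOVA for balanced RCBD multi-environment trials,
variance components from expected mean squares, and genetic parameters.

The joint model partitions plot-level variation into genotype (G),
environment (E), blocks-within-environment, G x E interaction and residual
sums of squares.  With genotypes random and environments fixed, the balanced
expected-mean-square equations give method-of-moments estimators

    sigma_e^2  = MS_res
    sigma_ge^2 = (MS_GxE - MS_res) / r
    sigma_g^2  = (MS_G - MS_GxE) / (r * e)

from which heritability, coefficients of variation and expected genetic gain
follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import METTable, cell_means, validate_balance
from .errors import DegenerateError, DesignError, ValidationError

# canonical source labels
SRC_GENOTYPES = "genotypes"
SRC_ENVIRONMENTS = "environments"
SRC_BLOCKS = "blocks"
SRC_BLOCKS_ENV = "blocks_within_env"
SRC_GXE = "gxe"
SRC_RESIDUAL = "residual"
SRC_TOTAL = "total"


@dataclass(frozen=True)
class AnovaTable:
    """ANOVA table with columns source, df, ss, ms, f, p.

    F ratios use the residual mean square as denominator; the genotype-vs-
    interaction F needed for selective accuracy is recomputed from the MS
    column (both denominators are therefore available).
    """

    frame: pd.DataFrame

    def row(self, source: str) -> pd.Series:
        match = self.frame[self.frame["source"] == source]
        if len(match) == 0:
            raise ValidationError(f"ANOVA table has no {source!r} row")
        return match.iloc[0]

    def ms(self, source: str) -> float:
        return float(self.row(source)["ms"])

    def has(self, source: str) -> bool:
        return bool((self.frame["source"] == source).any())


def _finish_table(rows: list[tuple], ss_total: float) -> AnovaTable:
    df = pd.DataFrame(rows, columns=["source", "df", "ss"])
    df["ms"] = np.where(df["df"] > 0, df["ss"] / df["df"].replace(0, np.nan), np.nan)
    ms_res = float(df.loc[df["source"] == SRC_RESIDUAL, "ms"].iloc[0])
    df_res = int(df.loc[df["source"] == SRC_RESIDUAL, "df"].iloc[0])
    f = np.full(len(df), np.nan)
    p = np.full(len(df), np.nan)
    for i, src in enumerate(df["source"]):
        if src in (SRC_RESIDUAL, SRC_TOTAL) or ms_res <= 0 or df_res <= 0:
            continue
        f[i] = df["ms"].iloc[i] / ms_res
        p[i] = stats.f.sf(f[i], df["df"].iloc[i], df_res)
    df["f"] = f
    df["p"] = p
    total = pd.DataFrame(
        [[SRC_TOTAL, int(df["df"].sum()), ss_total, np.nan, np.nan, np.nan]], columns=df.columns
    )
    return AnovaTable(pd.concat([df, total], ignore_index=True))


def individual_anova(met: METTable, trait: str, environment: str) -> AnovaTable:
    """RCBD ANOVA of one environment: genotype + block + residual."""
    sub = met.subset_trait(trait)
    sub = sub[sub["environment"] == environment]
    if len(sub) == 0:
        raise ValidationError(f"environment {environment!r} not present for trait {trait!r}")
    piv = sub.pivot_table(index="genotype", columns="block", values="value")
    if piv.isna().any().any():
        raise DesignError("incomplete RCBD: every genotype must appear in every block")
    y = piv.to_numpy(dtype=float)
    g, r = y.shape
    if r < 2:
        raise DesignError("individual ANOVA needs at least 2 blocks")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_g = float(r * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_b = float(g * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_res = ss_total - ss_g - ss_b
    rows = [
        (SRC_GENOTYPES, g - 1, ss_g),
        (SRC_BLOCKS, r - 1, ss_b),
        (SRC_RESIDUAL, (g - 1) * (r - 1), max(ss_res, 0.0)),
    ]
    return _finish_table(rows, ss_total)


def homogeneity_check(individual_tables: list[AnovaTable]) -> dict:
    """Bartlett test and max/min residual-MS ratio across environments.

    The ratio rule (ratio < 7) is the classical admissibility criterion for a
    joint analysis over environments with heterogeneous error variances.
    """
    if len(individual_tables) < 2:
        raise ValidationError("need at least two environments")
    variances, dfs = [], []
    for tab in individual_tables:
        row = tab.row(SRC_RESIDUAL)
        if row["df"] <= 0:
            raise ValidationError("residual df must be positive in every environment")
        variances.append(float(row["ms"]))
        dfs.append(int(row["df"]))
    v = np.asarray(variances)
    nu = np.asarray(dfs, dtype=float)
    k = len(v)
    pooled = float((nu * v).sum() / nu.sum())
    with np.errstate(divide="ignore"):
        stat = nu.sum() * np.log(pooled) - (nu * np.log(v)).sum()
    c = 1.0 + ((1.0 / nu).sum() - 1.0 / nu.sum()) / (3.0 * (k - 1))
    stat = float(stat / c)
    p = float(stats.chi2.sf(stat, k - 1))
    ratio = float(v.max() / v.min())
    return {
        "bartlett_stat": stat,
        "p": p,
        "ms_ratio": ratio,
        "pass_ratio_rule": bool(ratio < 7.0),
    }


def joint_anova(met: METTable, trait: str) -> AnovaTable:
    """Joint ANOVA of a balanced MET: G, E, blocks/E, GxE, residual."""
    report = validate_balance(met, trait)
    if not report.is_balanced:
        raise DesignError(
            "joint ANOVA requires balanced complete data; analyse a balanced subset "
            f"(missing cells: {report.missing_cells[:5]}...)"
            if report.missing_cells
            else "joint ANOVA requires equal replication in every cell"
        )
    sub = met.subset_trait(trait)
    g = len(sub["genotype"].unique())
    e = len(sub["environment"].unique())
    r = report.reps_per_cell
    y = sub["value"].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    gen_means = sub.groupby("genotype", sort=False)["value"].mean().to_numpy()
    env_means = sub.groupby("environment", sort=False)["value"].mean().to_numpy()
    cellm = sub.groupby(["genotype", "environment"], sort=False)["value"].mean()
    blk_means = sub.groupby(["environment", "block"], sort=False)["value"].mean()

    ss_g = float(e * r * ((gen_means - grand) ** 2).sum())
    ss_e = float(g * r * ((env_means - grand) ** 2).sum())
    env_of_blk = blk_means.index.get_level_values(0)
    env_mean_lookup = sub.groupby("environment", sort=False)["value"].mean()
    ss_blk = float(g * ((blk_means - env_mean_lookup.loc[env_of_blk].to_numpy()) ** 2).sum())
    cells = cellm.unstack()
    z = (
        cells.to_numpy()
        - cells.mean(axis=1).to_numpy()[:, None]
        - cells.mean(axis=0).to_numpy()[None, :]
        + grand
    )
    ss_gxe = float(r * (z**2).sum())
    ss_res = ss_total - ss_g - ss_e - ss_blk - ss_gxe
    rows = [
        (SRC_GENOTYPES, g - 1, ss_g),
        (SRC_ENVIRONMENTS, e - 1, ss_e),
        (SRC_BLOCKS_ENV, e * (r - 1), ss_blk),
        (SRC_GXE, (g - 1) * (e - 1), ss_gxe),
        (SRC_RESIDUAL, e * (g - 1) * (r - 1), max(ss_res, 0.0)),
    ]
    return _finish_table(rows, ss_total)


def ss_shares(anova: AnovaTable) -> dict:
    """Percent shares of G, E and GxE in their combined sum of squares."""
    ss = {s: float(anova.row(s)["ss"]) for s in (SRC_GENOTYPES, SRC_ENVIRONMENTS, SRC_GXE)}
    total = sum(ss.values())
    if total <= 0:
        raise DegenerateError("all effect sums of squares are zero")
    return {f"pct_ss_{k}": 100.0 * v / total for k, v in ss.items()}


def selective_accuracy(anova: AnovaTable) -> float:
    """Precision of genotype discrimination, sqrt(1 - 1/F) with F = MS_G/MS_GxE.

    F below 1 (no detectable genotype signal beyond interaction noise) maps
    to 0 rather than a complex number.
    """
    ms_g = anova.ms(SRC_GENOTYPES)
    ms_ge = anova.ms(SRC_GXE)
    if not np.isfinite(ms_ge) or ms_ge <= 0:
        raise DegenerateError("G x E mean square must be positive")
    f = ms_g / ms_ge
    if f < 1.0:
        warnings.warn("genotype F ratio below 1; selective accuracy reported as 0")
        return 0.0
    return float(np.sqrt(1.0 - 1.0 / f))


@dataclass(frozen=True)
class VarianceComponents:
    """Method-of-moments variance components on the plot basis."""

    var_g: float
    var_ge: float
    var_e: float
    var_p: float
    mode: str
    truncated: bool = False  # any negative EMS solution was clipped to 0

    def as_dict(self) -> dict:
        return {
            "var_g": self.var_g,
            "var_ge": self.var_ge,
            "var_e": self.var_e,
            "var_p": self.var_p,
            "mode": self.mode,
        }


def phenotypic_variance(var_g: float, var_ge: float, var_e: float, n_env: int, reps: int, mode: str) -> float:
    if mode == "component_sum":
        return var_g + var_ge + var_e
    if mode == "mean_basis":
        return var_g + var_ge / n_env + var_e / (n_env * reps)
    raise ValidationError(f"unknown variance mode {mode!r}")


def variance_components(
    anova: AnovaTable, reps: int, n_env: int, mode: str = "component_sum"
) -> VarianceComponents:
    """Solve the balanced EMS equations for sigma_g^2, sigma_ge^2, sigma_e^2."""
    if reps < 2 or n_env < 2:
        raise ValidationError("reps and n_env must both be >= 2")
    ms_g = anova.ms(SRC_GENOTYPES)
    ms_ge = anova.ms(SRC_GXE)
    ms_e = anova.ms(SRC_RESIDUAL)
    var_e = ms_e
    var_ge = (ms_ge - ms_e) / reps
    var_g = (ms_g - ms_ge) / (reps * n_env)
    truncated = bool(var_ge < 0 or var_g < 0)
    if truncated:
        warnings.warn("negative EMS variance solution truncated to 0")
    var_g, var_ge = max(var_g, 0.0), max(var_ge, 0.0)
    var_p = phenotypic_variance(var_g, var_ge, var_e, n_env, reps, mode)
    return VarianceComponents(float(var_g), float(var_ge), float(var_e), float(var_p), mode, truncated)


@dataclass(frozen=True)
class GeneticParameters:
    """Heritability, coefficients of variation and expected genetic gain."""

    h2: float
    cv_g: float
    cv_p: float
    cv_r: float
    cv_ratio: float
    p_minus_g: float
    ga: float
    gam: float
    k_intensity: float
    grand_mean: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "h2", "cv_g", "cv_p", "cv_r", "cv_ratio", "p_minus_g", "ga", "gam",
            "k_intensity", "grand_mean",
        )}


#: standardized selection differential for truncating the top 15% of a normal
DEFAULT_K_INTENSITY = 1.554


def genetic_parameters(
    vc: VarianceComponents, grand_mean: float, k_intensity: float = DEFAULT_K_INTENSITY
) -> GeneticParameters:
    """Genetic parameters from variance components and the overall mean.

    CVs are percent of the overall mean; GA = K * sigma_p * h^2 is the
    expected gain under truncation selection with standardized differential K,
    and GAM expresses it as a percent of the mean.
    """
    if grand_mean <= 0:
        raise ValidationError("grand mean must be positive")
    h2 = vc.var_g / vc.var_p if vc.var_p > 0 else 0.0
    cv_g = np.sqrt(vc.var_g) / grand_mean * 100.0
    cv_p = np.sqrt(vc.var_p) / grand_mean * 100.0
    cv_r = np.sqrt(vc.var_e) / grand_mean * 100.0
    cv_ratio = cv_g / cv_r if cv_r > 0 else np.nan
    ga = k_intensity * np.sqrt(vc.var_p) * h2
    gam = ga / grand_mean * 100.0
    return GeneticParameters(
        float(h2), float(cv_g), float(cv_p), float(cv_r), float(cv_ratio),
        float(cv_p - cv_g), float(ga), float(gam), float(k_intensity), float(grand_mean),
    )


def anova_table_from_ss(rows: list[tuple[str, int, float]]) -> AnovaTable:
    """Assemble an AnovaTable from externally supplied (source, df, ss) rows.

    Lets published ANOVA tables (sums of squares and degrees of freedom) feed
    the variance-component and accuracy machinery directly.
    """
    ss_total = float(sum(ss for _, _, ss in rows))
    return _finish_table(list(rows), ss_total)


def grand_mean(met: METTable, trait: str) -> float:
    return float(met.subset_trait(trait)["value"].mean())


def trait_summary(met: METTable, trait: str, mode: str = "component_sum",
                  k_intensity: float = DEFAULT_K_INTENSITY) -> dict:
    """One-call joint ANOVA -> variance components -> genetic parameters."""
    report = validate_balance(met, trait)
    anova = joint_anova(met, trait)
    cells = cell_means(met, trait)
    vc = variance_components(anova, report.reps_per_cell, cells.n_environments, mode)
    gp = genetic_parameters(vc, grand_mean(met, trait), k_intensity)
    return {"anova": anova, "components": vc, "parameters": gp, "cells": cells}
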