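"""Synthetic MET generator with the variance structure the analysis assumes.

The model is the balanced randomized-complete-block multi-environment trial

    y_ijk = mu + g_i + tau_j + (ge)_ij + b_k(j) + eps_ijk

with genotype effects g_i ~ N(0, var_g), environment effects
tau_j ~ N(0, env_effect_sd^2) (drawn once, treated as fixed downstream),
interaction (ge)_ij ~ N(0, var_ge), blocks-within-environment
b_k(j) ~ N(0, block_effect_sd^2) and plot error eps ~ N(0, var_error).

Defaults reproduce the design of the cassava VCU reference study:
12 genotypes x 12 environments x 3 blocks at the fresh-root-yield variance
magnitudes (var_g 20.16, var_ge 17.87, var_error 6.54 t^2 ha^-2, grand mean
26.14 t ha^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import METTable, met_table_from_frame
from .errors import ValidationError


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the simulated trial (variances in squared trait units)."""

    n_genotypes: int = 12
    n_environments: int = 12
    n_blocks: int = 3
    grand_mean: float = 26.14
    var_g: float = 20.16
    var_ge: float = 17.87
    var_error: float = 6.54
    env_effect_sd: float = 5.0
    block_effect_sd: float = 1.0
    seed: int = 0
    trait: str = "FRY"

    def validate(self) -> None:
        if min(self.n_genotypes, self.n_environments, self.n_blocks) < 2:
            raise ValidationError("all design counts must be >= 2")
        if min(self.var_g, self.var_ge, self.var_error) < 0:
            raise ValidationError("variances must be non-negative")
        if min(self.env_effect_sd, self.block_effect_sd) < 0:
            raise ValidationError("effect standard deviations must be non-negative")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def generate_met(config: SyntheticConfig) -> METTable:
    """Draw one balanced synthetic trial under ``config``.

    One global seed controls independent per-effect substreams, so the same
    seed always yields the identical table.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_g, rng_e, rng_ge, rng_b, rng_eps = (np.random.default_rng(s) for s in ss.spawn(5))
    ng, ne, nb = config.n_genotypes, config.n_environments, config.n_blocks
    g = rng_g.normal(0.0, np.sqrt(config.var_g), ng)
    tau = rng_e.normal(0.0, config.env_effect_sd, ne)
    ge = rng_ge.normal(0.0, np.sqrt(config.var_ge), (ng, ne))
    blk = rng_b.normal(0.0, config.block_effect_sd, (ne, nb))
    eps = rng_eps.normal(0.0, np.sqrt(config.var_error), (ng, ne, nb))
    y = (
        config.grand_mean
        + g[:, None, None]
        + tau[None, :, None]
        + ge[:, :, None]
        + blk[None, :, :]
        + eps
    )
    gi, ej, bk = np.meshgrid(np.arange(ng), np.arange(ne), np.arange(nb), indexing="ij")
    df = pd.DataFrame(
        {
            "genotype": [f"G{i + 1:02d}" for i in gi.ravel()],
            "environment": [f"E{j + 1:02d}" for j in ej.ravel()],
            "block": [f"B{k + 1}" for k in bk.ravel()],
            "trait": config.trait,
            "value": y.ravel(),
        }
    )
    return met_table_from_frame(df)


# ---------------------------------------------------------------------------
# handcrafted analytic fixtures
# ---------------------------------------------------------------------------

def _long_from_matrix(matrix: np.ndarray, n_blocks: int = 2, trait: str = "toy") -> METTable:
    """Replicate a genotype x environment matrix over noise-free blocks."""
    ng, ne = matrix.shape
    rows = []
    for i in range(ng):
        for j in range(ne):
            for k in range(n_blocks):
                rows.append((f"G{i + 1}", f"E{j + 1}", f"B{k + 1}", trait, float(matrix[i, j])))
    return met_table_from_frame(
        pd.DataFrame(rows, columns=["genotype", "environment", "block", "trait", "value"])
    )


def _additive_no_ge() -> METTable:
    g = np.array([0.0, 2.0, -1.0, 4.0])
    e = np.array([0.0, 3.0, -2.0, 1.0])
    return _long_from_matrix(10.0 + g[:, None] + e[None, :])


def _rank1_interaction() -> METTable:
    g = np.array([0.0, 2.0, -1.0, 4.0])
    e = np.array([0.0, 3.0, -2.0, 1.0])
    u = np.array([1.0, -1.0, 2.0, -2.0])
    v = np.array([1.0, 0.0, -1.0, 0.0])
    u = u - u.mean()
    v = v - v.mean()
    return _long_from_matrix(20.0 + g[:, None] + e[None, :] + np.outer(u, v))


def _crossover() -> METTable:
    # winners alternate between G1 and G3 across environments
    m = np.array(
        [
            [12.0, 4.0, 12.5, 4.5],
            [8.0, 8.0, 8.0, 8.0],
            [4.0, 12.0, 4.5, 12.5],
        ]
    )
    return _long_from_matrix(m)


FIXTURES = {
    "additive_no_ge": _additive_no_ge,
    "rank1_interaction": _rank1_interaction,
    "crossover": _crossover,
}


def generate_toy_fixture(name: str) -> METTable:
    """Small handcrafted tables with known analytic properties.

    ``additive_no_ge``  : purely additive, zero interaction everywhere.
    ``rank1_interaction``: interaction residual matrix of rank exactly 1.
    ``crossover``       : different genotypes win in different environments.
    """
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    return builder()
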