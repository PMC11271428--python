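import numpy as np
import pandas as pd
import pytest

from metstab.data import CellMeansMatrix, met_table_from_frame
from metstab.simulate import SyntheticConfig, generate_met, generate_toy_fixture


@pytest.fixture(scope="session")
def reference_config():
    """Design and variance magnitudes of the cassava VCU reference trial."""
    return SyntheticConfig(
        n_genotypes=12, n_environments=12, n_blocks=3,
        grand_mean=26.14, var_g=20.16, var_ge=17.87, var_error=6.54,
        env_effect_sd=5.0, block_effect_sd=1.0, seed=42,
    )


@pytest.fixture(scope="session")
def synthetic_met(reference_config):
    return generate_met(reference_config)


@pytest.fixture(scope="session")
def small_met():
    """Small balanced trial (5 genotypes x 4 environments x 3 blocks)."""
    cfg = SyntheticConfig(
        n_genotypes=5, n_environments=4, n_blocks=3, grand_mean=50.0,
        var_g=9.0, var_ge=4.0, var_error=1.0, env_effect_sd=3.0,
        block_effect_sd=0.5, seed=7,
    )
    return generate_met(cfg)


@pytest.fixture(scope="session")
def additive_fixture():
    return generate_toy_fixture("additive_no_ge")


@pytest.fixture(scope="session")
def rank1_fixture():
    return generate_toy_fixture("rank1_interaction")


@pytest.fixture(scope="session")
def crossover_fixture():
    return generate_toy_fixture("crossover")


def random_cells(rng: np.random.Generator, g: int = 6, e: int = 5,
                 loc: float = 30.0, scale: float = 5.0) -> CellMeansMatrix:
    means = rng.normal(loc, scale, (g, e))
    return CellMeansMatrix(
        tuple(f"G{i+1}" for i in range(g)),
        tuple(f"E{j+1}" for j in range(e)),
        means,
        reps_per_cell=1,
    )


def long_table(matrix: np.ndarray, n_blocks: int = 2, noise: float = 0.0,
               rng: np.random.Generator | None = None, trait: str = "y"):
    """Long-format table replicating a genotype x environment matrix over blocks."""
    g, e = matrix.shape
    rows = []
    for i in range(g):
        for j in range(e):
            for k in range(n_blocks):
                val = matrix[i, j]
                if noise and rng is not None:
                    val = val + rng.normal(0, noise)
                rows.append((f"G{i+1}", f"E{j+1}", f"B{k+1}", trait, float(val)))
    return met_table_from_frame(
        pd.DataFrame(rows, columns=["genotype", "environment", "block", "trait", "value"])
    )
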