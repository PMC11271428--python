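"""AMMI: additive main effects and multiplicative interaction.

The genotype x environment cell-means matrix is decomposed into additive
genotype and environment effects plus an SVD of the doubly centered
interaction residual Z_ij = Y_ij - Yi. - Y.j + Y.. .  Each singular axis is
an interaction principal component (IPCA); lambda_k^2 is the interaction sum
of squares captured by axis k (cell-mean basis).  The AMMI stability value
(ASV) condenses the first two axes into one distance-from-origin measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import CellMeansMatrix
from .errors import DegenerateError


def _signed_svd(z: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Truncated SVD with a deterministic sign convention.

    The largest-magnitude element of each left-singular (genotype) column is
    forced positive; the right factor is flipped in tandem.
    """
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    u, s, v = u[:, :k], s[:k], vt[:k].T
    for col in range(k):
        pivot = np.argmax(np.abs(u[:, col]))
        if u[pivot, col] < 0:
            u[:, col] = -u[:, col]
            v[:, col] = -v[:, col]
    return u, s, v


@dataclass(frozen=True)
class AMMIResult:
    grand_mean: float
    genotype_effects: np.ndarray  # deviations Yi. - Y.. (sum to 0)
    environment_effects: np.ndarray  # deviations Y.j - Y.. (sum to 0)
    singular_values: np.ndarray  # lambda_k, descending
    genotype_scores: np.ndarray  # g x K, u_ik * sqrt(lambda_k)
    environment_scores: np.ndarray  # e x K, v_jk * sqrt(lambda_k)
    ss_share: np.ndarray  # lambda_k^2 / sum lambda^2
    genotypes: tuple[str, ...]
    environments: tuple[str, ...]

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)

    @property
    def interaction_ss(self) -> float:
        """Interaction SS on the cell-mean basis (multiply by r for plot basis)."""
        return float((self.singular_values**2).sum())

    def reconstruct_interaction(self, n_axes: int | None = None) -> np.ndarray:
        k = self.n_axes if n_axes is None else n_axes
        gs, es, lam = self.genotype_scores[:, :k], self.environment_scores[:, :k], self.singular_values[:k]
        # scores carry sqrt(lambda) each, so gs @ es.T restores u diag(lambda) v'
        return gs @ es.T

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"IPCA{k + 1}" for k in range(self.n_axes)]
        gen = pd.DataFrame(self.genotype_scores, index=list(self.genotypes), columns=cols)
        gen.insert(0, "kind", "genotype")
        env = pd.DataFrame(self.environment_scores, index=list(self.environments), columns=cols)
        env.insert(0, "kind", "environment")
        return pd.concat([gen, env])


def ammi_decompose(cells: CellMeansMatrix) -> AMMIResult:
    """Full AMMI decomposition of a complete cell-means matrix."""
    cells.require_decomposable()
    g, e = cells.n_genotypes, cells.n_environments
    k = min(g, e) - 1
    z = cells.interaction_residuals()
    u, s, v = _signed_svd(z, k)
    total = float((s**2).sum())
    share = s**2 / total if total > 0 else np.zeros_like(s)
    root = np.sqrt(s)
    return AMMIResult(
        grand_mean=cells.grand_mean,
        genotype_effects=cells.genotype_means - cells.grand_mean,
        environment_effects=cells.environment_means - cells.grand_mean,
        singular_values=s,
        genotype_scores=u * root,
        environment_scores=v * root,
        ss_share=share,
        genotypes=cells.genotypes,
        environments=cells.environments,
    )


@dataclass(frozen=True)
class ASVTable:
    frame: pd.DataFrame  # columns: asv, rank; index: genotype

    @property
    def values(self) -> np.ndarray:
        return self.frame["asv"].to_numpy()


def asv(ammi: AMMIResult) -> ASVTable:
    """AMMI stability value: weighted IPCA1-IPCA2 distance from the origin.

    ASV_i = sqrt( [ (SS_IPCA1 / SS_IPCA2) * IPCA1_i ]^2 + IPCA2_i^2 ),
    smaller is more stable; rank 1 = smallest.
    """
    lam = ammi.singular_values
    if ammi.n_axes < 2 or lam[1] <= 1e-9 * max(lam[0], 1.0):
        raise DegenerateError("ASV needs two interaction axes with positive singular values")
    w = ammi.singular_values[0] ** 2 / ammi.singular_values[1] ** 2
    ipca1 = ammi.genotype_scores[:, 0]
    ipca2 = ammi.genotype_scores[:, 1]
    values = np.sqrt((w * ipca1) ** 2 + ipca2**2)
    ranks = stats.rankdata(values, method="average")
    frame = pd.DataFrame({"asv": values, "rank": ranks}, index=list(ammi.genotypes))
    return ASVTable(frame)
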