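"""GGE analysis: genotype main effect plus G x E interaction.

The cell-means matrix is environment-centered (each column minus its mean,
the "centering = 2" construction, unscaled) and decomposed by SVD.  Singular
values are allocated to genotype scores, environment scores, or split
symmetrically, according to the singular-value-partitioning (SVP) setting.
On the PC1-PC2 plane the which-won-where polygon and the environment
discrimination/representativeness metrics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .ammi import _signed_svd
from .data import CellMeansMatrix
from .errors import DegenerateError, ValidationError

SVP_OPTIONS = ("genotype", "environment", "symmetric")


@dataclass(frozen=True)
class GGEResult:
    centered: np.ndarray  # g x e, column means removed
    singular_values: np.ndarray
    genotype_scores: np.ndarray  # g x K under the chosen svp
    environment_scores: np.ndarray  # e x K
    svp: str
    pc_share: np.ndarray  # lambda^2 / sum lambda^2
    genotypes: tuple[str, ...]
    environments: tuple[str, ...]

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)

    def reconstruct(self, n_axes: int | None = None) -> np.ndarray:
        """Rebuild the centered matrix from the first n_axes components."""
        k = self.n_axes if n_axes is None else n_axes
        gs, es = self.genotype_scores[:, :k], self.environment_scores[:, :k]
        # under every svp the product restores u diag(lambda) v'
        return gs @ es.T

    def biplot_frame(self) -> pd.DataFrame:
        gen = pd.DataFrame(self.genotype_scores[:, :2], index=list(self.genotypes), columns=["PC1", "PC2"])
        gen.insert(0, "kind", "genotype")
        env = pd.DataFrame(self.environment_scores[:, :2], index=list(self.environments), columns=["PC1", "PC2"])
        env.insert(0, "kind", "environment")
        return pd.concat([gen, env])


def gge_decompose(cells: CellMeansMatrix, svp: str = "environment") -> GGEResult:
    """Environment-centered SVD of the cell-means matrix."""
    if svp not in SVP_OPTIONS:
        raise ValidationError(f"svp must be one of {SVP_OPTIONS}")
    cells.require_decomposable()
    centered = cells.means - cells.environment_means[None, :]
    k = min(cells.n_genotypes, cells.n_environments)
    u, s, v = _signed_svd(centered, k)
    total = float((s**2).sum())
    share = s**2 / total if total > 0 else np.zeros_like(s)
    if svp == "genotype":
        gs, es = u * s, v
    elif svp == "environment":
        gs, es = u, v * s
    else:
        root = np.sqrt(s)
        gs, es = u * root, v * root
    return GGEResult(
        centered=centered,
        singular_values=s,
        genotype_scores=gs,
        environment_scores=es,
        svp=svp,
        pc_share=share,
        genotypes=cells.genotypes,
        environments=cells.environments,
    )


@dataclass(frozen=True)
class WhichWonWhere:
    hull_vertices: list[str]  # counterclockwise order
    sectors: list[tuple[str, list[str]]]  # (vertex genotype, environments won)
    winners: dict[str, str]  # environment -> winning genotype

    @property
    def mega_environments(self) -> list[tuple[str, list[str]]]:
        return [(g, envs) for g, envs in self.sectors if envs]


def which_won_where(gge: GGEResult) -> WhichWonWhere:
    """Which-won-where partition on the PC1-PC2 plane.

    The winner predicted for environment j by the rank-2 model is the
    genotype maximizing the inner product of its (PC1, PC2) marker with the
    environment marker; that maximizer is always a vertex of the convex hull
    of the genotype markers, so the grouping of environments by winner is
    exactly the sector structure cut by rays perpendicular to the hull edges.
    """
    pts = gge.genotype_scores[:, :2]
    if pts.shape[0] < 3:
        raise DegenerateError("need at least 3 genotype markers")
    spread = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-10) < 2:
        raise DegenerateError("genotype markers are collinear in the PC1-PC2 plane")
    hull = ConvexHull(pts)
    hull_idx = list(hull.vertices)  # counterclockwise
    env_pts = gge.environment_scores[:, :2]
    winners: dict[str, str] = {}
    for j, env in enumerate(gge.environments):
        scores = [float(pts[i] @ env_pts[j]) for i in hull_idx]
        winners[env] = gge.genotypes[hull_idx[int(np.argmax(scores))]]
    sectors = []
    for i in hull_idx:
        gname = gge.genotypes[i]
        sectors.append((gname, [e for e in gge.environments if winners[e] == gname]))
    return WhichWonWhere([gge.genotypes[i] for i in hull_idx], sectors, winners)


@dataclass(frozen=True)
class EnvironmentMetrics:
    frame: pd.DataFrame  # per environment: vector_length, representativeness
    aec: np.ndarray  # average-environment coordinate in (PC1, PC2)


def environment_metrics(gge: GGEResult) -> EnvironmentMetrics:
    """Discrimination (vector length) and representativeness (cosine with AEC)."""
    if gge.n_axes < 2:
        raise ValidationError("need at least two axes")
    env_pts = gge.environment_scores[:, :2]
    aec = env_pts.mean(axis=0)
    aec_norm = float(np.linalg.norm(aec))
    if aec_norm == 0:
        raise DegenerateError("average-environment vector is zero")
    lengths = np.linalg.norm(env_pts, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosines = (env_pts @ aec) / (lengths * aec_norm)
    cosines = np.where(lengths > 0, cosines, 0.0)
    frame = pd.DataFrame(
        {"vector_length": lengths, "representativeness": cosines},
        index=list(gge.environments),
    )
    return EnvironmentMetrics(frame, aec)


def classify_angle(v1: np.ndarray, v2: np.ndarray, orthogonal_band_deg: float = 5.0) -> str:
    """Qualitative angle between two environment vectors: acute / orthogonal / obtuse."""
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise DegenerateError("zero-length vector")
    angle = np.degrees(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)))
    if abs(angle - 90.0) <= orthogonal_band_deg:
        return "orthogonal"
    return "acute" if angle < 90.0 else "obtuse"
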