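"""Data model, I/O and validation for multi-environment-trial (MET) phenotype tables.

The single input currency of the package is the long-format plot table: one
record per genotype x environment x block x trait with a numeric value
(``METTable``).  All stability mathematics runs on the genotype x environment
matrix of cell means derived from it (``CellMeansMatrix``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CompletenessError, FormatError, ValidationError

#: canonical column names of the long format
CANONICAL_COLUMNS = ("genotype", "environment", "block", "trait", "value")

#: key columns that must be jointly unique
KEY_COLUMNS = ("genotype", "environment", "block", "trait")


def _first_appearance(labels: Sequence[str]) -> list[str]:
    """Unique labels in order of first appearance (deterministic ordering rule)."""
    seen: dict[str, None] = {}
    for lab in labels:
        seen.setdefault(lab, None)
    return list(seen)


@dataclass(frozen=True)
class METTable:
    """Long-format plot-level phenotype records.

    Wraps a tidy :class:`pandas.DataFrame` with columns
    ``genotype, environment, block, trait, value``.  Labels are opaque
    strings; row order is preserved as read.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        values = df["value"].to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("value column is not numeric")
        if not np.isfinite(values).all():
            bad = df.index[~np.isfinite(values)].tolist()
            raise ValidationError(f"non-finite value(s) at row(s) {bad}")
        dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
        if dup.any():
            offenders = (
                df.loc[dup, list(KEY_COLUMNS)].drop_duplicates().to_records(index=False).tolist()
            )
            raise ValidationError(f"duplicate (genotype, environment, block, trait) keys: {offenders}")
        if len(df) == 0:
            raise ValidationError("empty table")

    # -- label sets ------------------------------------------------------
    @property
    def genotypes(self) -> list[str]:
        return _first_appearance(self.frame["genotype"].astype(str))

    @property
    def environments(self) -> list[str]:
        return _first_appearance(self.frame["environment"].astype(str))

    @property
    def blocks(self) -> list[str]:
        return _first_appearance(self.frame["block"].astype(str))

    @property
    def traits(self) -> list[str]:
        return _first_appearance(self.frame["trait"].astype(str))

    def subset_trait(self, trait: str) -> pd.DataFrame:
        sub = self.frame[self.frame["trait"] == trait]
        if len(sub) == 0:
            raise ValidationError(f"trait {trait!r} not present")
        return sub

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class CellMeansMatrix:
    """Genotype x environment table of phenotypic cell means.

    ``means[i, j]`` is the mean over blocks of genotype ``genotypes[i]`` in
    environment ``environments[j]``; ``reps_per_cell`` is the common replicate
    count when the design is balanced (``None`` otherwise).
    """

    genotypes: tuple[str, ...]
    environments: tuple[str, ...]
    means: np.ndarray
    reps_per_cell: int | None = None

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        object.__setattr__(self, "means", means)
        g, e = means.shape
        if g != len(self.genotypes) or e != len(self.environments):
            raise ValidationError("means shape does not match label counts")
        if not np.isfinite(means).all():
            raise CompletenessError("cell-means matrix contains non-finite cells")

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    @property
    def grand_mean(self) -> float:
        return float(self.means.mean())

    @property
    def genotype_means(self) -> np.ndarray:
        return self.means.mean(axis=1)

    @property
    def environment_means(self) -> np.ndarray:
        return self.means.mean(axis=0)

    def interaction_residuals(self) -> np.ndarray:
        """Doubly centered matrix Z_ij = Y_ij - Yi. - Y.j + Y.. ."""
        z = (
            self.means
            - self.genotype_means[:, None]
            - self.environment_means[None, :]
            + self.grand_mean
        )
        return z

    def require_decomposable(self) -> None:
        if self.n_genotypes < 3 or self.n_environments < 3:
            raise ValidationError(
                "multiplicative decomposition needs at least 3 genotypes and 3 environments"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=list(self.genotypes), columns=list(self.environments))


@dataclass(frozen=True)
class BalanceReport:
    """Replication structure of a trait within a METTable."""

    is_balanced: bool
    reps_per_cell: int | None
    missing_cells: list[tuple[str, str]] = field(default_factory=list)
    cell_counts: dict[tuple[str, str], int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers / constructors
# ---------------------------------------------------------------------------

DEFAULT_DIALECT: Mapping[str, str] = {
    "genotype": "genotype",
    "environment": "environment",
    "block": "block",
    "trait": "trait",
    "value": "value",
}


def met_table_from_frame(df: pd.DataFrame, dialect: Mapping[str, str] | None = None) -> METTable:
    """Build a validated METTable from a DataFrame, renaming per ``dialect``.

    ``dialect`` maps canonical names (genotype, environment, block, trait,
    value) to the column names actually present.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    missing = [src for src in mapping.values() if src not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    out = df[[mapping[c] for c in CANONICAL_COLUMNS]].copy()
    out.columns = list(CANONICAL_COLUMNS)
    for c in KEY_COLUMNS:
        out[c] = out[c].astype(str)
    raw = out["value"]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"non-numeric value {raw.iloc[row]!r} at row {row}")
    out["value"] = values.astype(float)
    return METTable(out.reset_index(drop=True))


def read_met_table(path: str | Path, dialect: Mapping[str, str] | None = None) -> METTable:
    """Read a long-format CSV into a validated METTable."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return met_table_from_frame(pd.read_csv(path, dtype={"value": object} if dialect is None else None), dialect)


def read_wide_matrix(path: str | Path, trait: str = "value") -> METTable:
    """Read a wide genotype x environment CSV (first column genotype).

    Converted to a single-replicate long table (``reps_per_cell`` = 1 in the
    derived cell-means matrix).
    """
    df = pd.read_csv(path)
    gen_col = df.columns[0]
    long = df.melt(id_vars=[gen_col], var_name="environment", value_name="value")
    long = long.rename(columns={gen_col: "genotype"})
    long["block"] = "1"
    long["trait"] = trait
    return met_table_from_frame(long)


# ---------------------------------------------------------------------------
# derived structures
# ---------------------------------------------------------------------------

def validate_balance(met: METTable, trait: str) -> BalanceReport:
    """Report replication counts per genotype x environment cell for a trait."""
    try:
        sub = met.subset_trait(trait)
    except ValidationError:
        missing = [(g, e) for g in met.genotypes for e in met.environments]
        return BalanceReport(False, None, missing, {})
    counts = sub.groupby(["genotype", "environment"], sort=False).size()
    gens = _first_appearance(sub["genotype"])
    envs = _first_appearance(sub["environment"])
    cell_counts: dict[tuple[str, str], int] = {}
    missing: list[tuple[str, str]] = []
    for g in gens:
        for e in envs:
            n = int(counts.get((g, e), 0))
            cell_counts[(g, e)] = n
            if n == 0:
                missing.append((g, e))
    observed = {n for n in cell_counts.values() if n > 0}
    balanced = not missing and len(observed) == 1
    reps = observed.pop() if len(observed) == 1 else None
    return BalanceReport(balanced, reps if balanced else reps, missing, cell_counts)


def cell_means(met: METTable, trait: str) -> CellMeansMatrix:
    """Genotype x environment matrix of block-averaged phenotypic means."""
    report = validate_balance(met, trait)
    if report.missing_cells:
        raise CompletenessError(f"empty genotype x environment cell(s): {report.missing_cells}")
    sub = met.subset_trait(trait)
    gens = _first_appearance(sub["genotype"])
    envs = _first_appearance(sub["environment"])
    piv = sub.groupby(["genotype", "environment"], sort=False)["value"].mean().unstack()
    means = piv.loc[gens, envs].to_numpy(dtype=float)
    return CellMeansMatrix(tuple(gens), tuple(envs), means, report.reps_per_cell)
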