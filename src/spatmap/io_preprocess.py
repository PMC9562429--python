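"""Reading and preprocessing of proteinGroups-style quantification tables.

Mirrors the standard Perseus workflow for organelle-profiling TMT data:
drop decoy/contaminant/site-only identifications, keep proteins with a
complete reporter-ion series, convert each protein's reporter
intensities into a relative (row-stochastic) fractionation profile,
average profiles across replicate maps, and, for whole-cell lysates,
log2-transform LFQ intensities and impute missing values from a
left-shifted normal distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ACCESSION_COL, FLAG_COLS, MW_COL, PEPTIDES_COL

logger = logging.getLogger(__name__)

TMT_PREFIX = "Reporter intensity corrected"
LFQ_PREFIX = "LFQ intensity"


@dataclass
class ProfileMatrix:
    """Proteins x fractions matrix of relative reporter intensities.

    ``data`` is indexed by accession with integer fraction columns.
    When ``normalized`` each row sums to 1 (a compositional profile).
    """

    data: pd.DataFrame
    normalized: bool = False
    replicate: str | None = None

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("accessions must be unique")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")
        if self.normalized:
            sums = self.data.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized profiles must have row sum 1")

    @property
    def accessions(self) -> pd.Index:
        return self.data.index

    @property
    def n_fractions(self) -> int:
        return self.data.shape[1]


@dataclass
class LysateMatrix:
    """log2 LFQ intensities with explicit missing values (NaN).

    ``groups`` maps each column to its condition label; ``peptide_counts``
    carries the razor+unique peptide counts used for variance estimation.
    """

    log2_intensities: pd.DataFrame
    peptide_counts: pd.Series
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.log2_intensities.columns) != set(self.groups):
            raise ValueError("groups must label exactly the intensity columns")
        if (self.peptide_counts < 1).any():
            raise ValueError("peptide counts must be >= 1")

    def columns_for(self, condition: str) -> list[str]:
        return [c for c, g in self.groups.items() if g == condition]


def intensity_columns(table: pd.DataFrame, dialect: str) -> list[str]:
    prefix = TMT_PREFIX if dialect == "tmt" else LFQ_PREFIX
    return [c for c in table.columns if str(c).startswith(prefix)]


def read_protein_groups(path, dialect: str = "tmt") -> pd.DataFrame:
    """Read a proteinGroups-style TSV into a typed, accession-indexed table.

    Intensity columns are parsed as floats and the "+"-convention flag
    columns (Reverse / Potential contaminant / Only identified by site)
    as booleans. A missing optional flag column is treated as
    all-unflagged with a warning.
    """
    if dialect not in ("tmt", "lfq"):
        raise ValueError(f"unknown dialect {dialect!r}")
    table = pd.read_csv(path, sep="\t")
    if ACCESSION_COL not in table.columns:
        raise ValueError(f"required column {ACCESSION_COL!r} not found in {path}")
    cols = intensity_columns(table, dialect)
    if not cols:
        prefix = TMT_PREFIX if dialect == "tmt" else LFQ_PREFIX
        raise ValueError(f"no {prefix!r} columns found in {path}")
    table = table.set_index(ACCESSION_COL)
    table[cols] = table[cols].astype(float)
    if PEPTIDES_COL in table.columns:
        table[PEPTIDES_COL] = table[PEPTIDES_COL].fillna(1).astype(int)
    for col in FLAG_COLS:
        if col in table.columns:
            table[col] = table[col].astype("string").fillna("") == "+"
        else:
            logger.warning("flag column %r absent; treating as unflagged", col)
            table[col] = False
    return table


def filter_identifications(table: pd.DataFrame) -> pd.DataFrame:
    """Remove decoy, contaminant, and site-only identifications."""
    mask = np.zeros(len(table), dtype=bool)
    for col in FLAG_COLS:
        if col in table.columns:
            mask |= table[col].to_numpy(dtype=bool)
    return table.loc[~mask]


def require_complete_reporters(
    table: pd.DataFrame, channel_cols: list[str] | None = None
) -> pd.DataFrame:
    """Keep only proteins with a complete reporter-ion series.

    A zero or missing intensity in any of the required channels drops
    the protein (MaxQuant writes 0 for unquantified channels). Passing
    the concatenated channels of several replicates enforces the
    combined-map rule that the series be complete across all replicates.
    """
    if channel_cols is None:
        channel_cols = intensity_columns(table, "tmt")
    missing = [c for c in channel_cols if c not in table.columns]
    if missing:
        raise ValueError(f"required channels absent from table: {missing}")
    vals = table[channel_cols].to_numpy(dtype=float)
    keep = np.isfinite(vals).all(axis=1) & (vals > 0).all(axis=1)
    return table.loc[keep]


def normalize_profiles(
    table: pd.DataFrame, channel_cols: list[str] | None = None,
    replicate: str | None = None,
) -> ProfileMatrix:
    """Convert raw reporter intensities of one replicate into profiles.

    Each protein's channels are divided by their sum, so rows become
    relative fractionation profiles summing to 1.
    """
    if channel_cols is None:
        channel_cols = intensity_columns(table, "tmt")
    vals = table[channel_cols].to_numpy(dtype=float)
    sums = vals.sum(axis=1)
    if (sums <= 0).any():
        bad = table.index[sums <= 0][:5].tolist()
        raise ValueError(f"zero/negative row sum for {bad}; filter first")
    data = pd.DataFrame(
        vals / sums[:, None],
        index=table.index,
        columns=range(1, len(channel_cols) + 1),
    )
    return ProfileMatrix(data=data, normalized=True, replicate=replicate)


def combine_replicates(maps: list[ProfileMatrix]) -> ProfileMatrix:
    """Average replicate profiles into a combined map.

    Restricted to the accession intersection; the per-protein mean of
    the replicate profiles is renormalized to row sum 1.
    """
    if not maps:
        raise ValueError("no maps to combine")
    if len({m.n_fractions for m in maps}) != 1:
        raise ValueError("replicate maps must share the fraction count")
    for m in maps:
        if not m.normalized:
            raise ValueError("combine_replicates expects normalized maps")
    common = maps[0].accessions
    for m in maps[1:]:
        common = common.intersection(m.accessions)
    if len(common) == 0:
        raise ValueError("no proteins shared across all replicates")
    stacked = np.stack([m.data.loc[common].to_numpy() for m in maps])
    mean = stacked.mean(axis=0)
    mean /= mean.sum(axis=1, keepdims=True)
    data = pd.DataFrame(mean, index=common, columns=maps[0].data.columns)
    return ProfileMatrix(data=data, normalized=True, replicate="combined")


def make_lysate_matrix(
    table: pd.DataFrame, groups: dict[str, str]
) -> LysateMatrix:
    """Log2-transform an LFQ table and keep proteins quantified in all
    replicates of at least one condition (0 counts as missing)."""
    cols = list(groups)
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"columns absent from table: {missing_cols}")
    vals = table[cols].to_numpy(dtype=float)
    vals = np.where(vals > 0, vals, np.nan)
    log2 = pd.DataFrame(np.log2(vals), index=table.index, columns=cols)
    conditions = sorted(set(groups.values()))
    keep = np.zeros(len(table), dtype=bool)
    for cond in conditions:
        sub = log2[[c for c in cols if groups[c] == cond]]
        keep |= sub.notna().all(axis=1).to_numpy()
    log2 = log2.loc[keep]
    if PEPTIDES_COL in table.columns:
        peptides = table.loc[keep, PEPTIDES_COL].astype(int)
    else:
        peptides = pd.Series(1, index=log2.index)
    return LysateMatrix(log2_intensities=log2, peptide_counts=peptides, groups=dict(groups))


def impute_lysate(
    matrix: LysateMatrix, downshift: float = 1.8, width: float = 0.3,
    seed: int = 0,
) -> LysateMatrix:
    """Impute missing log2 intensities per sample column.

    Missing cells are drawn from Normal(mean - downshift*sd,
    (width*sd)^2) of the column's observed values — the standard
    left-shifted imputation for values missing because a protein fell
    below the detection limit. Observed cells are untouched.
    """
    rng = np.random.default_rng(seed)
    out = matrix.log2_intensities.copy()
    for col in out.columns:
        observed = out[col].dropna()
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise ValueError(f"column {col!r} has < 2 observed values")
        mu, sd = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mu - downshift * sd, width * sd, size=n_missing)
        out.loc[out[col].isna(), col] = draws
    return LysateMatrix(
        log2_intensities=out,
        peptide_counts=matrix.peptide_counts,
        groups=dict(matrix.groups),
    )


def plan_highph_combination(n_collected: int = 70) -> list[list[int]]:
    """Pooling plan for offline high-pH reverse-phase fractions.

    Early eluting fractions 1-15 are pooled into one; fractions 16-49
    are pooled orthogonally in pairs (16+33, 17+34, ...); everything
    from fraction 50 on forms the final pool. The pools partition
    {1..n_collected}.
    """
    if n_collected < 50:
        raise ValueError("need at least 50 collected fractions")
    pools: list[list[int]] = [list(range(1, 16))]
    pools.extend([[i, i + 17] for i in range(16, 33)])
    pools.append(list(range(50, n_collected + 1)))
    return pools
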