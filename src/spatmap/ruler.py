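"""Proteomic-ruler copy numbers and organelle protein masses.

The proteomic ruler anchors a sample's total histone MS signal to the
cell's DNA mass (genome size x ploidy x mean base-pair molar mass),
turning relative intensities into absolute copies per cell without
spike-in standards:

    copies_i = (I_i / sum_h I_h) * m_DNA * N_A / MW_i

where the sum runs over histones and m_DNA * N_A =
genome_size_bp * ploidy * bp_molar_mass (g/mol). Multiplying copies by
the molecular weight gives each protein's mass per cell.

For fractionated TMT data, channels are first normalized to their
total intensity and weighted by the measured per-fraction protein
yield; summing the weighted channels yields one ruler-ready value per
protein and replicate, plus each protein's share over the three
coarse pools nucleus (fraction 1) / organelle (fractions 2-9) /
cytosol (fraction 10) used to weight organelle masses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import UNKNOWN, ClassifiedMap
from .synthetic import AVOGADRO, BP_MOLAR_MASS

logger = logging.getLogger(__name__)

NUCLEUS_GROUP_LABELS = ("nucleus", "nucleus_chromatin", "nucleus_nonchromatin")
CYTOSOL_GROUP_LABELS = ("cytosol",)


@dataclass(frozen=True)
class RulerConfig:
    """Genome parameters anchoring the ruler."""

    genome_size_bp: float
    ploidy: float | None = None
    reference_genome_size_bp: float | None = None
    bp_molar_mass: float = BP_MOLAR_MASS
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise ValueError("genome size must be positive")
        if self.ploidy is None and self.reference_genome_size_bp is None:
            raise ValueError("provide ploidy or a reference genome size to derive it")
        if self.ploidy is not None and self.ploidy <= 0:
            raise ValueError("ploidy must be positive")

    @property
    def effective_ploidy(self) -> float:
        if self.ploidy is not None:
            return self.ploidy
        return derive_ploidy(self.genome_size_bp, self.reference_genome_size_bp)

    @property
    def dna_mass_times_avogadro(self) -> float:
        """DNA mass per cell times N_A, in g/mol."""
        return self.genome_size_bp * self.effective_ploidy * self.bp_molar_mass


def derive_ploidy(genome_size_bp: float, reference_genome_size_bp: float) -> float:
    """Effective ploidy of a cell line relative to a diploid reference.

    Twice the ratio of the line's (haploid) genome size to the
    reference species' genome size, e.g. 2 x 2.399/2.72 = 1.76 for
    CHO-K1 against mouse.
    """
    if genome_size_bp <= 0 or reference_genome_size_bp <= 0:
        raise ValueError("genome sizes must be positive")
    return round(2.0 * genome_size_bp / reference_genome_size_bp, 2)


def weight_tmt_fractions(
    replicate_map: pd.DataFrame,
    yields: pd.Series,
    nucleus_fractions: tuple[int, ...] = (1,),
    cytosol_fractions: tuple[int, ...] = (10,),
) -> tuple[pd.Series, pd.DataFrame]:
    """Yield-weighted summed intensity and pool shares for one replicate.

    Each channel is divided by its total over proteins and multiplied
    by that fraction's protein yield, so channels are on a common
    protein-mass scale; the weighted channels are then summed per
    protein. Also returns each protein's share vector over the
    nucleus / organelle / cytosol pools.
    """
    cols = list(replicate_map.columns)
    yields = yields.reindex(cols)
    if yields.isna().any():
        raise ValueError("need one yield per fraction channel")
    totals = replicate_map.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero total intensity in a channel")
    weighted = replicate_map / totals * yields
    summed = weighted.sum(axis=1)
    organelle_fractions = [
        c for c in cols if c not in nucleus_fractions and c not in cytosol_fractions
    ]
    pools = pd.DataFrame(
        {
            "nucleus": weighted[list(nucleus_fractions)].sum(axis=1),
            "organelle": weighted[organelle_fractions].sum(axis=1),
            "cytosol": weighted[list(cytosol_fractions)].sum(axis=1),
        }
    )
    shares = pools.div(pools.sum(axis=1), axis=0)
    return summed, shares


def copies_per_cell(
    intensities: pd.Series,
    molecular_weights: pd.Series,
    histone_accessions: list[str] | pd.Index,
    config: RulerConfig,
) -> pd.DataFrame:
    """Proteomic-ruler copy numbers and masses per cell.

    ``molecular_weights`` in g/mol. Returns a table with columns
    intensity, mw, copies_per_cell, mass_per_cell (grams).
    """
    mw = molecular_weights.reindex(intensities.index)
    if mw.isna().any():
        raise ValueError("molecular weight missing for some proteins")
    hist = pd.Index(histone_accessions).intersection(intensities.index)
    hist_total = intensities.loc[hist].sum()
    if len(hist) == 0 or hist_total <= 0:
        raise ValueError("no histone with positive intensity; ruler has no anchor")
    copies = intensities / hist_total * config.dna_mass_times_avogadro / mw
    mass = copies * mw / config.avogadro
    return pd.DataFrame(
        {
            "intensity": intensities,
            "mw": mw,
            "copies_per_cell": copies,
            "mass_per_cell": mass,
        }
    )


def _share_group(compartment: str) -> str:
    if compartment in NUCLEUS_GROUP_LABELS:
        return "nucleus"
    if compartment in CYTOSOL_GROUP_LABELS:
        return "cytosol"
    return "organelle"


def organelle_masses(
    copies: pd.DataFrame,
    classified: ClassifiedMap,
    shares: pd.DataFrame,
) -> pd.Series:
    """Relative protein mass per organelle.

    Each protein's mass per cell is weighted by its share in the pool
    matching its assigned compartment (nucleus classes by the nucleus
    share, cytosol by the cytosol share, every other organelle class —
    including ribosome and proteasome, which pellet across the middle
    fractions — by the organelle share). Weighted masses are summed
    per compartment and expressed as a fraction of the total weighted
    mass; "unknown" proteins form their own pool, so the fractions sum
    to 1.
    """
    accs = copies.index.intersection(classified.assignments.index)
    missing_shares = accs.difference(shares.index)
    if len(missing_shares) > 0:
        raise ValueError(f"share vectors missing for {len(missing_shares)} proteins")
    labels = classified.predicted.loc[accs]
    group = labels.map(_share_group)
    share_of_group = pd.Series(
        shares.loc[accs].to_numpy()[
            np.arange(len(accs)),
            pd.Categorical(group, categories=shares.columns).codes,
        ],
        index=accs,
    )
    weighted = copies.loc[accs, "mass_per_cell"] * share_of_group
    per_comp = weighted.groupby(labels).sum()
    order = [c for c in classified.taxonomy if c in per_comp.index]
    if UNKNOWN in per_comp.index:
        order.append(UNKNOWN)
    per_comp = per_comp.reindex(order).fillna(0.0)
    total = per_comp.sum()
    if total <= 0:
        raise ValueError("total weighted protein mass is zero")
    return per_comp / total


def top_contributors(
    copies: pd.DataFrame,
    classified: ClassifiedMap,
    organelle: str,
    k: int = 10,
) -> pd.DataFrame:
    """Top-k proteins by mass within one organelle, with mass shares."""
    members = classified.members(organelle).intersection(copies.index)
    if len(members) == 0:
        raise ValueError(f"organelle {organelle!r} has no proteins with copy numbers")
    if k > len(members):
        logger.warning(
            "requested top %d of %d proteins in %s; returning all",
            k, len(members), organelle,
        )
        k = len(members)
    masses = copies.loc[members, "mass_per_cell"].sort_values(ascending=False)
    share = masses / masses.sum()
    out = pd.DataFrame({"mass_per_cell": masses, "mass_share": share}).head(k)
    return out


def cross_method_agreement(
    lysate_copies: pd.Series, fraction_copies: pd.Series
) -> tuple[float, float]:
    """Pearson r and regression slope of log10 copies, fractions vs lysate.

    Quantifies how well yield-weighted TMT fractions reproduce the
    whole-cell lysate ruler estimates.
    """
    overlap = lysate_copies.index.intersection(fraction_copies.index)
    x = np.log10(lysate_copies.loc[overlap].to_numpy(dtype=float))
    y = np.log10(fraction_copies.loc[overlap].to_numpy(dtype=float))
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >= 3 overlapping proteins with positive copies")
    x, y = x[ok], y[ok]
    r = float(stats.pearsonr(x, y).statistic)
    slope = float(np.polyfit(x, y, 1)[0])
    return r, slope
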