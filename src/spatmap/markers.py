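"""Organelle marker sets and homology-based transfer between species.

A marker set maps protein accessions to one compartment of a fixed
taxonomy (default: the 11-class subcellular taxonomy used throughout
this package). Marker sets curated for one species can be ported to
another through a table of homology search hits: hits above a sequence
identity cutoff are kept, the lowest e-value hit defines the homolog,
and markers without a surviving hit are dropped from both species'
sets so the two stay in one-to-one correspondence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .synthetic import DEFAULT_COMPARTMENTS

logger = logging.getLogger(__name__)


@dataclass
class MarkerSet:
    """accession -> compartment over a fixed compartment taxonomy."""

    entries: dict[str, str]
    taxonomy: tuple[str, ...] = DEFAULT_COMPARTMENTS

    def __post_init__(self) -> None:
        bad = {c for c in self.entries.values() if c not in self.taxonomy}
        if bad:
            raise ValueError(f"labels outside taxonomy: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def classes(self) -> list[str]:
        """Taxonomy classes with at least one marker, in taxonomy order."""
        present = set(self.entries.values())
        return [c for c in self.taxonomy if c in present]

    def counts(self) -> pd.Series:
        return pd.Series(self.entries).value_counts().reindex(
            self.taxonomy, fill_value=0
        )

    def as_series(self) -> pd.Series:
        return pd.Series(self.entries, name="compartment")


@dataclass(frozen=True)
class HomologyHit:
    """One homology search hit (BLAST outfmt-6 style)."""

    query: str
    subject: str
    identity: float
    e_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


def load_markers(path, taxonomy: tuple[str, ...] = DEFAULT_COMPARTMENTS) -> MarkerSet:
    """Load a two-column (accession, compartment) marker TSV."""
    table = pd.read_csv(path, sep="\t", header=None, names=["accession", "compartment"],
                        comment="#", dtype=str)
    if len(table) == 0:
        raise ValueError(f"marker file {path} is empty")
    dup = table["accession"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate marker accessions: {table['accession'][dup].tolist()[:5]}"
        )
    return MarkerSet(
        entries=dict(zip(table["accession"], table["compartment"])),
        taxonomy=taxonomy,
    )


def save_markers(markers: MarkerSet, path) -> None:
    markers.as_series().to_csv(path, sep="\t", header=False)


def load_homology_hits(path) -> list[HomologyHit]:
    """Load a BLAST outfmt-6-like hit TSV (qseqid, sseqid, pident, evalue).

    Percent identities above 1 are interpreted as percentages.
    """
    table = pd.read_csv(
        path, sep="\t", header=None,
        names=["query", "subject", "identity", "e_value"], comment="#",
    )
    hits = []
    for row in table.itertuples(index=False):
        ident = row.identity / 100.0 if row.identity > 1.0 else row.identity
        hits.append(HomologyHit(str(row.query), str(row.subject), ident, row.e_value))
    return hits


def transfer_markers(
    markers: MarkerSet,
    hits: list[HomologyHit],
    min_identity: float = 0.8,
) -> tuple[MarkerSet, MarkerSet]:
    """Port a marker set to a target species via homology hits.

    Per marker, hits with identity >= ``min_identity`` are retained and
    the lowest e-value hit names the homolog (e-value ties resolved by
    input order, with a warning). Markers without any surviving hit are
    dropped from both the returned target-species set and the filtered
    source set, which therefore always have equal size.
    """
    best: dict[str, HomologyHit] = {}
    for hit in hits:
        if hit.query not in markers.entries or hit.identity < min_identity:
            continue
        prev = best.get(hit.query)
        if prev is None or hit.e_value < prev.e_value:
            best[hit.query] = hit
        elif hit.e_value == prev.e_value:
            logger.warning(
                "e-value tie for %s (%s vs %s); keeping the first hit",
                hit.query, prev.subject, hit.subject,
            )
    target_entries: dict[str, str] = {}
    source_entries: dict[str, str] = {}
    for acc, comp in markers.entries.items():
        hit = best.get(acc)
        if hit is None:
            continue
        if hit.subject in target_entries:
            logger.warning(
                "subject %s already assigned; skipping duplicate homolog of %s",
                hit.subject, acc,
            )
            continue
        target_entries[hit.subject] = comp
        source_entries[acc] = comp
    if not target_entries:
        logger.warning("no markers survived homology transfer")
    return (
        MarkerSet(entries=target_entries, taxonomy=markers.taxonomy),
        MarkerSet(entries=source_entries, taxonomy=markers.taxonomy),
    )
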