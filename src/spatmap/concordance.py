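"""Classification reproducibility between pairs of maps.

Concordance is the fraction of overlapping proteins assigned the same
compartment in two maps (markers removed first; "unknown" is a
comparable label). Stratifying by SVM score — very high (>= 0.9), high
[0.7, 0.9), medium [0.5, 0.7), low (< 0.5), using the smaller of the
two maps' scores — separates confident, reproducible predictions from
uncertain ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassifiedMap

STRATA_ORDER = ("very_high", "high", "medium", "low")


@dataclass(frozen=True)
class ScoreStrata:
    """SVM-score strata boundaries partitioning [0, 1]."""

    very_high: float = 0.9
    high: float = 0.7
    medium: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.medium < self.high < self.very_high <= 1:
            raise ValueError("strata boundaries must satisfy 0 < medium < high < very_high <= 1")

    def assign(self, score: float) -> str:
        if score >= self.very_high:
            return "very_high"
        if score >= self.high:
            return "high"
        if score >= self.medium:
            return "medium"
        return "low"


def _overlap_non_markers(map_a: ClassifiedMap, map_b: ClassifiedMap) -> pd.Index:
    a = map_a.assignments.index[~map_a.assignments["is_marker"]]
    b = map_b.assignments.index[~map_b.assignments["is_marker"]]
    overlap = a.intersection(b)
    if len(overlap) == 0:
        raise ValueError("no overlapping non-marker proteins between the maps")
    return overlap


def pairwise_concordance(map_a: ClassifiedMap, map_b: ClassifiedMap) -> float:
    """Fraction of overlapping non-marker proteins with identical labels."""
    overlap = _overlap_non_markers(map_a, map_b)
    same = map_a.predicted.loc[overlap].to_numpy() == map_b.predicted.loc[overlap].to_numpy()
    return float(same.mean())


def stratified_concordance(
    map_a: ClassifiedMap,
    map_b: ClassifiedMap,
    strata: ScoreStrata | None = None,
) -> pd.DataFrame:
    """Concordance per SVM-score stratum.

    Each overlapping protein is assigned to the stratum of
    min(score_A, score_B); empty strata report NaN concordance.
    Returns a table indexed by stratum with columns ``concordance``
    and ``n``.
    """
    strata = strata or ScoreStrata()
    overlap = _overlap_non_markers(map_a, map_b)
    min_score = np.minimum(
        map_a.scores.loc[overlap].to_numpy(), map_b.scores.loc[overlap].to_numpy()
    )
    same = map_a.predicted.loc[overlap].to_numpy() == map_b.predicted.loc[overlap].to_numpy()
    labels = np.array([strata.assign(s) for s in min_score])
    rows = {}
    for name in STRATA_ORDER:
        mask = labels == name
        n = int(mask.sum())
        rows[name] = {
            "concordance": float(same[mask].mean()) if n else float("nan"),
            "n": n,
        }
    return pd.DataFrame.from_dict(rows, orient="index").reindex(STRATA_ORDER)


def compare_to_reference(
    cmap: ClassifiedMap, reference: pd.Series
) -> tuple[pd.Series, pd.DataFrame]:
    """Agreement of map predictions with an external annotation table.

    ``reference`` maps accession to a single location label; entries
    with multiple locations (";"-separated) are excluded. Returns per
    predicted class the fraction of overlapping proteins whose
    reference label matches, plus the full predicted x reference
    contingency table.
    """
    single = reference[~reference.astype(str).str.contains(";")]
    overlap = cmap.assignments.index.intersection(single.index)
    if len(overlap) == 0:
        raise ValueError("no overlap between map and reference annotations")
    pred = cmap.predicted.loc[overlap]
    ref = single.loc[overlap]
    contingency = pd.crosstab(pred, ref)
    agree = (pred == ref).groupby(pred).mean()
    return agree, contingency
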