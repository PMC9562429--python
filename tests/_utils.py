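"""Shared helpers for the test suite: simulation prep and hand-built maps."""

from __future__ import annotations

import numpy as np
import pandas as pd

import spatmap as sm
from spatmap import io_preprocess as io
from spatmap.classify import ClassifiedMap
from spatmap.io_preprocess import ProfileMatrix
from spatmap.markers import MarkerSet


def prep_experiment(config: sm.SimulationConfig):
    """Simulate and preprocess: returns (truth, reps, combined, marker_set)."""
    truth, maps, _ = sm.simulate_experiment(config)
    reps = {
        cond: [
            io.normalize_profiles(m, list(m.columns), replicate=f"{cond}{i}")
            for i, m in enumerate(ms, 1)
        ]
        for cond, ms in maps.items()
    }
    combined = {cond: io.combine_replicates(v) for cond, v in reps.items()}
    marker_set = MarkerSet(
        entries=truth.markers.to_dict(), taxonomy=config.compartments
    )
    return truth, reps, combined, marker_set


def classify_both(combined, marker_set, cost=50.0, sigma=1.0, threshold=0.7, seed=0):
    return {
        cond: sm.classify_map(
            combined[cond], marker_set, cost, sigma, threshold=threshold, seed=seed
        )
        for cond in ("A", "B")
    }


def build_cmap(
    records: dict[str, tuple[str, float, bool]],
    taxonomy: tuple[str, ...] = ("cytosol", "ER", "Golgi"),
    n_fractions: int = 4,
    threshold: float = 0.7,
) -> ClassifiedMap:
    """Hand-built ClassifiedMap: accession -> (label, score, is_marker)."""
    accs = list(records)
    rng = np.random.default_rng(0)
    profiles = rng.dirichlet(np.ones(n_fractions), size=len(accs))
    pm = ProfileMatrix(
        data=pd.DataFrame(profiles, index=pd.Index(accs), columns=range(1, n_fractions + 1)),
        normalized=True,
    )
    assignments = pd.DataFrame(
        {
            "predicted": [records[a][0] for a in accs],
            "svm_score": [records[a][1] for a in accs],
            "is_marker": [records[a][2] for a in accs],
        },
        index=pd.Index(accs),
    )
    return ClassifiedMap(
        profiles=pm, assignments=assignments, taxonomy=taxonomy, threshold=threshold
    )
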