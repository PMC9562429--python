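"""Reusable simulation studies: null FDR, power, recovery, concordance.

These routines run the full analysis chain on freshly generated
synthetic experiments and summarize how well it recovers the planted
truth. They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic as _syn
from .classify import classify_map, cross_validate_macro_f1, tune_svm, HyperparamGrid
from .concordance import STRATA_ORDER, stratified_concordance
from .dl_detect import merge_nuclear, run_dl_analysis
from .io_preprocess import combine_replicates, normalize_profiles
from .markers import MarkerSet
from .ruler import RulerConfig, copies_per_cell, organelle_masses, weight_tmt_fractions
from .synthetic import SimulationConfig, fraction_yields

DL_SIM_CONFIG = dict(n_proteins=440, marker_fraction=0.5, noise_sd=0.1)


def _prep(config: SimulationConfig):
    truth, maps, _ = _syn.simulate_experiment(config)
    reps = {
        cond: [normalize_profiles(m, list(m.columns)) for m in ms]
        for cond, ms in maps.items()
    }
    combined = {cond: combine_replicates(v) for cond, v in reps.items()}
    markers = MarkerSet(entries=truth.markers.to_dict(), taxonomy=config.compartments)
    return truth, reps, combined, markers


def _classify_pair(combined, markers, cost=50.0, sigma=1.0, threshold=0.7):
    return {
        cond: classify_map(combined[cond], markers, cost, sigma,
                           threshold=threshold, seed=0)
        for cond in ("A", "B")
    }


def dl_null_run(seed: int, **overrides) -> tuple[int, int]:
    """One no-translocation experiment; returns (false DL calls, proteins tested)."""
    config = SimulationConfig(**{**DL_SIM_CONFIG, **overrides}, seed=seed)
    _, reps, combined, markers = _prep(config)
    cms = _classify_pair(combined, markers)
    res = run_dl_analysis(cms["A"], cms["B"], reps["A"], reps["B"], seed=seed)
    quant = res["quantitative"]
    return int(quant["is_DL"].sum()), len(quant)


def dl_power_run(
    seed: int, n_translocators: int = 10, origin: str = "ER", target: str = "PM",
    **overrides,
) -> tuple[int, int]:
    """One planted-translocation experiment.

    Returns (translocators detected with the correct closest-compartment
    pair, translocators planted).
    """
    trans = tuple((None, origin, target) for _ in range(n_translocators))
    config = SimulationConfig(
        **{**DL_SIM_CONFIG, **overrides}, translocations=trans, seed=seed
    )
    truth, reps, combined, markers = _prep(config)
    cms = _classify_pair(combined, markers)
    res = run_dl_analysis(cms["A"], cms["B"], reps["A"], reps["B"], seed=seed)
    planted = truth.table.loc[
        truth.table.compartment_A != truth.table.compartment_B, "accession"
    ]
    quant = res["quantitative"]
    hits = quant.loc[quant.index.intersection(planted)]
    correct = (
        hits["is_DL"]
        & (hits["closest_A"] == origin)
        & (hits["closest_B"] == target)
    )
    return int(correct.sum()), len(planted)


def dl_null_study(n_runs: int, seed: int = 0, **overrides) -> dict:
    """Empirical DL false-positive proportion over null experiments."""
    props = []
    for i in range(n_runs):
        fp, n = dl_null_run(seed + i, **overrides)
        props.append(fp / n)
    props = np.array(props)
    return {
        "n_runs": n_runs,
        "false_positive_proportion": float(props.mean()),
        "se": float(props.std(ddof=1) / np.sqrt(n_runs)) if n_runs > 1 else 0.0,
    }


def dl_power_study(n_runs: int, seed: int = 0, **overrides) -> dict:
    """Detection rate of planted translocators over repeated experiments."""
    hits = planted = 0
    for i in range(n_runs):
        h, p = dl_power_run(seed + i, **overrides)
        hits += h
        planted += p
    return {"n_runs": n_runs, "n_planted": planted, "power": hits / planted}


def classifier_cv_study(
    seed: int = 0,
    n_proteins: int = 2002,
    marker_fraction: float = 0.36,
    noise_sd: float = 0.05,
    grid: HyperparamGrid | None = None,
) -> dict:
    """Grid-tuned 5-fold CV macro F1 on a well-separated synthetic map."""
    grid = grid or HyperparamGrid(
        costs=(20, 40, 60), sigmas=(0.1, 1.0, 10.0), inner_reps=10
    )
    config = SimulationConfig(
        n_proteins=n_proteins, marker_fraction=marker_fraction,
        noise_sd=noise_sd, seed=seed,
    )
    _, _, combined, markers = _prep(config)
    tune = tune_svm(combined["A"], markers, grid, seed=seed)
    return {
        "cost": tune.cost,
        "sigma": tune.sigma,
        "cv_macro_f1": tune.cv_macro_f1,
        "n_markers": len(markers),
    }


def concordance_study(seed: int = 0, **overrides) -> pd.DataFrame:
    """Stratified concordance averaged over replicate-map pairs.

    Uses study-scale marker coverage so SVM scores span the strata.
    """
    defaults = dict(n_proteins=2002, marker_fraction=0.36, noise_sd=0.1)
    config = SimulationConfig(**{**defaults, **overrides}, seed=seed)
    _, reps, combined, markers = _prep(config)
    tables = []
    for cond in ("A", "B"):
        cms = [
            classify_map(pm, markers, 50.0, 1.0, threshold=0.7, seed=0)
            for pm in reps[cond]
        ]
        for i in range(len(cms)):
            for j in range(i + 1, len(cms)):
                tables.append(stratified_concordance(cms[i], cms[j]))
    stacked = pd.concat(tables)
    out = pd.DataFrame(
        {
            "concordance": stacked["concordance"].groupby(level=0).mean(),
            "n": stacked["n"].groupby(level=0).sum(),
        }
    ).reindex(STRATA_ORDER)
    return out


def ruler_recovery_study(seed: int = 0, noise_sd: float = 0.05) -> dict:
    """Copy-number recovery error and organelle-mass closure."""
    config = SimulationConfig(
        n_proteins=440, marker_fraction=0.5, noise_sd=noise_sd, seed=seed
    )
    truth, reps, combined, markers = _prep(config)
    cms = _classify_pair(combined, markers, threshold=0.0)
    raw = _syn.simulate_replicate_map(truth, config, "A", 1)
    yields = fraction_yields(truth, config, "A")
    summed, shares = weight_tmt_fractions(raw, yields)
    rcfg = RulerConfig(genome_size_bp=config.genome_size_bp, ploidy=config.ploidy)
    hist = truth.table.loc[truth.table.is_histone, "accession"].tolist()
    copies = copies_per_cell(summed, truth.mw, hist, rcfg)
    err = np.abs(np.log2(copies["copies_per_cell"] / truth.copies("A")))
    masses = organelle_masses(copies, merge_nuclear(cms["A"]), shares)
    return {
        "median_abs_log2_error": float(err.median()),
        "mass_closure": float(masses.sum()),
        "organelle_mass_fractions": masses,
    }
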