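"""Config-driven orchestration of the full two-condition workflow.

simulate-or-ingest -> preprocess -> classify -> concordance ->
differential localization -> proteomic ruler -> differential
expression / enrichment, with every stage's tables written to a run
directory and a JSON summary report. A single global seed is fanned
out to per-stage seeds by stable hashing, so runs are reproducible
while stages stay statistically independent.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import concordance as _concordance
from . import de_enrich as _de
from . import dl_detect as _dl
from . import io_preprocess as _io
from . import ruler as _ruler
from . import synthetic as _syn
from .markers import MarkerSet, load_markers

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (zlib.crc32(stage.encode()) ^ seed) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """Thresholds, grid, and input source of one pipeline run."""

    simulation: _syn.SimulationConfig | None = None
    inputs: dict | None = None  # ingest mode: paths per condition
    svm_threshold: float = 0.7
    dl_alpha: float = 0.05
    de_alpha: float = 0.05
    enrich_alpha: float = 0.02
    grid: _classify.HyperparamGrid = field(
        default_factory=_classify.HyperparamGrid
    )
    ruler: dict = field(default_factory=dict)  # per-condition RulerConfig kwargs
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("svm_threshold", "dl_alpha", "de_alpha", "enrich_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of simulation / inputs must be set")
        if self.inputs is not None:
            for cond in ("A", "B"):
                for p in self.inputs.get("maps", {}).get(cond, []):
                    if not Path(p).exists():
                        raise FileNotFoundError(f"map file not found: {p}")
            mpath = self.inputs.get("markers")
            if mpath is None or not Path(mpath).exists():
                raise FileNotFoundError(f"marker file not found: {mpath}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            if "compartments" in sim:
                sim["compartments"] = tuple(sim["compartments"])
            if "translocations" in sim:
                sim["translocations"] = tuple(
                    tuple(t) for t in sim["translocations"]
                )
            raw["simulation"] = _syn.SimulationConfig(**sim)
        if "grid" in raw and raw["grid"] is not None:
            g = dict(raw["grid"])
            for key in ("costs", "sigmas"):
                if key in g:
                    g[key] = tuple(g[key])
            raw["grid"] = _classify.HyperparamGrid(**g)
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full workflow and write tables + report to ``outdir``.

    Returns the report dictionary (also written as report.json).
    Deterministic given ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    # ---- inputs -------------------------------------------------------
    if config.simulation is not None:
        sim = dataclasses.replace(
            config.simulation, seed=stage_seed(config.seed, "simulate")
        )
        truth, raw_maps, lysates = _syn.simulate_experiment(sim)
        marker_set = MarkerSet(
            entries=truth.markers.to_dict(), taxonomy=sim.compartments
        )
        yields = {
            cond: _syn.fraction_yields(truth, sim, cond) for cond in ("A", "B")
        }
        lysate_table = pd.concat(
            [lysates["A"].drop(columns=[_syn.PEPTIDES_COL, _syn.MW_COL]),
             lysates["B"]],
            axis=1,
        )
        mw = truth.mw
        histones = truth.table.loc[truth.table["is_histone"], "accession"].tolist()
        annotations = {
            acc: {f"LOC:{comp}"}
            for acc, comp in truth.compartment("A").items()
        }
        ruler_cfgs = {
            cond: _ruler.RulerConfig(
                genome_size_bp=sim.genome_size_bp, ploidy=sim.ploidy
            )
            for cond in ("A", "B")
        }
    else:
        truth = None
        marker_set = load_markers(config.inputs["markers"])
        raw_maps = {}
        for cond in ("A", "B"):
            raw_maps[cond] = []
            for path in config.inputs["maps"][cond]:
                table = _io.read_protein_groups(path, dialect="tmt")
                table = _io.filter_identifications(table)
                cols = _io.intensity_columns(table, "tmt")
                raw_maps[cond].append(
                    _io.require_complete_reporters(table, cols)[cols].set_axis(
                        range(1, len(cols) + 1), axis=1
                    )
                )
        lysate_table = None
        yields = config.inputs.get("yields", {})
        mw = None
        histones = config.inputs.get("histones", [])
        annotations = config.inputs.get("annotations", {})
        ruler_cfgs = {
            cond: _ruler.RulerConfig(**cfg)
            for cond, cfg in config.ruler.items()
        }

    # ---- preprocess ---------------------------------------------------
    single_maps: dict[str, list[_io.ProfileMatrix]] = {}
    combined: dict[str, _io.ProfileMatrix] = {}
    for cond in ("A", "B"):
        mats = []
        for r, raw in enumerate(raw_maps[cond], start=1):
            cols = list(raw.columns)
            complete = _io.require_complete_reporters(raw, cols)
            mats.append(
                _io.normalize_profiles(complete, cols, replicate=f"{cond}{r}")
            )
        single_maps[cond] = mats
        combined[cond] = _io.combine_replicates(mats)
        report[f"n_proteins_combined_{cond}"] = len(combined[cond].accessions)

    # ---- classify -----------------------------------------------------
    classified: dict[str, _classify.ClassifiedMap] = {}
    classified_reps: dict[str, list[_classify.ClassifiedMap]] = {}
    for cond in ("A", "B"):
        seed_c = stage_seed(config.seed, f"classify-{cond}")
        tune = _classify.tune_svm(
            combined[cond], marker_set, config.grid, seed=seed_c
        )
        report[f"svm_cost_{cond}"] = tune.cost
        report[f"svm_sigma_{cond}"] = tune.sigma
        report[f"cv_macro_f1_{cond}"] = tune.cv_macro_f1
        classified[cond] = _classify.classify_map(
            combined[cond], marker_set, tune.cost, tune.sigma,
            threshold=config.svm_threshold, seed=seed_c,
        )
        report[f"classified_fraction_{cond}"] = classified[
            cond
        ].classified_fraction()
        classified_reps[cond] = [
            _classify.classify_map(
                m, marker_set, tune.cost, tune.sigma,
                threshold=config.svm_threshold, seed=seed_c,
            )
            for m in single_maps[cond]
        ]
        _write(classified[cond].assignments, outdir / f"classified_{cond}.tsv")

    # ---- concordance --------------------------------------------------
    strata_tables = []
    whole = []
    for cond in ("A", "B"):
        for m1, m2 in itertools.combinations(classified_reps[cond], 2):
            whole.append(_concordance.pairwise_concordance(m1, m2))
            strata_tables.append(_concordance.stratified_concordance(m1, m2))
    report["mean_pairwise_concordance"] = float(np.mean(whole))
    strata_mean = (
        pd.concat(strata_tables)["concordance"].groupby(level=0).mean()
        .reindex(_concordance.STRATA_ORDER)
    )
    report["concordance_by_stratum"] = {
        k: (None if pd.isna(v) else float(v)) for k, v in strata_mean.items()
    }

    # ---- differential localization -----------------------------------
    dl = _dl.run_dl_analysis(
        classified["A"], classified["B"],
        single_maps["A"], single_maps["B"],
        alpha=config.dl_alpha, seed=stage_seed(config.seed, "dl"),
    )
    report["n_dl_qualitative"] = len(dl["qualitative"])
    report["n_dl_quantitative"] = int(dl["quantitative"]["is_DL"].sum())
    report["n_dl_total"] = len(dl["collated"])
    _write(dl["collated"], outdir / "dl_proteins.tsv")

    # ---- proteomic ruler ---------------------------------------------
    if mw is not None and histones:
        for cond in ("A", "B"):
            per_rep = []
            shares = None
            for raw in raw_maps[cond]:
                summed, shares = _ruler.weight_tmt_fractions(raw, yields[cond])
                per_rep.append(summed)
            intensity = pd.concat(per_rep, axis=1).mean(axis=1)
            copies = _ruler.copies_per_cell(
                intensity, mw, histones, ruler_cfgs[cond]
            )
            merged_map = _dl.merge_nuclear(classified[cond])
            masses = _ruler.organelle_masses(copies, merged_map, shares)
            report[f"organelle_mass_fractions_{cond}"] = {
                k: float(v) for k, v in masses.items()
            }
            _write(copies, outdir / f"copy_numbers_{cond}.tsv")
            if lysate_table is not None:
                lys_cols = {
                    c: cond for c in lysate_table.columns
                    if str(c).startswith(f"LFQ intensity {cond}")
                }
                lys = _io.make_lysate_matrix(lysate_table, lys_cols)
                lys = _io.impute_lysate(
                    lys, seed=stage_seed(config.seed, f"impute-{cond}")
                )
                lys_intensity = np.exp2(lys.log2_intensities).mean(axis=1)
                lys_copies = _ruler.copies_per_cell(
                    lys_intensity, mw, histones, ruler_cfgs[cond]
                )
                r, slope = _ruler.cross_method_agreement(
                    lys_copies["copies_per_cell"], copies["copies_per_cell"]
                )
                report[f"lysate_fraction_pearson_r_{cond}"] = r
                report[f"lysate_fraction_slope_{cond}"] = slope

    # ---- differential expression + enrichment ------------------------
    if lysate_table is not None:
        groups = {
            c: ("A" if "A_" in str(c) else "B")
            for c in lysate_table.columns
            if str(c).startswith("LFQ intensity")
        }
        lys = _io.make_lysate_matrix(lysate_table, groups)
        lys = _io.impute_lysate(lys, seed=stage_seed(config.seed, "impute-de"))
        de = _de.moderated_de(lys, "A", "B", alpha=config.de_alpha)
        report["n_de_significant"] = int(de["significant"].sum())
        report["n_lysate_proteins"] = len(de)
        _write(de, outdir / "de_proteins.tsv")
        foreground = de.index[de["significant"]].tolist()
        if foreground and annotations:
            enr = _de.fisher_enrichment(
                foreground, de.index, annotations, alpha=config.enrich_alpha
            )
            report["n_enriched_terms"] = int(enr["significant"].sum())
            _write(enr, outdir / "enrichment.tsv")

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
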