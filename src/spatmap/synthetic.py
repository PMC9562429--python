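"""Ground-truthed synthetic spatial-proteomics experiments.

Emulates a two-cell-line organelle-profiling study: each "cell line"
(condition A or B) is fractionated into ``n_fractions`` sequential
centrifugation fractions, quantified in ``n_replicates`` replicate TMT
maps, and additionally measured as unfractionated whole-cell lysates
with label-free quantification (LFQ).

Every protein belongs to one subcellular compartment per condition;
compartment mean profiles are compositional vectors over fractions with
one dominant fraction each (differential pelleting). Between-condition
"organelle shifts" perturb whole compartment means, translocating
proteins change compartment, and a histone subset anchors the
proteomic-ruler copy-number scale (total histone mass equals the
cell's DNA mass by construction).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

AVOGADRO = 6.02214076e23
BP_MOLAR_MASS = 615.8771  # g/mol per base pair, double-stranded

DEFAULT_COMPARTMENTS: tuple[str, ...] = (
    "cytosol",
    "ER",
    "Golgi",
    "lysosome",
    "mitochondrion",
    "nucleus_chromatin",
    "nucleus_nonchromatin",
    "peroxisome",
    "PM",
    "proteasome",
    "ribosome",
)

CONDITIONS = ("A", "B")

# MaxQuant-style column names (minimal dialect read by io_preprocess)
ACCESSION_COL = "Protein IDs"
PEPTIDES_COL = "Razor + unique peptides"
MW_COL = "Mol. weight [kDa]"
FLAG_COLS = ("Reverse", "Potential contaminant", "Only identified by site")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic two-condition experiment.

    Defaults mirror the design of the emulated study: two cell lines,
    three replicate maps of ten fractions each, eleven compartments,
    multiplicative reporter-ion noise and systematic between-line
    organelle profile shifts.
    """

    n_proteins: int = 1000
    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS
    n_fractions: int = 10
    n_replicates: int = 3
    marker_fraction: float = 0.35
    profile_concentration: float = 50.0
    noise_sd: float = 0.1
    organelle_shift_sd: float = 0.2
    translocations: tuple[tuple[str | None, str, str], ...] = ()
    expression_changes: tuple[tuple[str, float], ...] = ()
    abundance_mu: float = 10.0
    abundance_sigma: float = 1.5
    histone_count: int = 10
    genome_size_bp: float = 2.72e9
    ploidy: float = 2.0
    missing_rate_slope: float = 0.15
    missing_rate_intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ValueError("n_fractions must be >= 2")
        if not 0 < self.marker_fraction < 1:
            raise ValueError("marker_fraction must lie in (0, 1)")
        for name in ("n_proteins", "n_replicates", "histone_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(set(self.compartments)) != len(self.compartments):
            raise ValueError("compartment labels must be unique")
        for _, a, b in self.translocations:
            for comp in (a, b):
                if comp not in self.compartments:
                    raise ValueError(
                        f"translocation names unknown compartment {comp!r}"
                    )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Per-protein truth table for one simulated experiment.

    ``table`` columns: accession, compartment_A, compartment_B,
    copies_A, copies_B, mw (g/mol), peptides, is_histone, is_marker.
    """

    table: pd.DataFrame
    config: SimulationConfig

    @property
    def accessions(self) -> pd.Index:
        return pd.Index(self.table["accession"])

    def compartment(self, condition: str) -> pd.Series:
        _check_condition(condition)
        return self.table.set_index("accession")[f"compartment_{condition}"]

    def copies(self, condition: str) -> pd.Series:
        _check_condition(condition)
        return self.table.set_index("accession")[f"copies_{condition}"]

    @property
    def mw(self) -> pd.Series:
        return self.table.set_index("accession")["mw"]

    @property
    def markers(self) -> pd.Series:
        """accession -> compartment_A for marker proteins."""
        sub = self.table[self.table["is_marker"]]
        return sub.set_index("accession")["compartment_A"]


def _check_condition(condition: str) -> None:
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def min_markers_per_compartment(config: SimulationConfig) -> int:
    """Markers needed per compartment for downstream covariance fits."""
    return max(8, config.n_fractions + 2)


def compartment_profiles(config: SimulationConfig, condition: str) -> pd.DataFrame:
    """Mean fractionation profile of each compartment under one condition.

    Profiles are drawn from a Dirichlet scheme with one dominant
    fraction per compartment (compartments beyond the fraction count
    split their signature over two adjacent fractions). Condition B
    applies a compartment-wise multiplicative log-normal shift to the
    shared base profiles, emulating systematic organelle-profile
    differences between cell lines.
    """
    _check_condition(condition)
    n_c, n_f = len(config.compartments), config.n_fractions
    rng = _rng(config, 10)
    profiles = np.empty((n_c, n_f))
    for k in range(n_c):
        alpha = np.ones(n_f)
        if k < n_f:
            alpha[k] += config.profile_concentration
        else:
            j = (k - n_f) % (n_f - 1)
            alpha[j] += config.profile_concentration / 2.0
            alpha[j + 1] += config.profile_concentration / 2.0
        profiles[k] = rng.dirichlet(alpha)
    if condition == "B" and config.organelle_shift_sd > 0:
        shift_rng = _rng(config, 11)
        shift = np.exp(
            shift_rng.normal(0.0, config.organelle_shift_sd, size=(n_c, n_f))
        )
        profiles = profiles * shift
        profiles /= profiles.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        profiles,
        index=list(config.compartments),
        columns=range(1, n_f + 1),
    )


def _dna_mass_times_avogadro(config: SimulationConfig) -> float:
    """DNA mass per cell times Avogadro's number, in g/mol."""
    return config.genome_size_bp * config.ploidy * BP_MOLAR_MASS


def generate_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the per-protein ground truth for one experiment.

    Deterministic given ``config.seed``. Marker proteins cover every
    compartment with at least ``max(8, n_fractions + 2)`` members so
    that robust covariance estimation is feasible downstream; histones
    sit in the chromatin compartment, never translocate, and their
    total protein mass is scaled to equal the DNA mass per cell.
    """
    rng = _rng(config, 0)
    n = config.n_proteins
    comps = list(config.compartments)
    accessions = [f"P{i + 1:05d}" for i in range(n)]
    comp_a = [comps[i % len(comps)] for i in range(n)]
    table = pd.DataFrame({"accession": accessions, "compartment_A": comp_a})
    table["compartment_B"] = table["compartment_A"]

    # translocations: explicit accession, or None -> auto-pick from comp_a
    used: set[str] = set()
    trans_rows: list[tuple[str, str, str]] = []
    for name, a, b in config.translocations:
        if name is None:
            pool = table.index[
                (table["compartment_A"] == a) & ~table["accession"].isin(used)
            ]
            if len(pool) == 0:
                raise ValueError(f"no free protein available in {a!r} to translocate")
            idx = pool[0]
            name = table.at[idx, "accession"]
        else:
            match = table.index[table["accession"] == name]
            if len(match) == 0:
                raise ValueError(f"unknown accession {name!r} in translocations")
            idx = match[0]
        used.add(name)
        table.at[idx, "compartment_A"] = a
        table.at[idx, "compartment_B"] = b
        trans_rows.append((name, a, b))
    translocators = {name for name, _, _ in trans_rows}

    # histones: chromatin compartment, never translocators
    chrom = next(
        (c for c in comps if "chromatin" in c),
        next((c for c in comps if "nucleus" in c), comps[0]),
    )
    hist_pool = table.index[
        (table["compartment_A"] == chrom) & ~table["accession"].isin(translocators)
    ]
    if len(hist_pool) < config.histone_count:
        raise ValueError(
            f"compartment {chrom!r} has too few proteins for "
            f"{config.histone_count} histones"
        )
    hist_idx = hist_pool[: config.histone_count]
    table["is_histone"] = False
    table.loc[hist_idx, "is_histone"] = True

    # markers: sampled per compartment; translocators are never markers
    table["is_marker"] = False
    need = min_markers_per_compartment(config)
    for comp in comps:
        members = table.index[
            (table["compartment_A"] == comp) & ~table["accession"].isin(translocators)
        ]
        k = int(round(config.marker_fraction * len(members)))
        if k < need:
            raise ValueError(
                f"compartment {comp!r} would get {k} markers; "
                f"needs >= {need} (raise n_proteins or marker_fraction)"
            )
        chosen = rng.choice(members, size=k, replace=False)
        table.loc[chosen, "is_marker"] = True

    # molecular weights (g/mol); histones near 14 kDa
    mw = np.exp(rng.normal(np.log(4.5e4), 0.35, size=n)).clip(8e3, 5e5)
    mw[table["is_histone"].to_numpy()] = rng.normal(
        1.4e4, 500.0, size=config.histone_count
    ).clip(1.1e4, 1.7e4)
    table["mw"] = mw

    # copy numbers: log-normal, histones rescaled to the DNA-mass anchor
    copies = np.exp(rng.normal(config.abundance_mu, config.abundance_sigma, size=n))
    hist_mask = table["is_histone"].to_numpy()
    target = _dna_mass_times_avogadro(config)  # sum over histones of copies*mw
    weights = np.exp(rng.normal(0.0, 0.3, size=config.histone_count))
    hist_mass = target * weights / weights.sum()
    copies[hist_mask] = hist_mass / mw[hist_mask]
    table["copies_A"] = copies
    table["copies_B"] = copies
    for name, log2fc in config.expression_changes:
        match = table.index[table["accession"] == name]
        if len(match) == 0:
            raise ValueError(f"unknown accession {name!r} in expression_changes")
        table.loc[match, "copies_B"] = table.loc[match, "copies_A"] * 2.0**log2fc

    table["peptides"] = 1 + rng.poisson(mw / 4000.0)
    return GroundTruth(table=table, config=config)


def simulate_replicate_map(
    truth: GroundTruth,
    config: SimulationConfig,
    condition: str,
    replicate: int,
) -> pd.DataFrame:
    """Raw reporter-ion intensities of one replicate map.

    Each protein's row is its mass abundance (copies x MW) times its
    compartment's condition-specific mean profile, with independent
    multiplicative log-normal noise per channel. Entries are strictly
    positive; seeded per (condition, replicate).
    """
    _check_condition(condition)
    profiles = compartment_profiles(config, condition)
    comp = truth.compartment(condition)
    mass = (truth.copies(condition) * truth.mw).to_numpy()
    base = profiles.loc[comp].to_numpy() * mass[:, None]
    rng = _rng(config, 1, CONDITIONS.index(condition), replicate)
    if config.noise_sd > 0:
        base = base * np.exp(rng.normal(0.0, config.noise_sd, size=base.shape))
    return pd.DataFrame(base, index=truth.accessions, columns=profiles.columns)


def fraction_yields(
    truth: GroundTruth, config: SimulationConfig, condition: str
) -> pd.Series:
    """Noise-free protein mass recovered per fraction (arbitrary mass units).

    Plays the role of the per-fraction protein-yield measurements used
    to weight TMT channels in the proteomic-ruler workflow.
    """
    profiles = compartment_profiles(config, condition)
    comp = truth.compartment(condition)
    mass = (truth.copies(condition) * truth.mw).to_numpy()
    per_fraction = (profiles.loc[comp].to_numpy() * mass[:, None]).sum(axis=0)
    return pd.Series(per_fraction, index=profiles.columns, name="yield")


def simulate_lysate(
    truth: GroundTruth, config: SimulationConfig, condition: str
) -> pd.DataFrame:
    """Whole-cell lysate LFQ table with left-censored missing values.

    Log intensity tracks log(copies x MW) with additive noise; the
    probability that a value is missing increases as intensity drops
    below the lower quintile of the (noise-free) abundance
    distribution. Missing values are written as 0, the MaxQuant
    convention. Columns: one LFQ intensity column per replicate plus
    peptide counts and molecular weight.
    """
    _check_condition(condition)
    mass = (truth.copies(condition) * truth.mw).to_numpy()
    log2_true = np.log2(mass)
    center = np.quantile(log2_true, 0.2)
    sd_log2 = config.noise_sd / np.log(2)
    out = pd.DataFrame(index=truth.accessions)
    for rep in range(1, config.n_replicates + 1):
        rng = _rng(config, 2, CONDITIONS.index(condition), rep)
        log2_obs = log2_true + rng.normal(0.0, sd_log2, size=len(mass))
        p_missing = np.clip(
            config.missing_rate_intercept
            + config.missing_rate_slope * (center - log2_obs),
            0.0,
            0.95,
        )
        missing = rng.random(len(mass)) < p_missing
        vals = np.exp2(log2_obs)
        vals[missing] = 0.0
        out[f"LFQ intensity {condition}_{rep}"] = vals
    out[PEPTIDES_COL] = truth.table.set_index("accession")["peptides"]
    out[MW_COL] = truth.mw / 1000.0  # kDa, as MaxQuant reports
    return out


def write_protein_groups(
    table: pd.DataFrame,
    path: str | Path,
    dialect: str = "tmt",
    sample: str = "map1",
    peptides: pd.Series | None = None,
    mw_kda: pd.Series | None = None,
    flags: pd.DataFrame | None = None,
) -> Path:
    """Write a minimal MaxQuant proteinGroups-style TSV.

    ``tmt`` dialect: intensity columns become
    ``Reporter intensity corrected <i> <sample>``; ``lfq``: the table's
    ``LFQ intensity ...`` columns are written as-is. Flag columns use
    the "+" convention. Round-trips through
    :func:`spatmap.io_preprocess.read_protein_groups`.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty protein table")
    if dialect not in ("tmt", "lfq"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out = pd.DataFrame(index=table.index)
    if dialect == "tmt":
        fraction_cols = [c for c in table.columns if isinstance(c, (int, np.integer))]
        for c in fraction_cols:
            out[f"Reporter intensity corrected {c} {sample}"] = table[c]
    else:
        lfq_cols = [c for c in table.columns if str(c).startswith("LFQ intensity")]
        if not lfq_cols:
            raise ValueError("lfq dialect requires 'LFQ intensity' columns")
        for c in lfq_cols:
            out[c] = table[c]
    pep = peptides if peptides is not None else table.get(PEPTIDES_COL)
    out[PEPTIDES_COL] = 1 if pep is None else pep
    mw = mw_kda if mw_kda is not None else table.get(MW_COL)
    if mw is not None:
        out[MW_COL] = mw
    for col in FLAG_COLS:
        if flags is not None and col in flags.columns:
            out[col] = np.where(flags[col].astype(bool), "+", "")
        else:
            out[col] = ""
    out.insert(0, ACCESSION_COL, out.index)
    path = Path(path)
    out.to_csv(path, sep="\t", index=False)
    return path


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    truth.table.to_csv(path, sep="\t", index=False)
    return path


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[GroundTruth, dict[str, list[pd.DataFrame]], dict[str, pd.DataFrame]]:
    """Convenience: truth plus all replicate TMT maps and lysates.

    Returns ``(truth, {condition: [replicate map, ...]},
    {condition: lysate table})``.
    """
    truth = generate_truth(config)
    maps = {
        cond: [
            simulate_replicate_map(truth, config, cond, rep)
            for rep in range(1, config.n_replicates + 1)
        ]
        for cond in CONDITIONS
    }
    lysates = {cond: simulate_lysate(truth, config, cond) for cond in CONDITIONS}
    return truth, maps, lysates
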