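# spatmap

Subcellular spatial proteomics from differential-centrifugation TMT
profiles: build organelle maps, predict protein localization with a
marker-trained SVM, quantify map reproducibility, detect proteins that
change compartment between two cell lines, and estimate absolute copy
numbers and organelle protein masses with the proteomic ruler.

The package is aimed at proteomics groups running LOPIT-DC-style
experiments: organelles are partially separated into ten sequential
centrifugation pellets, each fraction is quantified through a TMT 10-plex
reporter channel, and every protein's relative abundance profile over the
fractions fingerprints its subcellular residence. `spatmap` consumes
MaxQuant-style `proteinGroups` tables (or generates fully ground-truthed
synthetic experiments) and covers the complete downstream chain.

## The methods at its core

- **Localization prediction.** An RBF-kernel SVM with kernel
  `exp(−σ‖x−y‖²)` is trained on organelle marker profiles over an
  11-class taxonomy. Cost and σ are tuned by grid search (cost 20–60 step
  2, σ ∈ {0.01, …, 100}) over repeated stratified 80/20 splits scored by
  macro F1, with a final 5-fold cross-validation estimate. Predictions
  carry an SVM score (maximum Platt class probability); scores < 0.7 are
  labeled `unknown`.
- **Differential localization.** Each protein is described *within its
  map* by a vector of Mahalanobis distances
  `d_c = √((x−μ_c)ᵀ Σ_c⁻¹ (x−μ_c))` to every compartment, with robust
  (minimum covariance determinant) location and scatter estimated in the
  full-rank simplex coordinates. A protein is differentially localized
  when its closest compartment changes between cell lines and the
  replicate-level distances to both closest compartments differ
  significantly (two-sided t test, Benjamini–Hochberg FDR 0.05), or when
  its confident map classification changes outright.
- **Proteomic ruler.** Copy numbers are anchored to DNA mass:
  `copies_i = (I_i / Σ_h I_h) · m_DNA·N_A / MW_i` with the sum over
  histones and `m_DNA·N_A = genome_bp · ploidy · 615.8771 g/mol`.
  TMT channels are normalized to total intensity, weighted by fraction
  protein yield, summed per protein, and split into
  nucleus/organelle/cytosol shares that weight per-organelle protein
  masses.
- **Differential expression.** A moderated t test whose variance prior
  follows a peptide-count trend (empirical-Bayes shrinkage with estimated
  prior degrees of freedom), plus Fisher-exact term enrichment and
  profile-correlation colocalization ranking.

See `docs/methods.md` for models, assumptions, and numerical choices.

## Worked example

A self-contained two-condition experiment — 2002 proteins, ~720 markers
across 11 compartments, 3 replicate maps of 10 fractions per condition,
and five planted translocating proteins — run end to end:

```yaml
# example.yaml
simulation:
  n_proteins: 2002
  marker_fraction: 0.36
  noise_sd: 0.1
  translocations: [[null, ER, PM], [null, ER, PM], [null, ER, PM],
                   [null, mitochondrion, cytosol], [null, Golgi, PM]]
grid:
  costs: [40, 50, 60]
  sigmas: [0.1, 1.0, 10.0]
  inner_reps: 10
seed: 7
```

```sh
spatmap run example.yaml --out demo_run
```

prints (abridged):

```json
{
  "cv_macro_f1_A": 1.0,
  "classified_fraction_A": 1.0,
  "mean_pairwise_concordance": 1.0,
  "n_dl_qualitative": 5,
  "n_dl_quantitative": 5,
  "n_dl_total": 5,
  "n_lysate_proteins": 1897,
  "svm_cost_A": 40.0,
  "svm_sigma_A": 0.1,
  "organelle_mass_fractions_A": {
    "ER": 0.1335, "Golgi": 0.1233, "PM": 0.1561, "cytosol": 0.0011,
    "lysosome": 0.1168, "mitochondrion": 0.1090, "nucleus": 0.0199,
    "peroxisome": 0.2270, "proteasome": 0.0225, "ribosome": 0.0908
  }
}
```

Reading the numbers: the tuned classifier assigns every marker correctly
under 5-fold cross-validation (`cv_macro_f1` = 1.0 — synthetic compartments
are cleanly separable at this noise level, where real maps reach ≈ 0.95),
replicate maps agree perfectly on classification (`concordance` = 1.0),
and the two-stage differential-localization test recovers exactly the five
planted translocators (`n_dl_total` = 5) with no false calls among the
other 1997 proteins. The organelle mass table is each compartment's share
of total cellular protein mass from the yield-weighted ruler; the run
directory holds the underlying per-protein tables
(`classified_A.tsv`, `dl_proteins.tsv`, `copy_numbers_A.tsv`,
`de_proteins.tsv`, `report.json`).

The same stages are available as library functions
(`spatmap.classify_map`, `spatmap.run_dl_analysis`,
`spatmap.copies_per_cell`, `spatmap.moderated_de`, …) for use on ingested
`proteinGroups` tables; `spatmap ploidy` and `spatmap plan-highph` expose
two small planning utilities.

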