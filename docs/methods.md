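# Methods

`spatmap` implements a complete analysis chain for organelle-profiling
("spatial") proteomics of the LOPIT-DC type: cells are lysed gently,
organelles are pelleted by a 10-step differential-centrifugation series,
each fraction is quantified with a TMT 10-plex reporter channel, and every
protein's relative abundance profile over the 10 fractions serves as a
fingerprint of its subcellular residence. Two "cell lines" (conditions A
and B) are each measured as three independent replicate maps plus
unfractionated whole-cell lysates. This note documents the models,
parameter choices, and numerical decisions behind each stage.

## Preprocessing

Raw tables follow the MaxQuant `proteinGroups.txt` conventions that the
pipeline consumes: per-channel `Reporter intensity corrected` columns (TMT)
or per-sample `LFQ intensity` columns (lysates), `Razor + unique peptides`,
`Mol. weight [kDa]`, and "+"-flagged `Reverse` / `Potential contaminant` /
`Only identified by site` columns. Processing mirrors the standard Perseus
workflow:

1. drop flagged identifications;
2. keep proteins with a complete reporter series — a zero intensity counts
   as missing, because MaxQuant writes 0 for unquantified channels. A
   combined (replicate-averaged) map requires completeness over all
   replicates, i.e. 30 channels for 3 × 10-plex;
3. divide each protein's channels by their sum within each replicate block,
   giving a compositional profile (row sum 1). Averaging the replicate
   profiles and renormalizing yields the combined map. We normalize per
   10-channel replicate block (not jointly over 30 channels) so that
   replicates contribute equally regardless of their total signal;
4. lysate LFQ intensities are log2-transformed, proteins are kept when
   quantified in all replicates of at least one condition, and missing
   values are imputed per sample column from
   Normal(mean − 1.8·SD, (0.3·SD)²) — the usual left-shifted imputation for
   below-detection-limit missingness. Imputation is seeded and never
   touches observed cells.

A utility reproduces the offline high-pH fraction pooling arithmetic
(fractions 1–15 into one pool, 16–49 orthogonally paired as 16+33, 17+34,
…, 50 onward into a final pool; 70 collected fractions give 19 pools).

## Marker sets and homology transfer

Localization prediction is supervised by organelle marker proteins over an
11-class taxonomy: cytosol, ER, Golgi, lysosome, mitochondrion,
nucleus–chromatin, nucleus–nonchromatin, peroxisome, plasma membrane,
proteasome, ribosome. A marker set curated for one species is ported to
another via a homology hit table (BLAST outfmt-6-like): hits with sequence
identity ≥ 80 % are kept, the lowest e-value hit names the homolog
(ties broken by input order, logged), and markers without a surviving hit
are dropped from both species' sets so they stay the same size.

## SVM classification

An RBF-kernel SVM (kernel `exp(−sigma·‖x−y‖²)`, so `sigma` is sklearn's
`gamma`) is trained on marker profiles. Hyperparameters are chosen by grid
search — cost 20–60 in steps of 2, sigma ∈ {0.01, 0.1, 1, 10, 100} — with
100 repeated stratified 80/20 splits per grid point, scored by macro F1
(unweighted mean over classes of 2PR/(P+R); classes absent from both
truths and predictions are excluded). The same splits are reused across
grid points; ties go to the lowest cost, then lowest sigma (the smoothest
model). A stratified 5-fold cross-validation at the chosen point, with
fold confusions pooled before computing macro F1, is the reported
performance figure.

The classifier is then refit on all markers with Platt-style per-class
membership probabilities (libsvm pairwise coupling). The **SVM score** is
the maximum class probability; predictions scoring below 0.7 are labeled
`unknown`, and markers always retain their curated annotation. One
consequence of Platt calibration worth knowing: the pairwise sigmoid
targets are smoothed to (n₊+1)/(n₊+2), so with few markers per class the
achievable maximum score is capped well below 1 (≈0.65 at 16 markers per
class across 11 classes). Realistic score distributions therefore require
marker sets of roughly the curated scale (~65 per class); the synthetic
demo configurations use ~720 markers over 11 classes.

Map resolution is quantified by normalized inter-cluster distances: entry
(i, j) is the mean euclidean distance between markers of clusters i and j
divided by the mean within-cluster distance of cluster j, so the diagonal
is 1 and large off-diagonal entries mean well-separated clusters.

## Concordance

Concordance of two classified maps is the fraction of overlapping
non-marker proteins with identical labels (`unknown` is a comparable
label). It is stratified by SVM score — very high (≥0.9), high [0.7,0.9),
medium [0.5,0.7), low (<0.5) — using the *minimum* of the two maps'
scores, a conservative symmetric choice. The whole-map concordance equals
the stratum-size-weighted mean of the stratified values by construction.

## Differential localization (DL)

Because whole organelle profiles shift systematically between cell lines,
profiles cannot be compared directly across conditions. Instead each
protein's position is expressed within its own map as a vector of
Mahalanobis distances to every compartment, and the distance profiles are
compared. Two stages:

- **qualitative** — proteins confidently (non-`unknown`) classified to
  different compartments in the two combined maps;
- **quantitative** — per protein and compartment, replicate distances of
  the two conditions are compared by a two-sided two-sample t test;
  p-values are Benjamini–Hochberg adjusted over the entire protein ×
  compartment family; a protein is DL when its closest compartment (argmin
  of the combined-map distance profile) differs between conditions *and*
  the distances to both closest compartments are significant (q ≤ 0.05).

Numerical decisions:

- Compositional 10-vectors are rank-deficient (rows sum to 1), so all
  covariance work happens after an isometric Helmert projection onto the
  9-dimensional complement of the all-ones direction, plus a ridge floor
  of 1e-8 · trace/dim on the scatter.
- Compartment location/scatter use the minimum covariance determinant
  (MCD) estimator with the standard high-breakdown support
  ⌊(n+p+1)/2⌋, fitted on each condition's SVM-classified members
  (markers included; compartments need at least dim+2 members). Clusters
  of identical profiles fall back to their common profile with the ridge
  floor as scatter.
- Replicate-level distances are measured against the *combined-map*
  statistics of their condition, so replicate-to-replicate variation
  reflects profile noise only. Re-estimating MCD scatter inside every
  3-replicate map (the obvious alternative, available as
  `stats_source="replicate"`) makes the distances so unstable at
  realistic cluster sizes (~15–30 members, 9 dimensions) that the
  3-vs-3 t test loses essentially all power; with shared combined-map
  geometry the test recovers planted translocators reliably while null
  experiments produce no calls at the same FDR level.
- When an 11-class map is compared with a 10-class one, the two nuclear
  classes are merged into one `nucleus` label. The merged cluster is
  bimodal, which defeats a high-breakdown MCD (its support collapses onto
  one sub-cluster and the other half appears infinitely far away — in an
  early version this produced hundreds of spurious nucleus-involved DL
  calls). Statistics are therefore fitted per unmerged class and the
  nuclear distance columns collapsed by row-wise minimum: the distance to
  a union of clusters is the distance to its nearest component.
- Distance ties for the closest compartment break by taxonomy order with
  a warning. Zero-variance t tests give p = 1 when the means agree and
  are treated as significant (with a warning) when they differ.
- Proteins `unknown` in either combined map still enter the quantitative
  stage; only the qualitative stage requires confident labels. Cluster-
  size bias (wide clusters attract, tight clusters repel) is inherent to
  the Mahalanobis formulation and not corrected.

## Proteomic ruler

Copy numbers per cell are anchored to the cell's DNA mass, with no
spike-ins:

    copies_i = (I_i / Σ_h I_h) · m_DNA · N_A / MW_i,
    m_DNA · N_A = genome_size_bp · ploidy · 615.8771 g/mol

where the sum runs over histones and 615.8771 g/mol is the mean
double-stranded base-pair molar mass (the Perseus default). Effective
ploidy can be derived as twice the ratio of the line's genome size to a
diploid reference genome (2 × 2.399/2.72 = 1.76 for a CHO-type line
against mouse). Mass per cell is copies × MW / N_A.

For TMT fractions, each channel is normalized to its total intensity and
weighted by the measured per-fraction protein yield; summing the weighted
channels gives one ruler-ready value per protein and replicate. Each
protein's weighted intensities are also pooled into nucleus (fraction 1),
organelle (fractions 2–9) and cytosol (fraction 10) shares. Organelle
protein masses weight each protein's mass per cell by the share of the
pool matching its assigned compartment — nuclear classes by the nucleus
share, cytosol by the cytosol share, everything else (including ribosome
and proteasome, which pellet across the middle fractions) by the organelle
share — sum per compartment, and divide by the total weighted mass, so
the compartment fractions plus the `unknown` pool close to 1. This
three-pool weighting is the package's documented interpretation of the
standard nucleus/organelle/cytosol split.

Agreement between lysate-based and fraction-based estimates is summarized
by the Pearson correlation and least-squares slope of log10 copies over
the common proteins.

## Differential expression and enrichment

Two-group DE on imputed lysates uses a moderated t statistic whose prior
variance depends on peptide counts (proteins quantified from few peptides
are noisier). The residual variance s² (pooled, df = n₁+n₂−2) is related
to the razor+unique peptide count by a trend — binned medians of log s²
over log count, smoothed by a decreasing isotonic fit, interpolated, and
debiased by the mean of log χ²_df/df — and each protein's variance is
shrunk toward the trend with prior degrees of freedom d₀ estimated by
trigamma moment matching on log(s²/s²_prior). The moderated t uses the
posterior variance (d₀s²_prior + df·s²)/(d₀+df) with df+d₀ degrees of
freedom; BH adjustment at α = 0.05. Setting the prior df to 0 recovers the
ordinary t test; letting it grow recovers a pure trend-variance test
(both are exposed for verification). Spline-level parity with published
moderated-test packages is not claimed; the two-group use case is what is
implemented.

Term enrichment is a two-sided Fisher exact test per annotation term
(foreground vs background × term vs no term), BH-adjusted at α = 0.02,
with the foreground/background frequency ratio reported. Colocalization
candidates for a set of anchor proteins (e.g. immunoglobulin chains in the
ER cluster) are ranked by the mean Pearson correlation between each
cluster member's combined-map profile and the anchors' profiles; anchors
are excluded from their own ranking.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with seeded determinism throughout (one integer seed; condition,
replicate, and stage get independent substreams):

- **Compartment profiles.** Each compartment's mean profile is drawn from
  a Dirichlet distribution with one dominant fraction (concentration
  `profile_concentration`, default 50); with 11 compartments and 10
  fractions the 11th signature splits over two adjacent fractions. This
  mimics differential pelleting and makes separability tunable.
- **Noise.** Reporter noise is multiplicative log-normal per channel
  (`noise_sd`, default 0.1) applied to mass-proportional raw intensities
  (copies × MW × profile) before row renormalization — reporter-ion noise
  scales with intensity.
- **Between-line shifts.** Condition B perturbs each compartment mean by a
  multiplicative log-normal shift (`organelle_shift_sd`, default 0.2),
  applied to compartment means rather than per protein, reproducing
  systematic whole-organelle profile shifts between cell lines.
- **Translocations.** Planted proteins change compartment between
  conditions; they are never markers or histones.
- **Abundances.** Copies per cell are log-normal (median ≈ 2×10⁴, σ = 1.5
  on the natural-log scale, spanning ~10²–10⁷); molecular weights are
  log-normal around 45 kDa. A configurable histone subset (default 10)
  sits in the chromatin compartment at ~14 kDa with total histone mass set
  exactly equal to the DNA mass, so ruler copy recovery is exact in the
  zero-noise limit.
- **Lysates.** log2 LFQ tracks log2(copies × MW) with additive noise; the
  probability of a missing value rises linearly as a replicate's log2
  intensity falls below the population's 20th percentile
  (slope `missing_rate_slope`, default 0.15), written as 0 in the MaxQuant
  convention.
- **Yields.** Per-fraction protein yields are the noise-free column mass
  sums, standing in for the measured yields that weight TMT channels in
  the ruler.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: peptide-level quantification and TMT
isotope impurities; proteins with genuinely mixed or dynamic localization
(every synthetic protein belongs cleanly to one compartment, which is why
synthetic classified fractions approach 100 % while real maps classify
roughly half the proteome); correlated noise across channels;
chromatographic artifacts; and marker mis-annotation.

## Problem sizes used in the checks

The simulation studies behind the test suite and the reproduction script
use two scales, chosen as the package's own benchmark conditions: a
compact configuration (440 proteins, 50 % markers ⇒ ~20 markers per class)
for the repeated differential-localization studies — 200 null experiments
for the false-positive proportion and 20 planted-translocator experiments
for power — and a study-scale marker configuration (2002 proteins, 36 %
markers ⇒ ~65 markers per class, matching the curated set's coverage) for
classifier cross-validation, score strata, and concordance. The
reproduction script uses 60 null and 15 power runs. All thresholds
(SVM score 0.7, DL and DE FDR 0.05, enrichment FDR 0.02) are the
workflow's standard operating points, not tuned values.

## Known limitations

- The SVM score is a Platt probability from pairwise coupling; other
  implementations may report differently calibrated scores, so absolute
  score values (and the 0.7 threshold's strictness) are
  implementation-relative even though the ranking is stable.
- The quantitative DL test treats the combined-map compartment geometry
  as fixed when testing replicate distances; compartment-estimation
  uncertainty is not propagated.
- Organelle mass weighting by three coarse pools is an interpretation of
  the standard nucleus/organelle/cytosol split; finer per-organelle
  weighting schemes would need per-fraction organelle enrichment data.
- The moderated-DE variance trend uses binned medians with isotonic
  smoothing rather than regression splines; with very few distinct
  peptide-count values the trend degenerates to a constant.
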