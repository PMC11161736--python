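# Methods

This note documents the models and procedures implemented in `proteosub`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Data model

All analyses operate on features × samples matrices of log2 intensities
(`OmicsMatrix`), one per layer: whole proteome (WP, protein rows), global
phosphoproteome (PP, phosphosite rows), and phosphotyrosine sites (YP).
Phosphosite keys are `PROTEIN_S123` / `_T45` / `_Y99` (residue + 1-based
position); YP keys must carry tyrosine. Missing values are NaN; downstream
clustering requires complete matrices, so imputation is an explicit step.

## Preprocessing

* **Quantile normalization** maps each sample's non-missing values onto a
  common reference (the mean of the samples' sorted values), ranking
  against the available entries only and interpolating at fractional ranks.
  On complete matrices this is classic quantile normalization and is
  idempotent to numerical precision. Ties share the averaged reference
  value.
* **Imputation.** Two families, chosen per layer: `downshift` draws each
  missing cell from Normal(μ_j − 1.8·σ_j, (0.3·σ_j)²) of its sample, the
  usual model for left-censored MS missingness and the default for YP;
  `knn` (default k = 5) averages, per missing cell, the k most correlated
  features observed in that sample — the default for WP/PP. These emulate
  the families of tools commonly used per layer, not any tool's internals.
* **Peptide→site collapse** sums linear-scale abundances of all peptides
  covering a site (a doubly phosphorylated peptide contributes its full
  abundance to both sites) and re-logs. Site totals therefore exceed the
  peptide total exactly when multi-site peptides exist.
* **Protein normalization** of phosphosites is the log-scale ratio
  log2(site) − log2(protein); sites whose host protein is unquantified are
  dropped with a count, and a missing protein value makes the ratio missing.
* **MAD filtering** retains the top ⌈fraction·n⌉ features by the *mean*
  absolute deviation from the feature mean — implemented literally as
  worded in the originating protocol, although the acronym usually denotes
  the median-based quantity; `center="median"` switches to the median form.
  Ties break by feature key, making retained sets nested across fractions.
* **Batch handling** is an optional per-batch median centering only; no
  mixed-model batch correction is attempted.

## Per-layer consensus subtyping

The matrix (min-shifted to be non-negative, because log2 data may be
negative and NMF requires V ≥ 0) is factorized V ≈ WH at rank k by
Brunet-style multiplicative updates under the KL divergence (Frobenius
available). The update rules guarantee a non-increasing objective; the run
stops when the relative change falls below `tol` (default 1e-5, evaluated
every 10 iterations) or at `max_iter` (300).

One hundred restarts with seeds derived deterministically from a root seed
give per-run labels (argmax of H per sample); the consensus matrix is the
co-assignment frequency. Final labels are *not* taken from any single run
but from average-linkage hierarchical clustering of 1 − consensus cut at k.
Stability is the cophenetic correlation of that tree against the consensus
dissimilarities (NaN when the off-diagonal is constant, e.g. a single
effective cluster); per-sample silhouettes on 1 − consensus QC the cut
(singleton clusters score 0 by convention).

Model selection maximizes the cophenetic coefficient over the grid
(MAD fraction ∈ {0.1, 0.2, 0.3, 0.5, 1.0}) × (k ∈ 2..6), ties broken by
smaller k then smaller fraction; the full grid is always reported.
Dispersion-based criteria are not used — stability is scored by the
cophenetic coefficient alone.

**Metagenes.** The basis matrix of the best-objective run (columns aligned
to the consensus clusters by majority vote of that run's assignments)
scores each feature's specificity as its weight share across components;
features whose specificity exceeds 1/k + margin (margin 0.1) join their
argmax cluster, capped at 15 per cluster by weight. Cluster lists are
disjoint by construction.

## Integrative subtyping

Per-layer labels are one-hot encoded into a (layer, cluster) × samples 1-0
table; within each layer block every column sums to 1. The samples are
consensus-clustered by 500 subsampling iterations: each draws ⌈0.8·m⌉
samples without replacement, clusters them hierarchically (average linkage,
Euclidean distance on the binary columns; 1 − Jaccard available), and cuts
at k; consensus is co-clustered / co-sampled counts. Pairs never co-sampled
are missing — excluded from the cophenetic computation and treated as
maximally distant when cutting the final tree (at 500 iterations this is
effectively never exercised). The target k defaults to 2; a CDF-area /
Δ-area report over k = 2..6 is available (`consensus_k_sweep`) as the usual
model-selection summary for subsampled consensus clustering. Replicate
columns are kept separate and their label agreement is reported post hoc.

The integrative result is invariant to relabeling cluster ids within any
input layer, since only co-membership enters the binary encoding.

## Kinase activity and target nomination

Per-site two-group statistics are Welch t-tests (Wilcoxon optional) on
log2 data; log2FC = mean(A) − mean(B). Three kinase-level estimators
consume them, each requiring ≥ 3 detected substrates (below which substrate
means are not meaningful):

* **mean fold difference** — mean substrate log2FC, one-sample t vs 0;
* **KSEA** — the standard z = (μ_substrates − μ_background)·√m /
  σ_background with σ the ddof-1 SD of all quantified sites' fold changes
  and a two-sided normal p (the published z-form; the original analyses
  delegated to a package without printing the formula);
* **MLR** — ridge-stabilized least squares of the site fold-change vector
  on the site × kinase substrate indicator matrix (λ = 0.01 for
  conditioning; λ→0 on disjoint designs reduces to per-kinase substrate
  means, which the tests verify); p from coefficient standard errors.

Applying all three to the raw and the protein-normalized PP matrix yields
six activity tables. A table votes a kinase into subgroup S1 when p < 0.05
and log2FC > 1, into S2 when p < 0.05 and log2FC < −1; raw p gates the vote
(BH-adjusted values are reported alongside, not used for gating). The 0–6
vote count measures differential activity. Group-level fold changes are
compared directly (matching the mean-fold-difference wording); a
per-sample-activity alternative was considered and not implemented.

**INKA-style ranking.** Per sample, the kinase-centric arm C sums the
linear-scale (2^log2, missing → 0: absent evidence contributes no weight)
intensities of the kinase's own phosphosites and the substrate arm S those
of its substrates; the score √(C·S) is zero if either arm is silent. This
two-arm geometric mean is a declared surrogate for the full
server-computed score, whose exact composition (activation-loop weighting,
predicted-substrate arm) is not public in the source protocol. Top-10
lists break ties by kinase id.

**Outlier kinases.** Every (feature, sample) entry is standardized across
samples within its feature (zero-spread rows excluded); entries above the
layer's 95th z-percentile are flagged and kinase-annotated flags reported.
The entry-level operationalization captures sample-selective extremes (one
cell line overexpressing one kinase), which a feature-level maximum rule
can miss; the rule's wording is ambiguous and the choice is documented
here. Flags are unioned and deduplicated by kinase across layers.

**Subset-specific hits** use Welch p and log2FC with two presets: drugs
p < 0.05 and |log2FC| > 1; genetic dependencies p < 0.1 and |log2FC| > 2.
Constant items have undefined p and are labeled equal.

## Consistency classification

A single-hidden-layer perceptron (width 16, lbfgs, features z-scored per
cohort) is trained on metagene profiles with a stratified 9:1 split. New
samples are assigned by repeating train+predict `n_reps` = 500 times —
fresh split *and* fresh initialization per repetition (a reinit-only mode
exists, since the protocol wording is ambiguous about what is redrawn) —
and keeping a sample's winning label only if its count strictly exceeds
n_reps/3: at 500 repetitions, 167 keeps, 166 does not. The wrapper is
model-agnostic; the bespoke content is the consistency rule, not the
architecture, whose depth/epochs/regularization were never published.

## Shared statistics

Benjamini–Hochberg step-up adjustment (statsmodels backend) with domain
validation. Note BH is *not* idempotent on its own output (re-adjusting
already-adjusted values inflates them further); the tests assert pointwise
dominance and order preservation instead. Contingency association uses
chi-square without continuity correction (Fisher exact optional for 2×2)
and reports row percentages to 2 decimals. The Grubbs test is two-sided
and iterated (G = max|x−mean|/sd against the t-based critical value),
assumes approximate normality, returns no outliers at zero spread, and is
invariant to affine transforms.

## Synthetic panel generator

The generator emulates a 14-line × 2-replicate panel with defaults chosen
to match the separable regime the recovery guarantees address: k_true = 3
subtypes (round-robin over lines), 600/800/300 features per layer,
separation 4 log2 units on 25% of features, residual SD 0.5, 20 kinases ×
10 substrates per matrix with activity shifts of 3 log2 units for a
quarter of kinases, and 2 planted outlier (kinase, line) pairs at +8 log2.
Intensities are simulated directly on the log2 scale (Gaussian blocks,
baseline N(20, 2)) because all analyses operate post-log2. WP and YP
express the full k_true-way split; PP expresses the 2-way super-group
obtained by merging the first ⌈k_true/2⌉ subtypes, giving the integrative
step a planted hierarchy. Replicates share their line's mean vector
exactly and differ by noise with SD = noise_sd/2, which is what makes the
replicate-correlation QC meaningful. Each synthetic kinase is also a
protein with two of its own phosphosites in PP and YP (the kinase-centric
arm needs them). Missingness is Bernoulli with a logistic dependence on
standardized intensity, normalized so the expected masked fraction equals
the nominal rate at any bias; positive bias mimics left-censoring.

What the generator does **not** emulate: peptide/spectrum-level structure,
realistic intensity distributions or correlation structure between sites
of one protein, overlapping substrate sets between kinases, annotation
errors in the kinase–substrate map, and non-block subtype architectures.
Passing recovery tests therefore demonstrates correctness of the
machinery under its stated assumptions, not expected performance on real
panels, where separations are weaker and annotations noisy.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full default panel
(28 samples, 620/840/340 features) with 100 NMF restarts per grid cell and
500 integrative iterations; calibration loops use 10–20 generator seeds
and 100-toy oracle batches. Oracle agreement is asserted at 1e-9;
factorization monotonicity at relative 1e-8. Degenerate inputs are handled
explicitly: constant consensus off-diagonals yield NaN cophenetic, single
final clusters yield zero silhouettes, zero-spread features are excluded
from outlier z-scores, and zero background SD makes KSEA undefined
(flagged) rather than infinite.

## Known limitations

* The per-layer imputation defaults emulate tool families, not the exact
  deposited pipelines; absolute imputed values differ from any specific
  software.
* The MLR p-values are conditional on the ridge stabilizer and the
  homoscedastic residual assumption; with heavily shared substrate sets
  the coefficients are shrunk and their errors approximate.
* The consistency classifier's repeated splits reuse the labeled panel;
  with very small panels the 9:1 split leaves 2–3 validation samples and
  the reported validation accuracy is coarse.
* Survival analysis, enrichment tooling, batch mixed models, and external
  cohort harmonization are intentionally out of scope.
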