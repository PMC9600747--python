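# Methods

This note documents the models, conventions and parameter choices behind
`ercdc`, in the order the pipeline runs them.

## Synthetic study conditions (`ercdc.sim`)

The generator emulates the structure of the data the pipeline was designed
for: sorted myeloid cell populations profiled on log2-scale expression
arrays across several study batches, and a bulk tumor cohort with linked
survival.

**Reference profiles.** `n_genes` per-gene baselines are drawn
N(`baseline_mean` = 7, `baseline_sd` = 1.5) on the log2 scale (typical
microarray intensities). Each of `n_celltypes` = 4 cell types (the target
"ercDC" plus three other myeloid types) receives a planted signature of
`n_signature_genes_per_type` = 30 genes shifted by ±`signature_effect` = 2.0
log2 units (4-fold), with a ~2:1 up:down split. Bidirectionality matters
beyond realism: if every marker shifted the same way by the same amount, a
tumor's marker expression would differ from the reference only by a common
offset, the regression slope that defines the ercDC score would be
collinear with its intercept, and the score would carry no information
about cell content. Replicates (12 per type) add N(0, `replicate_sd` = 0.5)
noise; three batches assigned round-robin add a per-batch per-gene location
shift N(0, 0.3) and a per-batch multiplicative factor exp(N(0, 0.1)) on the
noise — the location/scale structure the empirical-Bayes merge is built to
remove.

**Bulk tumors.** Mixing happens in linear space (cell abundances add
linearly, not their logs): tumor *j* is
`log2( Σ_k w_jk · 2^{μ_k} ) + ε`, with weights `w_j` ~ Dirichlet(1,…,1)
and ε ~ N(0, `bulk_noise_sd` = 0.25). Tumor grade is the tercile of the
true target-cell fraction mapped to {1, 2, 3} — grade is deliberately a
deterministic function of the fraction, so the score–grade trend the
pipeline should detect exists by construction.

**Survival.** Event times are Exponential with rate
`baseline_hazard · exp(hazard_log_hr · z)`, `baseline_hazard` = 0.1 per
time unit and `hazard_log_hr` = log 2 per SD of the target fraction;
censoring is administrative, Uniform(0, 20), giving ≈45–55% censoring at
the defaults. All times are strictly positive. `z` is by default the
standardized continuous fraction; with `dichotomize_at_median=True` it is
the 0/1 above-median indicator, making `exp(hazard_log_hr)` exactly the
hazard ratio between the high and low halves — the design used for
end-to-end recovery checks of a "true HR 2.0 between groups".

One integer seed feeds a hierarchical `SeedSequence`; reference, bulk and
survival generation each use their own child stream, so any stage can be
regenerated independently and all outputs are bit-reproducible.

**What the generator does not emulate:** probe-level structure beyond what
the collapse step needs, count noise (RNA-seq), correlated gene modules
outside the planted signatures, non-proportional hazards, informative
censoring, or covariate-driven grade. Passing tests therefore demonstrate
correctness of the chain under a clean, known-truth regime, not performance
on real cohorts.

## Preprocessing and batch merging

- Probe collapse removes zero-variance probes first, then keeps, per gene,
  the mapped probe with maximal sample variance. Variance ties break by
  first occurrence in input order (deterministic).
- Informative genes are the top `ceil(0.5 · G′)` by variance among the G′
  genes with positive variance, computed within a study group; merging
  happens afterwards on the intersection of gene universes.
- All variances and SDs use the n−1 denominator; z-scoring is idempotent
  and errors on zero-variance rows, naming the gene.
- `combat_merge` implements the parametric empirical-Bayes location/scale
  model: per-gene standardization against the pooled (intercept-only)
  model, method-of-moments hyperpriors per batch (normal prior on the
  location effect, inverse-gamma on the scale effect), and iterative
  conditional updates of the shrunken effects until the maximum absolute
  change falls below 1e-4 (cap 500 iterations). Degenerate hyperpriors
  (zero prior variance: all genes share one batch effect, or all scale
  estimates equal) short-circuit to the exact posterior rather than
  dividing by zero. A single batch returns the input unchanged. The
  covariate design is intercept-only: studies are merged whole and samples
  of interest selected afterwards.

## Nearest shrunken centroids (`ercdc.nsc`)

Standard soft-thresholded centroid shrinkage: `s_i` is the pooled
within-class SD (denominator n − K), the fudge `s0` is the median of the
`s_i` (configurable), `m_k = √(1/n_k − 1/n)`, and classification minimizes
`Σ_i (x_i − x̄′_ik)² / (s_i + s0)² − 2 log π_k` with priors defaulting to
class proportions and ties broken by class order. Cross-validation is
stratified k-fold (default 10, reduced to the smallest class size when
needed) with seeded fold assignment; the default threshold grid is 30
evenly spaced values from 0 to max |d_ik|.

**Threshold selection.** The published panel used the rule "false-positive
rate below 20% with a preferably small number of genes". The
false-positive rate is one-vs-rest for the target class by default
(non-target samples predicted as target), with the overall CV error rate
available via `mode="overall"`. "Preferably small" is operationalized as a
*stability-preferring parsimony* rule: among feasible thresholds, take the
active-gene count whose plateau (run of consecutive grid points with that
count) is widest, breaking plateau-length ties toward the smaller count
and count ties toward the largest threshold. The rationale: on
well-separated data the CV false-positive rate stays below the bound down
to panels of one or two genes, so a bare minimum-count rule returns a
panel that hinges on a single shrinkage value and discards most of the
class's signature; the widest-plateau count is the smallest panel that is
robust to the choice of Δ. When no count repeats, the rule reduces to the
plain minimum. The classifier stores the published shrinkage level 1.88 as
a provenance constant only — the grid and folds behind it are data-set
specific and not recoverable.

## Differential expression and enrichment (`ercdc.de`)

The moderated t-test shrinks per-gene residual variances toward an
inverse-chi-square prior. Hyperparameters (d0, s0²) come from
method-of-moments on log s²: the mean identifies s0², and the spread in
excess of trigamma(df/2) identifies d0 through a Newton inversion of the
trigamma function. A non-positive excess means the variances are
under-dispersed relative to pure chi-square noise and d0 = ∞ (complete
shrinkage; the t statistic then uses the common prior variance with
effectively normal reference). A single gene falls back to the ordinary
t-test with a warning. Significance defaults to BH-adjusted p < 0.05;
log-fold-changes are target-minus-control, "up" = higher in the target
group.

Hypergeometric enrichment is the flat two-tailed test
(P(X ≥ k) for enrichment, P(X ≤ k) for depletion) against an explicit
background (the informative genes), reporting sets with min p < 0.001.

GSEA-style enrichment ranks genes by signal-to-noise
`(μ₁ − μ₂)/(σ₁ + σ₂)`, computes the weighted (exponent 1)
Kolmogorov–Smirnov running sum, and takes the signed maximum deviation as
ES. The null is seeded phenotype permutation; NES divides ES by the mean
|null ES| of the same sign, and the p-value is the fraction of same-sign
null scores at least as extreme (so the smallest attainable p is 0 at
finite permutation counts; a set covering the whole universe scores
ES = 0 by convention since no complement exists to decrement against).

Overlap summaries report counts and percentages (rounded half-up to one
decimal) of markers among significant DEGs and of auxiliary gene lists
(e.g. M1-/M2-associated panels) among markers and DEGs.

## Polarization modules (`ercdc.modules`)

Profiles are cell-type medians, so the eigengene axis is cell types. A
module eigengene is the first right singular vector of the row-standardized
member submatrix (unit norm; variance explained = λ₁/Σλ), sign-fixed so
its correlation with the module's mean standardized expression is
nonnegative. Cell-type association uses Pearson correlation with the
one-hot indicator of each cell type over the profile axis — the standard
module-trait convention; because centered one-hot indicators span a
simplex, each module's correlations across cell types sum to ~0. Members
missing from the matrix are dropped; modules with below 50% coverage are
flagged. Row/column ordering for display uses complete-linkage Euclidean
clustering.

## Signature scoring (`ercdc.scoring`)

The reference signature collapses marker-gene expression over the sorted
ercDC arrays by the median. A sample's score is the OLS slope of its
expression on the reference values over the signature genes, with
intercept; both up- and down-regulated markers stay in the signature. The
regression direction (reference as predictor, sample as response) is the
only orientation that yields one slope per sample. FPKM-like cohorts are
log2(x+1)-transformed before scoring; microarray inputs, already on a log
scale, are not re-transformed. Genes absent from a cohort are dropped
(recorded in `n_genes_used`, warning below 80% coverage, error below 3
genes). The cytotoxic-infiltrate score is the per-sample mean of CD8A and
NKG7 log expression, cohort z-standardized (n−1); the contrast table
reports `z_cyto − z_score` per sample plus the cohort Pearson correlation.

## Survival analysis (`ercdc.survival`)

Kaplan–Meier estimation and the two-group log-rank test delegate to
lifelines (events precede censorings at tied times; Greenwood variance
from the event table). The univariate Cox model is fit by damped
Newton–Raphson on the Breslow partial likelihood (Breslow rather than
Efron ties: simpler, adequate at the tie rates simulated here), with Wald
confidence intervals; non-convergence within 50 iterations raises with the
gradient norm, and |β| > 20 flags a monotone likelihood (complete
separation).

The cutpoint search replaces a depth-1 conditional inference tree:
candidates are midpoints between consecutive sorted unique score values
leaving at least `min_group` = 10 subjects per side; the statistic is the
log-rank chi-square per candidate (vectorized over candidates); the
selection-adjusted p-value of the maximal statistic comes from seeded
score permutations of the same maximum (add-one estimator, so the
reported p is never exactly 0), and a split is returned only when it falls
below α = 0.1 — otherwise "no split", mirroring the stopping behavior of
conditional inference trees. The score–grade association uses the
linear-by-linear statistic T = Σ score·grade with grade scores 1/2/3
(equally spaced, as "linear trend" implies), standardized by the
permutation mean/SD, two-sided permutation p.

## Orchestration, problem sizes, determinism

The two workflows (`run_marker_discovery`, `run_cohort_scoring`) take a
flat YAML-able config in which every analysis constant is a named key
defaulting to the published value (informative quantile 0.5, FPR bound
0.20, DEG α 0.05, enrichment p 0.001, split α 0.1, minimum group 10,
grade scores 1/2/3); a seed is mandatory, with no silent default. Each run
writes a manifest with the config hash, seed, package version, per-stage
row counts and artifact checksums; identical config + seed reproduce
byte-identical TSVs (floats serialized at 10 significant digits).

Default problem sizes — 2000 genes, 4 × 12 reference samples, 400 tumors,
10 folds × 30 grid points, 100–600 Monte-Carlo replicates and 199–1999
permutations in the calibration and survival checks — keep a full test run
and the acceptance script in the tens of seconds while leaving the
recovery margins wide (marker recovery 100%, score–truth correlation
≈ 0.985, HR recovery well inside its band).

## Known limitations

- The moderated-t implementation covers the two-group design only; general
  design matrices are out of scope.
- ComBat is the parametric variant; no nonparametric prior.
- The cutpoint search is a single split on a single covariate, not a full
  recursive partitioning, and its permutation null conditions on the
  observed censoring pattern.
- GSEA offers phenotype permutation only down to groups of 3; gene-set
  sizes are not rescaled (no multi-set FDR).
- Scores from real cohorts depend on marker coverage after platform
  mapping; the synthetic tests do not exercise identifier mismatches.
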