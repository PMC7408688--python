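# Methods

This note documents the statistical procedures the package implements, the
generative models behind its synthetic data, the numerical conventions, and
the design choices made where the workflow it reproduces was underspecified.

## Growth quantification and RG/MSG classification

Each mouse contributes a radiance series sampled nominally every 7 days
from day 0. The analysis works on growth ratios
`R(t) = radiance(t) / radiance(0)`, so the (unknown, instrument-dependent)
absolute scale cancels: ratios are invariant to rescaling a series by any
positive constant, and `R(0) = 1` exactly.

A cell line's in vivo growth is `log10` of the *arithmetic* mean of its
mice's day-28 ratios. The arithmetic-mean-then-log order matches the
"mean normalized radiance ratio" readout convention; a geometric-mean
option (`aggregate="geometric"`) is provided for users who prefer averaging
on the log scale. Mice are weighted equally regardless of per-line group
size (3 or 4 in the emulated design); no weighting rule is defensible from
the available information, so none is applied.

The RG/MSG split has no published numeric cutoff, so the default classifier
is parameter-free: sort the per-line summaries, cut at the largest adjacent
gap, label the upper block RG, and report the gap midpoint as
`threshold_used`. This is invariant to adding a constant to all summaries
and is well-defined whenever the summaries are not all equal (otherwise a
degenerate-input error). A `fixed_threshold` method is available when the
cutoff is known. Day 28 is the default readout day but is a parameter
(experiments may run to 56-84 days).

Correlation of in vivo growth with in vitro growth (`log2 N(4)/N0`,
replicates averaged after the log) or marker levels (`log10` raw integrated
density) defaults to Pearson on these log-scale quantities, with Spearman
available; a p-value is reported but never thresholded, since the
correlation is descriptive.

## Signature extraction

z-scores standardize each gene across all nine samples jointly (one
conversion; the RG and MSG z-scores are then group means of the same
per-sample values). The sample (n-1) standard deviation is used,
configurable to population via `ddof`. Rows with zero variance get `z = 0`
by convention, and their count is logged rather than raised: constant rows
are legitimate (e.g. absent transcripts) and must not block the run.

The three filter statistics are computed on the log2 scale, where
fold-change ratios are differences: `rg_logfc` is oriented as MDA-MB-453
minus UACC-893 (orientation is irrelevant to the symmetric consistency
bound but fixed for reporting); `rg_msg_logfc` is RG mean minus MSG mean.
All threshold comparisons are strict (`> 1.0`, `< -1.0`), so a gene
sitting exactly at a cut is excluded; with continuous data this is a
measure-zero event, and the convention follows the criteria exactly as
printed.

"RG z-score" is read as the mean of the two RG samples' z-scores — the
minimal reading of a single scalar per gene. A stricter mode
(`rg_z_mode="both"`), requiring each RG sample's z to clear the cut
individually, is provided; it selects a subset of the mean mode's genes.

Useful structural properties (all tested): negating the matrix swaps the
up and down sets exactly; raising `z_cut` or `rg_msg_cut` can only shrink
the sets while raising `rg_consistency_cut` can only grow them; the
signature sets are subsets of the corresponding Venn sets at equal cuts.

Heatmap row ordering uses agglomerative clustering of the signature's
z-score rows — complete linkage on Euclidean distances by default (the
common heatmap-package default), average linkage and correlation distance
as options — via SciPy's implementation, whose tie-breaking by input order
makes the leaf order deterministic. Columns are never clustered; samples
stay in fixed group order (RG first).

Probe-level matrices can be collapsed to gene level before filtering,
default `max_mean` (keep the probe with the highest mean intensity), with
per-gene averaging as an option. Whether published signature counts are
probe- or gene-level is ambiguous in the emulated workflow; the pipeline
supports both and records the level on the matrix.

## Survival screening

The Kaplan-Meier estimator, Greenwood variance and two-sample log-rank
test are implemented directly in the package (their field-level contracts
— risk-set conventions, the hypergeometric variance, the log(-log) band —
are part of this package's interface, and the calibration checks evaluate
the log-rank statistic thousands of times, which wants a vectorized
implementation); `lifelines` serves as an independent cross-check oracle
in the test suite, never as the computation.

Conventions: subjects censored exactly at an event time remain in the risk
set at that time; confidence bands use the log(-log) transform
`S^(exp(±z·se))` with the Greenwood standard error, clipped to [0, 1] and
collapsed to the point estimate where `S` is 0 or 1; the log-rank p-value
comes from chi-square with 1 df. "Mean survival" is the restricted mean
survival time (RMST), the area under the KM step function up to a horizon
defaulting to the largest observed time in the pooled cohort — an
unrestricted mean is undefined under right censoring.

Dichotomization is a first-class parameter because published high/low
group sizes vary gene to gene, which no single fixed rule reproduces.
Strategies: `median`, `zscore_cut` (high iff standardized expression
exceeds a z cutoff) and `optimal_logrank`, which scans cuts at expression
quantiles 0.10-0.90 in steps of 0.05 and keeps the cut minimizing the
log-rank p. The scan optimizes the test statistic, so its p-value is
selection-biased; the result carries the full scan table and a
`selection_biased` flag rather than any post-hoc correction.

The screen emits one row per gene (genes that fail — constant expression,
degenerate splits — are logged and skipped, not fatal). A gene is flagged
`adverse-high` when its high-expression group has the smaller RMST at
p < alpha, `adverse-low` for the reverse. Raw p-values drive the flag,
mirroring prognostic tables reported without multiplicity control;
Benjamini-Hochberg q-values are emitted alongside so users can apply the
correction.

## Synthetic data: what it emulates and what it does not

**Expression.** Gene baselines are uniform on [4, 12] log2 units. The
seven MSG lines draw independent `N(0, noise_sd)` deviations per gene —
`noise_sd` (default 0.3) models between-cell-line biological
heterogeneity. The two RG lines are generated as near-replicates of a
common RG expression state: baseline plus the planted shift
(±`effect_delta`, default 2.5, for the 40 + 40 planted genes), each line
adding only `N(0, rg_inconsistency_sd)` (default 0.1). Generating the RG
pair as a coherent program is a deliberate design choice: consistency of
the rapid-growth pair is the biological premise of the within-RG logFC
filter, and planting it makes recovery of the planted sets a sharp oracle
— at these defaults the filters recover the planted sets exactly
(verified across hundreds of seeds), so any deviation signals an
implementation defect rather than sampling noise. The cost is realism:
with independent RG noise of the same magnitude as the MSG lines', the
consistency filter would itself reject a few percent of genuinely shifted
genes and occasionally admit null genes, so perfect recovery is *not* a
property to expect on real microarray data, where probe effects, batch
structure and correlated genes (all absent here) further blur the
boundary.

**Growth.** `radiance(t) = radiance0 · 2^(t/doubling_time) · exp(eps)`
with `eps ~ N(0, sigma)`, `sigma` set from the multiplicative noise CV
(default 0.2), applied at every day including day 0. Defaults mirror the
emulated design: nine lines, RG doubling 3.5 days vs MSG 14 days, 3 mice
per line (4 for HCC-1419 and HCC-2218), days 0-28. The model omits
growth-rate saturation, mouse attrition and detection floors.

**Survival.** Expression is iid standard normal per gene; event times are
exponential with rate `baseline_hazard · exp(Σ beta_g x_g)` (proportional
hazards by construction); censoring is the minimum of an independent
exponential and an administrative horizon. Defaults (400 patients,
baseline 0.01/month, censoring 0.004/month, horizon 300 months) give
roughly 25-30% censoring. Real cohorts violate proportional hazards,
have correlated gene expression and informative censoring; none of that
is modeled.

Each generator consumes a single `numpy` seed and no global state;
identical specs give identical outputs.

## Pipeline determinism

The results bundle is a pure function of (inputs, config): JSON artifacts
are written with sorted keys and floats rounded to 10 significant digits
purely to stabilize formatting, and wall-clock timestamps appear only in
the run log, never in the bundle, so repeated runs are byte-identical.
On stage failure the partial outputs are removed and the error is tagged
with the stage name.

## Problem sizes in the test suite and acceptance script

The statistical checks run at sizes chosen to give tight Monte-Carlo
error while keeping the default suite fast: 20 matrices for oracle
equivalence and planted recovery, 100 instances for the symmetry and
monotonicity properties, 2000 null pairs (n = 100/arm) for log-rank
calibration, 100 seeds (n = 400) for screen power, 1000 cohorts (n = 200)
for Greenwood coverage, and 50 seeds for growth classification. At these
sizes the binomial standard error of the calibration rate is ~0.005 and
of the coverage ~0.007, small relative to their acceptance bands.

## Known limitations

* The signature filters perform no significance testing — no p-values and
  no multiple-testing correction at the extraction stage, by design of the
  emulated workflow; the cuts are descriptive.
* `optimal_logrank` reports the minimized p-value uncorrected (flagged);
  a permutation-calibrated version is out of scope.
* The max-gap classifier assumes the growth summaries are genuinely
  bimodal; with a continuum of growth rates the largest gap is arbitrary.
* Survival handles a single endpoint; competing risks and covariate
  adjustment (e.g. Cox regression) are out of scope.
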