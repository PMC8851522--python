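# Methods

This note records the models, conventions and numerical choices behind
`ifncyto`, the reasoning where the design was genuinely open, and what the
synthetic validation does and does not demonstrate.

## IFN signature scoring

Ct is a log2-scale quantity, so "normalizing to the geomean of GAPDH,
ACTB and B2M" is implemented as subtraction of the arithmetic mean of the
three housekeeping Ct values: the geometric mean of expressions 2^(−Ct)
equals 2 to the minus arithmetic mean of Ct. A literal geometric mean of
the Ct numbers is available (`hk_mean="geometric"`); the two differ by
fractions of a cycle and preserve sample ranking. Relative expression is
2^(−ΔCt), the standard relative-quantification transform. Masked
("Undetermined") signature reactions become expression 0 — below
detection — which is conservative for an abundance-like score; a masked
housekeeping reaction invalidates the sample instead, because the
reference is undefined.

The cumulative score divides each transcript by its maximum across the
cohort and sums. It is therefore invariant to per-gene rescaling and to
sample order, bounded by the panel size, and — a property worth knowing —
anchored to the single highest-expressing sample per gene, so one extreme
patient compresses everyone else's contribution for that gene. Quartile
stratification uses linear-interpolation quantiles with inclusive bounds
(score ≥ Q3 → IFN-H, ≤ Q1 → IFN-L), which yields exactly 21 + 21 strata
on 81 distinct scores; if all SLE scores tie, both bounds degenerate to
the common value and every patient is assigned "mid" rather than to both
extremes.

## Cytometry processing and guided gating

Events are consumed as pre-cleaned per-cell tables (CSV; one row per
cell). Upstream instrument normalization and FlowJo-style pre-gating are
out of scope. The processing order is fixed: arcsinh with cofactor 5 on
lineage and functional channels, zero-thresholding (transformed values
strictly below 0.125 → 0), optional seeded downsampling without
replacement, then gating.

Per-marker +/− cuts come from a deterministic one-dimensional two-means:
centers start at the 10th/90th percentiles and iterate Lloyd updates; the
cut is the midpoint of the converged cluster means. Determinism and
auditability were the deciding criteria — the guided-gating literature
this mirrors does not pin down its threshold rule, and a k-means with
random restarts would make gate membership run-dependent. Degeneracy is
flagged when the between-center gap is under 2× the sum of within-cluster
SDs: on that measure a unimodal distribution tops out near 1.7 (uniform
≈ 1.73, Gaussian ≈ 1.33) while genuinely bimodal +/− markers exceed 2
comfortably, so the floor separates "no structure" from "two states"
without a density estimate. Degenerate markers fall back to a configured
cut (default: the zero threshold). Manual per-marker cuts can be supplied
instead.

Gate membership is the conjunction of constraints and the parent's
membership; "+" is strictly greater than the cut, so ties go to "−" and
membership is deterministic. Summaries are per-sample medians (robust to
the heavy tails left after thresholding; the mean is available) and
abundances relative to the parent gate. Populations with fewer than 25
cells in a sample are flagged and excluded from modelling — the median of
a handful of cells is too unstable to regress on.

## Effect-size regression

The modelling unit is the per-sample population summary, never the single
cell: cells within a sample are not independent, and per-cell fits would
pseudo-replicate by a factor of thousands. Each (population, marker,
stimulation) cell is fit by OLS, `response ~ Group + Treatment + Batch`,
with single-level covariates dropped automatically (per-stimulation
analyses therefore reduce to `response ~ Group`, avoiding aliasing). The
effect size is the Group coefficient divided by the SD of the response.

Two SD conventions are supported. `pooled` (default) is the sample SD over
all rows entering the fit — the simplest reading of "standard deviation of
Marker". `within` pools within-group SDs (Cohen's d). The distinction
matters for validation: a true standardized shift δ inflates the pooled SD
itself, so with balanced groups the pooled-SD effect converges to
δ/√(1 + δ²/4) — at δ = 2 the recovered value plateaus at √2 regardless of
sample size. Recovery experiments against the generator's truth therefore
use `within`, which is the convention the generator's δ is defined in;
the pooled default is kept for descriptive use on real data, where no
truth is being recovered. BH adjustment is applied within each
stimulation's family of tests (matching how per-stimulation dotmaps are
read), with a global family available by config. Dotmap/forest tables
filter at q < 0.05 strictly; negative effects are tagged "blue", positive
"red".

## SAM with rank statistics

The observed statistic per antigen is the standardized, tie-corrected
Wilcoxon rank-sum (the coherent unpaired analogue; the signed-rank variant
with sign-flip permutations serves paired designs). The null is built from
group-label permutations: all C(n, n₂) distinct assignments when that
count is within the configured bound, otherwise `n_perm` *distinct*
assignments sampled uniformly without replacement. Sampling without
replacement makes the Monte-Carlo estimator converge to the exhaustive
computation and coincide with it exactly once the space is covered;
with-replacement sampling was rejected because noise in the expected order
statistics can flip the ordering of near-tied observed-minus-expected
differences (the rank statistic is discrete), discretely changing the
delta-sweep call sets.

q-values follow the delta-sweep construction: sort observed statistics
against expected order statistics; for each achievable delta, the upper
cutoff is the smallest order statistic whose excess over its expectation
reaches delta (the lower cutoff symmetric); the FDR estimate is the mean
number of permutation statistics beyond the cutoffs divided by the number
of observed calls (π₀ = 1, conservative; the mean — the original
construction — rather than the median, which is unstable at distribution
boundaries); the per-antigen q is the smallest FDR at which it is called.
No fudge factor is added to the denominator (s0 = 0): rank statistics are
already standardized.

Known behaviour: on small panels the top-ranked feature's q is liberal —
the sweep selects the cutoff at the observed extreme, so on a 10-antigen
6v6 null about one cohort in ten shows a call at q < 0.05. At the
stringency actually used for calls (q < 0.001, the "FDR 0" setting), a
6v6 exhaustive design cannot call anything under the null: the observed
assignment is itself one of the 924 permutations, bounding every FDR
estimate below by 1/924.

Preprocessing fixes undetected features at MFI 1 and excludes antigens
whose maximum IgG MFI is under 1,000 (strict) as non-reactive. Missing
values are replaced by the mean of the k nearest samples (Euclidean
distance over mutually observed antigens; neighbors must have the target
antigen observed) — deliberately the classic array-heatmap replacement
rule, not a rescaled nan-distance. Heatmap ordering uses average-linkage
Euclidean clustering; with distinct distances the tree is
input-order-invariant, and ties follow the linkage implementation's
deterministic ordering. The ELISA detection limit is 2× the sample SD of
the blanks, with background subtraction of the BSA average.

## Synthetic cohorts: what they emulate

*qPCR*: one latent IFN activity per sample enters signature-gene Ct
multiplicatively (expression = baseline × 2^(loading × activity)), with
housekeeping assays activity-independent. SLE activities come from a
bimodal mixture — 25% of patients in a high mode shifted +2.5 activity
units — so the IFN-H quartile corresponds to a real subgroup; healthy
controls sit near zero. Gene loadings are U(1.0, 2.0) log2 units per
activity unit, i.e. roughly 8–64-fold induction in high-mode patients,
consistent with the dynamic range reported for canonical
interferon-stimulated genes; baseline Ct is U(26, 30), technical noise
0.15 cycles per assay and per replicate well, Ct clipped to [10, 40]. A
single shared factor is an assumption: real signature genes carry
residual correlation structure beyond one factor, which this generator
does not model.

*CyTOF*: cells draw from a population mixture (multinomial per sample);
defining lineage markers come from well-separated high (arcsinh scale
N(3.0, 0.35)) versus low (N(0.15, 0.10)) states, and raw counts are the
sinh back-transform, giving the canonical zero-inflated bimodal picture
after the stated arcsinh. Functional markers have cell-level SD 0.5 and a
between-sample random effect of SD 0.25 shared across stimulations; an
injected effect shifts the affected group's cells by δ × 0.25 under the
named stimulation, i.e. δ is standardized against the between-sample SD.
Instrument physics (spillover, bead drift, doublets) is not modelled, so
gating accuracy here measures the gate logic, not robustness to such
artifacts.

*Arrays*: log-normal MFI (baseline log MFI log 3000, SD 0.4), reactive
antigens shifted by a stated natural-log fold in the designated group,
and a configurable fraction of entries marked undetected.

Every generator draws from an RNG stream derived from the master seed by
hashing the artifact name, so adding a generator never perturbs existing
fixtures, and identical (parameters, seed) give byte-identical output.

## Validation experiments and their problem sizes

`ifncyto.validation` runs the recovery experiments end to end:
stratification recovery on 81 + 31 patients (recovered strata versus
latent quartiles; the headline fraction pools IFN-H and IFN-L agreement
over the 42 stratified patients); guided-gating accuracy on 200
replicates of 1,000-cell two-part mixtures with 99% binomial-interval
abundance checks; single-cohort effect recovery at 25 samples/group ×
5,000 cells; a bias sweep over δ ∈ {0.5, 1, 2} at 25 samples/group × 600
cells with 100 replicates per δ (fewer cells than the single-cohort run —
per-sample medians are already tight at 600 cells — and 100 rather than
fewer replicates so the bias estimate's own noise, ≈0.04 SE per δ, is
small against the 0.1 bound); and null FDR calibration of the effects
model over 300 replicates of 200 exchangeable-null tests each, generated
at the summary level the model actually consumes (the empirical FDR on an
all-null family is Bernoulli — any discovery is false — so replicates,
not tests per replicate, set the estimator's precision).

A single-cohort recovered effect has irreducible sampling SD ≈ √(2/n) ≈
0.3 at 25 samples/group — scale-free, so no generator noise setting can
shrink it; point recoveries scatter accordingly while the sweep means are
tight. Passing these experiments shows the machinery is correct and
calibrated under the generators' assumptions; it does not certify
performance under real-data features the generators omit (residual gene
correlation, instrument artifacts, non-lognormal MFI tails, unbalanced
cohorts).

## Degenerate inputs and tie-breaks, collected

Constant response → flagged degenerate, excluded from BH family. Aliased
covariate → explicit fit error. All-equal SLE scores → all "mid".
All-masked Ct replicate pairs stay masked. Gate-cut ties → "−". Two-means
on all-identical values → degenerate flag + fallback cut. Zero rank
variance → Spearman refused. Zero marginal → chi-square refused.
All-missing antigen → imputation refused. NaN in a clustering matrix →
refused (impute first). Exact Mann-Whitney switches to the tie- and
continuity-corrected normal approximation above combined n = 12 or in the
presence of ties.
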