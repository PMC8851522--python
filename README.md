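# ifncyto

Linking the interferon (IFN) gene-expression signature to single-cell
signaling and autoantibody reactivity in systemic lupus erythematosus
(SLE), as a tested, reusable Python pipeline. It is written for
computational immunologists and biostatisticians who need the three
analysis layers of an IFN-stratified cohort study — qPCR signature
scoring, guided CyTOF gating with effect-size regression, and autoantigen
array screening — plus seeded synthetic cohorts with recorded ground truth
so every stage can be validated without patient data.

## What it computes

**IFN signature score** (`ifncyto.ifnscore`). From duplicate qPCR Ct
values: replicates are averaged, ΔCt(g, s) = Ct(g, s) − mean of the
housekeeping Cts (GAPDH, ACTB, B2M; the arithmetic mean on the Ct scale is
the geometric mean on the linear scale), relative expression is
2^(−ΔCt), each transcript is normalized to its maximum across samples,
and the score is

    score(s) = Σ_g  expr(g, s) / max_s' expr(g, s')   ∈ [0, |panel|].

SLE patients with score ≥ Q3 form the IFN-H stratum, ≤ Q1 the IFN-L
stratum (linear-interpolation quartiles, boundary inclusive).

**Guided gating and effect sizes** (`ifncyto.cyto`, `ifncyto.effects`).
Raw ion counts are arcsinh-transformed with cofactor 5, transformed values
below 0.125 are set to 0, and cells are assigned to populations by
conjunctions of per-marker +/− constraints (Treg: CD25+CD127−, Tfh:
CXCR5+PD1+, Th17: CD45RA−IL17+, lineage exclusions), with cuts derived by
a deterministic one-dimensional two-means. Per-sample population medians
and abundances are modelled as

    Marker ~ Group (+ Treatment + Batch),   effect = β_Group / SD(Marker),

by OLS with Benjamini–Hochberg FDR within each stimulation; cells with
q < 0.05 populate dotmap/forest tables.

**SAM on antigen arrays** (`ifncyto.serology`). Undetected features are
set to MFI 1 and antigens whose maximum IgG MFI is below 1,000 are
excluded as non-reactive. Per antigen, a standardized Wilcoxon rank
statistic is compared with its expected order statistic over group-label
permutations (exhaustive, or distinct Monte-Carlo assignments); a
Tusher-style delta sweep converts false-call counts into per-antigen
q-values. KNN replacement, average-linkage Euclidean clustering and the
ELISA detection-limit rule (2 × SD of blanks) support the heatmap layer.

**Synthetic cohorts** (`ifncyto.synth`) generate all three data types from
known ground truth: a latent IFN activity driving 44 co-regulated
transcripts, population mixtures with marker-defined identities and
injected stimulation-dependent phospho shifts, and log-normal MFI with
antigen-specific elevations. `ifncyto.validation` packages the recovery
experiments built on them.

## Worked example

```bash
python examples/ifn_scoring.py
```

```
median IFN score  SLE 1.32   HC 0.92
Mann-Whitney SLE vs HC: U=2019, p=6.98e-07
stratum
mid      39
n/a      31
IFN-H    21
IFN-L    21
```

An 81-patient synthetic SLE cohort scores significantly higher than its 31
controls, and the quartile rule assigns exactly 21 patients to each of the
IFN-H and IFN-L strata. The other examples
(`guided_gating.py`, `effect_sizes.py`, `autoantigen_sam.py`,
`full_pipeline.py`) walk the remaining stages; `effect_sizes.py` recovers
an injected pSTAT1 effect of 1.5 as 1.63 ± 0.3 and prints the one dotmap
row surviving FDR < 0.05.

A thin CLI wraps the same functions:

```bash
ifncyto run --seed 7 --out demo_run        # full pipeline + manifest
ifncyto simulate qpcr --seed 5 --out sim   # one artifact + truth sidecar
ifncyto score-ifn --ct sim/ct.csv --out scores.csv
```

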