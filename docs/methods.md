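# Methods

## Coordinate conventions

All coordinates are 0-based, half-open (BED-native) throughout. The TSS of a
minus-strand transcript is `end − 1`, the biological 5′ end under UCSC
practice. Any 1-based source must be converted at the I/O boundary; keeping a
single internal convention prevents off-by-one drift between the chromatin,
methylation and CGI stages, which all share the same window arithmetic.
Windows are symmetric and strand-independent, clamped at position 0 (a
truncated window is valid input, not an error — a degenerate promoter must
not abort a genome-wide scan).

## Chromatin-state annotation and gain detection

A TSS is mark-positive when ≥ 1 peak interval overlaps the window TSS ± h
(h = 2 kb for H3K4me3, 5 kb for H3K27me3/H3K79me2). Overlap requires one
shared base and no minimum overlap fraction; the positivity signal is the
maximum score among overlapping peaks (ties are irrelevant to positivity).
Peaks are inputs — peak calling is out of scope.

"Upregulated H3K4me3 after demethylation" is ambiguous between de-novo
acquisition and quantitative increase, and the underlying peak statistic
(scores vs. read counts vs. presence) is not fixed by convention. Both
interpretations are therefore implemented:

* **binary** — gained ⇔ parent-negative ∧ derivative-positive;
* **quantitative** (default, ratio threshold 2.0) — gained ⇔
  derivative-positive ∧ (parent-negative ∨
  (s_deriv + 1)/(s_parent + 1) ≥ 2). The pseudocount of 1 on both signals
  keeps the ratio finite for parent-negative TSSs; with the ratio threshold
  at +∞ the quantitative mode reduces exactly to the binary mode (a tested
  invariant).

## Promoter methylation

Promoter = TSS ± 500 bp, the same window used for the CGI-overlap
requirement (one promoter definition for both filters; interpreting the CGI
requirement over a wider window is a documented alternative, not the
default). Per-promoter methylation is the **unweighted** mean of per-CpG
levels × 100 — the conventional per-region summary for bisulfite data; read
weighting would let a single deep site dominate the region estimate.
Sites with < 10 reads are dropped and promoters with < 3 surviving CpGs are
*unavailable*: a value, not an error, mirroring how reduced-representation
bisulfite sequencing covers only a fraction of promoters. Both defaults are
configurable.

Stratification bins are lower-inclusive, upper-exclusive with the top bin
closed ([80, 100]); the boundary convention is a package decision since only
the five labels are conventionally fixed. The cancer-specific filter uses
strict inequalities (> 60 % tumor, < 40 % normals) — exactly 60 % fails.
"Normal tissues low" means **all** available normal tissues by default (the
strictest reading); an "any" mode is available for sensitivity analysis.

## Expression criteria

Fold changes are (x + ε)/(y + ε) with a shared ε = 10⁻³, which is symmetric,
keeps fold(x, x) = 1 and registers reactivation from complete silence as a
large-but-finite fold. All comparisons are strict: exactly 2-fold never
passes. "Expressed in normal colon" has no standard operational definition
for relative qRT-PCR values; the default threshold is 0.01 relative units
(1 % of a typical housekeeping-normalized expressed gene) and is prominent
in the configuration. Criterion (b) is a disjunction of the pharmacological
and genetic demethylation routes; a conjunction flag exists for sensitivity
analysis.

## Funnel orchestration

Stages run in the fixed order universe → H3K4me3-positive-any → gained →
bisulfite-available → methylation filter → CGI → expression, with later
stages evaluated only for survivors; non-survivors carry "not evaluated"
(distinct from False) in records and TSV output so sensitivity analyses can
re-evaluate them honestly. Gene-level collapse defaults to *any-TSS* (a gene
silenced at any of its promoters is a candidate). Printed percentages use
round-half-away-from-zero to one decimal.

## Clinical statistics

* Student's t is the equal-variance form (Welch optional).
* Pearson p-values come from the exact t transform with n − 2 df;
  significance is declared at p < 0.01 two-sided.
* The Kaplan–Meier estimator is the standard product-limit form (via
  lifelines); with no censoring it equals the empirical survival function, a
  tested invariant.
* The log-rank statistic is the 1-df observed-minus-expected form with
  hypergeometric variance, implemented vectorized so the cutoff scan can
  evaluate hundreds of candidate cutoffs quickly; it is cross-checked
  against lifelines on random cohorts.
* **Cutoff optimization**: candidate cutoffs are midpoints between
  consecutive distinct methylation values; a candidate is admissible when
  each arm keeps ≥ 10 % of the cohort (midpoints avoid exact-tie ambiguity;
  the floor avoids degenerate arms). The winner minimizes the log-rank p,
  ties broken toward the more balanced split. Published cutoff-finding tools
  offer several method families; the minimal-p variant implemented here is
  recorded in the result metadata, and the reported p is explicitly
  uncorrected — on null cohorts the minimal-p distribution is strongly
  sub-uniform (≈ 40 % of null scans reach p < 0.05 at n = 40; the
  acceptance script measures this at run time).

## Synthetic-data generator

The generator emulates the full study design on one synthetic chromosome
(10 Mb, 200 genes by default): a parent tumor line and a demethylated
derivative with peak sets for three marks; per-CpG bisulfite counts for the
tumor line and five normal gastrointestinal tissues; expression under four
conditions (normal colon, tumor line, tumor line + demethylating drug,
demethylated derivative); and clinical cohorts of 46 normal / 38 adenoma /
41 advanced adenoma / 101 carcinoma samples with survival for the carcinoma
group.

Planted silenced genes (20 by default) carry the complete signature: tumor
promoter CpG levels Beta-distributed with mean 0.85 (concentration 50),
normal tissues mean 0.05; a CGI over the promoter; H3K4me3 only in the
derivative line; parent-line H3K27me3 for 39 % of them; expression silenced
8-fold in the tumor line and reactivated 6-fold under both demethylation
routes. Non-silenced genes split into active-everywhere (55 % of the
remainder), inactive-unmethylated (20 %) and tissue-silent (25 %) classes;
half of the tissue-silent class gains H3K4me3 and reactivates expression on
demethylation **without** promoter methylation, so the funnel's
gain→methylation attrition is non-trivial and the methylation filter is
load-bearing for precision.

CpG counts follow a beta-binomial observation model (Beta site-level means,
binomial reads at Poisson(30) depth, ~12 CpGs per promoter): the standard
bisulfite noise model, giving the filters realistic sampling variance.
Clinical methylation is Beta-distributed with group means 5/12/30/35 % —
chosen so the > 15 % elevation frequency rises from normal to carcinoma;
the rising shape, not any particular frequency, is the testable property.
Carcinoma survival is exponential with the hazard doubled above the cohort
methylation median and administrative censoring at 60 months.

What the simulation does **not** emulate: real genome sequence and CpG
spacing, multi-chromosome structure (unit fixtures cover multi-chromosome
handling), correlated methylation between neighboring promoters, batch or
tissue-composition effects, and peak-calling artifacts. Passing the
planted-truth recovery test therefore demonstrates the pipeline's internal
consistency under the stated noise model, not its operating characteristics
on real epigenomes — on real data the effect sizes are smaller and the
stage attrition far stronger.

## Problem sizes

Defaults used by the test suite and the acceptance script: 200-gene bundles
(20 planted silenced) for recovery, with 20 seeds for the stability
estimate; 100-gene bundles for the 100-replicate monotonicity checks;
n = 200 cohorts (50–100 replicates) for cutoff recovery; n = 40 null
cohorts (200–400 replicates) for the minimal-p calibration; 1,000+
randomized instances for the interval brute-force oracles. These sizes give
stable estimates at desk scale while keeping every property independently
re-computable from scratch.

## Known limitations

* The funnel reproduces the screen's logic, not the original counts: those
  derive from the original ChIP-seq/RRBS/qRT-PCR datasets, which are not
  inputs here.
* The quantitative gain mode depends on peak scores being comparable
  between cell lines; no cross-line normalization is applied.
* The cutoff scan's minimal p is knowingly optimistic; no multiplicity
  correction is applied because the per-probe uncorrected value is what the
  downstream consumer expects to see flagged, not hidden.
* Survival input is unit-agnostic; consistency of units within one table is
  the caller's responsibility.
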