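# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. Nothing here states a result the test suite or
`scripts/acceptance.py` does not itself compute.

## Subgroup discovery

Samples are clustered on the distance `1 − Pearson correlation` between
their profiles over a selected feature set. Correlation distance was chosen
(over Euclidean) because it is scale-free across FPKM magnitudes and is the
standard choice for expression subtyping; expression enters as
log2(FPKM + 1) (pseudocount 1) and methylation as M-values.

Variable features are ranked by three statistics — median absolute
deviation, variance, and the dip statistic — each combined with complete
and average linkage, giving six method combinations. For each combination
the number of top features is selected by a stability sweep: at each count
in an increasing grid (default 250, 500, 1000, 2000, 4000) the bootstrap
probability is the fraction of B feature-resampled replicates whose
two-group partition is *identical* (as an unordered set partition) to the
full-data partition. The selected count is the smallest one with
probability ≥ 0.70 whose assignment also agrees (≥ 90 % after optimal label
mapping) with the top-1000-feature assignment; if none qualifies the
maximal-probability count is used and the method is flagged unstable.
Design choices made where the procedure was genuinely open:

- **Resampling is over features, not samples.** The stability question
  asked is "does the partition depend on which features were measured";
  feature resampling also keeps every sample labeled in every replicate.
- **Partition match is exact identity,** not majority agreement — a crisper
  event whose probability is directly interpretable and oracle-checkable.
- **Consensus quorum is a strict majority (≥ 4 of 6)** after aligning labels
  across methods by the better of the two 2×2 mappings; samples without a
  strict majority are reported unclassifiable, never dropped.
- B defaults to 1000 in the CLI; tests and the acceptance study use B = 100,
  which bounds the Monte-Carlo standard error of a 0.7 probability at ~0.046.

The two consensus groups are named by the marker gene (ALK): the cluster
with the higher median marker expression becomes ALK_high. Equal medians
raise an error demanding an explicit override rather than a silent
tie-break.

## Dip statistic

The dip is implemented from its definition: the minimum over unimodal CDFs
`G` (convex left of the mode, concave right, an atom permitted only at the
mode) of the sup-norm distance to the empirical CDF. Feasibility of a
candidate half-width `d` is decided knot-by-knot: the greatest convex
minorant of the upper band envelope must clear the lower envelope left of
the mode, the reflected construction must hold on the right, and the two
pieces must share an attainable value at the mode (for atom modes, the two
one-sided values may differ across the jump). The dip is then located by
bisection (tolerance 1e-8 for ranking, 1e-10 for scalar calls). The
implementation is validated in the test suite against an exact
linear-programming oracle that solves the same minimization directly for
every mode placement. For n distinct values the dip lies in
[1/(2n), 1/4]; equally spaced points attain the lower bound, two equal
point masses the upper. A constant sample has dip 0 (it is exactly
unimodal), which correctly ranks constant features last.

Pooled-β bimodality profiling evaluates the dip on a deterministic
2000-point quantile grid of the pooled values; the discretization error
(~2.5e-4) is two orders of magnitude below the contrasts of interest.

## Statistical primitives

- **Moderated t.** Per-feature pooled variance with d = n_a + n_b − 2;
  prior (d₀, s₀²) by method of moments on z = log s² using
  digamma/trigamma moment expressions, with Newton inversion of the
  trigamma; under-dispersion (negative excess variance of z) falls back to
  d₀ = ∞ with s₀² the mean variance. Zero-variance features are floored at
  1e-5 of the median variance so they lean on the prior. Verified in the
  tests to reproduce limma's eBayes t and p values to 1e-8 on both
  branches. Known property, inherent to the plug-in prior: the far tail is
  slightly anti-conservative at small n (type-I ≈ 0.018 at α = 0.01 for
  n = 6+6; identical for limma on the same data), while α = 0.05
  calibration sits inside the binomial band.
- **Wilcoxon rank-sum.** Exact mode (combined n ≤ 20) computes the full
  permutation distribution of the midrank sum by a shift-algorithm dynamic
  program over doubled (hence integer) ranks — identical to enumerating all
  C(n, n_x) assignments, which the test oracle does directly. Larger
  samples use the normal approximation with tie correction and continuity
  correction.
- **Fisher's exact test** is two-sided by the probability-mass rule with the
  conventional 1 + 1e-7 tolerance factor. Over-representation analysis uses
  the one-sided (enrichment) hypergeometric tail instead, matching
  enrichment-tool convention; both conventions are deliberate and
  documented here.
- **Kaplan–Meier / log-rank** follow the textbook product-limit and
  (O − E)²/V forms and are cross-checked against lifelines. All-censored
  input yields a flat curve and a degenerate log-rank reported as p = 1
  with a warning, not an error.
- **ssGSEA.** Within each sample, genes get average ranks (ascending, so
  the top gene has rank N); walking the list from the highest-expressed
  gene, the score accumulates the difference between the in-set ECDF
  weighted by rank^α (α = 0.75, the canonical default) and the unweighted
  out-of-set ECDF. Scores are reported unnormalized by default; min-max
  normalization across samples is available behind a flag. Because the
  score is rank-based it is invariant to per-sample monotone transforms.
- **GSEA** ranks genes by signal-to-noise (group σ floored at
  max(0.2·|μ|, 0.2), the canonical constants) and uses phenotype
  permutation only — appropriate for the two-group designs here; gene-set
  permutation is intentionally unimplemented. NES divides the ES by the
  mean |null ES| of the same sign; FDR follows the positive/negative
  pooling procedure; nominal p uses the (1 + k)/(1 + m) form so it is never
  below 1/(n_perm + 1).

## Methylation conventions

Tests run on M-values (variance-stabilized); effect sizes are reported as
Δβ = mean β(group A) − mean β(group B) because β differences are the
field's interpretable unit. A probe is hyper(methylated in A) when
q < 0.05 and Δβ > 0. "Region" results are probe-level calls summarized by
the six-class genomic annotation vocabulary (TSS, 5'UTR, first exon, gene
body, 3'UTR, intergenic) rather than merged windows, matching the
annotation-class presentation of the counts. Probe filters (chrX/Y,
SNP VAF > 0.01 strict) are order-independent and idempotent; samples with
*missing* tumor fraction are retained with a logged warning since only
known-low-purity samples justify exclusion. The probe–ALK Spearman screen
runs on M-values; Spearman is rank-based and β → M is strictly monotone,
so β-space screening would select the identical probes. Probes constant
across the shared samples have undefined correlation and are reported with
ρ = NaN, never selected.

## Synthetic cohorts

The generator's defaults emulate the motivating cohort design: 32 diagnosis + 4
relapse samples, ALK_high fraction 14/32, 5 000 genes, 10 000 probes,
planted ALK log2 shift 2.0, immune and proliferation programs of 150 genes
each (log2 shift 1.5, opposite directions in the two groups), 36
relapse-up genes (log2 shift 2.0, attenuated by 0.5 in the diagnosis
samples of 6 planted eventual relapsers), 400 hypermethylated probes with
region-class bias gene_body(3) > TSS(1.5) > others(1) and Δβ ≈ 0.3, 50
marker-tracking probes, CN-alteration probabilities 0.727 (ALK_high) vs
0.0625 (ALK_low), exponential survival with hazard ratio 3 for eventual
relapsers (baseline hazard 0.08, censoring uniform on [4, 12], unitless
time — the analysis only requires a consistent unit per cohort).

Expression noise is log-normal (sd 0.5 on the log2 scale). β noise is
heteroscedastic, sd = 0.28·β(1−β) with floor 0.005 — EPIC-style arrays are
far less noisy near fully (un)methylated probes, i.e. noise is roughly
constant on the M scale; a constant-β-noise model would let extreme-β
probes dominate M-value variance and mask subgroup structure. The ALK_low
per-probe centers are drawn from a three-component Beta mixture (hypo,
hyper, mid modes; weights 0.35/0.35/0.30); ALK_high centers are the same
values pulled toward 0.5 by a factor 0.6, producing the moderate,
mid-concentrated ALK_high profile and the bimodal ALK_low profile while
giving methylation clustering a diffuse genuine subgroup signal.

What the generator does **not** emulate: probe-probe spatial correlation
along the genome, batch and chip effects, tumor-purity dilution of β
values, count-level sequencing noise, and realistic gene–gene correlation
beyond the planted programs. Passing recovery tests therefore demonstrates
the pipeline's correctness and power under the planted model, not
performance guarantees on real cohorts.

One consequence worth stating: in the default cohort nearly every
group-remodeled probe genuinely correlates with ALK expression *through
the subgroup structure*, so "precision" of the |ρ| ≥ 0.75 screen against
the 50 planted tracking probes is ill-defined there (the screen correctly
selects ~1 500–2 000 probes, as the large correlated-gene lists in real
cohorts suggest). The screen's operating characteristics are therefore
measured on a generator variant with the global remodeling switched off
(squeeze factor 1.0, no hyper block), where the planted tracking probes
are the only ALK-linked signal; there precision and recall both exceed
0.8.

## Problem sizes used by tests and the acceptance script

Consensus-clustering recovery runs 50 seeded default cohorts in the test
suite (20 in the acceptance script) at B = 100; relapse-signature recovery
uses the 4-vs-32 relapse-vs-diagnosis design; calibration uses 1000 null features
(moderated t) and 500 replicates of n = 40 (log-rank). These sizes keep
Monte-Carlo error well below the thresholds tested while the full suite
runs in minutes on one CPU.

## Known limitations

- Two groups only; k > 2 subtype discovery is out of scope by design.
- No Cox regression or multivariable survival modeling; outcome analysis is
  KM/log-rank only.
- No batch correction or covariate-adjusted differential models.
- The CLI consumes matrices already normalized upstream (FPKM, β); no
  IDAT/BAM/FASTQ handling.
- GSEA requires ≥ 3 samples per group (phenotype permutation); smaller
  designs error rather than silently switching null schemes.
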