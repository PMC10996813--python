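# alclomics

Multi-omic subtyping and relapse-risk analysis for pediatric ALK-positive
anaplastic large cell lymphoma (ALCL)-style cohorts.

Pediatric ALK+ ALCL cohorts profiled by RNA-seq (FPKM) and Illumina
EPIC-style DNA methylation arrays split into two molecular subgroups —
**ALK-high** (proliferative, MYC/E2F-driven) and **ALK-low** (immune-
infiltrated, globally hypermethylated) — and a minority of patients relapse
after therapy. This package re-implements that analysis as a tested,
reusable pipeline for anyone who wants to run the same subgrouping and
relapse-risk machinery on their own expression/methylation cohort, or to
study its operating characteristics on synthetic data:

- **Bootstrap feature-stability consensus clustering.** Features are ranked
  by MAD, variance, and the Hartigan–Hartigan dip statistic
  `D = min_G sup_t |F_n(t) − G(t)|` over unimodal CDFs `G`; samples are
  clustered on `1 − Pearson` correlation distance under complete and average
  linkage; the number of top features is chosen by sweeping counts and
  requiring ≥ 70 % bootstrap support (fraction of feature-resampled
  replicates reproducing the full-data two-group partition); the final
  label is the strict majority over the 6 statistic × linkage combinations,
  and clusters are named ALK_high/ALK_low by median ALK expression.
- **Differential expression** with the empirical-Bayes moderated t:
  posterior variance `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` with the prior
  `(d₀, s₀²)` fit by method of moments on `log s²_g`, BH-adjusted, called at
  |log2FC| > 1 and q < 0.05.
- **Relapse signature scoring.** Genes up-regulated in relapse vs diagnosis
  samples (raw p < 0.01, log2FC > 1, q < 0.25) form a gene set; each sample
  receives an ssGSEA enrichment score (rank-weighted ECDF difference,
  `α = 0.75`), dichotomized at the median of the diagnosis samples, and the
  HIGH/LOW strata are compared by Kaplan–Meier / log-rank.
- **Methylation analysis.** β → M conversion `M = log2(β/(1−β))`, chrX/Y and
  SNP-probe (VAF > 0.01) filtering, < 40 % tumor-content sample exclusion,
  probe-level Wilcoxon rank-sum differential methylation (BH q < 0.05)
  summarized by genomic region class, pooled-β bimodality profiling, and a
  Spearman screen of every probe against ALK expression at |ρ| ≥ 0.75.
- **Integration.** Cross-platform concordance (Fisher's exact), final
  labels with disagreements flagged unclassifiable, copy-number-alteration
  enrichment by subgroup, local over-representation analysis over
  user-supplied GMT libraries, and survival comparisons.
- **Synthetic cohorts.** A seeded generator plants all of the above
  structure (two subgroups, ALK shift, immune/proliferation programs,
  bimodal vs moderate β landscapes, gene-body-biased hypermethylation,
  marker-tracking probes, group-dependent CN alterations, relapse-linked
  hazards) with the truth carried alongside for evaluation.

## Worked example

Simulate a default cohort (32 diagnosis + 4 relapse samples, 5 000 genes,
10 000 probes, ALK_high fraction 14/32) and run the whole pipeline from one
config file:

```bash
alclomics simulate --seed 5 --out cohort
cat > cfg.yaml <<EOF
expression: cohort/expression.tsv
methylation: cohort/methylation.tsv
manifest: cohort/manifest.tsv
metadata: cohort/metadata.tsv
out: results
feature_counts: [250, 500, 1000, 2000]
bootstrap: 100
EOF
alclomics pipeline --config cfg.yaml --seed 3
```

which prints

```
concordance 29/29; DE {'n_up': 148, 'n_down': 148}; DMP {'n_hyper': 3763, 'n_hypo': 3352}
```

and writes `results/pipeline_summary.json` containing, among others:

- `concordance: 29/29 (fraction 1.0)` — expression- and methylation-based
  subgroup labels agree on all 29 dual-platform diagnosis samples that
  survive the purity filter (3 of 32 fall below 40 % tumor content);
- `cn_enrichment: ALK_high 0.714 vs ALK_low 0.0, Fisher p = 1.6e-05` — the
  planted group-dependent copy-number alteration probabilities are
  recovered;
- `relapse_signature: 36 genes` and `survival logrank_p = 0.185` — the
  relapse-up gene set and the (underpowered at n=32, as in real cohorts of
  this size) survival split of its HIGH/LOW score strata;
- `beta_profile` — pooled-β dip 0.0286 in ALK_low vs 0.0136 in ALK_high,
  the bimodal-vs-moderate methylation contrast between the subgroups.

Every stage is also available as its own subcommand (`cluster`, `de`,
`relapse-score`, `gsea`, `dmr`, `correlate`, `integrate`, `survival`) and as
plain library functions (`alclomics.subtype_clustering`,
`alclomics.expression_analysis`, ...).

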