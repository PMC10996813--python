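"""Seeded generator of synthetic ALCL-like cohorts.

The generator emulates the statistical structure the analysis assumes in a
pediatric ALK+ ALCL cohort: ~32 diagnostic plus 4 relapse samples; two
diagnosis subgroups (ALK_high ~ 14/32) separated by an ALK expression shift
and by opposed immune (up in ALK_low) and proliferation (up in ALK_high)
programs; methylation with a bimodal ALK_low beta landscape versus a
mid-squeezed moderate ALK_high profile, a block of gene-body-biased probes
hypermethylated in ALK_low, and probes tracking ALK expression; sex-
chromosome and SNP-overlapping probes to exercise the filters; group-
dependent copy-number alteration probability; and exponential survival with
an elevated hazard for planted eventual relapsers, whose diagnosis samples
carry an attenuated relapse expression program.  All draws descend from a
single seed; the planted truth travels with the cohort for evaluation only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as io
from .io_formats import (CohortMetadata, GeneSetLibrary, MutationTable,
                         OmicsMatrix, ProbeManifest, SegmentTable)

REGION_WEIGHTS = {"TSS": 0.20, "five_prime_UTR": 0.05, "first_exon": 0.05,
                  "gene_body": 0.45, "three_prime_UTR": 0.05, "intergenic": 0.20}
HYPER_REGION_BIAS = {"TSS": 1.5, "five_prime_UTR": 1.0, "first_exon": 1.0,
                     "gene_body": 3.0, "three_prime_UTR": 1.0, "intergenic": 1.0}


@dataclass
class CohortSpec:
    """Planted structure of a synthetic cohort (defaults mirror a reference
    cohort shape: 32 diagnosis + 4 relapse, ALK_high fraction 14/32)."""

    n_diagnosis: int = 32
    n_relapse: int = 4
    n_genes: int = 5000
    n_probes: int = 10000
    group_fraction: float = 14 / 32        # diagnosis fraction in ALK_high
    alk_log2_shift: float = 2.0
    n_immune_genes: int = 150
    n_proliferation_genes: int = 150
    n_relapse_genes: int = 36
    program_log2_shift: float = 1.5
    relapse_log2_shift: float = 2.0
    relapse_attenuation: float = 0.5       # shift factor at diagnosis of eventual relapsers
    n_eventual_relapsers: int = 6
    noise_sd: float = 0.5                  # log2-scale expression noise
    # methylation mixture: (low-mode a,b), (high-mode a,b), (mid a,b), weights
    meth_mixture: tuple = ((2.0, 10.0), (10.0, 2.0), (8.0, 8.0), (0.35, 0.35, 0.30))
    meth_squeeze: float = 0.6              # ALK_high centers pulled toward 0.5
    meth_noise_sd: float = 0.07
    n_hyper_probes: int = 400
    hyper_delta_beta: float = 0.30
    hyper_region_bias: dict = field(default_factory=lambda: dict(HYPER_REGION_BIAS))
    n_marker_tracking_probes: int = 50
    frac_chrX: float = 0.03
    frac_chrY: float = 0.01
    frac_snp_probes: float = 0.03
    frac_low_purity: float = 0.12
    cn_prob_high: float = 0.727
    cn_prob_low: float = 0.0625
    hazard_ratio: float = 3.0
    base_hazard: float = 0.08
    censor_range: tuple = (4.0, 12.0)
    seed: int = 0

    def validate(self) -> None:
        planted = self.n_immune_genes + self.n_proliferation_genes + \
            self.n_relapse_genes + 1
        if planted > self.n_genes:
            raise ValueError("planted gene programs exceed n_genes")
        if self.n_hyper_probes + self.n_marker_tracking_probes > self.n_probes:
            raise ValueError("planted probe sets exceed n_probes")
        for f in (self.group_fraction, self.frac_chrX, self.frac_chrY,
                  self.frac_snp_probes, self.frac_low_purity):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0,1]")
        if min(self.n_diagnosis, self.n_genes, self.n_probes) <= 0:
            raise ValueError("sizes must be positive")


@dataclass
class SyntheticCohort:
    expression: OmicsMatrix                # FPKM
    methylation: OmicsMatrix               # beta
    manifest: ProbeManifest
    metadata: CohortMetadata
    segments: SegmentTable
    mutations: MutationTable
    truth: dict
    spec: CohortSpec


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nd, nr = spec.n_diagnosis, spec.n_relapse
    n_samples = nd + nr
    diag_ids = [f"D{i + 1:03d}" for i in range(nd)]
    rel_ids = [f"R{i + 1:03d}" for i in range(nr)]
    samples = diag_ids + rel_ids

    # subgroup labels: diagnosis split by group_fraction; relapse samples too
    n_high = int(round(spec.group_fraction * nd))
    group = np.array(["ALK_low"] * n_samples, object)
    high_idx = rng.choice(nd, size=n_high, replace=False)
    group[high_idx] = "ALK_high"
    rel_high = rng.random(nr) < spec.group_fraction
    group[nd:][rel_high] = "ALK_high"
    is_high = group == "ALK_high"

    eventual = rng.choice(nd, size=min(spec.n_eventual_relapsers, nd),
                          replace=False)
    is_eventual = np.zeros(n_samples, bool)
    is_eventual[eventual] = True
    is_relapse_sample = np.array([False] * nd + [True] * nr)

    # ---- expression -----------------------------------------------------
    genes = [f"gene_{i + 1:05d}" for i in range(spec.n_genes - 1)] + ["ALK"]
    perm = rng.permutation(spec.n_genes - 1)
    immune = [genes[i] for i in perm[:spec.n_immune_genes]]
    prolif = [genes[i] for i in
              perm[spec.n_immune_genes:
                   spec.n_immune_genes + spec.n_proliferation_genes]]
    relapse_genes = [genes[i] for i in
                     perm[spec.n_immune_genes + spec.n_proliferation_genes:
                          spec.n_immune_genes + spec.n_proliferation_genes +
                          spec.n_relapse_genes]]
    mu = rng.normal(3.0, 1.5, size=spec.n_genes)
    gi = {g: i for i, g in enumerate(genes)}
    mu[gi["ALK"]] = 5.0
    L = np.tile(mu[:, None], (1, n_samples))
    L[gi["ALK"], is_high] += spec.alk_log2_shift
    for g in immune:
        L[gi[g], ~is_high] += spec.program_log2_shift
    for g in prolif:
        L[gi[g], is_high] += spec.program_log2_shift
    shift = spec.relapse_log2_shift
    for g in relapse_genes:
        L[gi[g], is_relapse_sample] += shift
        L[gi[g], is_eventual] += spec.relapse_attenuation * shift
    L += rng.normal(0.0, spec.noise_sd, size=L.shape)
    fpkm = np.maximum(np.exp2(L) - 1.0, 0.0)
    expression = OmicsMatrix(pd.DataFrame(fpkm, index=genes, columns=samples),
                             "fpkm")

    # ---- methylation ----------------------------------------------------
    probes = [f"cp{i + 1:06d}" for i in range(spec.n_probes)]
    region = rng.choice(list(REGION_WEIGHTS), size=spec.n_probes,
                        p=list(REGION_WEIGHTS.values()))
    chrom = rng.choice([f"chr{i}" for i in range(1, 23)], size=spec.n_probes)
    n_x = int(spec.frac_chrX * spec.n_probes)
    n_y = int(spec.frac_chrY * spec.n_probes)
    sex_idx = rng.choice(spec.n_probes, size=n_x + n_y, replace=False)
    chrom[sex_idx[:n_x]] = "chrX"
    chrom[sex_idx[n_x:]] = "chrY"
    snp_vaf = np.zeros(spec.n_probes)
    snp_idx = rng.choice(spec.n_probes, size=int(spec.frac_snp_probes *
                                                 spec.n_probes), replace=False)
    snp_vaf[snp_idx] = rng.uniform(0.02, 0.5, size=snp_idx.size)
    probe_gene = np.array([""] * spec.n_probes, object)
    with_gene = rng.random(spec.n_probes) < 0.8
    probe_gene[with_gene] = rng.choice(np.array(genes), size=int(with_gene.sum()))
    manifest = ProbeManifest(pd.DataFrame({
        "chrom": chrom,
        "position": rng.integers(1, 2_000_000_00, size=spec.n_probes),
        "gene": probe_gene,
        "region_class": region,
        "snp_vaf": snp_vaf,
    }, index=pd.Index(probes, name="probe_id")))

    # usable probes (survive filters) host the planted structure
    usable = np.flatnonzero(~np.isin(chrom, ("chrX", "chrY")) & (snp_vaf <= 0.01))
    bias_w = np.array([spec.hyper_region_bias.get(r, 1.0) for r in region[usable]])
    bias_w /= bias_w.sum()
    hyper_idx = rng.choice(usable, size=spec.n_hyper_probes, replace=False,
                           p=bias_w)
    remaining = np.setdiff1d(usable, hyper_idx)
    marker_idx = rng.choice(remaining, size=spec.n_marker_tracking_probes,
                            replace=False)

    (a_lo, b_lo), (a_hi, b_hi), (a_mid, b_mid), w = spec.meth_mixture
    comp = rng.choice(3, size=spec.n_probes, p=list(w))
    centers = np.empty(spec.n_probes)
    centers[comp == 0] = rng.beta(a_lo, b_lo, size=int((comp == 0).sum()))
    centers[comp == 1] = rng.beta(a_hi, b_hi, size=int((comp == 1).sum()))
    centers[comp == 2] = rng.beta(a_mid, b_mid, size=int((comp == 2).sum()))
    center_low = np.tile(centers[:, None], (1, n_samples))
    center_high = 0.5 + spec.meth_squeeze * (centers[:, None] - 0.5)
    B = np.where(is_high[None, :], center_high, center_low)
    # planted hyper block: extra methylation in ALK_low only
    B[hyper_idx[:, None], np.flatnonzero(~is_high)[None, :]] = np.minimum(
        centers[hyper_idx, None] * 0.5 + spec.hyper_delta_beta + 0.25, 0.97)
    # marker-tracking probes follow ALK log2 expression across all samples
    alk_log2 = np.log2(fpkm[gi["ALK"]] + 1.0)
    alk_c = (alk_log2 - alk_log2.mean()) / max(alk_log2.std(), 1e-9)
    sign = np.ones(spec.n_marker_tracking_probes)
    sign[spec.n_marker_tracking_probes // 2:] = -1.0
    B[marker_idx, :] = 0.5 + 0.18 * sign[:, None] * alk_c[None, :]
    # heteroscedastic beta noise: EPIC-style arrays are far less noisy near
    # fully (un)methylated probes, roughly constant on the M scale
    scale = np.maximum(spec.meth_noise_sd * 4.0 * B * (1.0 - B), 0.005)
    noise = rng.normal(0.0, 1.0, size=B.shape) * scale
    noise[marker_idx, :] = rng.normal(0.0, 0.03,
                                      size=(marker_idx.size, n_samples))
    B = np.clip(B + noise, 1e-3, 1 - 1e-3)
    methylation = OmicsMatrix(pd.DataFrame(B, index=probes, columns=samples),
                              "beta")

    # ---- metadata, survival, CN ----------------------------------------
    tumor_fraction = rng.uniform(0.45, 1.0, size=n_samples)
    low_pur = rng.random(n_samples) < spec.frac_low_purity
    tumor_fraction[low_pur] = rng.uniform(0.15, 0.40, size=int(low_pur.sum()))
    hazard = spec.base_hazard * np.where(is_eventual, spec.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor = rng.uniform(*spec.censor_range, size=n_samples)
    observed = np.minimum(event_time, censor)
    event = (event_time <= censor).astype(float)
    cn_p = np.where(is_high, spec.cn_prob_high, spec.cn_prob_low)
    cn = rng.random(n_samples) < cn_p
    histology = rng.choice(["common", "LH", "SCV"], size=n_samples,
                           p=[0.85, 0.08, 0.07])
    meta = pd.DataFrame({
        "timepoint": ["diagnosis"] * nd + ["relapse"] * nr,
        "tumor_fraction": tumor_fraction,
        "survival_time": observed,
        "event": event,
        "histology": histology,
        "cn_altered": np.where(cn, "true", "false"),
    }, index=pd.Index(samples, name="sample_id"))
    meta.loc[rel_ids, ["survival_time", "event"]] = np.nan
    meta.loc[rel_ids, "cn_altered"] = "unknown"
    metadata = CohortMetadata(meta)

    # ---- CN segments / mutations (carrier tables) ----------------------
    seg_rows = []
    for i, s in enumerate(samples):
        if cn[i]:
            for _ in range(int(rng.integers(1, 4))):
                c = rng.choice([f"chr{j}" for j in range(1, 23)])
                start = int(rng.integers(1, 1_000_000_00))
                end = start + int(rng.integers(1_000_000, 3_000_000_0))
                call = rng.choice(["gain", "loss"])
                lr = float(rng.normal(0.6 if call == "gain" else -0.7, 0.1))
                seg_rows.append((s, c, start, end, lr, call))
        else:
            seg_rows.append((s, "chr1", 1, 249_000_000, 0.0, "neutral"))
    segments = SegmentTable(pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start", "end",
                           "log2_ratio", "call"]))
    mut_rows = []
    for s in samples:
        for _ in range(int(rng.poisson(2.0))):
            g = genes[int(rng.integers(0, spec.n_genes))]
            mut_rows.append((s, g, f"p.A{int(rng.integers(1, 500))}V",
                             rng.choice(["missense", "nonsense", "frameshift"]),
                             float(rng.uniform(0.05, 0.6))))
    if not mut_rows:
        mut_rows.append((samples[0], genes[0], "p.A1V", "missense", 0.3))
    mutations = MutationTable(pd.DataFrame(
        mut_rows, columns=["sample_id", "gene", "protein_change",
                           "variant_class", "vaf"]))

    truth = {
        "group": dict(zip(samples, group)),
        "eventual_relapsers": [samples[i] for i in eventual],
        "immune_genes": immune,
        "proliferation_genes": prolif,
        "relapse_genes": relapse_genes,
        "hyper_probes": [probes[i] for i in hyper_idx],
        "marker_probes_positive": [probes[i] for i in
                                   marker_idx[:spec.n_marker_tracking_probes // 2]],
        "marker_probes_negative": [probes[i] for i in
                                   marker_idx[spec.n_marker_tracking_probes // 2:]],
        "cn_altered": dict(zip(samples, (bool(x) for x in cn))),
    }
    return SyntheticCohort(expression, methylation, manifest, metadata,
                           segments, mutations, truth, spec)


def program_library(cohort: SyntheticCohort) -> GeneSetLibrary:
    """Gene-set library of the planted programs (for scoring and GSEA)."""
    t = cohort.truth
    return GeneSetLibrary({
        "IMMUNE_PROGRAM": ("planted immune program", list(t["immune_genes"])),
        "PROLIFERATION_PROGRAM": ("planted proliferation program",
                                  list(t["proliferation_genes"])),
        "RELAPSE_PROGRAM": ("planted relapse program", list(t["relapse_genes"])),
    })


COHORT_FILES = ("expression.tsv", "methylation.tsv", "manifest.tsv",
                "metadata.tsv", "segments.tsv", "mutations.tsv",
                "truth.json", "spec.json")


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write every pipeline input plus the truth/spec sidecars; truth files
    are for evaluation only and are never read by analysis stages."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {name: d / name for name in COHORT_FILES}
    io.write_matrix(cohort.expression, paths["expression.tsv"])
    io.write_matrix(cohort.methylation, paths["methylation.tsv"])
    io.write_manifest(cohort.manifest, paths["manifest.tsv"])
    io.write_metadata(cohort.metadata, paths["metadata.tsv"])
    io.write_segments(cohort.segments, paths["segments.tsv"])
    io.write_mutations(cohort.mutations, paths["mutations.tsv"])
    with open(paths["truth.json"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    with open(paths["spec.json"], "w") as fh:
        json.dump(dataclasses.asdict(cohort.spec), fh, indent=1, default=list)
    return {k: str(v) for k, v in paths.items()}
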