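"""EPIC-style methylation processing.

Beta values (methylation fraction per probe) are converted to M-values
M = log2(beta / (1 - beta)) for testing and clustering; effect sizes are
reported as delta-beta for interpretability.  Probes on the sex chromosomes
or overlapping common SNPs (VAF > 0.01) are removed before analysis, as are
samples with low tumor content.  Differential methylation is probe-level
(Wilcoxon rank-sum on M-values, BH-adjusted) summarized by genomic region
class; probe methylation is screened against ALK expression by Spearman
correlation at |rho| >= 0.75.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import OmicsMatrix, ProbeManifest, CohortMetadata, \
    ValidationError, REGION_CLASSES
from .stats_core import benjamini_hochberg, dip_statistic, spearman_rho, \
    wilcoxon_rank_sum, UndefinedStatisticError

log = logging.getLogger("alclomics")


def beta_to_m(beta_matrix: OmicsMatrix, epsilon: float = 1e-6) -> OmicsMatrix:
    """M = log2(beta / (1 - beta)) after clamping beta to [eps, 1 - eps]."""
    if beta_matrix.value_kind != "beta":
        raise ValidationError("beta_to_m expects a beta matrix")
    b = beta_matrix.data.clip(lower=epsilon, upper=1.0 - epsilon)
    return OmicsMatrix(np.log2(b / (1.0 - b)), "m_value")


def m_to_beta(m_matrix: OmicsMatrix) -> OmicsMatrix:
    """Inverse logistic: beta = 2^M / (1 + 2^M)."""
    if m_matrix.value_kind != "m_value":
        raise ValidationError("m_to_beta expects an M-value matrix")
    e = np.exp2(m_matrix.data)
    return OmicsMatrix(e / (1.0 + e), "beta")


def filter_probes(beta_matrix: OmicsMatrix, manifest: ProbeManifest,
                  snp_vaf_cut: float = 0.01):
    """Drop chrX/chrY probes and probes with SNP VAF strictly above the cut."""
    probes = beta_matrix.feature_ids
    missing = [p for p in probes if p not in manifest.table.index]
    if missing:
        raise ValidationError(f"probes absent from manifest: {missing[:5]}")
    ann = manifest.table.loc[probes]
    on_xy = ann["chrom"].isin(["chrX", "chrY"]).to_numpy()
    snp = (ann["snp_vaf"].to_numpy(float) > snp_vaf_cut) & ~on_xy
    keep = ~(on_xy | snp)
    report = {
        "n_input": len(probes),
        "removed_chrXY": int(on_xy.sum()),
        "removed_snp": int(snp.sum()),
        "n_retained": int(keep.sum()),
    }
    kept = [p for p, k in zip(probes, keep) if k]
    log.info("probe filter: %s", report)
    return beta_matrix.subset(features=kept), report


def filter_samples_by_purity(matrix: OmicsMatrix, metadata: CohortMetadata,
                             min_fraction: float = 0.40):
    """Drop samples with tumor fraction strictly below the cut; samples with
    missing fraction are retained with a warning."""
    keep, removed, unknown = [], [], []
    for s in matrix.sample_ids:
        if s not in metadata.table.index:
            raise ValidationError(f"sample {s!r} absent from metadata")
        tf = metadata.table.loc[s, "tumor_fraction"]
        if pd.isna(tf):
            unknown.append(s)
            keep.append(s)
        elif float(tf) < min_fraction:
            removed.append(s)
        else:
            keep.append(s)
    if unknown:
        log.warning("purity filter: missing tumor fraction for %s (retained)",
                    unknown)
    report = {"removed": removed, "retained_missing_fraction": unknown,
              "n_retained": len(keep)}
    log.info("purity filter: removed %d of %d samples", len(removed),
             len(matrix.sample_ids))
    return matrix.subset(samples=keep), report


def differential_methylation(m_matrix: OmicsMatrix, beta_matrix: OmicsMatrix,
                             group_a, group_b, q_cut: float = 0.05,
                             manifest: ProbeManifest | None = None) -> pd.DataFrame:
    """Per-probe Wilcoxon rank-sum on M-values with BH adjustment.

    delta_beta is the mean beta difference (group_a minus group_b); a probe
    is hyper(methylated in group_a) when q < q_cut and delta_beta > 0.
    """
    if m_matrix.feature_ids != beta_matrix.feature_ids:
        raise ValidationError("M and beta matrices carry different probe sets")
    if set(group_a) & set(group_b):
        raise ValidationError("groups overlap")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValidationError("each group needs >= 3 samples")
    Ma = m_matrix.subset(samples=group_a).values
    Mb = m_matrix.subset(samples=group_b).values
    Ba = beta_matrix.subset(samples=group_a).values
    Bb = beta_matrix.subset(samples=group_b).values
    n = len(group_a) + len(group_b)
    mode = "exact" if n <= 20 else "normal_approx"
    p = np.array([wilcoxon_rank_sum(Ma[i], Mb[i], mode=mode).p_value
                  for i in range(Ma.shape[0])])
    q = benjamini_hochberg(p)
    delta = Ba.mean(axis=1) - Bb.mean(axis=1)
    direction = np.where((q < q_cut) & (delta > 0), "hyper",
                         np.where((q < q_cut) & (delta < 0), "hypo", "ns"))
    out = pd.DataFrame({
        "probe_id": m_matrix.feature_ids,
        "delta_beta": delta, "p": p, "q": q, "direction": direction,
    }).set_index("probe_id")
    if manifest is not None:
        out["region_class"] = manifest.table.loc[out.index, "region_class"].to_numpy()
    log.info("differential methylation: %d probes, %d hyper, %d hypo",
             len(out), int((direction == "hyper").sum()),
             int((direction == "hypo").sum()))
    return out


def summarize_regions(dmp: pd.DataFrame, manifest: ProbeManifest) -> pd.DataFrame:
    """Hyper/hypo DMP counts per genomic region class; conserves call totals."""
    region = manifest.table.reindex(dmp.index)["region_class"]
    if region.isna().any():
        bad = dmp.index[region.isna()].tolist()
        raise ValidationError(f"probes without annotation: {bad[:5]}")
    unknown = set(region) - set(REGION_CLASSES)
    if unknown:
        raise ValidationError(f"unknown region classes: {sorted(unknown)}")
    rows = []
    for cls in REGION_CLASSES:
        sel = dmp[region.to_numpy() == cls]
        rows.append((cls, int((sel["direction"] == "hyper").sum()),
                     int((sel["direction"] == "hypo").sum())))
    return pd.DataFrame(rows, columns=["region_class", "n_hyper", "n_hypo"]
                        ).set_index("region_class")


def beta_profile(beta_matrix: OmicsMatrix, group_labels: pd.Series,
                 n_bins: int = 50, mid=(0.33, 0.66),
                 dip_max_points: int = 2000) -> dict:
    """Pooled per-group beta histogram, fraction in the intermediate range,
    and dip statistic of the pooled betas as a bimodality index.

    The dip is evaluated on a deterministic quantile grid of at most
    ``dip_max_points`` values; the discretization error (~1/grid size) is
    far below the bimodality contrasts of interest.
    """
    out = {}
    for grp in pd.unique(group_labels):
        samples = group_labels.index[group_labels == grp].tolist()
        if not samples:
            raise ValidationError(f"group {grp!r} is empty")
        vals = beta_matrix.subset(samples=samples).values.ravel()
        vals = vals[np.isfinite(vals)]
        hist, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
        frac_mid = float(np.mean((vals > mid[0]) & (vals < mid[1])))
        dip_vals = vals
        if dip_vals.size > dip_max_points:
            dip_vals = np.quantile(dip_vals,
                                   np.linspace(0.0, 1.0, dip_max_points))
        out[grp] = {
            "histogram": hist,
            "bin_edges": edges,
            "fraction_mid": frac_mid,
            "dip": dip_statistic(dip_vals) if np.unique(dip_vals).size > 1 else 0.0,
        }
    return out


def correlate_with_expression(m_matrix: OmicsMatrix,
                              expression_matrix: OmicsMatrix,
                              manifest: ProbeManifest,
                              marker_gene: str = "ALK",
                              rho_cut: float = 0.75):
    """Spearman correlation of each probe with marker expression.

    Returns the per-probe record table and the deduplicated positively /
    negatively correlated gene lists for over-representation analysis.
    Probes with constant methylation across the shared samples have no
    defined correlation and are reported with rho = NaN, never selected.
    """
    if marker_gene not in expression_matrix.data.index:
        raise ValidationError(f"marker gene {marker_gene!r} absent from expression")
    shared = [s for s in m_matrix.sample_ids
              if s in set(expression_matrix.sample_ids)]
    if len(shared) < 5:
        raise ValidationError(f"only {len(shared)} shared samples; need >= 5")
    marker = expression_matrix.data.loc[marker_gene, shared].to_numpy(float)
    M = m_matrix.subset(samples=shared)
    rhos = np.full(len(M.feature_ids), np.nan)
    for i, row in enumerate(M.values):
        try:
            rhos[i] = spearman_rho(row, marker)
        except UndefinedStatisticError:
            pass
    genes = manifest.table.reindex(M.feature_ids)["gene"].fillna("").to_numpy()
    selected = np.abs(rhos) >= rho_cut
    selected &= np.isfinite(rhos)
    records = pd.DataFrame({
        "probe_id": M.feature_ids,
        "rho": rhos,
        "selected": selected,
        "sign": np.where(rhos >= 0, "positive", "negative"),
        "gene": genes,
    }).set_index("probe_id")
    pos = list(dict.fromkeys(
        g for g in genes[selected & (rhos > 0)] if g))
    neg = list(dict.fromkeys(
        g for g in genes[selected & (rhos < 0)] if g))
    log.info("probe-%s correlation: %d probes, %d selected (%d pos / %d neg genes)",
             marker_gene, len(records), int(selected.sum()), len(pos), len(neg))
    return records, pos, neg
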