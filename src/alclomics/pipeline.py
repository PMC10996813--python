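"""End-to-end orchestration of the analysis stages on an on-disk cohort.

Consumes the file set a cohort directory provides (expression FPKM matrix,
methylation beta matrix, probe manifest, sample metadata) and runs:
expression consensus clustering with ALK labeling, methylation consensus
clustering, cross-platform concordance and final labels, CN enrichment,
differential expression and methylation, the probe-ALK correlation screen,
relapse-signature scoring with median dichotomization, and the survival
comparison of score strata.  Every stage writes its tables plus a JSON
summary under the output directory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import expression_analysis as ex
from . import integration as integ
from . import io_formats as io
from . import methylation_analysis as meth
from . import subtype_clustering as sub

log = logging.getLogger("alclomics")

DEFAULTS = dict(
    feature_counts=(250, 500, 1000, 2000, 4000),
    bootstrap=1000,
    seed=0,
    marker="ALK",
    min_purity=0.40,
    rho_cut=0.75,
    lfc_cut=1.0,
    q_cut=0.05,
)


def run_pipeline(expression_path, methylation_path, manifest_path,
                 metadata_path, out_dir, **params) -> dict:
    cfg = {**DEFAULTS, **params}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    counts = tuple(int(c) for c in cfg["feature_counts"])

    expr_fpkm = io.read_matrix(expression_path, "fpkm")
    beta = io.read_matrix(methylation_path, "beta")
    manifest = io.read_manifest(manifest_path)
    metadata = io.read_metadata(metadata_path)
    meta = metadata.table
    diag = [s for s in expr_fpkm.sample_ids
            if meta.loc[s, "timepoint"] == "diagnosis"]
    rel = [s for s in expr_fpkm.sample_ids
           if meta.loc[s, "timepoint"] == "relapse"]
    log2 = ex.to_log2(expr_fpkm)

    # --- expression subgrouping (diagnosis samples only) -----------------
    rna_out = sub.run_consensus_clustering(
        log2.subset(samples=diag), feature_counts=counts,
        B=int(cfg["bootstrap"]), seed=seed, marker_gene=cfg["marker"])
    rna_labels = rna_out.marker_label
    rna_labels.rename_axis("sample_id").to_csv(out / "rna_labels.tsv", sep="\t")

    # --- methylation subgrouping ----------------------------------------
    beta_f, probe_report = meth.filter_probes(beta, manifest)
    beta_d, purity_report = meth.filter_samples_by_purity(
        beta_f.subset(samples=[s for s in beta_f.sample_ids if s in diag]),
        metadata, float(cfg["min_purity"]))
    mvals = meth.beta_to_m(beta_d)
    meth_out = sub.run_consensus_clustering(
        mvals, feature_counts=counts, B=int(cfg["bootstrap"]), seed=seed + 1,
        marker_gene=None)
    meth_labels, _ = sub.label_by_marker(
        meth_out.consensus_label, log2.subset(samples=mvals.sample_ids),
        cfg["marker"])
    meth_labels.rename_axis("sample_id").to_csv(out / "meth_labels.tsv",
                                                sep="\t")

    # --- integration ------------------------------------------------------
    conc = integ.concordance(rna_labels, meth_labels)
    conc.final_label.rename_axis("sample_id").to_csv(
        out / "final_labels.tsv", sep="\t")
    try:
        cn, cn_fisher = integ.cn_enrichment(metadata, conc.final_label)
    except io.ValidationError as exc:
        log.warning("skipping CN enrichment: %s", exc)
        cn = cn_fisher = None

    # --- differential expression -----------------------------------------
    high = [s for s in diag if conc.final_label.get(s) == "ALK_high"]
    low = [s for s in diag if conc.final_label.get(s) == "ALK_low"]
    de_table = None
    n_up = n_down = None
    if len(high) >= 2 and len(low) >= 2:
        de_table, (n_up, n_down) = ex.differential_expression(
            log2.subset(samples=diag), high, low,
            lfc_cut=float(cfg["lfc_cut"]), q_cut=float(cfg["q_cut"]))
        de_table.to_csv(out / "differential_expression.tsv", sep="\t")
    else:
        log.warning("skipping differential expression: group sizes %d/%d",
                    len(high), len(low))

    # --- differential methylation ----------------------------------------
    m_low = [s for s in mvals.sample_ids if conc.final_label.get(s) == "ALK_low"]
    m_high = [s for s in mvals.sample_ids if conc.final_label.get(s) == "ALK_high"]
    dmp = regions = None
    profile = {}
    if len(m_low) >= 3 and len(m_high) >= 3:
        dmp = meth.differential_methylation(mvals, beta_d, m_low, m_high,
                                            manifest=manifest)
        dmp.to_csv(out / "dmp.tsv", sep="\t")
        regions = meth.summarize_regions(dmp, manifest)
        regions.to_csv(out / "dmp_regions.tsv", sep="\t")
        profile = meth.beta_profile(
            beta_d, conc.final_label[[s for s in beta_d.sample_ids
                                      if conc.final_label.get(s) in integ.DEFINITE]])
    else:
        log.warning("skipping differential methylation: group sizes %d/%d",
                    len(m_low), len(m_high))

    # --- probe-marker correlation ----------------------------------------
    corr, pos_genes, neg_genes = meth.correlate_with_expression(
        mvals, log2, manifest, marker_gene=cfg["marker"],
        rho_cut=float(cfg["rho_cut"]))
    corr.to_csv(out / "probe_marker_correlation.tsv", sep="\t")

    # --- relapse signature and survival ----------------------------------
    signature = ex.derive_relapse_signature(log2, rel, diag) if len(rel) >= 2 \
        else None
    survival = None
    scorecard = None
    if signature is not None and signature.genes:
        io.write_gmt(signature.as_library(), out / "relapse_signature.gmt")
        scores = ex.ssgsea_score(log2, signature.genes)
        scorecard = ex.dichotomize_by_median(scores, diag)
        scorecard.rename_axis("sample_id").to_csv(out / "relapse_scores.tsv",
                                                  sep="\t")
        survival = integ.survival_by_stratum(
            metadata, scorecard.loc[diag, "stratum"])

    summary = dict(
        seed=seed,
        n_diagnosis=len(diag), n_relapse=len(rel),
        probe_filter=probe_report, purity_filter={
            "n_removed": len(purity_report["removed"]),
            "removed": purity_report["removed"]},
        concordance={"n_shared": conc.n_shared,
                     "n_concordant": conc.n_concordant,
                     "fraction": round(conc.fraction, 4),
                     "fisher_p": conc.fisher.p_value},
        cn_enrichment={"fractions": {k: round(v, 4)
                                     for k, v in cn["fractions"].items()},
                       "fisher_p": cn_fisher.p_value}
        if cn is not None else None,
        differential_expression={"n_up": n_up, "n_down": n_down}
        if de_table is not None else None,
        differential_methylation={
            "n_hyper": int((dmp.direction == "hyper").sum()),
            "n_hypo": int((dmp.direction == "hypo").sum())}
        if dmp is not None else None,
        beta_profile={str(k): {"dip": v["dip"],
                               "fraction_mid": round(v["fraction_mid"], 4)}
                      for k, v in profile.items()},
        correlation_screen={"n_selected": int(corr.selected.sum()),
                            "n_pos_genes": len(pos_genes),
                            "n_neg_genes": len(neg_genes)},
        relapse_signature={"n_genes": len(signature.genes)}
        if signature is not None else None,
        survival={"logrank_p": survival["test"].p_value}
        if survival is not None else None,
    )
    io.write_run_summary(out / "pipeline_summary.json", "pipeline", **summary)
    return {"summary": summary, "final_labels": conc.final_label,
            "de": de_table, "dmp": dmp, "regions": regions,
            "correlation": corr, "scorecard": scorecard,
            "rna_labels": rna_labels, "meth_labels": meth_labels}
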