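"""Differential expression, gene-set scoring and relapse-risk stratification.

Expression enters as FPKM and is log2(FPKM + 1) transformed before any
statistic.  Differential calls use the empirical-Bayes moderated t with BH
adjustment.  The relapse signature is the gene set up-regulated in relapse
versus diagnosis samples (raw p < 0.01, log2FC > 1, q < 0.25); each sample's
relapse score is its ssGSEA enrichment for that set, dichotomized at the
median score of the diagnosis samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GeneSetLibrary, OmicsMatrix, ValidationError
from .stats_core import benjamini_hochberg, moderated_t, signal_to_noise

log = logging.getLogger("alclomics")


def to_log2(matrix: OmicsMatrix, pseudocount: float = 1.0) -> OmicsMatrix:
    """log2(FPKM + pseudocount) transform."""
    if matrix.value_kind == "log2_expression":
        return matrix
    if matrix.value_kind != "fpkm":
        raise ValidationError(f"cannot log-transform value_kind {matrix.value_kind}")
    return OmicsMatrix(np.log2(matrix.data + pseudocount), "log2_expression")


@dataclass
class SignatureResult:
    name: str
    genes: list[str]
    params: dict
    table: pd.DataFrame

    def as_library(self) -> GeneSetLibrary:
        desc = ";".join(f"{k}={v}" for k, v in self.params.items())
        if not self.genes:
            raise ValidationError("empty signature cannot become a gene set")
        return GeneSetLibrary({self.name: (desc, list(self.genes))})


def _group_indices(matrix: OmicsMatrix, group_a, group_b):
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)[:5]}")
    pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    missing = [s for s in list(group_a) + list(group_b) if s not in pos]
    if missing:
        raise ValidationError(f"samples absent from matrix: {missing[:5]}")
    return (np.array([pos[s] for s in group_a]),
            np.array([pos[s] for s in group_b]))


def differential_expression(matrix: OmicsMatrix, group_a, group_b,
                            lfc_cut: float = 1.0, q_cut: float = 0.05):
    """Moderated-t differential expression (group_a minus group_b).

    Returns a per-feature table (log2fc, statistic, p, q, direction) and the
    (n_up, n_down) call counts at the given log2FC and FDR cutoffs.
    """
    if matrix.value_kind != "log2_expression":
        raise ValidationError("differential_expression expects log2 expression")
    ia, ib = _group_indices(matrix, group_a, group_b)
    log2fc, t, p, _, prior = moderated_t(matrix.values, ia, ib)
    q = benjamini_hochberg(p)
    direction = np.where((log2fc > lfc_cut) & (q < q_cut), "up",
                         np.where((log2fc < -lfc_cut) & (q < q_cut), "down", "ns"))
    table = pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "log2fc": log2fc, "statistic": t, "p": p, "q": q,
        "direction": direction,
    }).set_index("feature_id")
    n_up = int((direction == "up").sum())
    n_down = int((direction == "down").sum())
    log.info("differential expression: %d features, %d up, %d down (d0=%.3g)",
             len(table), n_up, n_down, prior.d0)
    return table, (n_up, n_down)


def derive_relapse_signature(matrix: OmicsMatrix, relapse_ids, diagnosis_ids,
                             p_cut: float = 0.01, lfc_cut: float = 1.0,
                             q_cut: float = 0.25,
                             name: str = "RELAPSE_UP") -> SignatureResult:
    """Genes up-regulated in relapse vs diagnosis samples (conjunctive rule:
    raw p < p_cut AND log2fc > lfc_cut AND BH q < q_cut)."""
    if len(relapse_ids) < 2 or len(diagnosis_ids) < 2:
        raise ValidationError("need >= 2 relapse and >= 2 diagnosis samples")
    table, _ = differential_expression(matrix, relapse_ids, diagnosis_ids,
                                       lfc_cut=lfc_cut, q_cut=q_cut)
    hit = (table["p"] < p_cut) & (table["log2fc"] > lfc_cut) & (table["q"] < q_cut)
    genes = table.index[hit].tolist()
    params = {"p_cut": p_cut, "lfc_cut": lfc_cut, "q_cut": q_cut,
              "n_relapse": len(relapse_ids), "n_diagnosis": len(diagnosis_ids)}
    if not genes:
        warnings.warn("relapse signature is empty under the given thresholds")
    return SignatureResult(name, genes, params, table)


def ssgsea_score(matrix: OmicsMatrix, gene_set, alpha: float = 0.75,
                 normalize: bool = False) -> pd.Series:
    """Single-sample GSEA enrichment score per sample.

    Genes are ranked ascending by expression within each sample (average
    ranks for ties); walking the list from the highest-expressed gene down,
    the score accumulates the gap between the in-set ECDF weighted by
    rank^alpha and the unweighted out-of-set ECDF.  Rank-based, hence
    invariant to per-sample monotone transforms.
    """
    genes = [g for g in dict.fromkeys(gene_set) if g in matrix.data.index]
    n_feat = len(matrix.feature_ids)
    if not genes:
        raise ValidationError("gene set does not intersect the matrix features")
    if len(genes) == n_feat:
        raise ValidationError("gene set covers every feature; score undefined")
    in_set = np.isin(np.array(matrix.feature_ids), np.array(genes))
    X = matrix.values
    scores = {}
    n_out = n_feat - in_set.sum()
    for j, sample in enumerate(matrix.sample_ids):
        col = X[:, j]
        ranks = sps.rankdata(col)               # ascending: top gene gets n
        order = np.argsort(-ranks, kind="mergesort")
        inset_o = in_set[order]
        w = ranks[order] ** alpha
        w_in = np.where(inset_o, w, 0.0).cumsum()
        denom_in = w_in[-1]
        ecdf_in = w_in / denom_in
        ecdf_out = np.where(~inset_o, 1.0, 0.0).cumsum() / n_out
        scores[sample] = float((ecdf_in - ecdf_out).sum())
    s = pd.Series(scores, name="ssgsea")
    if normalize:
        rng_ = s.max() - s.min()
        if rng_ > 0:
            s = (s - s.min()) / rng_
    return s


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    leading_edge: list[str]


def _enrichment_score(ranked_genes, weights, set_mask):
    """Weighted Kolmogorov-Smirnov running-sum ES and its peak position."""
    n = len(ranked_genes)
    n_in = int(set_mask.sum())
    if n_in == 0 or n_in == n:
        raise ValidationError("gene set must be a non-trivial subset of ranked genes")
    w = np.abs(weights) * set_mask
    denom = w.sum()
    if denom == 0:
        w = set_mask.astype(float)
        denom = w.sum()
    step_in = w / denom
    step_out = (~set_mask).astype(float) / (n - n_in)
    running = np.cumsum(step_in - step_out)
    i_peak = int(np.argmax(np.abs(running)))
    return float(running[i_peak]), i_peak


def gsea(matrix: OmicsMatrix, group_a, group_b, library: GeneSetLibrary,
         n_perm: int = 1000, seed=None) -> list[GseaResult]:
    """Two-group GSEA: signal-to-noise ranking, weighted running-sum ES,
    phenotype-permutation null, NES by same-sign null mean, pooled FDR."""
    if matrix.value_kind != "log2_expression":
        raise ValidationError("gsea expects log2 expression")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValidationError(
            "phenotype permutation needs >= 3 samples per group; "
            "gene-set permutation is not supported")
    ia, ib = _group_indices(matrix, group_a, group_b)
    rng = np.random.default_rng(seed)
    X = matrix.values
    feats = np.array(matrix.feature_ids)
    set_masks = {}
    for name in library.sets:
        mask = np.isin(feats, np.array(library.genes(name)))
        set_masks[name] = mask

    def scores_for(idx_a, idx_b):
        s2n = signal_to_noise(X, idx_a, idx_b)
        order = np.argsort(-s2n, kind="mergesort")
        out = {}
        for name, mask in set_masks.items():
            out[name] = _enrichment_score(feats[order], s2n[order], mask[order])
        return out, order, s2n

    obs, order, s2n = scores_for(ia, ib)
    pooled = np.concatenate([ia, ib])
    null_es = {name: np.empty(n_perm) for name in set_masks}
    for b in range(n_perm):
        perm = rng.permutation(pooled)
        pa, pb = perm[:ia.size], perm[ia.size:]
        null, _, _ = scores_for(pa, pb)
        for name in set_masks:
            null_es[name][b] = null[name][0]

    def nes_of(es, null):
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same).mean() if same.size else np.nan
        return es / denom if denom and np.isfinite(denom) else np.nan

    results = []
    all_null_nes = []
    obs_nes = {}
    for name in set_masks:
        es, _ = obs[name]
        obs_nes[name] = nes_of(es, null_es[name])
        same = null_es[name][np.sign(null_es[name]) == np.sign(es)]
        denom = np.abs(same).mean() if same.size else np.nan
        if denom and np.isfinite(denom):
            all_null_nes.append(null_es[name] / denom)
        else:
            all_null_nes.append(null_es[name])
    all_null_nes = np.concatenate(all_null_nes)
    obs_nes_arr = np.array(list(obs_nes.values()))
    for name in set_masks:
        es, i_peak = obs[name]
        mask_o = set_masks[name][order]
        if es >= 0:
            lead = feats[order][: i_peak + 1][mask_o[: i_peak + 1]].tolist()
        else:
            lead = feats[order][i_peak:][mask_o[i_peak:]].tolist()
        null = null_es[name]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        n_extreme = int((np.abs(same) >= abs(es)).sum())
        nominal_p = (1 + n_extreme) / (1 + max(same.size, 1))
        nes = obs_nes[name]
        if np.isfinite(nes):
            if nes >= 0:
                num = np.mean(all_null_nes >= nes)
                den = np.mean(obs_nes_arr[np.isfinite(obs_nes_arr)] >= nes)
            else:
                num = np.mean(all_null_nes <= nes)
                den = np.mean(obs_nes_arr[np.isfinite(obs_nes_arr)] <= nes)
            fdr = float(min(1.0, num / den)) if den > 0 else 1.0
        else:
            fdr = 1.0
        results.append(GseaResult(name, es, float(nes), float(nominal_p),
                                  fdr, lead))
    results.sort(key=lambda r: -abs(r.nes) if np.isfinite(r.nes) else 0)
    return results


def dichotomize_by_median(scores: pd.Series, reference_ids) -> pd.DataFrame:
    """HIGH/LOW strata at the median score of the reference (diagnosis)
    samples; scores exactly at the median are LOW."""
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ValidationError("empty reference for median dichotomization")
    missing = set(reference_ids) - set(scores.index)
    if missing:
        raise ValidationError(f"reference samples without scores: {sorted(missing)[:5]}")
    med = float(scores[reference_ids].median())
    return pd.DataFrame({
        "score": scores,
        "stratum": np.where(scores > med, "HIGH", "LOW"),
        "reference_median": med,
    })


def program_score(matrix: OmicsMatrix, library: GeneSetLibrary,
                  programs) -> pd.DataFrame:
    """ssGSEA score per sample for each named program, plus their mean as a
    summary (immune-style) score."""
    programs = list(dict.fromkeys(programs))
    unknown = [p for p in programs if p not in library]
    if unknown:
        raise ValidationError(f"unknown program(s): {unknown}")
    cols = {}
    for p in programs:
        cols[p] = ssgsea_score(matrix, library.genes(p))
    out = pd.DataFrame(cols)
    out["program_mean"] = out[programs].mean(axis=1)
    return out
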