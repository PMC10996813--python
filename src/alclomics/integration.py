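"""Cross-platform integration: concordance of expression- and
methylation-based subgroup labels, copy-number enrichment, local
over-representation analysis over user-supplied GMT libraries, and
Kaplan-Meier / log-rank comparison of derived strata."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import CohortMetadata, GeneSetLibrary, ValidationError
from .stats_core import TestResult, benjamini_hochberg, fisher_exact_2x2, \
    km_estimate, logrank_test

log = logging.getLogger("alclomics")

DEFINITE = ("ALK_high", "ALK_low")


@dataclass
class ConcordanceReport:
    n_shared: int                   # shared samples with definite labels on both
    n_concordant: int
    fraction: float
    fisher: TestResult
    final_label: pd.Series          # over the union of platform samples
    crosstab: pd.DataFrame


def concordance(labels_rna: pd.Series, labels_meth: pd.Series) -> ConcordanceReport:
    """Agreement of the two platform label vectors.

    The 2x2 Fisher test and the concordance fraction use samples carrying a
    definite (non-unclassifiable) label on both platforms.  Final labels:
    concordant platform label, else a single available platform's label,
    else unclassifiable.
    """
    shared = [s for s in labels_rna.index if s in set(labels_meth.index)]
    both_definite = [s for s in shared
                     if labels_rna[s] in DEFINITE and labels_meth[s] in DEFINITE]
    if not both_definite:
        raise ValidationError("no shared samples with definite labels on both platforms")
    r = labels_rna[both_definite]
    m = labels_meth[both_definite]
    n_conc = int((r.to_numpy() == m.to_numpy()).sum())
    tab = np.zeros((2, 2), int)
    for i, a in enumerate(DEFINITE):
        for j, b in enumerate(DEFINITE):
            tab[i, j] = int(((r == a) & (m == b)).sum())
    fisher = fisher_exact_2x2(*tab.ravel())
    union = list(dict.fromkeys(list(labels_rna.index) + list(labels_meth.index)))
    final = {}
    for s in union:
        lr = labels_rna.get(s)
        lm = labels_meth.get(s)
        have_r = lr in DEFINITE
        have_m = lm in DEFINITE
        if s in set(shared):
            final[s] = lr if (have_r and have_m and lr == lm) else "unclassifiable"
        elif have_r:
            final[s] = lr
        elif have_m:
            final[s] = lm
        else:
            final[s] = "unclassifiable"
    crosstab = pd.DataFrame(tab, index=[f"rna_{x}" for x in DEFINITE],
                            columns=[f"meth_{x}" for x in DEFINITE])
    report = ConcordanceReport(
        n_shared=len(both_definite),
        n_concordant=n_conc,
        fraction=n_conc / len(both_definite),
        fisher=fisher,
        final_label=pd.Series(final, name="final_label"),
        crosstab=crosstab,
    )
    log.info("concordance: %d/%d (%.1f%%), Fisher p=%.3g", n_conc,
             len(both_definite), 100 * report.fraction, fisher.p_value)
    return report


def cn_enrichment(metadata: CohortMetadata, final_labels: pd.Series):
    """Copy-number-alteration fraction per subgroup and a two-sided Fisher
    test on the altered/unaltered x group table; unknown CN status excluded."""
    counts = {}
    excluded = []
    for grp in DEFINITE:
        samples = [s for s in final_labels.index if final_labels[s] == grp]
        altered = unaltered = 0
        for s in samples:
            status = metadata.table.loc[s, "cn_altered"] \
                if s in metadata.table.index else "unknown"
            if status == "true":
                altered += 1
            elif status == "false":
                unaltered += 1
            else:
                excluded.append(s)
        if altered + unaltered == 0:
            raise ValidationError(f"group {grp} has no samples with known CN status")
        counts[grp] = (altered, unaltered)
    a, b = counts["ALK_high"]
    c, d = counts["ALK_low"]
    fisher = fisher_exact_2x2(a, b, c, d)
    fractions = {grp: alt / (alt + un) for grp, (alt, un) in counts.items()}
    log.info("CN enrichment: high %d/%d vs low %d/%d, p=%.3g (excluded %d unknown)",
             a, a + b, c, c + d, fisher.p_value, len(excluded))
    return {"fractions": fractions, "counts": counts,
            "n_excluded_unknown": len(excluded)}, fisher


def over_representation(gene_list, universe, library: GeneSetLibrary) -> pd.DataFrame:
    """One-sided (enrichment) Fisher/hypergeometric over-representation of a
    gene list against each library set, BH-adjusted, sorted by -log10(p)."""
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValidationError("empty universe")
    uni = set(universe)
    gene_list = list(dict.fromkeys(gene_list))
    outside = [g for g in gene_list if g not in uni]
    if outside:
        raise ValidationError(f"gene_list members outside universe: {outside[:5]}")
    if not library.sets:
        raise ValidationError("empty gene-set library")
    N = len(universe)
    n = len(gene_list)
    hits = set(gene_list)
    rows = []
    for name in library.sets:
        members = [g for g in library.genes(name) if g in uni]
        K = len(members)
        k = len(hits.intersection(members))
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, p))
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "p"])
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["neg_log10_p"] = -np.log10(np.maximum(out["p"], 1e-300))
    return out.sort_values("neg_log10_p", ascending=False).set_index("set_name")


def survival_by_stratum(metadata: CohortMetadata, strata: pd.Series):
    """Kaplan-Meier curve per stratum plus the two-group log-rank test.

    Samples with missing survival data are dropped (and reported); all-
    censored input yields flat curves and a degenerate log-rank (p = 1)."""
    levels = [l for l in pd.unique(strata) if not pd.isna(l)]
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 strata, got {levels}")
    times, events, labels, used, dropped = [], [], [], [], []
    for s, lab in strata.items():
        if s not in metadata.table.index:
            dropped.append(s)
            continue
        t = metadata.table.loc[s, "survival_time"]
        e = metadata.table.loc[s, "event"]
        if pd.isna(t) or pd.isna(e):
            dropped.append(s)
            continue
        times.append(float(t))
        events.append(int(e))
        labels.append(lab)
        used.append(s)
    times = np.array(times)
    events = np.array(events)
    labels = np.array(labels)
    curves = {}
    for lev in levels:
        sel = labels == lev
        if not sel.any():
            raise ValidationError(f"stratum {lev!r} empty after missing-data removal")
        curves[lev] = km_estimate(times[sel], events[sel])
    test = logrank_test(times, events, labels)
    if events.sum() == 0:
        log.warning("survival: no events in either stratum; log-rank degenerate")
    log.info("survival: strata %s (n=%s), logrank p=%.3g, dropped=%d",
             levels, [int((labels == l).sum()) for l in levels],
             test.p_value, len(dropped))
    return {"curves": curves, "test": test, "samples_used": used,
            "samples_dropped": dropped}
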