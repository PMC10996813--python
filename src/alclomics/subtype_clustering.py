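"""Bootstrap feature-stability consensus clustering into two subgroups.

The subgrouping procedure ranks variable features by three statistics (MAD,
variance, dip), clusters samples by correlation distance under two linkages,
sweeps the number of top features for bootstrap stability, and takes a
strict-majority consensus over the six statistic x linkage combinations.
The two consensus groups are then named by a marker gene (ALK): the cluster
with the higher median marker expression becomes ALK_high.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .io_formats import OmicsMatrix, ValidationError
from .stats_core import dip_statistics, wilcoxon_rank_sum, TestResult

log = logging.getLogger("alclomics")

STATISTICS = ("mad", "variance", "dip")
LINKAGES = ("complete", "average")
DEFAULT_FEATURE_COUNTS = (250, 500, 1000, 2000, 4000)
REFERENCE_COUNT = 1000          # assignments are anchored to the top-1000 cut


@dataclass
class SweepResult:
    selected_count: int
    assignment: pd.Series           # 0/1 per sample
    curve: pd.DataFrame             # columns: feature_count, bootstrap_probability
    stable: bool
    agrees_with_reference: bool


@dataclass
class ClusterOutcome:
    sample_ids: list[str]
    per_method_assignment: dict[tuple[str, str], pd.Series]
    bootstrap_probability: dict[tuple[str, str, int], float]
    selected_feature_count: dict[tuple[str, str], int]
    consensus_label: pd.Series      # group1 / group2 / unclassifiable
    marker_label: pd.Series | None = None
    marker_test: TestResult | None = None
    unstable_methods: list = field(default_factory=list)


# --------------------------------------------------------------------------

def rank_variable_features(matrix: OmicsMatrix, statistic: str) -> list[str]:
    """Features sorted descending by across-sample variability.

    Ties break lexicographically by feature id so rankings are reproducible.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if matrix.value_kind not in ("log2_expression", "m_value"):
        raise ValidationError(
            f"rank_variable_features expects log2_expression or m_value input, "
            f"got {matrix.value_kind}")
    X = matrix.values
    if statistic == "dip" and X.shape[1] < 4:
        raise ValidationError("dip ranking requires at least 4 samples")
    if statistic == "mad":
        med = np.median(X, axis=1, keepdims=True)
        score = np.median(np.abs(X - med), axis=1)
    elif statistic == "variance":
        score = X.var(axis=1, ddof=1)
    else:
        score = dip_statistics(X)
    order = sorted(range(len(score)),
                   key=lambda i: (-score[i], matrix.feature_ids[i]))
    return [matrix.feature_ids[i] for i in order]


def _correlation_distance(X: np.ndarray, sample_ids) -> np.ndarray:
    """1 - Pearson correlation between sample columns of X."""
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = sample_ids[int(np.argmax(sd == 0))]
        raise ValidationError(
            f"sample {bad!r} has a constant profile; correlation undefined")
    D = 1.0 - np.corrcoef(X, rowvar=False)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def hierarchical_cut(matrix: OmicsMatrix, feature_list, linkage: str,
                     k: int = 2) -> pd.Series:
    """Agglomerative clustering of samples on correlation distance, cut at k."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    if len(feature_list) < 2 or len(matrix.sample_ids) < 3:
        raise ValidationError("need >= 2 features and >= 3 samples")
    sub = matrix.subset(features=feature_list)
    D = _correlation_distance(sub.values, sub.sample_ids)
    Z = scipy_linkage(squareform(D, checks=False), method=linkage)
    labels = fcluster(Z, k, criterion="maxclust") - 1
    return pd.Series(labels, index=sub.sample_ids, name="cluster")


def _same_bipartition(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.array_equal(a, b) or np.array_equal(a, 1 - b))


def bootstrap_partition_probability(matrix: OmicsMatrix, feature_list,
                                    linkage: str, k: int = 2, B: int = 100,
                                    seed=None) -> float:
    """Fraction of feature-resampled replicates reproducing the full-data
    two-group partition (exact set-partition identity)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(feature_list) < 10:
        raise ValidationError("bootstrap needs >= 10 features")
    rng = np.random.default_rng(seed)
    sub = matrix.subset(features=feature_list)
    X = sub.values
    ref = hierarchical_cut(matrix, feature_list, linkage, k).to_numpy()
    n_feat = X.shape[0]
    hits = 0
    degenerate = 0
    for _ in range(B):
        idx = rng.integers(0, n_feat, size=n_feat)
        Xb = X[idx]
        try:
            D = _correlation_distance(Xb, sub.sample_ids)
        except ValidationError:
            degenerate += 1
            continue
        Z = scipy_linkage(squareform(D, checks=False), method=linkage)
        lab = fcluster(Z, k, criterion="maxclust") - 1
        if _same_bipartition(lab, ref):
            hits += 1
    if degenerate:
        log.warning("bootstrap: %d/%d degenerate replicates counted as non-matching",
                    degenerate, B)
    return hits / B


def _best_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """Agreement between two binary labelings under the better label mapping."""
    same = float(np.mean(a == b))
    return max(same, 1.0 - same)


def stability_sweep(matrix: OmicsMatrix, statistic: str, linkage: str,
                    feature_counts=DEFAULT_FEATURE_COUNTS, B: int = 100,
                    seed=None, support_threshold: float = 0.70,
                    ranked=None) -> SweepResult:
    """Bootstrap probability at steadily increasing feature counts; select the
    smallest count that is stable and agrees with the top-1000 assignment.

    ``ranked`` may carry a precomputed ranking for the same statistic to
    avoid recomputation across linkages.
    """
    counts = [int(c) for c in feature_counts]
    if counts != sorted(counts):
        raise ValueError("feature_counts must be increasing")
    if ranked is None:
        ranked = rank_variable_features(matrix, statistic)
    counts = [c for c in counts if c <= len(ranked)]
    if not counts:
        raise ValidationError("all feature counts exceed the number of features")
    ref_count = min(REFERENCE_COUNT, len(ranked))
    reference = hierarchical_cut(matrix, ranked[:ref_count], linkage).to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    assignments = {}
    for c in counts:
        feats = ranked[:c]
        prob = bootstrap_partition_probability(
            matrix, feats, linkage, B=B, seed=rng.integers(2 ** 31))
        assignments[c] = hierarchical_cut(matrix, feats, linkage)
        rows.append((c, prob))
    curve = pd.DataFrame(rows, columns=["feature_count", "bootstrap_probability"])
    selected = None
    agrees = False
    for c, prob in rows:
        agree = _best_agreement(assignments[c].to_numpy(), reference) >= 0.90
        if prob >= support_threshold and agree:
            selected, agrees = c, agree
            break
    if selected is None:
        c_best = int(curve.loc[curve["bootstrap_probability"].idxmax(),
                               "feature_count"])
        agrees = _best_agreement(assignments[c_best].to_numpy(), reference) >= 0.90
        return SweepResult(c_best, assignments[c_best], curve, False, agrees)
    return SweepResult(selected, assignments[selected], curve, True, agrees)


def consensus_assignment(per_method: dict) -> pd.Series:
    """Strict-majority consensus over method assignments.

    Labels are aligned to the first method by the better of the two 2x2
    mappings; a sample with no strict majority is flagged unclassifiable.
    """
    if len(per_method) < 2:
        raise ValueError("consensus needs >= 2 method assignments")
    keys = list(per_method)
    ref = per_method[keys[0]]
    samples = list(ref.index)
    aligned = []
    for key in keys:
        a = per_method[key]
        if set(a.index) != set(samples):
            raise ValidationError(f"method {key!r} covers a different sample set")
        a = a.reindex(samples).to_numpy()
        if np.mean(a == ref.to_numpy()) < 0.5:
            a = 1 - a
        aligned.append(a)
    votes = np.vstack(aligned)
    n_methods = votes.shape[0]
    ones = votes.sum(axis=0)
    labels = np.where(ones * 2 > n_methods, "group2",
                      np.where((n_methods - ones) * 2 > n_methods,
                               "group1", "unclassifiable"))
    return pd.Series(labels, index=samples, name="consensus")


def label_by_marker(consensus: pd.Series, matrix: OmicsMatrix,
                    marker_gene: str = "ALK"):
    """Name the two consensus groups by marker expression level.

    The cluster with the higher median marker value becomes ALK_high.  Also
    reports a two-sided Wilcoxon test of the marker between the groups.
    """
    if marker_gene not in matrix.data.index:
        raise ValidationError(f"marker gene {marker_gene!r} absent from matrix")
    marker = matrix.data.loc[marker_gene]
    g1 = consensus.index[consensus == "group1"]
    g2 = consensus.index[consensus == "group2"]
    m1 = float(marker[g1].median())
    m2 = float(marker[g2].median())
    if m1 == m2:
        raise ValidationError(
            f"groups have equal median {marker_gene} expression ({m1}); "
            "explicit override required")
    high, low2 = ("group1", "group2") if m1 > m2 else ("group2", "group1")
    mapping = {high: "ALK_high", low2: "ALK_low",
               "unclassifiable": "unclassifiable"}
    test = wilcoxon_rank_sum(marker[g1].to_numpy(), marker[g2].to_numpy(),
                             mode="auto" if len(g1) + len(g2) <= 20 else "normal_approx")
    return consensus.map(mapping).rename("marker_label"), test


def run_consensus_clustering(matrix: OmicsMatrix,
                             feature_counts=DEFAULT_FEATURE_COUNTS,
                             B: int = 100, seed=None,
                             support_threshold: float = 0.70,
                             marker_gene: str | None = "ALK") -> ClusterOutcome:
    """Full subgrouping pipeline over all six statistic x linkage methods."""
    rng = np.random.default_rng(seed)
    per_method = {}
    probs = {}
    sel = {}
    unstable = []
    for stat in STATISTICS:
        ranked = rank_variable_features(matrix, stat)
        for link in LINKAGES:
            res = stability_sweep(matrix, stat, link, feature_counts, B=B,
                                  seed=rng.integers(2 ** 31),
                                  support_threshold=support_threshold,
                                  ranked=ranked)
            per_method[(stat, link)] = res.assignment
            sel[(stat, link)] = res.selected_count
            if not res.stable:
                unstable.append((stat, link))
            for _, row in res.curve.iterrows():
                probs[(stat, link, int(row["feature_count"]))] = \
                    float(row["bootstrap_probability"])
    consensus = consensus_assignment(per_method)
    marker_label = None
    marker_test = None
    if marker_gene is not None and marker_gene in matrix.data.index:
        marker_label, marker_test = label_by_marker(consensus, matrix, marker_gene)
    log.info("consensus clustering: %d samples, %d unclassifiable, unstable=%s",
             len(consensus), int((consensus == "unclassifiable").sum()), unstable)
    return ClusterOutcome(
        sample_ids=list(consensus.index),
        per_method_assignment=per_method,
        bootstrap_probability=probs,
        selected_feature_count=sel,
        consensus_label=consensus,
        marker_label=marker_label,
        marker_test=marker_test,
        unstable_methods=unstable,
    )
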