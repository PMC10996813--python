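"""Independent oracles used by the test suite.

These deliberately re-derive quantities by brute force (exhaustive
enumeration, linear programming, naive rescanning) and stay independent of
the implementation paths they check.
"""

import numpy as np
from scipy.optimize import linprog
from scipy import stats as sps


# ---------------------------------------------------------------------------
# dip: exact minimization of the sup-norm distance to the ECDF over unimodal
# CDFs (piecewise linear, optional atom at the mode) via linear programming,
# scanning every mode knot.
# ---------------------------------------------------------------------------

def _lp_mode(z, F, Fm, t, atom):
    m = z.size
    nv = m + (2 if atom else 1)
    iv = m
    idd = nv - 1
    A, b = [], []

    def row_of(**coef):
        r = np.zeros(nv)
        for k, v in coef.items():
            r[int(k[1:])] += v
        return r

    for k in range(m):
        r = np.zeros(nv); r[k] = -1.0; r[idd] = -1.0
        A.append(r); b.append(-F[k])                    # g_k + d >= F_k
        r = np.zeros(nv); r[k] = 1.0; r[idd] = -1.0
        A.append(r); b.append(F[k] if (atom and k == t) else Fm[k])
    if atom:
        r = np.zeros(nv); r[iv] = 1.0; r[idd] = -1.0
        A.append(r); b.append(Fm[t])
        r = np.zeros(nv); r[iv] = -1.0; r[idd] = -1.0
        A.append(r); b.append(-Fm[t])
        if t > 0:
            r = np.zeros(nv); r[t - 1] = 1.0; r[iv] = -1.0
            A.append(r); b.append(0.0)
        r = np.zeros(nv); r[iv] = 1.0; r[t] = -1.0
        A.append(r); b.append(0.0)
    for k in range(m - 1):
        r = np.zeros(nv); r[k] = 1.0; r[k + 1] = -1.0
        A.append(r); b.append(0.0)

    def left_node(k):
        if k < t:
            return z[k], k
        return z[t], (iv if atom else t)

    nodes = list(range(t)) + [t]
    for i in range(len(nodes) - 2):
        x0, v0 = left_node(nodes[i])
        x1, v1 = left_node(nodes[i + 1])
        x2, v2 = left_node(nodes[i + 2])
        r = np.zeros(nv)
        r[v0] += -1.0 / (x1 - x0)
        r[v1] += 1.0 / (x1 - x0) + 1.0 / (x2 - x1)
        r[v2] += -1.0 / (x2 - x1)
        A.append(r); b.append(0.0)                      # convex left piece
    for k in range(t, m - 2):
        r = np.zeros(nv)
        r[k] += 1.0 / (z[k + 1] - z[k])
        r[k + 1] += -1.0 / (z[k + 1] - z[k]) - 1.0 / (z[k + 2] - z[k + 1])
        r[k + 2] += 1.0 / (z[k + 2] - z[k + 1])
        A.append(r); b.append(0.0)                      # concave right piece
    c = np.zeros(nv); c[idd] = 1.0
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b),
                  bounds=[(0.0, 1.0)] * (nv - 1) + [(0.0, None)],
                  method="highs")
    return res.fun if res.status == 0 else np.inf


def dip_lp_oracle(x):
    x = np.sort(np.asarray(x, float))
    n = x.size
    z, counts = np.unique(x, return_counts=True)
    if z.size == 1:
        return 0.0
    F = np.cumsum(counts) / n
    Fm = F - counts / n
    best = np.inf
    for t in range(z.size):
        best = min(best, _lp_mode(z, F, Fm, t, atom=False))
        best = min(best, _lp_mode(z, F, Fm, t, atom=True))
    return best


# ---------------------------------------------------------------------------
# brute-force agglomeration that rescans all pairwise distances each step
# ---------------------------------------------------------------------------

def agglomerate_oracle(D, method):
    """Naive hierarchical clustering; returns merge heights and the final
    2-cluster partition as a frozenset of frozensets."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 2:
        best = None
        for a in sorted(clusters):
            for c in sorted(clusters):
                if c <= a:
                    continue
                pair_d = [D[i, j] for i in clusters[a] for j in clusters[c]]
                d = max(pair_d) if method == "complete" else float(np.mean(pair_d))
                if best is None or d < best[0]:
                    best = (d, a, c)
        d, a, c = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[c]
        del clusters[c]
    parts = frozenset(frozenset(v) for v in clusters.values())
    return heights, parts


# ---------------------------------------------------------------------------
# exact rank-sum p by enumerating group assignments of the raw data
# ---------------------------------------------------------------------------

def wilcoxon_enumeration_oracle(x, y):
    from itertools import combinations
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, len(x)
    ranks = sps.rankdata(pooled)
    mean = nx * (n + 1) / 2.0
    obs = abs(ranks[:nx].sum() - mean)
    hits = total = 0
    for idx in combinations(range(n), nx):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= obs - 1e-9:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Fisher two-sided p by direct summation over all admissible tables
# ---------------------------------------------------------------------------

def fisher_enumeration_oracle(a, b, c, d):
    from math import comb
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(aa):
        bb, cc = r1 - aa, c1 - aa
        dd = n - r1 - cc
        if min(bb, cc, dd) < 0:
            return None
        return comb(r1, aa) * comb(n - r1, cc) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for aa in range(0, min(r1, c1) + 1):
        p = prob(aa)
        if p is not None and p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# ssGSEA by literal re-summation of the weighted/unweighted ECDF difference
# ---------------------------------------------------------------------------

def ssgsea_hand_oracle(values, gene_ids, set_genes, alpha):
    order = np.argsort(-sps.rankdata(values), kind="mergesort")
    ranks = sps.rankdata(values)
    in_set = np.array([g in set_genes for g in gene_ids])
    total_w = sum(ranks[i] ** alpha for i in order if in_set[i])
    n_out = (~in_set).sum()
    es = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for i in order:
        if in_set[i]:
            cum_in += ranks[i] ** alpha / total_w
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es
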