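"""Statistical primitives used throughout the pipeline.

Everything here is pure and deterministic.  The dip statistic, the
empirical-Bayes moderated t, the GSEA-style signal-to-noise score, the
Kaplan-Meier estimator and the log-rank test are implemented from first
principles; the scipy special-function layer (hypergeometric pmf, t/chi2
survival functions, rank transforms) provides the underlying numerics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats as sps

__all__ = [
    "TestResult",
    "SurvivalCurve",
    "dip_statistic",
    "spearman_rho",
    "wilcoxon_rank_sum",
    "fisher_exact_2x2",
    "benjamini_hochberg",
    "ModeratedTPrior",
    "moderated_t",
    "signal_to_noise",
    "km_estimate",
    "logrank_test",
]


class InsufficientDataError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    pass


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method_label: str
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0,1]")


@dataclass
class SurvivalCurve:
    times: np.ndarray       # distinct event times, increasing
    survival: np.ndarray    # S(t) immediately after each listed time
    at_risk: np.ndarray     # number at risk just before each time
    n_events: np.ndarray    # events at each time


# --------------------------------------------------------------------------
# Hartigan-Hartigan dip statistic
# --------------------------------------------------------------------------
#
# dip(x) = min over unimodal CDFs G of sup_t |F_n(t) - G(t)|, where G is
# convex to the left of its mode, concave to the right, and may carry an
# atom at the mode.  Computed by bisection on the band half-width d: G
# exists within the band [F_n - d, F_n + d] iff for some mode knot the
# greatest convex minorant of the upper band envelope stays above the lower
# envelope on the left, the least concave majorant of the lower envelope
# stays below the upper on the right, and the two pieces can share a value
# at the mode.  Verified against an exact linear-programming oracle.

def _left_scan(z, lo, hi):
    """Feasibility and value range of convex nondecreasing fits on prefixes.

    For each prefix 0..p of knots z with box constraints lo <= g <= hi:
      feas[p]  : a convex nondecreasing g exists through boxes 0..p
      vvirt[p] : min value attainable at z[p] extrapolating from knots < p
      vend[p]  : min value attainable at z[p] including its own box
    """
    m = z.size
    feas = np.zeros(m, np.bool_)
    vvirt = np.zeros(m)
    vend = np.zeros(m)
    s = np.empty(m)                     # steepest required entry slope at j
    for j in range(1, m):
        best = -np.inf
        for i in range(j):
            cand = (lo[j] - hi[i]) / (z[j] - z[i])
            if cand > best:
                best = cand
        s[j] = best
    hull = np.zeros(m, np.int64)        # lower convex hull of (z, hi)
    nh = 1
    ok = lo[0] <= hi[0]
    feas[0] = ok
    vend[0] = max(lo[0], 0.0)
    for p in range(1, m):
        while nh >= 2:
            i, j = hull[nh - 2], hull[nh - 1]
            if (hi[j] - hi[i]) * (z[p] - z[i]) >= (hi[p] - hi[i]) * (z[j] - z[i]):
                nh -= 1
            else:
                break
        hull[nh] = p
        nh += 1
        if ok:
            # walk hull segments and verify the minorant clears lo
            seg = 0
            for jj in range(p + 1):
                while seg < nh - 1 and z[hull[seg + 1]] < z[jj]:
                    seg += 1
                i0, i1 = hull[seg], hull[min(seg + 1, nh - 1)]
                if i1 == i0:
                    hv = hi[i0]
                else:
                    t_ = (z[jj] - z[i0]) / (z[i1] - z[i0])
                    hv = hi[i0] + t_ * (hi[i1] - hi[i0])
                if hv < lo[jj] - 1e-13:
                    ok = False
                    break
        feas[p] = ok
        v = lo[p - 1]
        for j in range(1, p):
            if s[j] > 0.0:
                cand = lo[j] + s[j] * (z[p] - z[j])
                if cand > v:
                    v = cand
        vvirt[p] = max(v, 0.0)
        vend[p] = max(lo[p], vvirt[p])
    return feas, vend, vvirt


def _band_feasible(d, z, F, Fm):
    """Does a unimodal CDF exist within the sup-norm band of half-width d?"""
    m = z.size
    lo = np.maximum(F - d, 0.0)
    hi = Fm + d
    hi_above = F + d
    Lfeas, Lvend, Lvvirt = _left_scan(z, lo, hi)
    # the concave (right) side is the convex problem on reflected data
    zr = -z[::-1]
    lor = np.maximum(1.0 - hi[::-1], 0.0)
    hir = 1.0 - lo[::-1]
    Rfeas_r, Rvend_r, Rvvirt_r = _left_scan(zr, lor, hir)
    Rfeas = Rfeas_r[::-1]
    Rvstart_max = 1.0 - Rvend_r[::-1]
    Rvvirt_max = 1.0 - Rvvirt_r[::-1]
    eps = 1e-13
    for t in range(m):
        # continuous mode at knot t: both pieces share g_t
        if Lfeas[t] and Rfeas[t] and Lvend[t] <= hi[t] + eps \
                and Rvstart_max[t] >= lo[t] - eps \
                and Lvend[t] <= Rvstart_max[t] + eps:
            return True
    for t in range(m):
        # mode atom at knot t: left limit v <= g_t, band split at the jump
        okL = True if t == 0 else Lfeas[t - 1]
        okR = True if t == m - 1 else Rfeas[t + 1]
        if not (okL and okR):
            continue
        vminus_min = max(Lvvirt[t], Fm[t] - d)
        gt_max = hi_above[t] if t == m - 1 else min(hi_above[t], Rvvirt_max[t])
        if vminus_min <= hi[t] + eps and lo[t] <= gt_max + eps \
                and vminus_min <= gt_max + eps:
            return True
    return False


def _dip_from_ecdf(z, F, Fm, tol):
    if z.size == 1:
        return 0.0
    if _band_feasible(1e-13, z, F, Fm):
        return 0.0
    lo, hi = 0.0, 0.25 + 1e-9
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _band_feasible(mid, z, F, Fm):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _dip_batch(X, tol):
    """Dip statistic per row of a matrix (rows sorted internally)."""
    n_rows, n = X.shape
    out = np.empty(n_rows)
    z = np.empty(n)
    counts = np.empty(n)
    for r in range(n_rows):
        x = np.sort(X[r])
        m = 0
        z[0] = x[0]
        counts[0] = 1.0
        for i in range(1, n):
            if x[i] == z[m]:
                counts[m] += 1.0
            else:
                m += 1
                z[m] = x[i]
                counts[m] = 1.0
        m += 1
        F = np.cumsum(counts[:m]) / n
        Fm = F - counts[:m] / n
        out[r] = _dip_from_ecdf(z[:m].copy(), F, Fm, tol)
    return out


try:  # pragma: no cover - exercised implicitly when numba is installed
    from numba import njit as _njit

    _left_scan = _njit(cache=True)(_left_scan)
    _band_feasible = _njit(cache=True)(_band_feasible)
    _dip_from_ecdf = _njit(cache=True)(_dip_from_ecdf)
    _dip_batch = _njit(cache=True)(_dip_batch)
except ImportError:  # pragma: no cover
    pass


def dip_statistics(matrix, tol: float = 1e-8) -> np.ndarray:
    """Dip statistic for every row of a features x samples matrix."""
    X = np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[1] < 4:
        raise InsufficientDataError("dip requires a 2-D matrix with >= 4 columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("dip_statistics: input contains non-finite values")
    return np.asarray(_dip_batch(X, tol))


def dip_statistic(values, tol: float = 1e-10) -> float:
    """Hartigan-Hartigan dip: departure of the sample from unimodality.

    For n distinct values the dip lies in [1/(2n), 1/4]; the lower bound is
    attained by equally spaced points and the upper by two equal point
    masses.  Affine-invariant.  Requires n >= 4 finite values.
    """
    x = np.asarray(values, float).ravel()
    if x.size < 4:
        raise InsufficientDataError(f"dip requires n >= 4, got n = {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip_statistic: input contains non-finite values")
    x = np.sort(x)
    n = x.size
    z, counts = np.unique(x, return_counts=True)
    F = np.cumsum(counts) / n
    Fm = F - counts / n
    return float(_dip_from_ecdf(z.astype(float), F, Fm, tol))


# --------------------------------------------------------------------------
# correlation and rank tests
# --------------------------------------------------------------------------

def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("spearman_rho requires two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def _rank_sum_exact_p(ranks: np.ndarray, nx: int, observed: float) -> float:
    """Two-sided exact p for the rank sum over the permutation distribution.

    Midranks doubled to integers; the count of nx-subsets per rank sum is
    built by the shift algorithm (equivalent to full enumeration of the
    C(n, nx) group assignments, which the test oracle performs directly).
    """
    n = ranks.size
    r2 = np.rint(ranks * 2).astype(np.int64)
    total_sum = int(r2.sum())
    # counts[k][s] = number of k-subsets with doubled-rank sum s
    counts = np.zeros((nx + 1, total_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in r2:
        kmax = min(nx, n)
        for k in range(kmax - 1, -1, -1):
            row = counts[k]
            nz = np.nonzero(row)[0]
            counts[k + 1, nz + r] += row[nz]
    dist = counts[nx]
    mean2 = nx * (n + 1)                 # doubled null mean, exact integer
    obs_dev = abs(int(round(observed * 2)) - mean2)
    sums = np.arange(total_sum + 1)
    extreme = dist[np.abs(sums - mean2) >= obs_dev].sum()
    return float(extreme / dist.sum())


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``exact`` enumerates the permutation distribution of the rank sum
    (midranks for ties; requires nx + ny <= 20); ``normal_approx`` applies
    the tie-corrected normal approximation with continuity correction.
    ``auto`` picks exact when the combined size allows it.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum: both groups must be non-empty")
    n, nx = x.size + y.size, x.size
    if mode == "auto":
        mode = "exact" if n <= 20 else "normal_approx"
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:nx].sum())
    if mode == "exact":
        if n > 20:
            raise ValueError("exact mode requires nx + ny <= 20")
        p = _rank_sum_exact_p(ranks, nx, w)
    elif mode == "normal_approx":
        mean = nx * (n + 1) / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts ** 3 - counts).sum()) / ((n) * (n - 1))
        var = nx * (n - nx) / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            zstat = (abs(w - mean) - 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(max(zstat, 0.0)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(w, p, f"wilcoxon_rank_sum_{mode}",
                      {"n_x": nx, "n_y": n - nx})


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test by hypergeometric probability-mass
    summation (tables with probability <= observed x (1 + 1e-7))."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("fisher_exact_2x2 requires non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("fisher_exact_2x2: empty table")
    r1, c1 = a + b, a + c
    lo_a, hi_a = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo_a, hi_a + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo_a]
    p = float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return TestResult(float(p_obs), p, "fisher_exact_2x2",
                      {"odds_ratio": odds, "table": (a, b, c, d)})


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values outside [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# --------------------------------------------------------------------------
# moderated t (empirical-Bayes variance shrinkage)
# --------------------------------------------------------------------------

@dataclass
class ModeratedTPrior:
    d0: float               # prior degrees of freedom (inf when under-dispersed)
    s0_sq: float            # prior variance


def _trigamma_inverse(y: float, iters: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(iters):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_variance_prior(s_sq: np.ndarray, df: float) -> ModeratedTPrior:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior
    on z = log(s^2), using digamma/trigamma moment expressions."""
    s_sq = np.asarray(s_sq, float)
    keep = np.isfinite(s_sq) & (s_sq >= 0)
    if keep.sum() < 2:
        return ModeratedTPrior(math.inf, float(np.nanmean(s_sq[keep])) if keep.any() else 1.0)
    x = s_sq[keep]
    med = float(np.median(x))
    if med == 0:
        med = 1.0
    x = np.maximum(x, 1e-5 * med)       # zero-variance features lean on the prior
    z = np.log(x)
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0 = float(x.mean())
    return ModeratedTPrior(d0, s0)


def moderated_t(values: np.ndarray, idx_a, idx_b):
    """Per-feature moderated t between two sample groups of a log-scale matrix.

    Returns (log2fc, t_mod, p, df_total, prior): pooled per-feature variance
    with df = n_a + n_b - 2 is shrunk toward the empirical-Bayes prior
    (d0, s0^2); t = log2fc / (s_tilde * sqrt(1/n_a + 1/n_b)) is referred to a
    t distribution on d0 + df degrees of freedom.
    """
    values = np.asarray(values, float)
    idx_a = np.asarray(idx_a, int)
    idx_b = np.asarray(idx_b, int)
    na, nb = idx_a.size, idx_b.size
    if na < 2 or nb < 2:
        raise ValueError("moderated_t requires >= 2 samples per group")
    A = values[:, idx_a]
    B = values[:, idx_b]
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    df = na + nb - 2
    s_sq = (A.var(axis=1, ddof=1) * (na - 1) + B.var(axis=1, ddof=1) * (nb - 1)) / df
    prior = fit_variance_prior(s_sq, df)
    if math.isinf(prior.d0):
        s_tilde_sq = np.full_like(s_sq, prior.s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)
        df_total = prior.d0 + df
    se = np.sqrt(s_tilde_sq * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    return log2fc, t, np.minimum(p, 1.0), df_total, prior


def signal_to_noise(values: np.ndarray, idx_a, idx_b) -> np.ndarray:
    """GSEA signal-to-noise: (mu_a - mu_b) / (sd_a + sd_b) with each group sd
    floored at max(0.2 * |mu|, 0.2)."""
    values = np.asarray(values, float)
    idx_a = np.asarray(idx_a, int)
    idx_b = np.asarray(idx_b, int)
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("signal_to_noise requires >= 2 samples per group")
    A = values[:, idx_a]
    B = values[:, idx_b]
    mu_a, mu_b = A.mean(axis=1), B.mean(axis=1)
    sd_a = np.maximum(A.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mu_a), 0.2))
    sd_b = np.maximum(B.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mu_b), 0.2))
    return (mu_a - mu_b) / (sd_a + sd_b)


# --------------------------------------------------------------------------
# survival
# --------------------------------------------------------------------------

def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if np.any(times < 0):
        raise ValueError("negative survival time")
    if not np.all(np.isin(events, (0, 1))):
        raise ValueError("events must be 0/1")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    surv, risk, nev = [], [], []
    s = 1.0
    for t in event_times:
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        risk.append(n_risk)
        nev.append(d)
    return SurvivalCurve(event_times, np.array(surv), np.array(risk, int),
                         np.array(nev, int))


def logrank_test(times, events, group_labels) -> TestResult:
    """Two-group log-rank test: chi-square (O-E)^2/V on 1 df."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"logrank_test requires exactly 2 groups, got {groups.size}")
    in_a = labels == groups[0]
    if in_a.all() or not in_a.any():
        raise ValueError("one group is empty")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(((times == t) & (events == 1)).sum())
        d_a = int(((times == t) & (events == 1) & in_a).sum())
        if n == 0 or d == 0:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var <= 0:
        return TestResult(0.0, 1.0, "logrank", {"note": "degenerate (no variance)"})
    chi2 = o_minus_e ** 2 / var
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult(float(chi2), p, "logrank",
                      {"observed_minus_expected": float(o_minus_e), "variance": float(var)})
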