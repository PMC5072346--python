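"""Independent brute-force oracles used to verify pipeline computations.

Everything here is deliberately written from first principles (scalar
loops, exhaustive enumeration, textbook formulas) and shares no code
path with the package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import optimize, special, stats


# -- moderated t ------------------------------------------------------------


def moderated_t_oracle(xa: np.ndarray, xb: np.ndarray):
    """Formula-by-formula moderated two-sample t over a probes x samples pair.

    Returns (effect, t, p, d0, s0_sq, s2).  The prior df solves
    trigamma(d0/2) = excess variance of log s^2 by bisection (independent
    of the package's Newton solver).
    """
    na, nb = xa.shape[1], xb.shape[1]
    d = na + nb - 2
    effect = np.empty(xa.shape[0])
    s2 = np.empty(xa.shape[0])
    for i in range(xa.shape[0]):
        ma, mb = xa[i].mean(), xb[i].mean()
        effect[i] = ma - mb
        ss = ((xa[i] - ma) ** 2).sum() + ((xb[i] - mb) ** 2).sum()
        s2[i] = ss / d
    z = np.log(s2[s2 > 0])
    e = z - special.digamma(d / 2) + math.log(d / 2)
    n = len(e)
    evar = ((e - e.mean()) ** 2).sum() / (n - 1) - special.polygamma(1, d / 2)
    if evar <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e.mean()))
    else:
        half_d0 = optimize.brentq(
            lambda x: special.polygamma(1, x) - evar, 1e-8, 1e8, xtol=1e-12
        )
        d0 = 2 * half_d0
        s0_sq = float(np.exp(e.mean() + special.digamma(half_d0) - math.log(half_d0)))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df = d0 + d
    t = effect / np.sqrt(s2_post * (1 / na + 1 / nb))
    if np.isinf(df):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df)
    return effect, t, p, d0, s0_sq, s2


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p by explicit sort and cumulative min."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


# -- survival ---------------------------------------------------------------


def km_oracle(times: np.ndarray, events: np.ndarray):
    """Product-limit estimate by explicit risk-set recomputation.

    Returns (event_times, survival) over distinct observed event times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ts = sorted(set(times[events == 1]))
    surv = []
    s = 1.0
    for t in ts:
        at_risk = sum(1 for u in times if u >= t)
        d = sum(1 for u, e in zip(times, events) if u == t and e == 1)
        s *= 1 - d / at_risk
        surv.append(s)
    return np.array(ts), np.array(surv)


def logrank_oracle(times, events, group):
    """Observed-minus-expected log-rank statistic by hand, group 0 vs 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    o_e, v = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        risk = times >= t
        n = risk.sum()
        n0 = (risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d0 = ((times == t) & (events == 1) & (group == 0)).sum()
        o_e += d0 - d * n0 / n
        if n > 1:
            v += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    chi2 = o_e**2 / v
    return chi2, stats.chi2.sf(chi2, 1)


def efron_loglik(beta: float, times, events, x) -> float:
    """Cox partial log-likelihood with Efron tie handling, term by term."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        tied = (times == t) & (events == 1)
        m = int(tied.sum())
        risk = times >= t
        sum_risk = float(np.exp(beta * x[risk]).sum())
        sum_tied = float(np.exp(beta * x[tied]).sum())
        ll += beta * x[tied].sum()
        for j in range(m):
            ll -= math.log(sum_risk - j / m * sum_tied)
    return ll


# -- enrichment -------------------------------------------------------------


def hypergeom_enumeration(universe_size: int, set_size: int, list_size: int, overlap: int):
    """P[X >= overlap] by exhaustive enumeration of all candidate draws."""
    universe = list(range(universe_size))
    in_set = set(range(set_size))
    hits = 0
    total = 0
    for draw in combinations(universe, list_size):
        total += 1
        if len(in_set.intersection(draw)) >= overlap:
            hits += 1
    return hits / total


# -- PCA --------------------------------------------------------------------


def pca_scores_oracle(x: np.ndarray, n_components: int) -> np.ndarray:
    """Principal-component scores via explicit covariance eigendecomposition."""
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:n_components]
    return xc @ v[:, order]
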