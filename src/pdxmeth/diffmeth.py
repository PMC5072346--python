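"""Moderated differential methylation on the M-value scale.

Per probe, an ordinary two-sample comparison gives the effect
``b = mean_a - mean_b`` and a pooled residual variance ``s^2`` on
``d = n_a + n_b - 2`` degrees of freedom.  Probe-wise variances are then
shrunk toward an empirical-Bayes prior estimated from the whole matrix:
the prior degrees of freedom ``d0`` and prior variance ``s0^2`` are
obtained by closed-form moment matching on ``log s^2`` (a scaled-F model
for the sample variances), and the posterior variance is

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

The moderated statistic ``t = b / (s_tilde * sqrt(1/n_a + 1/n_b))`` is
referred to a t distribution on ``d0 + d`` degrees of freedom; false
discovery is controlled per contrast by Benjamini-Hochberg adjustment.

Beta-value effect sizes (delta beta) are carried alongside for direction
calls, because "demethylated" is a statement about beta, not M.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import m_to_beta

D0_CAP = 1e6  # prior df above this is treated as effectively infinite


@dataclass
class Contrast:
    """Unpaired two-group comparison (group_a minus group_b)."""

    name: str
    group_a: list[str]
    group_b: list[str]
    paired: bool = False

    def __post_init__(self) -> None:
        if self.paired:
            raise NotImplementedError("only unpaired contrasts are supported")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each contrast group needs >= 2 samples")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("contrast groups must be disjoint")


@dataclass
class ModerationPrior:
    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        # d0 = 0 is admitted as the no-shrinkage limit (ordinary t)
        if self.d0 < 0 or self.s0_sq <= 0:
            raise ValueError("prior df must be >= 0 and prior variance positive")


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < tol:
            break
    return x


def estimate_prior(s2: np.ndarray, d: float) -> ModerationPrior:
    """Moment-matching fit of (d0, s0^2) from the spread of log s^2.

    Follows the classical scaled-F empirical-Bayes estimator: the excess
    variance of ``log s^2`` beyond what ``d`` residual df explain is
    attributed to the prior, and inverted through the trigamma function.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    n = len(e)
    e_mean = float(e.mean())
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1)) - float(special.polygamma(1, d / 2.0))
    if e_var <= 0:
        return ModerationPrior(D0_CAP, float(np.exp(e_mean)))
    d0 = 2.0 * trigamma_inverse(e_var)
    d0 = min(d0, D0_CAP)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationPrior(d0, s0_sq)


def fit_moderated(
    m: pd.DataFrame,
    contrast: Contrast,
    prior: ModerationPrior | None = None,
) -> tuple[pd.DataFrame, ModerationPrior]:
    """Moderated two-group comparison of every probe in an M matrix.

    Returns a results frame (effect, delta_beta, t_mod, df_total, p, q,
    direction) and the estimated moderation prior.  Probes with missing
    values in the contrast samples are dropped (count in
    ``results.attrs['n_dropped']``).  Passing ``prior`` overrides the
    empirical estimate (used to force the d0 -> 0 / d0 -> inf limits).
    """
    missing_cols = [s for s in contrast.group_a + contrast.group_b if s not in m.columns]
    if missing_cols:
        raise ValueError(f"contrast samples absent from matrix: {missing_cols}")
    sub = m[contrast.group_a + contrast.group_b]
    complete = ~sub.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    sub = sub[complete]
    xa = sub[contrast.group_a].values
    xb = sub[contrast.group_b].values
    na, nb = xa.shape[1], xb.shape[1]
    d = na + nb - 2
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    effect = mean_a - mean_b
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / d
    if prior is None:
        prior = estimate_prior(s2, d)
    d0, s0_sq = prior.d0, prior.s0_sq
    if d0 >= D0_CAP:
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t_mod = effect / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    q = multipletests(p, method="fdr_bh")[1]

    beta = m_to_beta(sub)
    delta_beta = beta[contrast.group_a].values.mean(axis=1) - beta[contrast.group_b].values.mean(
        axis=1
    )
    direction = np.where(delta_beta < 0, "hypo", np.where(delta_beta > 0, "hyper", "none"))
    results = pd.DataFrame(
        {
            "effect": effect,
            "delta_beta": delta_beta,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "q": q,
            "direction": direction,
        },
        index=sub.index,
    )
    results.attrs["contrast"] = contrast.name
    results.attrs["n_dropped"] = n_dropped
    return results, prior


def significant_sites(
    results: pd.DataFrame, p_cut: float = 0.01, q_cut: float | None = 0.10
) -> pd.DataFrame:
    """Subset of probes with p < p_cut (and q < q_cut when given)."""
    mask = results["p"] < p_cut
    if q_cut is not None:
        mask &= results["q"] < q_cut
    return results[mask]


class DirectionSplit(NamedTuple):
    hypo: pd.Index
    hyper: pd.Index
    zero: pd.Index


def direction_split(sites: pd.Index | pd.DataFrame, results: pd.DataFrame) -> DirectionSplit:
    """Partition sites by the sign of delta beta.

    Sites with exactly zero delta beta belong to neither class and are
    returned separately.
    """
    idx = sites.index if isinstance(sites, pd.DataFrame) else pd.Index(sites)
    missing = idx.difference(results.index)
    if len(missing):
        raise ValueError(f"sites not present in results: {missing.tolist()[:5]}")
    delta = results.loc[idx, "delta_beta"]
    return DirectionSplit(
        hypo=idx[delta < 0], hyper=idx[delta > 0], zero=idx[delta == 0]
    )
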