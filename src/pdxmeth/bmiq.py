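"""Beta-mixture quantile (BMIQ) normalization of Infinium probe-type bias.

Type-II Infinium probes have a compressed dynamic range relative to
type-I probes assaying the same methylation states.  BMIQ corrects this
per sample: a three-state (unmethylated / hemimethylated / methylated)
beta-distribution mixture is fitted by EM separately to type-I and
type-II beta values, and type-II values are quantile-mapped state by
state onto the corresponding fitted type-I component.  The outer states
are mapped through the component CDFs (inverse-CDF transform); the
middle state, whose beta fit is the least reliable, is carried across by
an affine interpolation between the mapped boundaries.  Type-I values
are never touched and the rank order of type-II values within a sample
is preserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .manifest_io import ProbeManifest
from .preprocess import BETA_CLAMP

logger = logging.getLogger(__name__)

EM_TOL = 1e-4  # relative log-likelihood change declaring convergence
EM_MAX_ITER = 200
MIN_PROBES_PER_TYPE = 50


@dataclass
class BetaMixture:
    """Three-component beta mixture, components ordered by mean."""

    weights: np.ndarray  # (3,)
    params: np.ndarray  # (3, 2) shape pairs (a, b)
    log_likelihood: float
    converged: bool
    iterations: int

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return sum(
            w * stats.beta.pdf(x, a, b) for w, (a, b) in zip(self.weights, self.params)
        )

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        comp = np.stack(
            [w * stats.beta.pdf(x, a, b) for w, (a, b) in zip(self.weights, self.params)],
            axis=1,
        )
        comp = np.clip(comp, 1e-300, None)
        return comp / comp.sum(axis=1, keepdims=True)


@dataclass
class NormalizationModel:
    """Fitted per-sample BMIQ models and convergence flags."""

    per_sample: dict[str, dict] = field(default_factory=dict)

    def converged(self, sample_id: str) -> bool:
        return self.per_sample[sample_id]["converged"]


def _moment_match(x: np.ndarray) -> tuple[float, float]:
    """Beta shape parameters from sample mean/variance (method of moments)."""
    mu = float(np.mean(x))
    var = float(np.var(x))
    mu = min(max(mu, 1e-4), 1 - 1e-4)
    var = min(max(var, 1e-8), mu * (1 - mu) * 0.999)
    nu = mu * (1 - mu) / var - 1.0
    return max(mu * nu, 1e-2), max((1 - mu) * nu, 1e-2)


def _weighted_beta_mle(x: np.ndarray, w: np.ndarray, a0: float, b0: float) -> tuple[float, float]:
    """Weighted maximum-likelihood beta fit via damped Newton on digamma equations.

    Falls back to weighted moment matching if Newton leaves the feasible
    region, keeping the EM deterministic.
    """
    wsum = w.sum()
    if wsum < 1e-12:
        return a0, b0
    t1 = float(np.dot(w, np.log(x)) / wsum)
    t2 = float(np.dot(w, np.log1p(-x)) / wsum)
    a, b = a0, b0
    for _ in range(50):
        psi_ab = special.digamma(a + b)
        f1 = special.digamma(a) - psi_ab - t1
        f2 = special.digamma(b) - psi_ab - t2
        tri_ab = special.polygamma(1, a + b)
        j11 = special.polygamma(1, a) - tri_ab
        j22 = special.polygamma(1, b) - tri_ab
        det = j11 * j22 - tri_ab * tri_ab
        if not np.isfinite(det) or abs(det) < 1e-300:
            break
        da = (f1 * j22 + f2 * tri_ab) / det
        db = (f2 * j11 + f1 * tri_ab) / det
        step = 1.0
        while (a - step * da <= 0 or b - step * db <= 0) and step > 1e-4:
            step /= 2
        a_new, b_new = a - step * da, b - step * db
        if a_new <= 0 or b_new <= 0 or not (np.isfinite(a_new) and np.isfinite(b_new)):
            mu = float(np.dot(w, x) / wsum)
            var = float(np.dot(w, (x - mu) ** 2) / wsum)
            mu = min(max(mu, 1e-4), 1 - 1e-4)
            var = min(max(var, 1e-8), mu * (1 - mu) * 0.999)
            nu = mu * (1 - mu) / var - 1.0
            return max(mu * nu, 1e-2), max((1 - mu) * nu, 1e-2)
        if abs(a_new - a) < 1e-10 * a and abs(b_new - b) < 1e-10 * b:
            a, b = a_new, b_new
            break
        a, b = a_new, b_new
    return a, b


def fit_beta_mixture(x: np.ndarray) -> BetaMixture:
    """EM fit of a three-state beta mixture, initialized by tercile moments."""
    x = np.clip(np.asarray(x, dtype=float), BETA_CLAMP, 1 - BETA_CLAMP)
    order = np.sort(x)
    thirds = np.array_split(order, 3)
    params = np.array([_moment_match(t) for t in thirds])
    weights = np.full(3, 1.0 / 3.0)
    lx = np.log(x)
    l1x = np.log1p(-x)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, EM_MAX_ITER + 1):
        logcomp = np.stack(
            [
                np.log(w) + (a - 1) * lx + (b - 1) * l1x - special.betaln(a, b)
                for w, (a, b) in zip(weights, params)
            ],
            axis=1,
        )
        top = logcomp.max(axis=1, keepdims=True)
        comp = np.exp(logcomp - top)
        total = comp.sum(axis=1)
        ll = float((np.log(total) + top[:, 0]).sum())
        resp = comp / total[:, None]
        weights = resp.mean(axis=0)
        weights = np.clip(weights, 1e-6, None)
        weights /= weights.sum()
        params = np.array(
            [
                _weighted_beta_mle(x, resp[:, k], params[k, 0], params[k, 1])
                for k in range(3)
            ]
        )
        # keep components ordered by mean so labels stay U < hemi < M
        means = params[:, 0] / params.sum(axis=1)
        order_idx = np.argsort(means)
        params = params[order_idx]
        weights = weights[order_idx]
        if abs(ll - ll_old) < EM_TOL * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll
    return BetaMixture(weights, params, ll_old if not converged else ll, converged, it)


def _map_type_ii(x: np.ndarray, mix_ii: BetaMixture, mix_i: BetaMixture) -> np.ndarray:
    """Quantile-map type-II values onto the type-I component fits."""
    labels = np.argmax(mix_ii.responsibilities(x), axis=1)
    y = x.copy()
    for state in (0, 2):
        mask = labels == state
        if not mask.any():
            continue
        a2, b2 = mix_ii.params[state]
        a1, b1 = mix_i.params[state]
        p = np.clip(stats.beta.cdf(x[mask], a2, b2), 1e-9, 1 - 1e-9)
        y[mask] = stats.beta.ppf(p, a1, b1)
    hemi = labels == 1
    if hemi.any() and (labels == 0).any() and (labels == 2).any():
        # blended interpolation: carry the middle state across by the affine
        # map taking the source U/M boundary values onto their mapped images
        lo_src, hi_src = x[labels == 0].max(), x[labels == 2].min()
        lo_dst, hi_dst = y[labels == 0].max(), y[labels == 2].min()
        if hi_src > lo_src and hi_dst > lo_dst:
            y[hemi] = lo_dst + (x[hemi] - lo_src) * (hi_dst - lo_dst) / (hi_src - lo_src)
    # enforce global monotonicity across state boundaries so type-II ranks
    # survive exactly; the ramp breaks any ties the cummax introduces
    order = np.argsort(x, kind="stable")
    y_sorted = np.maximum.accumulate(y[order])
    y_sorted = y_sorted + np.arange(len(y_sorted)) * 1e-12
    out = np.empty_like(y)
    out[order] = y_sorted
    return np.clip(out, BETA_CLAMP, 1 - BETA_CLAMP)


def bmiq_normalize(
    beta: pd.DataFrame, manifest: ProbeManifest
) -> tuple[pd.DataFrame, NormalizationModel]:
    """Per-sample BMIQ normalization of a probes x samples beta matrix.

    Samples whose EM fails to converge within the iteration budget are
    left unnormalized (flagged in the returned model, warning logged).
    """
    ann = manifest.df.loc[beta.index]
    is_ii = (ann["design_type"] == "II").values
    n_i, n_ii = int((~is_ii).sum()), int(is_ii.sum())
    if n_i < MIN_PROBES_PER_TYPE or n_ii < MIN_PROBES_PER_TYPE:
        raise ValueError(
            f"need >= {MIN_PROBES_PER_TYPE} probes of each design type "
            f"(got I: {n_i}, II: {n_ii})"
        )
    out = beta.copy()
    model = NormalizationModel()
    for sample in beta.columns:
        col = np.clip(beta[sample].values.astype(float), BETA_CLAMP, 1 - BETA_CLAMP)
        mix_i = fit_beta_mixture(col[~is_ii])
        mix_ii = fit_beta_mixture(col[is_ii])
        ok = mix_i.converged and mix_ii.converged
        model.per_sample[sample] = {
            "type_I": mix_i,
            "type_II": mix_ii,
            "converged": ok,
            "iterations": max(mix_i.iterations, mix_ii.iterations),
        }
        if not ok:
            logger.warning("BMIQ EM did not converge for sample %s; left unnormalized", sample)
            continue
        vals = col.copy()
        vals[is_ii] = _map_type_ii(col[is_ii], mix_ii, mix_i)
        out[sample] = vals
    return out, model
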