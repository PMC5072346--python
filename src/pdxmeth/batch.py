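"""Empirical-Bayes batch-effect adjustment of M-value matrices.

Location/scale batch correction in the ComBat style: probes are
standardized against the batch-design fit, per-batch per-probe location
and scale estimates are shrunk toward parametric priors (normal for
location, inverse-gamma for scale) shared across probes, and the data
are rebuilt on the original M-value scale.  The per-probe pooled mean of
the input is restored exactly after adjustment.

Applied on M-values (not beta), where the location/scale model is
appropriate; no covariates beyond batch are modeled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_CONV = 1e-4  # convergence of the iterative posterior solution


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(z_batch: np.ndarray, g_hat, d_hat, g_bar, t2, a, b) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the coupled posterior location/scale equations to a fixpoint."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(500):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < _CONV:
            break
    return g_old, d_old


def batch_adjust(
    m: pd.DataFrame,
    batches: pd.Series | dict,
    parametric: bool = True,
    restore_grand_mean: bool = True,
) -> pd.DataFrame:
    """Remove batch location/scale effects from a probes x samples M matrix.

    Parameters
    ----------
    m : probes x samples M-values.
    batches : batch label per sample (all samples of ``m`` must be covered).
    parametric : only the parametric (normal / inverse-gamma) priors are
        implemented; passing False raises.
    restore_grand_mean : re-center each probe on its original pooled mean
        after adjustment.
    """
    if not parametric:
        raise NotImplementedError("only parametric empirical-Bayes priors are implemented")
    batches = pd.Series(batches)
    missing = m.columns.difference(batches.index)
    if len(missing):
        raise ValueError(f"no batch label for sample(s): {missing.tolist()[:5]}")
    labels = batches.loc[m.columns]
    level_names = labels.unique().tolist()
    if len(level_names) == 1:
        return m.copy()
    sizes = labels.value_counts()
    singletons = sizes[sizes < 2]
    if len(singletons):
        raise ValueError(f"batch(es) with fewer than 2 samples: {singletons.index.tolist()}")

    x = m.values.astype(float)
    n_probes, n_samples = x.shape
    batch_cols = {lev: np.flatnonzero((labels == lev).values) for lev in level_names}

    # batch-design fit: per-batch means, size-weighted grand mean, pooled variance
    b_hat = np.stack([x[:, cols].mean(axis=1) for cols in batch_cols.values()], axis=1)
    props = np.array([len(cols) for cols in batch_cols.values()], dtype=float) / n_samples
    grand = b_hat @ props
    resid = x.copy()
    for i, cols in enumerate(batch_cols.values()):
        resid[:, cols] -= b_hat[:, [i]]
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)
    z = (x - grand[:, None]) / sd[:, None]

    z_adj = np.empty_like(z)
    for i, (lev, cols) in enumerate(batch_cols.items()):
        zb = z[:, cols]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1)
        d_mean = d_hat.mean()
        d_s2 = d_hat.var(ddof=1)
        a = (2 * d_s2 + d_mean**2) / d_s2
        b = (d_mean * d_s2 + d_mean**3) / d_s2
        g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a, b)
        z_adj[:, cols] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = z_adj * sd[:, None] + grand[:, None]
    if restore_grand_mean:
        out += (x.mean(axis=1) - out.mean(axis=1))[:, None]
    return pd.DataFrame(out, index=m.index, columns=m.columns)
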