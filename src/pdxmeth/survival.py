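"""Prognostic association of a marker with right-censored survival.

A continuous marker (methylation beta at a CpG, or gene expression) is
dichotomized into high/low groups — by a fixed cutoff (e.g. beta > 0.9
for high methylation, the cutoff value itself counting as "low"), by the
median, or by a quartile-bounded scan that picks the cutoff minimizing
the log-rank p-value.  The groups are compared by Kaplan-Meier
estimation (Greenwood variance), a two-group log-rank test, and a
univariate Cox proportional-hazards model (Efron tie handling via
lifelines) reporting the hazard ratio with a 95% Wald interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats


@dataclass
class DichotomyRule:
    """How to split a continuous marker into high/low groups."""

    mode: str  # fixed_cutoff | median | quartile_auto
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_cutoff", "median", "quartile_auto"):
            raise ValueError(f"unknown dichotomy mode {self.mode!r}")
        if self.mode == "fixed_cutoff" and self.cutoff is None:
            raise ValueError("fixed_cutoff mode needs a cutoff value")


@dataclass
class DichotomyResult:
    table: pd.DataFrame  # input columns + 'group' in {high, low}
    cutoff: float
    mode: str


@dataclass
class CoxFit:
    coef: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_wald: float
    p_lr: float
    n_high: int
    n_low: int
    events_high: int
    events_low: int

    def __post_init__(self) -> None:
        assert self.hazard_ratio > 0
        assert self.ci_low <= self.hazard_ratio <= self.ci_high


def dichotomize(table: pd.DataFrame, rule: DichotomyRule) -> DichotomyResult:
    """Split subjects into high (marker > cutoff) and low (marker <= cutoff).

    quartile_auto scans every observed marker value between the lower
    and upper quartile and keeps the cutoff with the smallest log-rank
    p-value (smallest cutoff on ties).
    """
    if table["marker"].isna().any():
        raise ValueError("marker must be present for every subject")
    marker = table["marker"].values.astype(float)
    if rule.mode == "fixed_cutoff":
        cutoff = float(rule.cutoff)
    elif rule.mode == "median":
        cutoff = float(np.median(marker))
    else:
        q1, q3 = np.percentile(marker, [25, 75])
        candidates = np.unique(marker[(marker >= q1) & (marker <= q3)])
        best_p, cutoff = np.inf, None
        for c in candidates:
            high = marker > c
            if high.all() or not high.any():
                continue
            trial = table.copy()
            trial["group"] = np.where(high, "high", "low")
            _, p = logrank(trial)
            if np.isfinite(p) and p < best_p:
                best_p, cutoff = p, float(c)
        if cutoff is None:
            raise ValueError("no quartile-bounded cutoff produced two non-empty groups")
    high = marker > cutoff
    if high.all() or not high.any():
        raise ValueError(f"cutoff {cutoff} puts all subjects in one group")
    out = table.copy()
    out["group"] = np.where(high, "high", "low")
    return DichotomyResult(table=out, cutoff=cutoff, mode=rule.mode)


def km_estimate(table: pd.DataFrame, group_col: str = "group") -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group with Greenwood variance.

    Returns, per group, a frame over distinct event times: number at
    risk, events, survival S(t) and its Greenwood variance.  Curves
    start at S=1; right-censored subjects leave the risk set after their
    censoring time.
    """
    curves = {}
    for name, grp in table.groupby(group_col):
        times = grp["time"].values.astype(float)
        events = grp["event"].values.astype(int)
        event_times = np.unique(times[events == 1])
        rows = []
        surv = 1.0
        greenwood_sum = 0.0
        for t in event_times:
            at_risk = int((times >= t).sum())
            d = int(((times == t) & (events == 1)).sum())
            surv *= 1.0 - d / at_risk
            if at_risk > d:
                greenwood_sum += d / (at_risk * (at_risk - d))
            rows.append(
                {
                    "time": t,
                    "at_risk": at_risk,
                    "events": d,
                    "survival": surv,
                    "variance": surv**2 * greenwood_sum,
                }
            )
        curves[name] = pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival", "variance"])
    return curves


def logrank(table: pd.DataFrame, group_col: str = "group") -> tuple[float, float]:
    """Two-group log-rank test (hypergeometric variance at each event time).

    Returns (chi-square statistic, p).  With no events at all the test
    is undefined and (nan, nan) is returned.
    """
    groups = table[group_col].unique()
    if len(groups) != 2:
        raise ValueError("log-rank test needs exactly two groups")
    g0 = groups[0]
    times = table["time"].values.astype(float)
    events = table["event"].values.astype(int)
    in_g0 = (table[group_col] == g0).values
    event_times = np.unique(times[events == 1])
    if len(event_times) == 0:
        return np.nan, np.nan
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n0 = int((at_risk & in_g0).sum())
        d = int(((times == t) & (events == 1)).sum())
        d0 = int(((times == t) & (events == 1) & in_g0).sum())
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_univariate(table: pd.DataFrame, group_col: str = "group") -> CoxFit:
    """Univariate Cox PH fit of the high-vs-low indicator (Efron ties).

    The hazard ratio is for the "high" group relative to "low".  Raises
    when either group has no events (monotone partial likelihood).
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError("cox_univariate needs exactly two groups")
    if set(groups) == {"high", "low"}:
        high_label = "high"
    else:
        high_label = groups[1]
    df = pd.DataFrame(
        {
            "time": table["time"].astype(float),
            "event": table["event"].astype(int),
            "x": (table[group_col] == high_label).astype(int),
        }
    )
    ev = df.groupby("x")["event"].sum()
    if (ev == 0).any():
        raise ValueError(
            "a group has no observed events; the partial likelihood is monotone "
            "(consider exact or penalized methods)"
        )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    zcrit = stats.norm.ppf(0.975)
    return CoxFit(
        coef=coef,
        hazard_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - zcrit * se)),
        ci_high=float(np.exp(coef + zcrit * se)),
        p_wald=float(cph.summary.loc["x", "p"]),
        p_lr=float(cph.log_likelihood_ratio_test().p_value),
        n_high=int((df["x"] == 1).sum()),
        n_low=int((df["x"] == 0).sum()),
        events_high=int(ev.get(1, 0)),
        events_low=int(ev.get(0, 0)),
    )


def methylation_expression_correlation(
    meth: np.ndarray | pd.Series, expr: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Pearson correlation between per-sample methylation and expression.

    Returns (r, two-sided t-based p); (nan, nan) when either vector has
    zero variance.
    """
    x = np.asarray(meth, dtype=float)
    y = np.asarray(expr, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
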