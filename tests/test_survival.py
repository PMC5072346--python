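"""Dichotomization, Kaplan-Meier, log-rank and Cox PH against hand oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from pdxmeth.survival import (
    DichotomyRule,
    cox_univariate,
    dichotomize,
    km_estimate,
    logrank,
    methylation_expression_correlation,
)

from oracles import efron_loglik, km_oracle, logrank_oracle


def _table(times, events, markers=None, group=None):
    df = pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(len(times))],
            "time": times,
            "event": events,
            "marker": markers if markers is not None else 0.5,
        }
    )
    if group is not None:
        df["group"] = group
    return df


def _exp_sample(rng, n, rate, censor_rate=None):
    t = rng.exponential(1 / rate, n)
    if censor_rate is None:
        return t, np.ones(n, dtype=int)
    c = rng.exponential(1 / censor_rate, n)
    return np.minimum(t, c), (t <= c).astype(int)


class TestDichotomize:
    def test_fixed_cutoff_strictly_greater_is_high(self):
        res = dichotomize(
            _table([1, 2], [1, 1], markers=[0.8, 0.95]),
            DichotomyRule("fixed_cutoff", 0.9),
        )
        assert list(res.table["group"]) == ["low", "high"]

    def test_cutoff_value_itself_is_low(self):
        res = dichotomize(
            _table([1, 2, 3], [1, 1, 1], markers=[0.9, 0.95, 0.85]),
            DichotomyRule("fixed_cutoff", 0.9),
        )
        assert res.table.loc[0, "group"] == "low"

    def test_median_mode_splits_evenly(self):
        res = dichotomize(
            _table([1, 2, 3, 4], [1, 1, 1, 1], markers=[1, 2, 3, 4]),
            DichotomyRule("median"),
        )
        assert res.cutoff == 2.5
        assert (res.table["group"] == "high").sum() == 2

    def test_degenerate_cutoff_rejected(self):
        with pytest.raises(ValueError, match="one group"):
            dichotomize(
                _table([1, 2], [1, 1], markers=[0.1, 0.2]),
                DichotomyRule("fixed_cutoff", 0.9),
            )

    def test_quartile_auto_lands_between_populations(self, rng):
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 40
            marker = np.concatenate(
                [rng.normal(0.3, 0.05, n), rng.normal(0.7, 0.05, n)]
            )
            # low-marker population enjoys longer survival
            t_good, e_good = _exp_sample(rng, n, rate=0.5)
            t_poor, e_poor = _exp_sample(rng, n, rate=1.5)
            table = _table(
                np.concatenate([t_good, t_poor]),
                np.concatenate([e_good, e_poor]),
                markers=marker,
            )
            res = dichotomize(table, DichotomyRule("quartile_auto"))
            if 0.3 < res.cutoff < 0.7:
                hits += 1
        assert hits / n_rep >= 0.95


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        curves = km_estimate(_table([5, 6, 7], [0, 0, 0], group=["g"] * 3))
        assert curves["g"].empty  # no drops: survival remains 1 throughout

    def test_three_events_product_limit_by_hand(self):
        curves = km_estimate(_table([1, 2, 3], [1, 1, 1], group=["g"] * 3))
        s = curves["g"].set_index("time")["survival"]
        assert s[1] == pytest.approx(2 / 3)
        assert s[2] == pytest.approx(1 / 3)  # (2/3)*(1/2)
        assert s[3] == pytest.approx(0.0)

    def test_matches_risk_set_oracle_with_censoring(self, rng):
        t, e = _exp_sample(rng, 80, rate=1.0, censor_rate=0.7)
        t = np.round(t, 1)  # force ties
        curves = km_estimate(_table(t, e, group=["g"] * 80))
        ts, surv = km_oracle(t, e)
        got = curves["g"].set_index("time")["survival"]
        np.testing.assert_allclose(got.loc[ts].values, surv, atol=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t, e = _exp_sample(rng, 60, rate=1.0, censor_rate=0.5)
        curves = km_estimate(_table(t, e, group=["g"] * 60))
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in curves["g"].iterrows():
            assert kmf.predict(row["time"]) == pytest.approx(row["survival"], abs=1e-10)

    def test_monotone_and_bounded_and_order_invariant(self, rng):
        t, e = _exp_sample(rng, 50, rate=1.0, censor_rate=0.5)
        tab = _table(t, e, group=["g"] * 50)
        shuffled = tab.sample(frac=1, random_state=2)
        a = km_estimate(tab)["g"]["survival"].values
        b = km_estimate(shuffled)["g"]["survival"].values
        np.testing.assert_allclose(a, b)
        assert (np.diff(a) <= 1e-12).all()
        assert ((a >= 0) & (a <= 1)).all()


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4]
        e = [1, 1, 0, 1]
        table = _table(t + t, e + e, group=["a"] * 4 + ["b"] * 4)
        chi2, p = logrank(table)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_table_matches_hand_computation(self):
        table = _table(
            [1, 3, 5, 2, 4, 6], [1, 1, 0, 1, 1, 1], group=list("aaabbb")
        )
        chi2, p = logrank(table)
        ref_chi2, ref_p = logrank_oracle(
            table["time"], table["event"], (table["group"] == "b").astype(int)
        )
        assert chi2 == pytest.approx(ref_chi2, abs=1e-12)
        assert p == pytest.approx(ref_p, abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        t0, e0 = _exp_sample(rng, 50, 1.0, 0.5)
        t1, e1 = _exp_sample(rng, 50, 2.0, 0.5)
        table = _table(
            np.concatenate([t0, t1]),
            np.concatenate([e0, e1]),
            group=["a"] * 50 + ["b"] * 50,
        )
        chi2, p = logrank(table)
        ref = logrank_test(t0, t1, e0, e1)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_reported_missing(self):
        table = _table([1, 2], [0, 0], group=["a", "b"])
        chi2, p = logrank(table)
        assert np.isnan(chi2) and np.isnan(p)

    def test_power_against_planted_hazard_ratio(self, rng):
        rejections = 0
        n_rep = 30
        for _ in range(n_rep):
            t0, e0 = _exp_sample(rng, 200, 1.0, 1.0)  # ~50% censoring
            t1, e1 = _exp_sample(rng, 200, 2.0, 1.0)
            table = _table(
                np.concatenate([t0, t1]),
                np.concatenate([e0, e1]),
                group=["a"] * 200 + ["b"] * 200,
            )
            _, p = logrank(table)
            rejections += p < 0.05
        assert rejections / n_rep > 0.9


class TestCox:
    def test_identical_groups_hr_one(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        e = [1, 1, 0, 1, 1]
        table = _table(t + t, e + e, group=["high"] * 5 + ["low"] * 5)
        fit = cox_univariate(table)
        assert fit.hazard_ratio == pytest.approx(1.0, abs=1e-6)

    def test_label_swap_inverts_hazard_ratio(self, rng):
        t0, e0 = _exp_sample(rng, 100, 1.0)
        t1, e1 = _exp_sample(rng, 100, 2.0)
        times = np.concatenate([t0, t1])
        events = np.concatenate([e0, e1])
        fit_a = cox_univariate(_table(times, events, group=["low"] * 100 + ["high"] * 100))
        fit_b = cox_univariate(_table(times, events, group=["high"] * 100 + ["low"] * 100))
        assert fit_a.hazard_ratio == pytest.approx(1 / fit_b.hazard_ratio, rel=1e-6)

    def test_tied_events_match_efron_bruteforce(self):
        # heavily tied toy table: maximize the hand-coded Efron likelihood
        times = [1, 1, 1, 2, 2, 3, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        group = ["high", "low", "high", "high", "low", "low", "low", "high"]
        x = np.array([1 if g == "high" else 0 for g in group])
        fit = cox_univariate(_table(times, events, group=group))
        brute = minimize_scalar(
            lambda b: -efron_loglik(b, times, events, x), bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        # 1e-3 separates Efron from Breslow here (Breslow argmax is ~0.02 away)
        assert fit.coef == pytest.approx(brute.x, abs=1e-3)

    def test_no_events_in_group_rejected(self):
        table = _table([1, 2, 3, 4], [1, 1, 0, 0], group=["low", "low", "high", "high"])
        with pytest.raises(ValueError, match="monotone"):
            cox_univariate(table)

    def test_hr_estimate_converges_with_n(self, rng):
        # consistency: estimates tighten around the true rate ratio 2.0
        errs = {}
        for n in (100, 1000):
            t0, e0 = _exp_sample(rng, n, 1.0)
            t1, e1 = _exp_sample(rng, n, 2.0)
            fit = cox_univariate(
                _table(
                    np.concatenate([t0, t1]),
                    np.concatenate([e0, e1]),
                    group=["low"] * n + ["high"] * n,
                )
            )
            errs[n] = abs(fit.hazard_ratio - 2.0)
        assert errs[1000] < 0.25
        assert fit.ci_low < 2.0 < fit.ci_high


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        x = np.linspace(0, 1, 10)
        r, p = methylation_expression_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_five_point_hand_table(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, _ = methylation_expression_correlation(x, y)
        ref = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(ref, abs=1e-12)

    def test_null_correlation_stays_small(self, rng):
        small = 0
        n_rep = 50
        for _ in range(n_rep):
            x = rng.normal(size=1_000)
            y = rng.normal(size=1_000)
            r, _ = methylation_expression_correlation(x, y)
            small += abs(r) < 0.08
        assert small / n_rep >= 0.95

    def test_zero_variance_reported_missing(self):
        r, p = methylation_expression_correlation([1, 1, 1], [1, 2, 3])
        assert np.isnan(r) and np.isnan(p)
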