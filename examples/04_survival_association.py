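"""Prognostic association of a methylation marker with survival.

Dichotomizes subjects at beta > 0.9 (high methylation), estimates
Kaplan-Meier curves, runs the log-rank test and a univariate Cox
proportional-hazards model, and correlates methylation with expression.
"""

import numpy as np
import pandas as pd

from pdxmeth.survival import (
    DichotomyRule,
    cox_univariate,
    dichotomize,
    km_estimate,
    logrank,
    methylation_expression_correlation,
)

rng = np.random.default_rng(42)
n = 120
marker = np.clip(rng.normal(0.88, 0.06, n), 0, 1)
high = marker > 0.9
# high methylation silences the gene and worsens the hazard ~1.8-fold
times = rng.exponential(np.where(high, 14, 25), n)
censor = rng.uniform(10, 40, n)
table = pd.DataFrame(
    {
        "id": [f"pt{i}" for i in range(n)],
        "time": np.minimum(times, censor),
        "event": (times <= censor).astype(int),
        "marker": marker,
    }
)

res = dichotomize(table, DichotomyRule("fixed_cutoff", 0.9))
groups = res.table["group"].value_counts()
print(f"cutoff 0.9: {groups.get('high', 0)} high- / {groups.get('low', 0)} low-methylation patients")

curves = km_estimate(res.table)
for g, curve in curves.items():
    mid = curve.iloc[len(curve) // 2]
    print(f"  {g}: S({mid['time']:.1f}) = {mid['survival']:.2f} "
          f"(Greenwood sd {np.sqrt(mid['variance']):.3f})")

chi2, p = logrank(res.table)
fit = cox_univariate(res.table)
print(f"log-rank chi2 = {chi2:.2f}, p = {p:.4f}")
print(f"Cox HR (high vs low) = {fit.hazard_ratio:.2f} "
      f"[{fit.ci_low:.2f}, {fit.ci_high:.2f}], Wald p = {fit.p_wald:.4f}")

expression = 10 - 8 * marker + rng.normal(0, 0.5, n)
r, pr = methylation_expression_correlation(marker, expression)
print(f"methylation-expression Pearson r = {r:.3f} (p = {pr:.2e})")
print("\nAn HR above 1 says high promoter methylation of the marker gene "
      "associates with earlier progression; the negative correlation shows "
      "methylation silencing expression.")
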