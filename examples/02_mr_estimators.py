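"""Two-sample MR estimators and diagnostics on a small harmonised dataset.

Builds six harmonised variant pairs with a true causal ratio of 0.5 plus one
pleiotropic outlier, then prints the Wald ratios, the IVW combination, the
MR-Egger intercept test and Cochran's Q.
"""

import pandas as pd

from mrclustmed import mr_core
from mrclustmed.gwas_io import PAIR_COLUMNS

rows = []
betas = [0.08, 0.10, 0.12, 0.15, 0.09, 0.11]
for i, bx in enumerate(betas):
    by = 0.5 * bx          # true ratio 0.5
    if i == 5:
        by += 0.04         # one variant with extra (pleiotropic) effect
    rows.append({
        "rsid": f"rs{i + 1}", "chr": "1", "pos": 1 + i, "ea": "A", "oa": "G",
        "beta_exp": bx, "se_exp": 0.004, "eaf_exp": 0.3, "n_exp": 500_000,
        "beta_out": by, "se_out": 0.01, "eaf_out": 0.3, "n_out": 240_000,
        "palindromic": False, "flipped": False,
    })
pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)

ratios = mr_core.wald_ratios(pairs)
print("Per-variant Wald ratios (outcome units per exposure unit):")
for r in ratios:
    print(f"  {r.rsid}: theta = {r.theta:.3f} (se {r.se_theta:.3f})")

ivw = mr_core.ivw(ratios)
lo, hi = ivw.ci()
print(f"\nIVW estimate: {ivw.beta:.3f} (95% CI {lo:.3f}, {hi:.3f}), "
      f"p = {ivw.pvalue:.2e} over {ivw.n_snps} variants")

egger = mr_core.egger_intercept_test(pairs)
print(f"MR-Egger intercept: {egger['intercept']:.4f} "
      f"(p = {egger['intercept_p']:.3f}) — tests directional pleiotropy")

q = mr_core.cochran_q(ratios, ivw.beta)
print(f"Cochran's Q: {q['q']:.2f} on {q['df']} df (p = {q['p']:.3f}) "
      f"— heterogeneity across ratios")

print(
    "\nThe IVW estimate sits near the generating ratio 0.5; the pleiotropic"
    "\nvariant inflates Q and nudges the Egger intercept away from zero."
)
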