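"""Core two-sample Mendelian randomisation estimators and diagnostics.

Per-variant causal effects are Wald ratios theta_j = beta_out / beta_exp with
first-order delta-method standard errors; the combined causal estimate is the
fixed-effect inverse-variance weighted (IVW) mean of the ratios.  Directional
pleiotropy is probed with the MR-Egger intercept and heterogeneity with
Cochran's Q.  All p-values come from the normal distribution, the convention
for summary-statistics MR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class RatioEstimate:
    """Per-variant Wald ratio: causal effect in outcome units per exposure unit."""

    rsid: str
    theta: float
    se_theta: float

    def __post_init__(self) -> None:
        if not self.se_theta > 0:
            raise ValueError(f"{self.rsid}: se_theta must be > 0")

    @property
    def weight(self) -> float:
        return 1.0 / self.se_theta**2


@dataclass
class MrEstimate:
    """A combined MR estimate with optional heterogeneity / pleiotropy diagnostics."""

    method: str  # 'ivw' | 'wald' | 'egger-slope'
    beta: float
    se: float
    pvalue: float
    n_snps: int
    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    extra: dict = field(default_factory=dict)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.beta - z * self.se, self.beta + z * self.se

    def to_record(self) -> dict:
        d = asdict(self)
        d.update(d.pop("extra"))
        lo, hi = self.ci()
        d["ci_lower"], d["ci_upper"] = lo, hi
        return d


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _ratio_p(beta: float, se: float) -> float:
    # exact fits give se == 0: infinite evidence against 0 unless beta is 0 too
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return _normal_p(beta / se)


def fixed_effect_meta(a: pd.Series, b: pd.Series) -> pd.Series:
    """Fixed-effect inverse-variance meta-analysis of two harmonised records.

    Both records must carry the same rsid and allele orientation (harmonise
    first); sample sizes add.
    """
    if str(a["rsid"]) != str(b["rsid"]):
        raise ValueError(f"rsid mismatch: {a['rsid']} vs {b['rsid']}")
    if (a["ea"], a["oa"]) != (b["ea"], b["oa"]):
        raise ValueError(f"{a['rsid']}: allele mismatch; harmonise before meta-analysis")
    wa, wb = 1.0 / a["se"] ** 2, 1.0 / b["se"] ** 2
    beta = (a["beta"] * wa + b["beta"] * wb) / (wa + wb)
    se = (wa + wb) ** -0.5
    out = a.copy()
    out["beta"], out["se"] = beta, se
    out["p"] = _normal_p(beta / se)
    out["n"] = a["n"] + b["n"]
    # pool the allele frequency by sample size when both sides report one
    if not (pd.isna(a.get("eaf")) or pd.isna(b.get("eaf"))):
        out["eaf"] = (a["eaf"] * a["n"] + b["eaf"] * b["n"]) / (a["n"] + b["n"])
    return out


def meta_analyse(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect meta-analysis of two summary-statistics tables over shared rsids."""
    bi = b.set_index("rsid", drop=False)
    rows = [
        fixed_effect_meta(row, bi.loc[row["rsid"]])
        for _, row in a.iterrows()
        if row["rsid"] in bi.index
    ]
    return pd.DataFrame(rows).reset_index(drop=True)


def wald_ratio(pair: pd.Series, second_order: bool = False) -> RatioEstimate:
    """Wald ratio for one harmonised pair: theta = beta_out / beta_exp.

    The default SE is first-order delta method, |se_out / beta_exp|, ignoring
    the exposure uncertainty (the usual choice when instruments are strong).
    With ``second_order`` the exposure term enters as well:
    se^2 = se_out^2/beta_exp^2 + beta_out^2 se_exp^2 / beta_exp^4, which
    matters for large ratios.
    """
    if pair["beta_exp"] == 0:
        raise ZeroDivisionError(f"{pair['rsid']}: undefined ratio (beta_exp = 0)")
    theta = pair["beta_out"] / pair["beta_exp"]
    var = (pair["se_out"] / pair["beta_exp"]) ** 2
    if second_order:
        var += pair["beta_out"] ** 2 * pair["se_exp"] ** 2 / pair["beta_exp"] ** 4
    return RatioEstimate(str(pair["rsid"]), float(theta), float(np.sqrt(var)))


def wald_ratios(pairs: pd.DataFrame, second_order: bool = False) -> list[RatioEstimate]:
    return [wald_ratio(row, second_order=second_order) for _, row in pairs.iterrows()]


def ivw(estimates: list[RatioEstimate]) -> MrEstimate:
    """Fixed-effect IVW combination of Wald ratios.

    beta = sum(w_j theta_j) / sum(w_j), se = sum(w_j)^-1/2 with
    w_j = 1/se_j^2.  The multiplicative-error (random-effect) rescaling is
    deliberately not applied.
    """
    if not estimates:
        raise ValueError("ivw requires at least one ratio estimate")
    w = np.array([e.weight for e in estimates])
    theta = np.array([e.theta for e in estimates])
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return MrEstimate("ivw", beta, se, _normal_p(beta / se), len(estimates))


def egger_intercept_test(pairs: pd.DataFrame) -> dict:
    """MR-Egger regression: weighted LS of beta_out on beta_exp, free intercept.

    Pairs are oriented so every beta_exp > 0 (flipping both betas of a pair
    preserves the ratio), weights are 1/se_out².  A non-zero intercept flags
    directional pleiotropy.  Needs at least 3 pairs; otherwise the diagnostic
    is returned as not evaluable.
    """
    if len(pairs) < 3:
        return {"evaluable": False, "reason": f"need >= 3 pairs, got {len(pairs)}"}
    sgn = np.sign(pairs["beta_exp"].to_numpy(dtype=float))
    bx = pairs["beta_exp"].to_numpy(dtype=float) * sgn
    by = pairs["beta_out"].to_numpy(dtype=float) * sgn
    w = 1.0 / pairs["se_out"].to_numpy(dtype=float) ** 2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    icept, slope = float(fit.params[0]), float(fit.params[1])
    se_icept, se_slope = float(fit.bse[0]), float(fit.bse[1])
    return {
        "evaluable": True,
        "intercept": icept,
        "se_intercept": se_icept,
        "intercept_p": _ratio_p(icept, se_icept),
        "slope": slope,
        "se_slope": se_slope,
        "slope_p": _ratio_p(slope, se_slope),
    }


def cochran_q(estimates: list[RatioEstimate], beta_ivw: float) -> dict:
    """Cochran's Q heterogeneity statistic around an IVW estimate."""
    if len(estimates) < 2:
        return {"evaluable": False, "reason": f"need >= 2 estimates, got {len(estimates)}"}
    w = np.array([e.weight for e in estimates])
    theta = np.array([e.theta for e in estimates])
    q = float(np.sum(w * (theta - beta_ivw) ** 2))
    df = len(estimates) - 1
    return {"evaluable": True, "q": q, "df": df, "p": float(stats.chi2.sf(q, df))}


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q_(i) = min_{k >= i} m * p_(k) / k, clipped at 1.  Input values must lie
    in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
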