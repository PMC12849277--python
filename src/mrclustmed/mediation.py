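"""Two-step mediation MR: screening, product-of-coefficients, contrasts.

Step 1 estimates the effect of each cluster-scaled exposure on every protein;
step 2 estimates each protein's effect on the outcome.  Proteins passing FDR
in both steps are candidate mediators.  The mediated effect is the product of
the two step estimates, with a first-order delta-method SE

    se = sqrt(beta1^2 se2^2 + beta2^2 se1^2)

and, because the product of two normals is not normal near the significance
boundary, an empirical Monte Carlo confidence interval from independent
normal resamples of the two estimates.  The proportion mediated divides the
product by the cluster's total exposure-outcome effect; for odds-ratio
outcomes this is an approximation (non-collapsibility), reported as ratio
arithmetic only.

Between-cluster contrasts exploit that the step-2 estimate is shared by all
clusters for a given protein: the difference of mediated effects equals
(beta_A - beta_B) * beta_protein, tested with the delta-method SE for a
product of two random variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mr_core import bh_fdr


@dataclass
class MediationResult:
    """Product-of-coefficients mediation estimate for one (cluster, protein)."""

    cluster: str
    protein: str
    beta_step1: float
    se_step1: float
    q_step1: float
    beta_step2: float
    se_step2: float
    q_step2: float
    mediated: float
    se_mediated: float
    sobel_z: float
    sobel_p: float
    ci_level: float
    ci_lower: float
    ci_upper: float
    mc_draws: int
    mc_seed: int
    total: float | None = None
    proportion: float | None = None

    def to_record(self) -> dict:
        return self.__dict__.copy()


@dataclass
class ClusterContrast:
    """Difference in mediating effects of one protein between two clusters."""

    protein: str
    cluster_a: str
    cluster_b: str
    beta_diff: float           # step-1 difference between clusters
    se_diff: float
    beta_protein: float        # shared step-2 estimate
    se_protein: float
    effect: float              # beta_diff * beta_protein
    se_effect: float           # delta-method SE of the product
    z: float
    p: float
    ci_level: float
    ci_lower: float
    ci_upper: float
    mc_draws: int
    mc_seed: int

    def to_record(self) -> dict:
        return self.__dict__.copy()


def z_test(beta1: float, se1: float, beta2: float, se2: float) -> tuple[float, float]:
    """Two-sided normal Z-test for the difference of two independent estimates."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be > 0")
    z = (beta1 - beta2) / np.sqrt(se1**2 + se2**2)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def product_of_coefficients(
    beta1: float, se1: float, beta2: float, se2: float
) -> tuple[float, float]:
    """Mediated effect beta1*beta2 with first-order delta-method SE."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be > 0")
    mediated = beta1 * beta2
    se = np.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)
    return float(mediated), float(se)


def monte_carlo_ci(
    beta1: float, se1: float, beta2: float, se2: float,
    draws: int = 1_000_000, seed: int = 0, level: float = 0.95,
) -> tuple[float, float]:
    """Empirical CI for a product of two independent normal estimates.

    Draws b1* ~ N(beta1, se1^2) and b2* ~ N(beta2, se2^2) independently and
    takes the (1-level)/2 and 1-(1-level)/2 quantiles of b1*b2*.
    """
    if draws < 10_000:
        raise ValueError("use at least 10,000 draws")
    rng = np.random.default_rng(seed)
    prod = rng.normal(beta1, se1, draws) * rng.normal(beta2, se2, draws)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(prod, [alpha, 1 - alpha])
    return float(lo), float(hi)


def proportion_mediated(mediated: float, total: float) -> float:
    """Signed fraction of the total effect carried by the mediator.

    Negative values mean the mediator works against the cluster's total
    effect.  Percentage formatting belongs to reports, not here.
    """
    if total == 0:
        raise ZeroDivisionError("total effect is zero")
    return mediated / total


def screen_mediators(
    step1: pd.DataFrame,
    step2: pd.DataFrame,
    alpha: float = 0.05,
    pooled_step1_fdr: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Double-FDR screen for candidate mediators.

    ``step1`` has columns (cluster, protein, beta, se, p); ``step2`` has
    (protein, beta, se, p).  Step-1 p-values are BH-corrected within each
    cluster across the protein panel (or pooled across clusters when
    ``pooled_step1_fdr``); step-2 p-values across all proteins.  A
    (cluster, protein) pair is a candidate iff both q-values fall below
    ``alpha``.  Proteins present in step 1 but missing from step 2 are
    excluded and logged.

    Returns the annotated candidate table (all pairs, with q1/q2 and a
    ``candidate`` flag) and the exclusion log.
    """
    s1 = step1.copy()
    s2 = step2.copy().set_index("protein", drop=False)
    if pooled_step1_fdr:
        s1["q"] = bh_fdr(s1["p"].to_numpy())
    else:
        s1["q"] = np.nan
        for _, idx in s1.groupby("cluster").groups.items():
            s1.loc[idx, "q"] = bh_fdr(s1.loc[idx, "p"].to_numpy())
    s2["q"] = bh_fdr(s2["p"].to_numpy())

    log: list[str] = []
    rows = []
    for _, r in s1.iterrows():
        protein = r["protein"]
        if protein not in s2.index:
            log.append(f"{r['cluster']}/{protein}: absent from step 2; excluded")
            continue
        r2 = s2.loc[protein]
        rows.append({
            "cluster": r["cluster"], "protein": protein,
            "beta1": r["beta"], "se1": r["se"], "q1": r["q"],
            "beta2": r2["beta"], "se2": r2["se"], "q2": r2["q"],
            "candidate": bool(r["q"] < alpha and r2["q"] < alpha),
        })
    return pd.DataFrame(rows), log


def mediate(
    cluster: str,
    protein: str,
    beta1: float, se1: float, q1: float,
    beta2: float, se2: float, q2: float,
    total: float | None = None,
    draws: int = 1_000_000,
    seed: int = 0,
    level: float = 0.95,
) -> MediationResult:
    """Full mediation bookkeeping for one (cluster, protein) pair."""
    mediated, se_med = product_of_coefficients(beta1, se1, beta2, se2)
    lo, hi = monte_carlo_ci(beta1, se1, beta2, se2, draws=draws, seed=seed, level=level)
    sobel_z = mediated / se_med if se_med > 0 else np.nan
    return MediationResult(
        cluster=cluster, protein=protein,
        beta_step1=beta1, se_step1=se1, q_step1=q1,
        beta_step2=beta2, se_step2=se2, q_step2=q2,
        mediated=mediated, se_mediated=se_med,
        sobel_z=float(sobel_z), sobel_p=float(2 * stats.norm.sf(abs(sobel_z))),
        ci_level=level, ci_lower=lo, ci_upper=hi, mc_draws=draws, mc_seed=seed,
        total=total,
        proportion=proportion_mediated(mediated, total) if total else None,
    )


def cluster_difference(
    protein: str,
    cluster_a: str, beta_a: float, se_a: float,
    cluster_b: str, beta_b: float, se_b: float,
    beta_protein: float, se_protein: float,
    draws: int = 1_000_000,
    seed: int = 0,
    level: float = 0.95,
) -> ClusterContrast:
    """Between-cluster contrast of mediated effects for one protein.

    beta_diff = beta_A - beta_B (step 1), se_diff = sqrt(se_A^2 + se_B^2);
    the contrasted quantity is beta_diff * beta_protein with delta-method SE

        sigma = sqrt(beta_diff^2 se_protein^2 + beta_protein^2 se_diff^2),

    a two-sided normal p for z = (beta_diff * beta_protein) / sigma, and a
    Monte Carlo CI for the product.
    """
    for se in (se_a, se_b, se_protein):
        if se <= 0:
            raise ValueError("standard errors must be > 0")
    beta_diff = beta_a - beta_b
    se_diff = float(np.sqrt(se_a**2 + se_b**2))
    effect, se_effect = product_of_coefficients(beta_diff, se_diff, beta_protein, se_protein)
    z = effect / se_effect if se_effect > 0 else 0.0
    lo, hi = monte_carlo_ci(
        beta_diff, se_diff, beta_protein, se_protein,
        draws=draws, seed=seed, level=level,
    )
    return ClusterContrast(
        protein=protein, cluster_a=cluster_a, cluster_b=cluster_b,
        beta_diff=float(beta_diff), se_diff=se_diff,
        beta_protein=beta_protein, se_protein=se_protein,
        effect=effect, se_effect=se_effect,
        z=float(z), p=float(2 * stats.norm.sf(abs(z))),
        ci_level=level, ci_lower=lo, ci_upper=hi, mc_draws=draws, mc_seed=seed,
    )


def significance_tier(p: float, ci: tuple[float, float]) -> str:
    """Report tier: '**' p<0.01, '*' p<0.05, '°' only the MC CI excludes 0."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    lo, hi = ci
    if lo > 0 or hi < 0:
        return "°"
    return ""
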