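"""Weighted allele scores and one-sample Mendelian randomisation.

Cluster-specific polygenic scores are per-individual weighted sums of
effect-allele dosages.  Using the score as a single joint instrument, the
one-sample MR estimate is the Wald ratio of the score-outcome association
(logistic, log odds ratio) over the score-exposure association (linear, on
the rank-based inverse-normal transformed exposure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class Association:
    """A single regression coefficient with its SE and normal p-value."""

    beta: float
    se: float
    pvalue: float
    n: int


@dataclass
class WaldMr:
    """One-sample Wald-ratio MR estimate from two score associations."""

    beta_num: float
    se_num: float
    beta_den: float
    se_den: float

    @property
    def wald(self) -> float:
        return self.beta_num / self.beta_den

    @property
    def se_wald(self) -> float:
        return abs(self.se_num / self.beta_den)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.wald - z * self.se_wald, self.wald + z * self.se_wald


def inverse_normal_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset by default).

    A value with rank r (average ranks for ties) maps to
    Phi^-1((r - offset) / (n - 2*offset + 1)) where n counts non-missing
    values; missing values are excluded from ranking and stay missing.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.nanmin(x) == np.nanmax(x):
        raise ValueError("degenerate ranks: all values identical")
    ranks = stats.rankdata(x[mask], method="average")
    out[mask] = stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))
    return out


def compute_pgs(
    dosages: pd.DataFrame,
    scored_alleles: pd.Series,
    weights: pd.Series,
    weight_alleles: pd.Series | None = None,
) -> pd.Series:
    """Per-individual weighted allele score.

    Parameters
    ----------
    dosages
        individuals x variants matrix of effect-allele dosages in [0, 2];
        columns are rsids.
    scored_alleles
        rsid -> allele the dosage column counts.
    weights
        rsid -> per-allele weight; variants without a weight are ignored.
    weight_alleles
        rsid -> allele the weight refers to.  Where it differs from the
        scored allele the weight's variant is re-oriented
        (dosage -> 2 - dosage).  A joint allele/weight-sign flip therefore
        changes the score only by an additive constant (2w per flipped
        variant), which the intercept of any downstream regression absorbs.
    """
    if ((dosages < 0) | (dosages > 2)).any().any():
        raise ValueError("dosages must lie in [0, 2]")
    shared = [r for r in weights.index if r in dosages.columns]
    if not shared:
        raise ValueError("no overlap between weighted variants and the dosage matrix")
    score = pd.Series(0.0, index=dosages.index)
    for rsid in shared:
        w = float(weights[rsid])
        d = dosages[rsid]
        if weight_alleles is not None and weight_alleles[rsid] != scored_alleles[rsid]:
            d = 2.0 - d
        score += w * d
    return score


def _design(score: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    cols = [np.ones(len(score)), np.asarray(score, dtype=float)]
    names = ["const", "score"]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design (rank {rank} < {X.shape[1]}): "
                         f"check columns {names}")
    return X


def linear_association(
    score,
    outcome,
    covariates: pd.DataFrame | None = None,
) -> Association:
    """OLS of a quantitative outcome on the score plus covariates (and intercept)."""
    X = _design(np.asarray(score), covariates)
    y = np.asarray(outcome, dtype=float)
    fit = sm.OLS(y, X).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    return Association(beta, se, float(2 * stats.norm.sf(abs(z))), len(y))


def logistic_association(
    score,
    case,
    covariates: pd.DataFrame | None = None,
) -> Association:
    """Maximum-likelihood logistic regression of case status on the score.

    The score coefficient is a log odds ratio; SEs come from the observed
    information at the optimum.  Perfect separation raises.
    """
    y = np.asarray(case, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("case must contain both classes, coded 0/1")
    X = _design(np.asarray(score), covariates)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, tol=1e-10, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError among others
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(fit.bse)):
        raise ValueError("logistic fit did not yield finite standard errors "
                         "(possible separation)")
    beta, se = float(fit.params[1]), float(fit.bse[1])
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return Association(beta, se, p, len(y))


def one_sample_wald(num: Association, den: Association) -> WaldMr:
    """One-sample Wald MR: score-outcome effect over score-exposure effect."""
    if den.beta == 0:
        raise ZeroDivisionError("denominator association is zero: undefined ratio")
    return WaldMr(num.beta, num.se, den.beta, den.se)


def assert_disjoint_samples(ids_a, ids_b) -> None:
    """Guard for the two-sample-within-one-cohort design: id sets must not overlap."""
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise ValueError(
            f"sub-samples are not disjoint: {len(overlap)} shared ids "
            f"(e.g. {sorted(overlap)[:5]})"
        )
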