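"""Soft clustering of per-variant Wald ratios by expectation-maximization.

Variants instrumenting the same exposure need not act through the same
pathway: groups of variants sharing a causal mechanism show similar ratio
estimates on the outcome, while mechanism-free variants scatter around zero
and a few outliers fit nothing at all.  The mixture here captures that
structure with K substantive clusters, a null component and a junk component:

* cluster k:  theta_j ~ Normal(mu_k, sigma_j^2)   (per-variant sampling noise)
* null:       theta_j ~ Normal(0, sigma_j^2)      (mean fixed at zero)
* junk:       theta_j ~ Uniform over a widened interval around the observed
              ratios (location-free, heavy)

The per-variant variances sigma_j^2 are the squared Wald-ratio standard
errors, so precisely estimated variants dominate the cluster means.  Fitting
is by EM with seeded multi-restart initialisation; the number of substantive
clusters is selected by BIC.  Cluster labels are canonicalised with means in
ascending order, so fits differing only by label permutation are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .mr_core import MrEstimate, RatioEstimate, ivw

_MAX_ITER = 5000
_TOL = 1e-8


@dataclass
class MixtureModel:
    """Fitted ratio-estimate mixture: K substantive clusters + null + junk."""

    K: int
    means: np.ndarray          # ascending, length K
    pi: np.ndarray             # mixing proportions of substantive clusters
    pi_null: float
    pi_junk: float
    junk_low: float
    junk_high: float
    log_likelihood: float
    bic: float
    n_restarts: int
    seed: int
    overdispersion: float = 1.0
    trace: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        total = self.pi.sum() + self.pi_null + self.pi_junk
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixing proportions sum to {total}, not 1")
        if not np.isfinite(self.log_likelihood):
            raise ValueError("log-likelihood must be finite")

    @property
    def component_labels(self) -> list[str]:
        return [f"cluster_{k + 1}" for k in range(self.K)] + ["null", "junk"]

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "means": self.means.tolist(),
            "pi": self.pi.tolist(),
            "pi_null": self.pi_null,
            "pi_junk": self.pi_junk,
            "junk_interval": [self.junk_low, self.junk_high],
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "overdispersion": self.overdispersion,
        }


@dataclass
class ClusterAssignment:
    """Per-variant inclusion probabilities over {cluster_1..K, null, junk}."""

    table: pd.DataFrame        # rsid, theta, se, prob_*, label, confident
    prob_threshold: float
    model: MixtureModel

    @property
    def prob_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("prob_")]

    def members(self, label: str, confident_only: bool = True) -> pd.DataFrame:
        t = self.table[self.table["label"] == label]
        return t[t["confident"]] if confident_only else t

    def counts(self) -> dict[str, int]:
        return {
            lbl: int(len(self.members(lbl)))
            for lbl in self.model.component_labels
        }


def _as_arrays(estimates: list[RatioEstimate]) -> tuple[np.ndarray, np.ndarray]:
    theta = np.array([e.theta for e in estimates], dtype=float)
    se = np.array([e.se_theta for e in estimates], dtype=float)
    return theta, se


def _junk_interval(theta: np.ndarray) -> tuple[float, float]:
    # uniform junk support: observed range widened by one range on each side
    lo, hi = float(theta.min()), float(theta.max())
    r = hi - lo
    if r == 0:
        r = 1.0  # degenerate: all ratios identical
    return lo - r, hi + r


def _component_loglik(
    theta: np.ndarray,
    se: np.ndarray,
    means: np.ndarray,
    junk: tuple[float, float],
    overdispersion: float,
) -> np.ndarray:
    """Per-variant log density under each component, shape (n, K+2)."""
    K = len(means)
    var = se**2
    norm_const = -0.5 * np.log(2 * np.pi * var)
    ll = np.empty((len(theta), K + 2))
    ll[:, :K] = norm_const[:, None] - 0.5 * (theta[:, None] - means[None, :]) ** 2 / var[:, None]
    var_null = var * overdispersion
    ll[:, K] = -0.5 * np.log(2 * np.pi * var_null) - 0.5 * theta**2 / var_null
    lo, hi = junk
    inside = (theta >= lo) & (theta <= hi)
    ll[:, K + 1] = np.where(inside, -np.log(hi - lo), -np.inf)
    return ll


def _em(
    theta: np.ndarray,
    se: np.ndarray,
    means0: np.ndarray,
    junk: tuple[float, float],
    overdispersion: float,
    pi0: np.ndarray | None = None,
    max_iter: int = _MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Run EM from one initialisation.

    Returns (means, pi over all K+2 components, log-likelihood, trace).
    The null and junk log-densities are parameter-free and precomputed.
    """
    K = len(means0)
    means = means0.astype(float).copy()
    pi = np.full(K + 2, 1.0 / (K + 2)) if pi0 is None else pi0.astype(float).copy()
    var = se**2
    prec = 1.0 / var
    norm_const = -0.5 * np.log(2 * np.pi * var)

    comp_ll = np.empty((len(theta), K + 2))
    var_null = var * overdispersion
    comp_ll[:, K] = -0.5 * np.log(2 * np.pi * var_null) - 0.5 * theta**2 / var_null
    lo, hi = junk
    inside = (theta >= lo) & (theta <= hi)
    comp_ll[:, K + 1] = np.where(inside, -np.log(hi - lo), -np.inf)

    trace = []
    prev = -np.inf
    prec_theta = prec * theta
    for _ in range(max_iter):
        comp_ll[:, :K] = (
            norm_const[:, None]
            - 0.5 * (theta[:, None] - means[None, :]) ** 2 * prec[:, None]
        )
        with np.errstate(divide="ignore"):
            weighted = comp_ll + np.log(pi)
        row_max = weighted.max(axis=1)
        shifted = np.exp(weighted - row_max[:, None])
        row_sum = shifted.sum(axis=1)
        ll = float(np.sum(np.log(row_sum) + row_max))
        trace.append(ll)
        resp = shifted / row_sum[:, None]
        # M-step: precision- and responsibility-weighted cluster means
        pi = resp.mean(axis=0)
        if K:
            denom = resp[:, :K].T @ prec
            numer = resp[:, :K].T @ prec_theta
            ok = denom > 0
            means[ok] = numer[ok] / denom[ok]
        if ll - prev < _TOL and np.isfinite(prev):
            break
        prev = ll
    return means, pi, trace[-1], np.array(trace)


def _initial_means(theta: np.ndarray, K: int, restart: int, rng: np.random.Generator) -> np.ndarray:
    if K == 0:
        return np.empty(0)
    if restart == 0:
        # deterministic first restart: evenly spaced quantiles of theta
        return np.quantile(theta, (np.arange(K) + 0.5) / K)
    lo, hi = theta.min(), theta.max()
    return rng.uniform(lo, hi, size=K)


def _canonicalise(means: np.ndarray, pi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K = len(means)
    order = np.argsort(means, kind="mergesort")
    return means[order], np.concatenate([pi[:K][order], pi[K:]])


def fit_em(
    estimates: list[RatioEstimate],
    K: int,
    seed: int,
    n_restarts: int = 1,
    overdispersion: float = 1.0,
) -> MixtureModel:
    """Fit the K-cluster + null + junk mixture by seeded multi-restart EM.

    The first restart starts the cluster means at evenly spaced quantiles of
    the observed ratios; further restarts draw starting means uniformly over
    the ratio range.  The best log-likelihood wins.  EM stops when the
    log-likelihood improves by less than 1e-8 or after 5000 iterations; the
    log-likelihood trace is monotone non-decreasing by construction of EM.
    """
    n = len(estimates)
    if K < 0:
        raise ValueError("K must be >= 0")
    if K + 2 > n:
        raise ValueError(f"need at least K+2={K + 2} estimates, got {n}")
    theta, se = _as_arrays(estimates)
    junk = _junk_interval(theta)
    rng = np.random.default_rng(seed)

    # short-run strategy: every restart gets a capped burn-in, only the most
    # promising run is polished to full convergence (EM continues from the
    # burn-in state, so the joined trace remains monotone non-decreasing)
    short = None
    for restart in range(max(1, n_restarts)):
        means0 = _initial_means(theta, K, restart, rng)
        means, pi, ll, trace = _em(
            theta, se, means0, junk, overdispersion, max_iter=100,
        )
        if short is None or ll > short[2]:
            short = (means, pi, ll, trace)
        if K == 0:
            break  # no means to randomise; restarts are identical
    means, pi, ll, trace = short
    means, pi, ll, tail = _em(theta, se, means, junk, overdispersion, pi0=pi)
    trace = np.concatenate([trace, tail])
    means, pi = _canonicalise(means, pi)
    bic = -2.0 * ll + (2 * K + 1) * np.log(n)
    return MixtureModel(
        K=K, means=means, pi=pi[:K], pi_null=float(pi[K]), pi_junk=float(pi[K + 1]),
        junk_low=junk[0], junk_high=junk[1], log_likelihood=ll, bic=bic,
        n_restarts=max(1, n_restarts), seed=seed,
        overdispersion=overdispersion, trace=trace,
    )


def select_model(
    estimates: list[RatioEstimate],
    K_max: int,
    n_restarts: int = 30,
    seed: int = 0,
    overdispersion: float = 1.0,
) -> MixtureModel:
    """Fit K = 0..K_max and return the BIC-minimising mixture.

    BIC = -2 logL + (2K+1) log n: each substantive cluster adds a mean and a
    free mixing proportion, and one proportion is free in the K=0 model.
    Restart seeds derive deterministically from ``seed``, so the result is a
    pure function of (estimates, K_max, n_restarts, seed).  Ties in BIC break
    toward the smaller K.
    """
    if K_max < 0:
        raise ValueError("K_max must be >= 0")
    seeds = np.random.SeedSequence(seed).generate_state(K_max + 1)
    best: MixtureModel | None = None
    for K in range(K_max + 1):
        if K + 2 > len(estimates):
            break
        model = fit_em(
            estimates, K, seed=int(seeds[K] % (2**31)), n_restarts=n_restarts,
            overdispersion=overdispersion,
        )
        if best is None or model.bic < best.bic:
            best = model
    if best is None:
        raise ValueError("no model could be fitted (too few estimates)")
    return best


def responsibilities(model: MixtureModel, estimates: list[RatioEstimate]) -> np.ndarray:
    """Posterior inclusion probabilities under a fitted model, shape (n, K+2)."""
    theta, se = _as_arrays(estimates)
    comp_ll = _component_loglik(
        theta, se, model.means, (model.junk_low, model.junk_high), model.overdispersion
    )
    pi = np.concatenate([model.pi, [model.pi_null, model.pi_junk]])
    with np.errstate(divide="ignore"):
        weighted = comp_ll + np.log(pi)
    return np.exp(weighted - logsumexp(weighted, axis=1)[:, None])


def assign(
    model: MixtureModel,
    estimates: list[RatioEstimate],
    prob_threshold: float = 0.8,
    min_cluster_size: int = 4,
) -> ClusterAssignment:
    """Assign variants to components and dissolve under-populated clusters.

    Hard labels are the argmax of the posterior inclusion probabilities; a
    variant is 'confident' when its top probability reaches
    ``prob_threshold``.  Any substantive cluster retaining fewer than
    ``min_cluster_size`` confident members is dissolved: its probability mass
    is removed, each variant's remaining probabilities are renormalised (so
    members fall to their next-best component) and labels recomputed, until
    all surviving clusters are large enough.
    """
    resp = responsibilities(model, estimates)
    labels = np.array(model.component_labels)
    active = np.ones(len(labels), dtype=bool)

    while True:
        probs = resp * active
        probs = probs / probs.sum(axis=1, keepdims=True)
        hard = probs.argmax(axis=1)
        confident = probs.max(axis=1) >= prob_threshold
        dissolved = None
        for k in range(model.K):
            if not active[k]:
                continue
            n_conf = int(np.sum((hard == k) & confident))
            if n_conf < min_cluster_size:
                # dissolve the smallest offender first for determinism
                if dissolved is None or n_conf < dissolved[1]:
                    dissolved = (k, n_conf)
        if dissolved is None:
            break
        active[dissolved[0]] = False

    table = pd.DataFrame({
        "rsid": [e.rsid for e in estimates],
        "theta": [e.theta for e in estimates],
        "se": [e.se_theta for e in estimates],
    })
    for i, lbl in enumerate(labels):
        table[f"prob_{lbl}"] = probs[:, i]
    table["label"] = labels[hard]
    table["confident"] = confident
    return ClusterAssignment(table=table, prob_threshold=prob_threshold, model=model)


def cluster_ivw(
    assignment: ClusterAssignment,
    pairs: pd.DataFrame,
    second_order: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cluster fixed-effect IVW MR over confident members (junk excluded).

    For every substantive cluster and the null component, combine the Wald
    ratios of the confidently assigned variants by IVW and report, alongside,
    the unweighted mean of the member ratios ('cluster mean').  Clusters with
    no confident members are omitted and logged.

    Returns a per-cluster results table and a log of omissions.
    """
    from .mr_core import wald_ratio

    pair_index = pairs.set_index("rsid", drop=False)
    rows, log = [], []
    for lbl in assignment.model.component_labels:
        if lbl == "junk":
            continue
        members = assignment.members(lbl, confident_only=True)
        if len(members) == 0:
            log.append(f"{lbl}: no confident members; omitted")
            continue
        missing = [r for r in members["rsid"] if r not in pair_index.index]
        if missing:
            raise KeyError(f"{lbl}: confident members absent from pairs: {missing[:5]}")
        ratios = [wald_ratio(pair_index.loc[r], second_order=second_order)
                  for r in members["rsid"]]
        est: MrEstimate = ivw(ratios)
        lo, hi = est.ci()
        rows.append({
            "cluster": lbl,
            "n_snps": len(ratios),
            "cluster_mean": float(np.mean([e.theta for e in ratios])),
            "beta": est.beta, "se": est.se, "p": est.pvalue,
            "ci_lower": lo, "ci_upper": hi,
        })
    return pd.DataFrame(rows), log
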