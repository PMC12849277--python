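"""Synthetic GWAS summary statistics and cohort data with the structure the
analysis assumes.

The generator emulates a clustered-pleiotropy study: variants associated with
a quantitative exposure fall into K substantive clusters sharing a common
ratio effect on a binary outcome, plus a mass of null variants (no outcome
effect) and a few junk outliers.  Per-variant sampling noise follows the
standard GWAS variance approximation se^2 = 1 / (2 n f (1-f)) for a
variance-1 trait, so noise shrinks with sample size and intermediate allele
frequency.  A configurable mediation architecture links clusters to the
outcome through a molecular (protein) panel, both at summary level (pQTL
tables per protein) and at individual level (a cohort with dosages,
phenotypes and protein measurements split into two disjoint sub-samples for
the two-sample-within-one-cohort design).

Default parameters mirror the study conditions the pipeline targets: clusters
of 24/73/7 variants at ratio means 0.98/-0.61/-1.74, 360 null variants,
exposure GWAS components of 266,130 + 322,154 samples, an outcome GWAS of
247,173, and an outcome prevalence of 0.085.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .gwas_io import CANONICAL_COLUMNS, LdMatrix
from .protein_instruments import GeneLocus

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


@dataclass
class MediationLink:
    """One edge of the mediation architecture."""

    cluster: int               # index into SimulationConfig.clusters
    protein: int               # index into the protein panel
    exposure_effect: float     # cluster-scaled exposure -> protein, per exposure SD
    outcome_effect: float      # protein -> outcome, log-OR per protein SD


@dataclass
class SimulationConfig:
    """Everything the generator needs; reproducible end-to-end from ``seed``."""

    seed: int = 0
    # variant panel
    clusters: tuple = ((24, 0.98), (73, -0.61), (7, -1.74))
    n_null_snps: int = 360
    n_junk_snps: int = 0
    junk_theta_range: tuple = (-4.0, 4.0)
    # instruments are parameterised by their per-variant exposure correlation
    # r = beta * sqrt(2 f (1-f)); the panel emulates post-selection instruments
    # (the strength at which the published filtering flow retains the cluster
    # architecture), not a full realistic GWAS effect-size spectrum
    instrument_r_range: tuple = (0.05, 0.11)
    beta_exp_range: tuple | None = None   # direct |beta| draw, overrides the above
    eaf_range: tuple = (0.20, 0.80)
    # GWAS sample sizes
    n_exp_components: tuple = (266_130, 322_154)
    n_out: int = 247_173
    outcome_case_fraction: float = 133_384 / 247_173
    n_protein_gwas: int = 34_000
    binary_normal_approx_min_n: int = 50_000
    # protein panel + mediation architecture
    # mediator effects are sized to be detectable at the desk-scale cohort
    # size below (the emulated study's proteomics sub-cohort is an order of
    # magnitude larger); outcome effects mirror strong-mediator magnitudes
    n_proteins: int = 20
    architecture: tuple = (
        MediationLink(0, 0, -0.50, -0.148),
        MediationLink(1, 1, -0.40, 0.19),
        MediationLink(2, 2, 0.90, -0.148),
    )
    protein_noise_sd: float = 1.0
    n_pqtl_per_protein: int = 5
    n_cis_pqtl: int = 4
    pqtl_beta_range: tuple = (0.08, 0.20)
    # cohort
    n_individuals: int = 20_000
    prevalence: float = 0.085
    protein_subsample_fraction: float = 0.50
    cohort_h2: float = 0.25   # exposure heritability the cohort's effects rescale to

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=list)


@dataclass
class SummaryData:
    """Output of :func:`simulate_summary_stats`."""

    exposure: list                       # one canonical table per GWAS component
    outcome: pd.DataFrame                # covers exposure variants and all pQTLs
    proteins: dict                       # protein label -> pQTL canonical table
    loci: dict                           # protein label -> GeneLocus
    truth: pd.DataFrame                  # rsid, component, true_theta, true_beta_exp
    ld: LdMatrix
    config: SimulationConfig = field(repr=False, default=None)


def _se(n, f, case_fraction: float | None = None) -> np.ndarray:
    """Standard GWAS SE approximation.

    For a variance-1 quantitative trait, se^2 = 1 / (2 n f (1-f)).  For a
    binary trait analysed as a log-OR the phenotypic variance term
    phi (1 - phi) (phi = case fraction) enters the denominator as well.
    """
    denom = 2.0 * np.asarray(n, dtype=float) * f * (1.0 - f)
    if case_fraction is not None:
        denom = denom * case_fraction * (1.0 - case_fraction)
    return 1.0 / np.sqrt(denom)


def _p_from_z(beta, se) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta / se))


def _variant_panel(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Truth table for the exposure-instrument panel.

    Variants are laid out round-robin over 22 chromosomes with 1 Mb spacing
    within a chromosome, so the default (LD-free) panel survives distance
    clumping intact.
    """
    comps, thetas = [], []
    for k, (n_k, mu_k) in enumerate(config.clusters):
        comps += [f"cluster_{k + 1}"] * n_k
        thetas += [mu_k] * n_k
    comps += ["null"] * config.n_null_snps
    thetas += [0.0] * config.n_null_snps
    lo, hi = config.junk_theta_range
    comps += ["junk"] * config.n_junk_snps
    thetas += list(rng.uniform(lo, hi, config.n_junk_snps))

    m = len(comps)
    order = rng.permutation(m)  # interleave components along the genome
    chrom = (np.arange(m) % 22) + 1
    pos = (np.arange(m) // 22 + 1) * 1_000_000
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), m)]
    swap = rng.random(m) < 0.5
    ea = [p[1] if s else p[0] for p, s in zip(pairs, swap)]
    oa = [p[0] if s else p[1] for p, s in zip(pairs, swap)]

    eaf = rng.uniform(*config.eaf_range, m)
    signs = rng.choice([-1.0, 1.0], m)
    if config.beta_exp_range is not None:
        beta = rng.uniform(*config.beta_exp_range, m) * signs
    else:
        r = rng.uniform(*config.instrument_r_range, m)
        beta = r / np.sqrt(2.0 * eaf * (1.0 - eaf)) * signs
    return pd.DataFrame({
        "rsid": [f"rs{i + 1:06d}" for i in range(m)],
        "chr": chrom.astype(str),
        "pos": pos,
        "ea": ea,
        "oa": oa,
        "eaf": eaf,
        "component": np.array(comps)[order],
        "true_theta": np.array(thetas)[order],
        "true_beta_exp": beta,
    })


def _observe(
    truth: pd.DataFrame,
    true_beta: np.ndarray,
    n: int,
    rng: np.random.Generator,
    case_fraction: float | None = None,
) -> pd.DataFrame:
    se = _se(n, truth["eaf"].to_numpy(), case_fraction)
    beta = true_beta + rng.normal(0.0, se)
    df = truth[["rsid", "chr", "pos", "ea", "oa", "eaf"]].copy()
    df["beta"], df["se"] = beta, se
    df["p"] = np.clip(_p_from_z(beta, se), 1e-300, 1.0)
    df["n"] = n
    return df[CANONICAL_COLUMNS]


def _scramble_orientation(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Randomly swap allele order and strand so harmonisation has work to do."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    out = df.copy()
    swap = rng.random(len(out)) < 0.5
    flip_strand = rng.random(len(out)) < 0.5
    ea, oa = out["ea"].to_numpy().copy(), out["oa"].to_numpy().copy()
    palindromic = np.array([comp[a] == b for a, b in zip(ea, oa)])
    for i in range(len(out)):
        if flip_strand[i] and not palindromic[i]:
            ea[i], oa[i] = comp[ea[i]], comp[oa[i]]
        if swap[i]:
            ea[i], oa[i] = oa[i], ea[i]
    out["ea"], out["oa"] = ea, oa
    out.loc[swap, "beta"] = -out.loc[swap, "beta"]
    out.loc[swap, "eaf"] = 1.0 - out.loc[swap, "eaf"]
    return out


def simulate_summary_stats(config: SimulationConfig) -> SummaryData:
    """Generate exposure, outcome and per-protein pQTL summary statistics.

    Per variant j the true outcome effect is theta_component(j) times the true
    exposure effect (zero for null variants, a random heavy-tailed ratio for
    junk); observed betas add Normal(0, se^2) noise with the sample-size-driven
    SE.  The outcome table is allele-scrambled relative to the exposure so the
    harmonisation stage is exercised.  Each protein gets cis (and a few trans)
    pQTLs whose outcome effects flow through the protein's outcome effect in
    the mediation architecture.
    """
    rng = np.random.default_rng(config.seed)
    truth = _variant_panel(config, rng)

    exposure = [
        _observe(truth, truth["true_beta_exp"].to_numpy(), n, rng)
        for n in config.n_exp_components
    ]
    beta_out_true = truth["true_theta"].to_numpy() * truth["true_beta_exp"].to_numpy()
    outcome = _observe(truth, beta_out_true, config.n_out, rng,
                       case_fraction=config.outcome_case_fraction)
    outcome = _scramble_orientation(outcome, rng)

    outcome_effects = _protein_outcome_effects(config)
    proteins: dict[str, pd.DataFrame] = {}
    loci: dict[str, GeneLocus] = {}
    extra_outcome_rows = []
    rs_counter = len(truth)
    for p in range(config.n_proteins):
        label = f"protein_{p + 1}"
        chrom = str((p % 22) + 1)
        gene_start = 120_000_000 + (p // 22) * 10_000_000
        loci[label] = GeneLocus(label, chrom, gene_start, gene_start + 50_000)

        n_q = config.n_pqtl_per_protein
        n_cis = min(config.n_cis_pqtl, n_q)
        pos = [gene_start - 900_000 + i * 600_000 for i in range(n_cis)]
        chroms = [chrom] * n_cis
        for t in range(n_q - n_cis):  # trans pQTLs on another chromosome
            chroms.append(str(((p + 7 + t) % 22) + 1))
            pos.append(200_000_000 + t * 2_000_000)
        pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), n_q)]
        qt = pd.DataFrame({
            "rsid": [f"rs{rs_counter + i + 1:06d}" for i in range(n_q)],
            "chr": chroms,
            "pos": pos,
            "ea": [a for a, _ in pairs],
            "oa": [b for _, b in pairs],
            "eaf": rng.uniform(*config.eaf_range, n_q),
        })
        rs_counter += n_q
        beta_q = rng.uniform(*config.pqtl_beta_range, n_q) * rng.choice([-1.0, 1.0], n_q)
        se_q = _se(config.n_protein_gwas, qt["eaf"].to_numpy())
        qt["beta"] = beta_q + rng.normal(0.0, se_q)
        qt["se"] = se_q
        qt["p"] = np.clip(_p_from_z(qt["beta"], qt["se"]), 1e-300, 1.0)
        qt["n"] = config.n_protein_gwas
        proteins[label] = qt[CANONICAL_COLUMNS]

        b_out = outcome_effects.get(label, 0.0)
        se_o = _se(config.n_out, qt["eaf"].to_numpy(),
                   config.outcome_case_fraction)
        beta_o = b_out * beta_q + rng.normal(0.0, se_o)
        orow = qt[["rsid", "chr", "pos", "ea", "oa", "eaf"]].copy()
        orow["beta"], orow["se"] = beta_o, se_o
        orow["p"] = np.clip(_p_from_z(beta_o, se_o), 1e-300, 1.0)
        orow["n"] = config.n_out
        extra_outcome_rows.append(orow[CANONICAL_COLUMNS])

    if extra_outcome_rows:
        outcome = pd.concat([outcome, *extra_outcome_rows], ignore_index=True)

    all_rsids = list(outcome["rsid"])
    return SummaryData(
        exposure=exposure, outcome=outcome, proteins=proteins, loci=loci,
        truth=truth, ld=LdMatrix.identity(all_rsids), config=config,
    )


def _protein_outcome_effects(config: SimulationConfig) -> dict[str, float]:
    effects: dict[str, float] = {}
    for link in config.architecture:
        effects[f"protein_{link.protein + 1}"] = link.outcome_effect
    return effects


def _cluster_exposure_effects(config: SimulationConfig) -> dict[str, dict[int, float]]:
    out: dict[str, dict[int, float]] = {}
    for link in config.architecture:
        out.setdefault(f"protein_{link.protein + 1}", {})[link.cluster] = link.exposure_effect
    return out


def simulate_cohort(
    config: SimulationConfig,
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate individual-level dosages and phenotypes consistent with the
    summary-level model.

    Genotypes are Binomial(2, f_j); the exposure is the genetic score plus
    normal residual scaled to unit variance; each protein is linear in the
    cluster-specific genetic exposure components plus residual noise; the
    binary outcome follows a logistic model whose intercept is solved by
    bisection to hit the target prevalence.  Individuals are split into two
    disjoint sub-samples (``subsample`` 1 and 2); protein levels are observed
    in sub-sample 2 only, mirroring a proteomics sub-cohort.

    Returns (dosages, scored_alleles, cohort).
    """
    rng = np.random.default_rng(config.seed + 1)
    if truth is None:
        truth = _variant_panel(config, np.random.default_rng(config.seed))
    panel = truth[truth["component"] != "junk"].reset_index(drop=True)

    n, m = config.n_individuals, len(panel)
    f = panel["eaf"].to_numpy()
    dosages = pd.DataFrame(
        rng.binomial(2, f, size=(n, m)).astype(float),
        columns=panel["rsid"], index=pd.RangeIndex(n, name="iid"),
    )
    scored_alleles = pd.Series(panel["ea"].to_numpy(), index=panel["rsid"])

    # rescale per-variant effects so the genetic component explains cohort_h2
    # of the unit-variance exposure; the Wald ratio is invariant to this common
    # factor (score-outcome and score-exposure effects scale together)
    beta = panel["true_beta_exp"].to_numpy().copy()
    raw_var_g = float(np.sum(beta**2 * 2 * f * (1 - f)))
    beta *= np.sqrt(config.cohort_h2 / raw_var_g)
    centred = dosages.to_numpy() - 2 * f
    genetic = centred @ beta
    var_g = config.cohort_h2
    exposure = genetic + rng.normal(0.0, np.sqrt(1 - var_g), n)

    # cluster-specific genetic exposure components
    comps: dict[int, np.ndarray] = {}
    for k in range(len(config.clusters)):
        mask = (panel["component"] == f"cluster_{k + 1}").to_numpy()
        comps[k] = centred[:, mask] @ beta[mask]

    cohort = pd.DataFrame({
        "iid": dosages.index,
        "exposure": exposure,
        "age": rng.normal(57.0, 8.0, n),
    }).set_index("iid", drop=False)

    arch = _cluster_exposure_effects(config)
    protein_signal = np.zeros(n)
    for p in range(config.n_proteins):
        label = f"protein_{p + 1}"
        level = rng.normal(0.0, config.protein_noise_sd, n)
        for k, effect in arch.get(label, {}).items():
            if k in comps:  # links to clusters absent from this config are inert
                level = level + effect * comps[k]
        cohort[label] = level
        b_out = _protein_outcome_effects(config).get(label, 0.0)
        protein_signal = protein_signal + b_out * level

    lp = protein_signal.copy()
    for k, (_, theta_k) in enumerate(config.clusters):
        lp += theta_k * comps[k]
    alpha = optimize.brentq(
        lambda a: float(np.mean(special.expit(a + lp))) - config.prevalence, -30, 10,
    )
    cohort["case"] = rng.binomial(1, special.expit(alpha + lp))

    n2 = int(round(config.protein_subsample_fraction * n))
    sub = np.ones(n, dtype=int)
    idx2 = rng.choice(n, size=n2, replace=False)
    sub[idx2] = 2
    cohort["subsample"] = sub
    # proteins are measured in sub-sample 2 only
    for p in range(config.n_proteins):
        cohort.loc[cohort["subsample"] == 1, f"protein_{p + 1}"] = np.nan

    return dosages, scored_alleles, cohort


def simulate_mediation_summary(
    n_proteins: int,
    clusters: tuple[str, ...],
    true_links: dict[tuple[str, int], float],
    protein_outcome_effects: dict[int, float],
    se_step1: float = 0.03,
    se_step2: float = 0.04,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directly simulate step-1 and step-2 MR estimate tables.

    A fast summary-level generator for screening studies over large protein
    panels, where simulating a cohort per replicate would be wasteful:
    step-1 estimates are Normal(true effect, se_step1^2) per (cluster,
    protein); step-2 estimates Normal(true outcome effect, se_step2^2) per
    protein.  ``true_links`` maps (cluster, protein index) to the true step-1
    effect (unlisted pairs are null); ``protein_outcome_effects`` maps protein
    index to the true step-2 effect (unlisted proteins are null).
    """
    rng = np.random.default_rng(seed)
    rows1 = []
    for cluster in clusters:
        true = np.array([true_links.get((cluster, p), 0.0) for p in range(n_proteins)])
        beta = rng.normal(true, se_step1)
        p = np.clip(_p_from_z(beta, se_step1), 1e-300, 1.0)
        for j in range(n_proteins):
            rows1.append({
                "cluster": cluster, "protein": f"protein_{j + 1}",
                "beta": beta[j], "se": se_step1, "p": p[j],
            })
    true2 = np.array([protein_outcome_effects.get(p, 0.0) for p in range(n_proteins)])
    beta2 = rng.normal(true2, se_step2)
    p2 = np.clip(_p_from_z(beta2, se_step2), 1e-300, 1.0)
    step2 = pd.DataFrame({
        "protein": [f"protein_{j + 1}" for j in range(n_proteins)],
        "beta": beta2, "se": se_step2, "p": p2,
    })
    return pd.DataFrame(rows1), step2
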