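"""End-to-end orchestration of the clustered-MR and mediation analysis.

Part 1 (clustering): meta-analyse the exposure GWAS components, clump to
independent genome-wide-significant instruments, harmonise against the
outcome, Steiger-filter, fit the ratio mixture, and compute per-cluster IVW
MR estimates.

Part 2 (mediation): estimate each cluster's effect on every protein with a
two-sample-within-one-cohort Wald MR (cluster-specific allele score as the
instrument, score-exposure and score-protein associations in disjoint
sub-samples), estimate each protein's effect on the outcome by IVW over its
selected instruments, screen mediators by double FDR, and compute
product-of-coefficients mediation estimates with Monte Carlo CIs plus all
pairwise between-cluster contrasts.

Every stage logs its in/out counts; the run report serialises the full
configuration and all seeds, so a re-run with the same inputs reproduces the
outputs exactly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import gwas_io, mediation, mr_clust, mr_core, pgs_mr, protein_instruments


@dataclass
class RunConfig:
    """All pipeline parameters, with published defaults where one is printed."""

    seed: int = 0
    # instrument selection / harmonisation
    window_kb: float = 500.0
    r2_threshold: float = 0.001
    p_threshold: float = 5e-8
    maf_ambiguity_threshold: float = 0.42
    steiger_alpha: float = 0.05
    # clustering
    K_max: int = 5
    n_restarts: int = 30
    prob_threshold: float = 0.8
    min_cluster_size: int = 4
    # ratio SEs include the exposure-side delta-method term; the purely
    # first-order SE understates uncertainty for large ratios
    wald_second_order: bool = True
    # mediation
    fdr_alpha: float = 0.05
    protein_p_threshold: float = 1.7e-11
    min_instruments: int = 3
    min_cis: int = 1
    cis_window_kb: float = 1000.0
    mc_draws: int = 1_000_000
    mc_level: float = 0.95
    covariates: tuple = ()

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Part1Result:
    meta: pd.DataFrame
    retained_rsids: list
    pairs: pd.DataFrame
    model: mr_clust.MixtureModel
    assignment: mr_clust.ClusterAssignment
    cluster_table: pd.DataFrame
    stage_log: list = field(default_factory=list)


@dataclass
class Part2Result:
    step1: pd.DataFrame
    step2: pd.DataFrame
    screen: pd.DataFrame
    mediation_table: pd.DataFrame
    contrast_table: pd.DataFrame
    stage_log: list = field(default_factory=list)


def run_part1(
    exposure: list[pd.DataFrame],
    outcome: pd.DataFrame,
    ld: gwas_io.LdMatrix | None,
    config: RunConfig,
) -> Part1Result:
    """Clustering arm: meta -> clump -> harmonise -> Steiger -> EM -> cluster IVW."""
    log = []
    try:
        if len(exposure) == 0:
            raise ValueError("at least one exposure summary-statistics table required")
        exp = exposure[0]
        for other in exposure[1:]:
            exp = mr_core.meta_analyse(exp, other)
        log.append(f"meta: {len(exp)} variants after combining "
                   f"{len(exposure)} exposure component(s)")

        retained = gwas_io.clump(
            exp, ld=ld, window_kb=config.window_kb,
            r2_threshold=config.r2_threshold, p_threshold=config.p_threshold,
        )
        exp = exp[exp["rsid"].isin(retained)].reset_index(drop=True)
        log.append(f"clump: {len(retained)} independent instruments "
                   f"(p < {config.p_threshold:g})")

        pairs, excl_h = gwas_io.harmonise(
            exp, outcome, maf_ambiguity_threshold=config.maf_ambiguity_threshold,
        )
        log.append(f"harmonise: {len(pairs)} pairs kept, {len(excl_h)} removed")

        pairs, excl_s = gwas_io.steiger_filter(pairs, alpha=config.steiger_alpha)
        log.append(f"steiger: {len(pairs)} pairs kept, {len(excl_s)} removed")

        ratios = mr_core.wald_ratios(pairs, second_order=config.wald_second_order)
        model = mr_clust.select_model(
            ratios, K_max=config.K_max, n_restarts=config.n_restarts, seed=config.seed,
        )
        assignment = mr_clust.assign(
            model, ratios,
            prob_threshold=config.prob_threshold,
            min_cluster_size=config.min_cluster_size,
        )
        log.append(f"cluster: selected K={model.K}, BIC={model.bic:.1f}, "
                   f"counts={assignment.counts()}")

        cluster_table, omissions = mr_clust.cluster_ivw(
            assignment, pairs, second_order=config.wald_second_order)
        log.extend(omissions)
    except Exception as exc:
        raise RuntimeError(
            f"part 1 failed ({exc}); completed stages: {log}"
        ) from exc
    return Part1Result(
        meta=exp, retained_rsids=retained, pairs=pairs, model=model,
        assignment=assignment, cluster_table=cluster_table, stage_log=log,
    )


def _cluster_weights(part1: Part1Result, cluster: str) -> tuple[pd.Series, pd.Series]:
    """Per-allele score weights (exposure betas) for one cluster's confident members."""
    members = part1.assignment.members(cluster, confident_only=True)["rsid"]
    meta = part1.meta.set_index("rsid")
    present = [r for r in members if r in meta.index]
    weights = meta.loc[present, "beta"]
    alleles = meta.loc[present, "ea"]
    return weights, alleles


def step1_cluster_protein_mr(
    part1: Part1Result,
    dosages: pd.DataFrame,
    scored_alleles: pd.Series,
    cohort: pd.DataFrame,
    config: RunConfig,
    protein_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Step-1 Wald MR of each non-null cluster's exposure effect on each protein.

    The cluster-specific allele score instruments the exposure: its effect on
    the (inverse-normal transformed) exposure is estimated in sub-sample 1,
    its effect on each protein in sub-sample 2.  The two id sets are asserted
    disjoint so the design is genuinely two-sample.
    """
    if protein_columns is None:
        protein_columns = [c for c in cohort.columns if c.startswith("protein_")]
    sub1 = cohort[cohort["subsample"] == 1]
    sub2 = cohort[cohort["subsample"] == 2]
    pgs_mr.assert_disjoint_samples(sub1.index, sub2.index)

    covars1 = sub1[list(config.covariates)] if config.covariates else None
    covars2 = sub2[list(config.covariates)] if config.covariates else None
    exposure_int = pgs_mr.inverse_normal_transform(sub1["exposure"])

    rows = []
    clusters = [f"cluster_{k + 1}" for k in range(part1.model.K)]
    for cluster in clusters:
        weights, alleles = _cluster_weights(part1, cluster)
        if len(weights) == 0:
            continue
        score1 = pgs_mr.compute_pgs(dosages.loc[sub1.index], scored_alleles,
                                    weights, weight_alleles=alleles)
        score2 = pgs_mr.compute_pgs(dosages.loc[sub2.index], scored_alleles,
                                    weights, weight_alleles=alleles)
        den = pgs_mr.linear_association(score1, exposure_int, covars1)
        for protein in protein_columns:
            y = sub2[protein]
            ok = y.notna()
            num = pgs_mr.linear_association(
                score2[ok.to_numpy()], y[ok],
                covars2.loc[ok] if covars2 is not None else None,
            )
            wald = pgs_mr.one_sample_wald(num, den)
            z = wald.wald / wald.se_wald
            rows.append({
                "cluster": cluster, "protein": protein,
                "beta": wald.wald, "se": wald.se_wald,
                "p": float(2.0 * stats.norm.sf(abs(z))),
            })
    return pd.DataFrame(rows)


def step2_protein_outcome_mr(
    proteins: dict[str, pd.DataFrame],
    loci: dict[str, protein_instruments.GeneLocus],
    outcome: pd.DataFrame,
    ld: gwas_io.LdMatrix | None,
    config: RunConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Step-2 IVW MR of each eligible protein on the outcome, with diagnostics."""
    rows, log = [], []
    for protein, assocs in proteins.items():
        iset = protein_instruments.select_instruments(
            assocs, protein, loci.get(protein), ld=ld,
            p_threshold=config.protein_p_threshold,
            cis_window_kb=config.cis_window_kb,
            window_kb=config.window_kb, r2_threshold=config.r2_threshold,
            min_total=config.min_instruments, min_cis=config.min_cis,
        )
        log.extend(iset.log)
        if not iset.eligible:
            log.append(f"{protein}: ineligible "
                       f"(n_total={iset.n_total}, n_cis={iset.n_cis})")
            continue
        pairs, _ = gwas_io.harmonise(
            iset.instruments.drop(columns=["cis"]), outcome,
            maf_ambiguity_threshold=config.maf_ambiguity_threshold,
        )
        if len(pairs) < config.min_instruments:
            log.append(f"{protein}: instruments lost in harmonisation; skipped")
            continue
        ratios = mr_core.wald_ratios(pairs)
        est = mr_core.ivw(ratios)
        egger = mr_core.egger_intercept_test(pairs)
        q = mr_core.cochran_q(ratios, est.beta)
        rows.append({
            "protein": protein, "n_snps": est.n_snps, "n_cis": iset.n_cis,
            "beta": est.beta, "se": est.se, "p": est.pvalue,
            "egger_intercept": egger.get("intercept"),
            "egger_intercept_p": egger.get("intercept_p"),
            "q": q.get("q"), "q_df": q.get("df"), "q_p": q.get("p"),
        })
    return pd.DataFrame(rows), log


def run_part2(
    part1: Part1Result,
    dosages: pd.DataFrame,
    scored_alleles: pd.Series,
    cohort: pd.DataFrame,
    proteins: dict[str, pd.DataFrame],
    loci: dict[str, protein_instruments.GeneLocus],
    outcome: pd.DataFrame,
    ld: gwas_io.LdMatrix | None,
    config: RunConfig,
) -> Part2Result:
    """Mediation arm: step-1 and step-2 MRs, double-FDR screen, products, contrasts."""
    log = []
    try:
        step1 = step1_cluster_protein_mr(
            part1, dosages, scored_alleles, cohort, config,
        )
        log.append(f"step1: {len(step1)} (cluster, protein) Wald MR estimates")
        step2, step2_log = step2_protein_outcome_mr(
            proteins, loci, outcome, ld, config,
        )
        log.extend(step2_log)
        log.append(f"step2: {len(step2)} eligible protein IVW estimates")

        if len(step1) == 0 or len(step2) == 0:
            empty = pd.DataFrame()
            return Part2Result(step1, step2, empty, empty, empty, log)

        screen, screen_log = mediation.screen_mediators(
            step1, step2[["protein", "beta", "se", "p"]], alpha=config.fdr_alpha,
        )
        log.extend(screen_log)
        candidates = screen[screen["candidate"]] if len(screen) else screen
        log.append(f"screen: {len(candidates)} candidate (cluster, protein) pairs")

        totals = part1.cluster_table.set_index("cluster")["beta"]
        seeds = iter(np.random.SeedSequence(config.seed).generate_state(
            2 * max(1, len(candidates)) * max(1, len(screen)) + 64))

        med_rows = []
        for _, c in candidates.iterrows():
            res = mediation.mediate(
                c["cluster"], c["protein"],
                c["beta1"], c["se1"], c["q1"], c["beta2"], c["se2"], c["q2"],
                total=float(totals.get(c["cluster"], np.nan)),
                draws=config.mc_draws, seed=int(next(seeds) % (2**31)),
                level=config.mc_level,
            )
            rec = res.to_record()
            rec["tier"] = mediation.significance_tier(
                res.sobel_p, (res.ci_lower, res.ci_upper))
            med_rows.append(rec)
        mediation_table = pd.DataFrame(med_rows)

        contrast_rows = []
        cand_proteins = sorted(set(candidates["protein"])) if len(candidates) else []
        s1 = step1.set_index(["cluster", "protein"])
        s2 = step2.set_index("protein")
        cluster_labels = sorted(set(step1["cluster"]))
        for protein in cand_proteins:
            for a, b in itertools.combinations(cluster_labels, 2):
                if (a, protein) not in s1.index or (b, protein) not in s1.index:
                    continue
                ra, rb, rp = s1.loc[(a, protein)], s1.loc[(b, protein)], s2.loc[protein]
                contrast = mediation.cluster_difference(
                    protein,
                    a, float(ra["beta"]), float(ra["se"]),
                    b, float(rb["beta"]), float(rb["se"]),
                    float(rp["beta"]), float(rp["se"]),
                    draws=config.mc_draws, seed=int(next(seeds) % (2**31)),
                    level=config.mc_level,
                )
                rec = contrast.to_record()
                rec["tier"] = mediation.significance_tier(
                    contrast.p, (contrast.ci_lower, contrast.ci_upper))
                contrast_rows.append(rec)
        contrast_table = pd.DataFrame(contrast_rows)
        log.append(f"contrasts: {len(contrast_table)} pairwise cluster comparisons")
    except Exception as exc:
        raise RuntimeError(f"part 2 failed ({exc}); completed stages: {log}") from exc
    return Part2Result(step1, step2, screen, mediation_table, contrast_table, log)


def run_report(config: RunConfig, stage_logs: dict[str, list], extra: dict | None = None) -> str:
    """JSON run report embedding the full configuration and per-stage logs."""
    report = {"config": config.to_dict(), "stages": stage_logs}
    if extra:
        report.update(extra)
    return json.dumps(report, indent=2, default=str)
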