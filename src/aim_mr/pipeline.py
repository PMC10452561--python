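"""End-to-end orchestration: panel -> AIM preselection -> supervised admixture
-> ancestry GWAS -> instrument filters -> radial MR -> estimator suite ->
mediation (two-step MR and MVMR).

Every stage appends its (threshold, count in, count out) record to a filter
ledger, so the cascade that in the motivating study ran
candidates -> genome-wide-significant -> exclusion+LD-pruned -> post-radial
is fully reconstructible from the output bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as aio
from .admixture import estimate_proportions
from .datatypes import ConfigurationError
from .informativeness import preselect_markers
from .instruments import (
    FilterLog,
    InstrumentSet,
    ancestry_gwas,
    exclusion_filter,
    explained_variance_series,
    instrument_strength,
    ld_prune,
    mean_f_statistic,
    outcome_gwas,
    steiger_filter,
)
from .mr import (
    egger,
    harmonize,
    ivw,
    radial_filter,
    scatter_funnel_data,
    subset_harmonized,
    weighted_median,
)
from .mvmr import build_mvmr_input, mvmr_fit
from .pca import genotype_pca, pc_adjustment_matrix
from .synthetic import (
    SimulationConfig,
    case_control_sample,
    simulate_admixed_cohort,
    simulate_reference_panel,
)


@dataclass
class PipelineConfig:
    """Thresholds, sample sizes and seeds of one synthetic end-to-end run.

    Defaults follow the analysis design the pipeline reimplements: relevance
    p < 5e-8, PheWAS-style exclusion p < 5e-8, LD pruning at r^2 <= 0.01,
    radial outlier alpha 0.05 with single-pass removal, palindromic variants
    dropped. The stricter sensitivity presets (LD r^2 <= 1e-3, exclusion
    p < 5e-6) are selectable through the same fields.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_individuals_i: int = 1861
    n_pairs_ii: int = 412
    n_prospective_ii: int = 12000
    top_k: int = 300
    relevance_p: float = 5e-8
    phewas_p: float = 5e-8
    ld_r2: float = 0.01
    radial_alpha: float = 0.05
    palindromic_policy: str = "drop"
    steiger: bool = False
    pc_mode: str = "none"  # none | all | drop_ancestry_pc
    n_pcs: int = 10
    use_estimated_ancestry: bool = True
    admixture_tol: float = 1e-6
    admixture_max_iter: int = 2000
    wmedian_n_boot: int = 1000
    seed: int = 0
    # mediator (gallstone-disease analogue) chain generation; the liability
    # coupling 0.11 x ancestry effect 0.072 implies a total outcome log-odds
    # effect of ~0.008 per 1% target ancestry
    mediator_effect_per_pct: float = 0.072
    mediator_prevalence: float = 0.5
    mediator_liability_effect: float = 0.11
    n_pairs_mediator: int = 6000
    n_mediator_instruments: int = 5
    mediator_instrument_logor: float = 0.5
    # user-supplied published second-step (mediator -> outcome) estimate for
    # two-step mediation reporting
    published_mediator_outcome_logor: float = 0.678
    published_mediator_outcome_se: float = 0.11

    def validate(self) -> None:
        self.sim.validate()
        for name, val, lo, hi in [
            ("relevance_p", self.relevance_p, 0.0, 1.0),
            ("phewas_p", self.phewas_p, 0.0, 1.0),
            ("ld_r2", self.ld_r2, 0.0, 1.0),
            ("radial_alpha", self.radial_alpha, 0.0, 1.0),
        ]:
            if not (lo < val <= hi):
                raise ConfigurationError(f"{name} must lie in ({lo}, {hi}]")
        if self.palindromic_policy not in {"drop", "maf", "keep"}:
            raise ConfigurationError("palindromic_policy must be drop|maf|keep")
        if self.pc_mode not in {"none", "all", "drop_ancestry_pc"}:
            raise ConfigurationError("pc_mode must be none|all|drop_ancestry_pc")


def _mr_suite(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    config: PipelineConfig,
    log: FilterLog | None = None,
    exponentiate: bool = False,
) -> dict:
    """Harmonize, radial-filter, and run the three estimators; JSON-ready dict."""
    h = harmonize(exposure_stats, outcome_stats, config.palindromic_policy)
    n_harmonized = h.n_instruments
    radial = radial_filter(h, alpha=config.radial_alpha)
    h_kept = subset_harmonized(h, radial.retained)
    if log is not None:
        log.add("harmonization", config.palindromic_policy, len(exposure_stats), n_harmonized)
        log.add("radial_outliers", config.radial_alpha, n_harmonized, h_kept.n_instruments)
    res_ivw = ivw(h_kept)
    res_egger = egger(h_kept)
    res_wm = weighted_median(h_kept, n_boot=config.wmedian_n_boot, seed=config.seed + 7)
    plots = scatter_funnel_data(h_kept, [res_ivw, res_egger])
    rows = {}
    for res in (res_ivw, res_egger, res_wm):
        d = res.to_dict(exponentiate=exponentiate)
        if res.method == "ivw":
            d["q_p_value"] = res.q_p
        rows[res.method] = d
    rows["ivw"]["intercept_p_value"] = res_egger.egger_intercept_p
    return {
        "results": rows,
        "harmonized": h_kept,
        "audit": h.audit,
        "radial": radial,
        "n_outliers": int(radial.table["outlier"].sum()),
        "plot_data": plots,
    }


def select_instruments(panel, cohort_i, config: PipelineConfig, exclusion_list=None):
    """AIM preselection, exposure estimation, GWAS, and the filter cascade.

    Returns (exposure summary stats restricted to retained instruments,
    InstrumentSet, exposure vector used, PC result or None).
    """
    target = config.sim.target_population
    others = [p for p in panel.populations if p != target]
    candidates, _ = preselect_markers(panel, target, others, config.top_k)
    log = FilterLog()
    log.add("in_preselection", config.top_k, panel.n_variants, len(candidates))

    geno_cand = cohort_i.genotypes.subset_variants(candidates)
    if config.use_estimated_ancestry:
        ancestry = estimate_proportions(
            geno_cand, panel, tol=config.admixture_tol, max_iter=config.admixture_max_iter
        )
        exposure = ancestry.component(target)
    else:
        ancestry = cohort_i.ancestry_true
        exposure = ancestry.component(target)

    pcs = None
    pc_block = None
    if config.pc_mode != "none":
        pcs = genotype_pca(cohort_i.genotypes, n_pcs=config.n_pcs)
        pc_block, _ = pc_adjustment_matrix(pcs, config.pc_mode, exposure)

    stats_exp = ancestry_gwas(
        geno_cand, exposure, age=cohort_i.age, sex=cohort_i.sex, pcs=pc_block
    )
    usable = stats_exp[stats_exp["flag"] == ""]
    sig = usable[usable["p"] < config.relevance_p].reset_index(drop=True)
    log.add("relevance", config.relevance_p, len(candidates), len(sig))

    sig, _dropped = exclusion_filter(sig, exclusion_list, config.phewas_p)
    log.add("phewas_exclusion", config.phewas_p, log.records[-1]["n_out"], len(sig))

    expl = explained_variance_series(sig, exposure_sd=float(np.std(exposure, ddof=1)))
    ranked = (
        pd.DataFrame({"variant": sig["variant"], "ev": expl.to_numpy()})
        .sort_values(["ev", "variant"], ascending=[False, True], kind="mergesort")[
            "variant"
        ]
        .tolist()
    )
    kept = ld_prune(cohort_i.genotypes, ranked, r2_threshold=config.ld_r2)
    log.add("ld_pruning", config.ld_r2, len(sig), len(kept))

    final = sig[sig["variant"].isin(set(kept))].reset_index(drop=True)
    expl_final = expl.loc[final["variant"]]
    n_i = cohort_i.genotypes.n_individuals
    # Joint R^2 from regressing the exposure on all retained dosages at once.
    # The per-variant Eq-style explained variances share the latent ancestry
    # factor, so their sum can exceed 1 on strongly informative markers; the
    # joint R^2 is the bounded variance proportion and is what total_r2 and
    # the joint F report. Both quantities are kept.
    total_r2 = joint_r2(cohort_i.genotypes, final["variant"].tolist(), exposure)
    iset = InstrumentSet(
        stats=final,
        explained=expl_final,
        total_r2=total_r2,
        f_statistic=instrument_strength(total_r2, n_i, max(len(final), 1)),
        f_mean_per_instrument=mean_f_statistic(final),
        log=log,
    )
    return final, iset, exposure, pcs


def joint_r2(genotypes, variants, exposure) -> float:
    """R^2 of the exposure jointly regressed on all instrument dosages."""
    g = genotypes.subset_variants(variants).dosage.astype(float)
    g = np.where(g < 0, np.nan, g)
    g = np.where(np.isnan(g), np.nanmean(g, axis=0), g)
    y = np.asarray(exposure, float)
    x = np.column_stack([np.ones(len(y)), g])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    return float(max(0.0, min(1.0 - 1e-12, 1.0 - float((resid**2).sum()) / tss)))


def _simulate_sample_ii(panel, config: PipelineConfig, variants, seed: int):
    """Prospective outcome cohort down-sampled to the matched case-control design."""
    sim2 = SimulationConfig(
        **{
            **asdict_shallow(config.sim),
            "n_individuals": config.n_prospective_ii,
        }
    )
    cohort = simulate_admixed_cohort(panel, sim2, seed=seed)
    sub = cohort
    sampled, frac = case_control_sample(sub, config.n_pairs_ii, seed=seed + 1)
    return sampled, frac


def asdict_shallow(sim: SimulationConfig) -> dict:
    d = asdict(sim)
    d["dirichlet_alpha"] = tuple(d["dirichlet_alpha"])
    return d


def run_pipeline(
    config: PipelineConfig,
    exclusion_list: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full synthetic study and return (and optionally write) the bundle.

    The bundle contains the stage ledger, the instrument-strength summary,
    Table-1-style estimator rows for the binary outcome, and the mediation
    summary (two-step MR stage 1 + MVMR direct effects) when a mediator is
    simulated.
    """
    config.validate()
    base_seed = config.seed
    panel = simulate_reference_panel(
        SimulationConfig(**{**asdict_shallow(config.sim), "seed": base_seed})
    )
    sim1 = SimulationConfig(
        **{**asdict_shallow(config.sim), "n_individuals": config.n_individuals_i}
    )
    cohort_i = simulate_admixed_cohort(panel, sim1, seed=base_seed + 1)

    exp_stats, iset, exposure, _pcs = select_instruments(
        panel, cohort_i, config, exclusion_list
    )

    cohort_ii, sampling_fraction = _simulate_sample_ii(
        panel, config, exp_stats["variant"], seed=base_seed + 2
    )
    geno_ii = cohort_ii.genotypes.subset_variants(exp_stats["variant"].tolist())
    out_stats = outcome_gwas(
        geno_ii, cohort_ii.outcome_binary, age=cohort_ii.age, sex=cohort_ii.sex
    )
    out_stats = out_stats[out_stats["flag"] == ""].reset_index(drop=True)

    exp_used = exp_stats
    if config.steiger:
        retained, _diag = steiger_filter(
            exp_stats, out_stats, outcome_binary=True, case_fraction=0.5
        )
        exp_used = exp_stats[exp_stats["variant"].isin(set(retained))].reset_index(
            drop=True
        )
        iset.log.add("steiger", "r2_exp>r2_out", len(exp_stats), len(exp_used))

    suite = _mr_suite(exp_used, out_stats, config, log=iset.log, exponentiate=True)

    bundle = {
        "config": {
            "seed": config.seed,
            "relevance_p": config.relevance_p,
            "phewas_p": config.phewas_p,
            "ld_r2": config.ld_r2,
            "radial_alpha": config.radial_alpha,
            "palindromic_policy": config.palindromic_policy,
            "steiger": config.steiger,
            "pc_mode": config.pc_mode,
            "case_sampling_fraction": sampling_fraction,
        },
        "ledger": iset.log.records,
        "instruments": {
            "n_final": suite["harmonized"].n_instruments,
            "total_r2": iset.total_r2,
            "explained_variance_pct": 100.0 * iset.total_r2,
            "sum_per_variant_explained": float(iset.explained.sum()),
            "f_statistic": iset.f_statistic,
            "f_mean_per_instrument": iset.f_mean_per_instrument,
        },
        "binary_outcome": suite["results"],
        "n_radial_outliers": suite["n_outliers"],
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ok_marker = outdir / "FAILED"
        ok_marker.write_text("pipeline running\n")
        aio.write_summary_stats(exp_used, outdir / "exposure_stats.tsv")
        aio.write_summary_stats(out_stats, outdir / "outcome_stats.tsv")
        suite["audit"].to_csv(outdir / "harmonization_audit.tsv", sep="\t", index=False)
        pd.DataFrame(iset.log.records).to_csv(
            outdir / "stage_ledger.tsv", sep="\t", index=False
        )
        with open(outdir / "results.json", "w") as fh:
            json.dump(
                {k: v for k, v in bundle.items() if k != "plot_data"},
                fh,
                indent=2,
                sort_keys=True,
                default=float,
            )
        ok_marker.unlink()
    return bundle


def two_sample_replicate(
    config: PipelineConfig,
    seed: int,
    n_variants: int = 80,
) -> dict:
    """One replicate of the two-sample summary-statistic pipeline.

    Simulates a fresh panel, an exposure sample (ancestry GWAS on the true
    simulated ancestry, age/sex-adjusted), and a case-control outcome sample
    (logistic GWAS); applies the genome-wide relevance filter; harmonizes
    and runs IVW. Used for calibration and coverage studies, where the
    replicate must isolate estimator behaviour from admixture-estimation
    error. Returns the IVW result plus the true causal log-odds per 1%.
    """
    sim = SimulationConfig(
        **{**asdict_shallow(config.sim), "n_variants": n_variants, "seed": seed}
    )
    panel = simulate_reference_panel(sim)
    sim1 = SimulationConfig(
        **{**asdict_shallow(sim), "n_individuals": config.n_individuals_i}
    )
    cohort_i = simulate_admixed_cohort(panel, sim1, seed=seed + 1)
    q_t = cohort_i.ancestry_true.component(sim.target_population)
    exp_stats = ancestry_gwas(
        cohort_i.genotypes, q_t, age=cohort_i.age, sex=cohort_i.sex
    )
    sig = exp_stats[
        (exp_stats["flag"] == "") & (exp_stats["p"] < config.relevance_p)
    ].reset_index(drop=True)

    sim2 = SimulationConfig(
        **{**asdict_shallow(sim), "n_individuals": config.n_prospective_ii}
    )
    pool = simulate_admixed_cohort(panel, sim2, seed=seed + 2)
    sample_ii, _ = case_control_sample(pool, config.n_pairs_ii, seed=seed + 3)
    geno_ii = sample_ii.genotypes.subset_variants(sig["variant"].tolist())
    out_stats = outcome_gwas(
        geno_ii, sample_ii.outcome_binary, age=sample_ii.age, sex=sample_ii.sex
    )
    out_stats = out_stats[out_stats["flag"] == ""].reset_index(drop=True)
    h = harmonize(sig, out_stats, config.palindromic_policy)
    return {
        "ivw": ivw(h),
        "theta_true": config.sim.causal_effect_binary,
        "n_instruments": h.n_instruments,
    }


# ---------------------------------------------------------------------------
# mediation: two-step MR and MVMR on a simulated ancestry -> mediator ->
# outcome chain (gallstone-disease analogue)
# ---------------------------------------------------------------------------


def simulate_mediation_study(
    config: PipelineConfig,
    direct_effect_per_pct: float = 0.0,
    n_ancestry_instruments: int = 60,
    apply_relevance_filter: bool = True,
):
    """Simulate summary statistics for a mediation analysis.

    Ancestry raises the mediator's log-odds (``mediator_effect_per_pct`` per
    1%); the outcome depends on mediator status (log-OR
    ``mediator_to_outcome_logor``) and, optionally, directly on ancestry
    (``direct_effect_per_pct``, default 0: complete mediation). Dedicated
    mediator instruments act on the mediator only. Three non-overlapping
    samples yield: ancestry GWAS (sample I), mediator GWAS (mediator
    case-control sample), and outcome GWAS (outcome case-control sample).
    """
    config.validate()
    rng_seed = config.seed + 101
    sim = SimulationConfig(
        **{
            **asdict_shallow(config.sim),
            "n_variants": n_ancestry_instruments + config.n_mediator_instruments,
            "seed": rng_seed,
        }
    )
    panel = simulate_reference_panel(sim)
    m_anc = n_ancestry_instruments
    med_idx = np.arange(m_anc, sim.n_variants)
    # mediator instruments carry no ancestry information: equal frequencies
    panel.freq[:, med_idx] = panel.freq[0, med_idx]

    target_j = panel.population_index(sim.target_population)

    def _draw(n_ind, seed):
        s = SimulationConfig(**{**asdict_shallow(sim), "n_individuals": n_ind})
        return simulate_admixed_cohort(panel, s, seed=seed)

    def _mediator_outcome(cohort, seed, with_outcome: bool):
        # The mediator is a binary diagnosis driven by a continuous liability
        # (log-odds scale); the outcome risk depends on that liability, not
        # on the dichotomized status — disease burden, of which diagnosis is
        # a noisy indicator, is what carries the downstream risk.
        rng = np.random.default_rng(seed)
        q_t = cohort.ancestry_true.component(sim.target_population)
        g_med = cohort.genotypes.dosage[:, med_idx].astype(float)
        eta_med = (
            logit(config.mediator_prevalence)
            + config.mediator_effect_per_pct * (q_t - q_t.mean())
            + config.mediator_instrument_logor
            * (g_med - g_med.mean(axis=0)).sum(axis=1)
        )
        mediator = rng.binomial(1, expit(eta_med))
        outcome = None
        if with_outcome:
            eta_out = (
                logit(config.sim.baseline_prevalence)
                + config.mediator_liability_effect * (eta_med - eta_med.mean())
                + direct_effect_per_pct * (q_t - q_t.mean())
            )
            outcome = rng.binomial(1, expit(eta_out))
        return mediator, outcome

    # sample I: ancestry GWAS
    cohort_i = _draw(config.n_individuals_i, rng_seed + 1)
    q_target = cohort_i.ancestry_true.component(sim.target_population)
    stats_anc = ancestry_gwas(
        cohort_i.genotypes, q_target, age=cohort_i.age, sex=cohort_i.sex
    )

    # mediator sample: case-control on mediator status
    pool_med = _draw(config.n_prospective_ii, rng_seed + 2)
    med_status, _ = _mediator_outcome(pool_med, rng_seed + 3, with_outcome=False)
    pool_med.outcome_binary = med_status.astype(np.int8)
    samp_med, _ = case_control_sample(pool_med, config.n_pairs_mediator, rng_seed + 4)
    stats_med = outcome_gwas(
        samp_med.genotypes, samp_med.outcome_binary, age=samp_med.age, sex=samp_med.sex
    )

    # outcome sample: case-control on the final outcome
    pool_out = _draw(config.n_prospective_ii, rng_seed + 5)
    _, out_status = _mediator_outcome(pool_out, rng_seed + 6, with_outcome=True)
    pool_out.outcome_binary = out_status.astype(np.int8)
    samp_out, _ = case_control_sample(pool_out, config.n_pairs_ii, rng_seed + 7)
    stats_out = outcome_gwas(
        samp_out.genotypes, samp_out.outcome_binary, age=samp_out.age, sex=samp_out.sex
    )

    anc_variants = panel.variant_ids[:m_anc]
    if apply_relevance_filter:
        sig = stats_anc[
            (stats_anc["flag"] == "") & (stats_anc["p"] < config.relevance_p)
        ]["variant"]
        anc_variants = [v for v in anc_variants if v in set(sig)]
    med_variants = panel.variant_ids[med_idx]
    return {
        "ancestry_stats": stats_anc,
        "mediator_stats": stats_med,
        "outcome_stats": stats_out,
        "ancestry_variants": list(anc_variants),
        "mediator_variants": list(med_variants),
    }


def two_step_and_mvmr(study: dict, config: PipelineConfig) -> dict:
    """Two-step MR (stage 1 computed, stage 2 user-supplied) plus MVMR.

    Stage 1: univariable IVW of ancestry -> mediator using the ancestry
    instruments. Stage 2: the published mediator -> outcome estimate carried
    in the config (provenance recorded). MVMR: direct effects of ancestry
    and mediator on the outcome using both instrument sets jointly.
    """
    anc_ids = set(study["ancestry_variants"])
    exp_anc = study["ancestry_stats"]
    exp_anc_sub = exp_anc[exp_anc["variant"].isin(anc_ids)]
    med = study["mediator_stats"]
    out = study["outcome_stats"]

    h1 = harmonize(exp_anc_sub, med[med["variant"].isin(anc_ids)], config.palindromic_policy)
    stage1 = ivw(h1)

    # univariable ancestry -> outcome (the total effect MVMR decomposes)
    h_total = harmonize(
        exp_anc_sub, out[out["variant"].isin(anc_ids)], config.palindromic_policy
    )
    total = ivw(h_total)

    used = set(study["ancestry_variants"]) | set(study["mediator_variants"])
    inp = build_mvmr_input(
        [
            study["ancestry_stats"][study["ancestry_stats"]["variant"].isin(used)],
            study["mediator_stats"][study["mediator_stats"]["variant"].isin(used)],
        ],
        study["outcome_stats"][study["outcome_stats"]["variant"].isin(used)],
        exposure_names=["ancestry", "mediator"],
    )
    mv = mvmr_fit(inp)
    return {
        "stage1_ancestry_to_mediator": stage1.to_dict(exponentiate=True),
        "stage2_mediator_to_outcome": {
            "source": "user_supplied",
            "beta": config.published_mediator_outcome_logor,
            "or": float(np.exp(config.published_mediator_outcome_logor)),
            "se": config.published_mediator_outcome_se,
        },
        "univariable_ancestry_to_outcome": total.to_dict(exponentiate=True),
        "mvmr": mv.to_dict(),
    }
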