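"""End-to-end orchestration and built-in validation experiments.

``run_individual_analysis`` and ``run_summary_analysis`` reproduce the
report layout of the individual-level and summary-level analyses (OLS /
univariable MR / multivariable MR per outcome; IVW / Egger / Q with
odds-ratio presentation). The experiment functions — parameter recovery,
attenuation signature, empirical power, selection bias — are the
package's own checks that the estimators recover the generating DAG.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import individual as ind
from . import summary as smr
from .phenotypes import build_covariates
from .scores import compute_prs
from .simulate import Cohort, SimParams, simulate_cohort, simulate_two_sample_summary

__all__ = [
    "RunConfig",
    "run_individual_analysis",
    "run_summary_analysis",
    "estimate_power_by_simulation",
    "parameter_recovery_experiment",
    "attenuation_signature_experiment",
]

OUTCOMES = ("current", "ever", "former")


@dataclass
class RunConfig:
    """One reproducible analysis run.

    Either ``sim`` (a :class:`SimParams` block) or pre-built inputs
    (``cohort``/``panel`` or ``summary_data``) must be given, not both.
    """

    sim: SimParams | None = None
    cohort: Cohort | None = None
    panel: object = None
    summary_data: object = None
    outcomes: tuple = OUTCOMES
    n_pcs: int = 10
    weights: np.ndarray | None = None
    outlier_alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        has_sim = self.sim is not None
        has_data = self.cohort is not None or self.summary_data is not None
        if has_sim == has_data:
            raise ValueError(
                "exactly one input mode: a SimParams block or prepared data"
            )
        if not (0 < self.outlier_alpha < 1):
            raise ValueError("outlier_alpha must lie in (0, 1)")


def _row(est: ind.MREstimate, sd_exposure: float) -> dict:
    per_sd, pct = ind.sd_scale(est.effect, sd_exposure) if sd_exposure else (est.effect, np.nan)
    return {
        "exposure": est.exposure,
        "method": est.method,
        "effect": est.effect,
        "se": est.se,
        "ci_low": est.ci95[0],
        "ci_high": est.ci95[1],
        "pval": est.pval,
        "f_stat": est.f_stat,
        "cond_f": est.cond_f,
        "effect_per_sd": per_sd,
        "pct_per_sd": pct,
        "n": est.n,
    }


def run_individual_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Per outcome: OLS, two univariable MRs, multivariable MR.

    Exposure effects are reported per unit (year of education / SD of
    cognition) and SD-scaled; F and conditional F are attached to the MR
    rows. Returns outcome -> table, and writes TSVs when ``out_dir`` set.
    """
    if config.sim is not None:
        cohort, panel = simulate_cohort(replace(config.sim, seed=config.seed))
    else:
        cohort, panel = config.cohort, config.panel
        if cohort is None or panel is None:
            raise ValueError("individual analysis needs a cohort and panel")
    covs = build_covariates(cohort.covariates, config.n_pcs)
    score_edu = compute_prs(cohort.dosages, panel, "edu")
    score_cog = compute_prs(cohort.dosages, panel, "cog")
    exposures = np.column_stack([cohort.edu_years, cohort.cog_score])
    scores = np.column_stack([score_edu, score_cog])
    weights = cohort.weights if config.weights is None else config.weights

    tables = {}
    for outcome in config.outcomes:
        y, mask = cohort.outcome(outcome)
        ym, Xm, Zm = y[mask], exposures[mask], scores[mask]
        Wm, wm = covs[mask], weights[mask]
        sd_edu = float(np.std(Xm[:, 0], ddof=1))
        sds = (sd_edu, 1.0)  # cognition is already per-SD
        rows = []
        Xm_named = pd.DataFrame(Xm, columns=["edu", "cog"])
        for est, sd in zip(
            ind.ols_estimate(ym, Xm_named, Wm, wm, outcome_label=outcome), sds
        ):
            rows.append(_row(est, sd))
        for j, (label, sd) in enumerate(zip(("edu", "cog"), sds)):
            est = ind.tsls_univariable(
                ym, Xm[:, j], Zm[:, j], Wm, wm,
                exposure_label=label, outcome_label=outcome,
            )
            rows.append(_row(est, sd))
        for est, sd in zip(
            ind.tsls_multivariable(
                ym, Xm, Zm, Wm, wm, outcome_label=outcome
            ),
            sds,
        ):
            rows.append(_row(est, sd))
        tables[outcome] = pd.DataFrame(rows)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for outcome, tab in tables.items():
            tab.to_csv(out / f"individual_{outcome}.tsv", sep="\t", index=False)
    return tables


def run_summary_analysis(
    config: RunConfig,
    n_gwas_exposure: int = 20_000,
    n_gwas_outcome: int = 20_000,
    outcome: str = "ever",
    scale: str = "risk_difference",
):
    """Summary-data track: univariable IVW per exposure, multivariable
    IVW, Egger (uni + multi), modified Q, and one-shot outlier removal.

    Returns ``(table, q_report)``. When the outcome associations are on
    the log-odds scale the table also carries odds ratios. With a
    univariable dataset only the single-exposure path is run.
    """
    if config.sim is not None:
        data = simulate_two_sample_summary(
            replace(config.sim, seed=config.seed),
            n_gwas_exposure, n_gwas_outcome, outcome=outcome, scale=scale,
        )
    else:
        data = config.summary_data
        if data is None:
            raise ValueError("summary analysis needs summary data")

    rows = []

    def add(est: ind.MREstimate):
        row = {
            "exposure": est.exposure,
            "method": est.method,
            "effect": est.effect,
            "se": est.se,
            "ci_low": est.ci95[0],
            "ci_high": est.ci95[1],
            "pval": est.pval,
            "n_snps": est.n,
        }
        if data.scale == "log_odds":
            orr, (lo, hi) = smr.to_odds_ratio(est.effect, est.se)
            row.update({"or": orr, "or_ci_low": lo, "or_ci_high": hi})
        rows.append(row)

    add(smr.ivw_univariable(data, "edu"))
    multivariable = data.pi2 is not None
    if multivariable:
        add(smr.ivw_univariable(data, "cog"))
        for est in smr.mvmr_ivw(data):
            add(est)
        slopes, intercept = smr.mr_egger(data, multivariable=True)
        for est in slopes:
            add(est)
        add(intercept)
    else:
        slopes, intercept = smr.mr_egger(data, multivariable=False)
        add(slopes[0])
        add(intercept)
    removed, refit, q_report = smr.remove_outliers_and_refit(
        data, config.outlier_alpha
    )
    for est in refit:
        est = dataclasses.replace(est, method=est.method + "-outlier-removed")
        add(est)
    table = pd.DataFrame(rows)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "summary_mr.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "snp_id": q_report.snp_id,
                "q": q_report.q_per_snp,
                "p": q_report.p_per_snp,
            }
        ).to_csv(out / "summary_q.tsv", sep="\t", index=False)
    return table, q_report


def estimate_power_by_simulation(
    base_params: SimParams,
    effect: float,
    n: int,
    replicates: int = 200,
    alpha: float = 0.05,
    outcome: str = "ever",
    seed: int = 0,
):
    """Empirical power of the univariable education MR.

    Fraction of replicate cohorts (education -> outcome risk difference
    set to ``effect``) in which the 2SLS education effect has p < alpha,
    with its binomial Monte-Carlo SE. At effect 0 this estimates the size
    of the test.
    """
    if replicates < 100:
        raise ValueError("need at least 100 replicates for a stable estimate")
    root = np.random.default_rng(seed)
    hits = 0
    for _ in range(replicates):
        params = replace(
            base_params,
            beta1=effect,
            n_individuals=n,
            seed=int(root.integers(2**31 - 1)),
        )
        cohort, panel = simulate_cohort(params)
        y, mask = cohort.outcome(outcome)
        covs = build_covariates(cohort.covariates, 0)
        score = compute_prs(cohort.dosages, panel, "edu")
        est = ind.tsls_univariable(
            y[mask], cohort.edu_years[mask], score[mask], covs[mask]
        )
        hits += est.pval < alpha
    power = hits / replicates
    mc_se = float(np.sqrt(power * (1 - power) / replicates))
    return power, mc_se


def parameter_recovery_experiment(
    params: SimParams,
    n: int = 20_000,
    replicates: int = 200,
    outcome: str = "ever",
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate the cohort, estimate, and summarise recovery.

    Returns per-estimator means, Monte-Carlo SEs of the mean, and the
    generating truths: the multivariable estimates target the direct
    effects (beta1, beta2); the univariable ones the total effects
    beta1 + alpha_E beta2 and beta2 + alpha_CA beta1.
    """
    root = np.random.default_rng(seed)
    est = {k: [] for k in ("uni_edu", "uni_cog", "multi_edu", "multi_cog")}
    for _ in range(replicates):
        p = replace(params, n_individuals=n, seed=int(root.integers(2**31 - 1)))
        cohort, panel = simulate_cohort(p)
        y, mask = cohort.outcome(outcome)
        covs = build_covariates(cohort.covariates, 0)
        s_edu = compute_prs(cohort.dosages, panel, "edu")
        s_cog = compute_prs(cohort.dosages, panel, "cog")
        X = np.column_stack([cohort.edu_years, cohort.cog_score])[mask]
        Z = np.column_stack([s_edu, s_cog])[mask]
        ym, Wm = y[mask], covs[mask]
        est["uni_edu"].append(
            ind.tsls_univariable(ym, X[:, 0], Z[:, 0], Wm).effect
        )
        est["uni_cog"].append(
            ind.tsls_univariable(ym, X[:, 1], Z[:, 1], Wm).effect
        )
        multi = ind.tsls_multivariable(ym, X, Z, Wm)
        est["multi_edu"].append(multi[0].effect)
        est["multi_cog"].append(multi[1].effect)
    truth = {
        "uni_edu": params.beta1 + params.alpha_E * params.beta2,
        "uni_cog": params.beta2 + params.alpha_CA * params.beta1,
        "multi_edu": params.beta1,
        "multi_cog": params.beta2,
    }
    rows = []
    for k, v in est.items():
        v = np.asarray(v)
        rows.append(
            {
                "estimator": k,
                "mean": v.mean(),
                "mc_se": v.std(ddof=1) / np.sqrt(replicates),
                "truth": truth[k],
                "replicates": replicates,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def attenuation_signature_experiment(
    params: SimParams | None = None,
    n: int | None = None,
    replicates: int = 100,
    outcome: str = "ever",
    seed: int = 0,
):
    """Rate at which replicates reproduce the mediation signature.

    Under the education-mediates-cognition DAG the univariable cognition
    effect is the nonzero total effect beta2 + alpha_CA beta1 while its
    multivariable (direct) counterpart is beta2; a replicate shows the
    signature when the univariable estimate has the sign of the total
    effect and the multivariable estimate moves from it toward zero.
    Returns ``(rate, per-replicate indicator array)``.
    """
    params = SimParams() if params is None else params
    n = params.n_individuals if n is None else n
    total_cog = params.beta2 + params.alpha_CA * params.beta1
    if total_cog == 0:
        raise ValueError("signature undefined: total cognition effect is zero")
    sign = np.sign(total_cog)
    root = np.random.default_rng(seed)
    hits = []
    for _ in range(replicates):
        p = replace(params, n_individuals=n, seed=int(root.integers(2**31 - 1)))
        cohort, panel = simulate_cohort(p)
        y, mask = cohort.outcome(outcome)
        covs = build_covariates(cohort.covariates, 0)
        s_edu = compute_prs(cohort.dosages, panel, "edu")
        s_cog = compute_prs(cohort.dosages, panel, "cog")
        X = np.column_stack([cohort.edu_years, cohort.cog_score])[mask]
        Z = np.column_stack([s_edu, s_cog])[mask]
        uni = ind.tsls_univariable(y[mask], X[:, 1], Z[:, 1], covs[mask])
        multi = ind.tsls_multivariable(y[mask], X, Z, covs[mask])[1]
        attenuated = sign * (uni.effect - multi.effect) > 0
        right_sign = sign * uni.effect > 0
        hits.append(bool(attenuated and right_sign))
    hits = np.asarray(hits)
    return float(hits.mean()), hits
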