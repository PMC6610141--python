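"""Causal-DAG synthetic data.

Generates individual-level cohorts, and two-sample GWAS summary
statistics, whose generating structure matches the causal diagrams the
estimators are meant to untangle:

* two continuous exposures — years of education (SD ~2.4 years) and a
  standardised cognitive score — each driven by its own set of SNPs, a
  shared latent confounder U, and optionally one mediating the other
  (education -> cognition via ``alpha_E``, or cognition -> education via
  ``alpha_CA``; the two DAGs are alternatives and cannot both be active);
* binary smoking outcomes generated by a linear-probability mechanism
  (risk differences are the estimands): smoking initiation is the
  structural outcome with direct effects ``beta1`` (per year of
  education) and ``beta2`` (per SD of cognition); a mirrored cessation
  mechanism among ever-smokers yields current/former status;
* optional per-SNP horizontal pleiotropy (a nonzero mean encodes
  directional pleiotropy), dynastic effects through explicitly generated
  parental genotypes, and logistic selection into the analysed sample.

Because the generating weights are returned as a :class:`SnpPanel`,
every downstream estimator can be validated by parameter recovery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .scores import SnpPanel
from .summary import SummaryDataset

__all__ = [
    "SimParams",
    "SelectionModel",
    "Cohort",
    "simulate_cohort",
    "simulate_two_sample_summary",
    "sample_summary_from_truth",
    "apply_selection",
]

log = logging.getLogger(__name__)

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
    ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T"),
]


@dataclass(frozen=True)
class SelectionModel:
    """Logistic participation propensity.

    logit P(selected) = intercept + coef_edu * (education - mean)
                        + coef_smoke * current-smoker.
    The intercept sets the overall retention fraction; with both
    coefficients zero selection is uniform.
    """

    intercept: float = 0.0
    coef_edu: float = 0.0
    coef_smoke: float = 0.0


@dataclass(frozen=True)
class SimParams:
    """Structural coefficients of the generating DAG.

    Defaults emulate the target cohort: ~120,050 individuals, education
    with SD 2.4 years, standardised cognition, initiation prevalence
    0.438 with 0.824 of ever-smokers former (so ~7.7% current), score
    instruments whose variance explained puts the first-stage F near the
    hundreds at the full sample size, and the education-mediates-cognition
    DAG (``alpha_CA = 0.5`` years per SD) that reproduces the attenuation
    of the univariable cognition effect.
    """

    n_individuals: int = 120_050
    n_snps_edu: int = 74
    n_snps_cog: int = 18
    maf_range: tuple = (0.05, 0.45)
    beta1: float = -0.09        # education -> initiation, risk diff per year
    beta2: float = 0.0          # cognition -> initiation, risk diff per SD
    alpha_E: float = 0.0        # education -> cognition, SD per year
    alpha_CA: float = 0.5       # cognition -> education, years per SD
    confounder_effects: tuple = (0.6, 0.25, 0.05)  # U on edu, cog, outcome
    pleiotropy: tuple = (0.0, 0.0)   # per-SNP direct outcome effect (mean, sd)
    dynastic_effect: float = 0.0     # parental education -> offspring smoking
    selection_model: SelectionModel = field(default_factory=SelectionModel)
    baseline_prevalence: float = 0.438   # initiation at mean exposures
    # Cessation mechanism among ever-smokers. Ever-smokers are selected
    # towards low education, which lowers their cessation probability, so
    # the intercept is set above the target former-among-ever share of
    # 0.824 to reproduce it after that conditioning.
    cessation_baseline: float = 0.885
    cessation_beta1: float = 0.053       # education -> cessation, per year
    cessation_beta2: float = -0.051      # cognition -> cessation, per SD
    mean_edu: float = 18.3
    sd_edu: float = 2.4
    r2_edu: float = 0.0046      # education variance explained by its score
    r2_cog: float = 0.0074      # cognition variance explained by its score
    n_pcs: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.alpha_E != 0 and self.alpha_CA != 0:
            raise ValueError(
                "alpha_E and alpha_CA cannot both be nonzero: the two "
                "mediation DAGs are alternatives"
            )
        lo, hi = self.maf_range
        if not (0.01 < lo < hi < 0.5):
            raise ValueError("maf_range must lie within (0.01, 0.5)")
        if self.n_individuals < 1 or self.n_snps_edu < 1 or self.n_snps_cog < 1:
            raise ValueError("counts must be positive")
        if not (0 < self.baseline_prevalence < 1 and 0 < self.cessation_baseline < 1):
            raise ValueError("baseline prevalences must lie in (0, 1)")
        c_e, c_c, _ = self.confounder_effects
        if self.r2_edu * self.sd_edu**2 + c_e**2 >= self.sd_edu**2:
            raise ValueError("education score + confounder variance exceed total")
        if self.r2_cog + c_c**2 >= 1:
            raise ValueError("cognition score + confounder variance exceed total")


@dataclass
class Cohort:
    """Individual-level data: dosages, covariates, exposures, outcomes.

    ``smoke_former`` is NaN for never-smokers — cessation is defined only
    among ever-smokers. ``weights`` default to 1 (no re-weighting).
    """

    dosages: np.ndarray
    covariates: pd.DataFrame
    edu_years: np.ndarray
    cog_score: np.ndarray
    smoke_current: np.ndarray
    smoke_ever: np.ndarray
    smoke_former: np.ndarray
    weights: np.ndarray
    confounder: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if np.any((self.smoke_current == 1) & (self.smoke_ever == 0)):
            raise ValueError("current smoker with ever = 0")
        ever = self.smoke_ever == 1
        if np.any(np.isnan(self.smoke_former[ever])):
            raise ValueError("smoke_former undefined for an ever-smoker")
        if not np.all(np.isnan(self.smoke_former[~ever])):
            raise ValueError("smoke_former defined for a never-smoker")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    @property
    def n(self) -> int:
        return int(self.edu_years.size)

    def subset(self, index) -> "Cohort":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Cohort(
            dosages=self.dosages[idx],
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            edu_years=self.edu_years[idx],
            cog_score=self.cog_score[idx],
            smoke_current=self.smoke_current[idx],
            smoke_ever=self.smoke_ever[idx],
            smoke_former=self.smoke_former[idx],
            weights=self.weights[idx],
            confounder=None if self.confounder is None else self.confounder[idx],
        )

    def outcome(self, name: str):
        """Outcome vector and analysis mask for 'current', 'ever' or 'former'.

        For 'former' the mask restricts to ever-smokers, where cessation
        is defined."""
        if name == "current":
            return self.smoke_current.astype(float), np.ones(self.n, bool)
        if name == "ever":
            return self.smoke_ever.astype(float), np.ones(self.n, bool)
        if name == "former":
            mask = self.smoke_ever == 1
            return self.smoke_former, mask
        raise ValueError("outcome must be 'current', 'ever' or 'former'")


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _score_weights(mafs: np.ndarray, target_var: float) -> np.ndarray:
    """Equal-contribution per-allele weights achieving a target score
    variance under Hardy–Weinberg dosage variance 2p(1-p)."""
    var_per_unit = 2 * mafs * (1 - mafs)
    m = mafs.size
    return np.sqrt(target_var / (m * var_per_unit))


def _draw_panel(params: SimParams, rng: np.random.Generator) -> SnpPanel:
    m = params.n_snps_edu + params.n_snps_cog
    mafs = rng.uniform(*params.maf_range, size=m)
    pairs = [_NONPALINDROMIC_PAIRS[i] for i in rng.integers(0, 8, size=m)]
    w_edu = np.zeros(m)
    w_cog = np.zeros(m)
    w_edu[: params.n_snps_edu] = _score_weights(
        mafs[: params.n_snps_edu], params.r2_edu * params.sd_edu**2
    )
    w_cog[params.n_snps_edu:] = _score_weights(
        mafs[params.n_snps_edu:], params.r2_cog * 1.0
    )
    return SnpPanel(
        snp_id=np.array([f"rs{i + 1:05d}" for i in range(m)], dtype=object),
        effect_allele=np.array([p[0] for p in pairs], dtype=object),
        other_allele=np.array([p[1] for p in pairs], dtype=object),
        weight_edu=w_edu,
        weight_cog=w_cog,
        pval_edu=np.where(w_edu != 0, 1e-12, 1.0),
        pval_cog=np.where(w_cog != 0, 1e-12, 1.0),
        maf=mafs,
    )


def _draw_genotypes(params: SimParams, mafs, rng):
    """Offspring dosages; with dynastic effects on, parental genotypes are
    generated explicitly and one allele per parent is transmitted."""
    n, m = params.n_individuals, mafs.size
    if params.dynastic_effect == 0:
        return rng.binomial(2, mafs, size=(n, m)).astype(np.int8), None, None
    mother = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    father = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    child = (
        rng.binomial(1, mother / 2.0) + rng.binomial(1, father / 2.0)
    ).astype(np.int8)
    return child, mother, father


def simulate_cohort(params: SimParams, panel: SnpPanel | None = None):
    """Draw one cohort from the generating DAG.

    Returns ``(cohort, panel)`` where the panel carries the true
    generating weights, so the instruments are known exactly. Passing a
    ``panel`` reuses its SNPs (MAFs and weights) instead of drawing new
    ones — required when several samples must share one instrument set,
    as in the two-sample summary design.
    """
    (
        rng_panel, rng_geno, rng_conf, rng_edu, rng_cog,
        rng_out, rng_cov, rng_pleio,
    ) = _streams(params.seed, 8)
    if panel is None:
        panel = _draw_panel(params, rng_panel)
    elif panel.maf is None:
        raise ValueError("a reused panel must carry generating MAFs")
    elif len(panel) != params.n_snps_edu + params.n_snps_cog:
        raise ValueError("panel size does not match params SNP counts")
    mafs = panel.maf
    G, G_mother, G_father = _draw_genotypes(params, mafs, rng_geno)
    Gc = G - 2 * mafs  # centred dosages
    n = params.n_individuals

    c_e, c_c, c_s = params.confounder_effects
    U = rng_conf.standard_normal(n)
    score_edu = Gc @ panel.weight_edu
    score_cog = Gc @ panel.weight_cog
    sigma_edu = np.sqrt(params.sd_edu**2 - params.r2_edu * params.sd_edu**2 - c_e**2)
    sigma_cog = np.sqrt(1.0 - params.r2_cog - c_c**2)
    e_edu = rng_edu.standard_normal(n) * sigma_edu
    e_cog = rng_cog.standard_normal(n) * sigma_cog

    if params.alpha_E != 0:
        # education upstream: cognition mediates part of its effect
        edu = params.mean_edu + score_edu + c_e * U + e_edu
        cog = score_cog + params.alpha_E * (edu - params.mean_edu) + c_c * U + e_cog
    else:
        # cognition upstream (alpha_CA, possibly 0): education mediates
        cog = score_cog + c_c * U + e_cog
        edu = params.mean_edu + score_edu + params.alpha_CA * cog + c_e * U + e_edu
    edu_c = edu - params.mean_edu

    p_ever = params.baseline_prevalence + params.beta1 * edu_c + params.beta2 * cog
    p_ever = p_ever + c_s * U
    mu, sd = params.pleiotropy
    if mu != 0 or sd != 0:
        delta = rng_pleio.normal(mu, sd, size=mafs.size)
        p_ever = p_ever + Gc @ delta
    if params.dynastic_effect != 0:
        # parental education from parental genotype (mean of the parents)
        par_noise = rng_pleio.standard_normal((n, 2)) * sigma_edu
        e_p = 0.5 * (
            ((G_mother - 2 * mafs) @ panel.weight_edu + par_noise[:, 0])
            + ((G_father - 2 * mafs) @ panel.weight_edu + par_noise[:, 1])
        )
        p_ever = p_ever + params.dynastic_effect * e_p

    clipped = np.mean((p_ever < 0) | (p_ever > 1))
    if clipped > 0.01:
        warnings.warn(
            f"outcome probability clamped for {clipped:.1%} of individuals; "
            "generated risk differences are attenuated at the boundaries",
            stacklevel=2,
        )
        log.warning("probability clamp active for %.2f%% of cohort", 100 * clipped)
    p_ever = np.clip(p_ever, 0.0, 1.0)
    ever = rng_out.binomial(1, p_ever).astype(np.int8)

    # cessation mechanism among ever-smokers: education raises, the
    # confounder lowers, the probability of having quit
    p_former = (
        params.cessation_baseline
        + params.cessation_beta1 * edu_c
        + params.cessation_beta2 * cog
        - c_s * U
    )
    p_former = np.clip(p_former, 0.0, 1.0)
    former_draw = rng_out.binomial(1, p_former).astype(np.int8)
    former = np.where(ever == 1, former_draw.astype(float), np.nan)
    current = (ever == 1) & (former_draw == 0)

    age = rng_cov.integers(38, 74, size=n)
    assessment_year = rng_cov.integers(2006, 2011, size=n)
    covariates = pd.DataFrame(
        {
            "age": age.astype(float),
            "sex": rng_cov.binomial(1, 0.5, size=n).astype(float),
            "year_of_birth": (assessment_year - age).astype(float),
        }
    )
    for i in range(1, params.n_pcs + 1):
        covariates[f"pc{i}"] = rng_cov.standard_normal(n)

    cohort = Cohort(
        dosages=G,
        covariates=covariates,
        edu_years=edu,
        cog_score=cog,
        smoke_current=current.astype(np.int8),
        smoke_ever=ever,
        smoke_former=former,
        weights=np.ones(n),
        confounder=U,
    )
    return cohort, panel


def _snp_regressions(G: np.ndarray, y: np.ndarray):
    """Per-SNP simple linear regressions of y on each dosage column.

    Vectorised: returns (beta, se) arrays. Monomorphic columns get NaN.
    """
    n = y.size
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    ssx = np.sum(Gc**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (Gc.T @ yc) / ssx
        rss = np.sum(yc**2) - beta**2 * ssx
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / ssx)
    bad = ssx == 0
    beta[bad] = np.nan
    se[bad] = np.nan
    return beta, se


def _snp_logistic(G: np.ndarray, y: np.ndarray, max_iter=60, tol=1e-10):
    """Per-SNP logistic regressions (intercept + dosage), vectorised IRLS.

    Returns per-SNP (log-odds slope, SE)."""
    n, m = G.shape
    a = np.full(m, np.log(max(y.mean(), 1e-12) / max(1 - y.mean(), 1e-12)))
    b = np.zeros(m)
    for _ in range(max_iter):
        eta = a[None, :] + G * b[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        wgt = p * (1 - p)
        r = y[:, None] - p
        s0 = wgt.sum(axis=0)
        s1 = (wgt * G).sum(axis=0)
        s2 = (wgt * G**2).sum(axis=0)
        g0 = r.sum(axis=0)
        g1 = (r * G).sum(axis=0)
        det = s0 * s2 - s1**2
        da = (s2 * g0 - s1 * g1) / det
        db = (s0 * g1 - s1 * g0) / det
        a += da
        b += db
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < tol:
            break
    eta = a[None, :] + G * b[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    wgt = p * (1 - p)
    s0 = wgt.sum(axis=0)
    s1 = (wgt * G).sum(axis=0)
    s2 = (wgt * G**2).sum(axis=0)
    var_b = s0 / (s0 * s2 - s1**2)
    return b, np.sqrt(var_b)


def simulate_two_sample_summary(
    params: SimParams,
    n_gwas_exposure: int,
    n_gwas_outcome: int,
    outcome: str = "ever",
    scale: str = "risk_difference",
) -> SummaryDataset:
    """Two-sample GWAS summary statistics from non-overlapping samples.

    Three cohorts are drawn independently from the same DAG: one provides
    the per-SNP education associations (pi1), one the cognition
    associations (pi2), one the outcome associations (Gamma), so no
    individual contributes to both an exposure and the outcome GWAS.
    ``scale`` selects risk-difference (linear) or log-odds (logistic)
    outcome associations. Monomorphic SNPs are excluded with a log entry.
    """
    if scale not in ("risk_difference", "log_odds"):
        raise ValueError("scale must be 'risk_difference' or 'log_odds'")
    root = np.random.default_rng(params.seed)
    seeds = root.integers(0, 2**31 - 1, size=3)
    # one instrument set shared by all three samples
    coh_edu, panel = simulate_cohort(
        replace(params, n_individuals=n_gwas_exposure, seed=int(seeds[0]))
    )
    coh_cog, _ = simulate_cohort(
        replace(params, n_individuals=n_gwas_exposure, seed=int(seeds[1])),
        panel=panel,
    )
    coh_out, _ = simulate_cohort(
        replace(params, n_individuals=n_gwas_outcome, seed=int(seeds[2])),
        panel=panel,
    )
    pi1, se_pi1 = _snp_regressions(coh_edu.dosages, coh_edu.edu_years)
    pi2, se_pi2 = _snp_regressions(coh_cog.dosages, coh_cog.cog_score)
    y, mask = coh_out.outcome(outcome)
    Gout = coh_out.dosages[mask]
    yout = y[mask]
    if scale == "risk_difference":
        gamma, se_gamma = _snp_regressions(Gout, yout)
    else:
        gamma, se_gamma = _snp_logistic(Gout.astype(float), yout)
        mono = Gout.std(axis=0) == 0
        gamma[mono] = np.nan
        se_gamma[mono] = np.nan

    ok = ~(
        np.isnan(pi1) | np.isnan(pi2) | np.isnan(gamma)
        | np.isnan(se_pi1) | np.isnan(se_pi2) | np.isnan(se_gamma)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("excluded %d monomorphic/degenerate SNPs", n_dropped)
    return SummaryDataset(
        snp_id=panel.snp_id[ok],
        gamma=gamma[ok],
        se_gamma=se_gamma[ok],
        pi1=pi1[ok],
        se_pi1=se_pi1[ok],
        pi2=pi2[ok],
        se_pi2=se_pi2[ok],
        n_exposure=n_gwas_exposure,
        n_outcome=n_gwas_outcome,
        scale=scale,
        harmonised=True,
    )


def sample_summary_from_truth(
    n_snps: int,
    beta1: float,
    beta2: float,
    se_gamma=0.02,
    se_pi=0.01,
    pi_scale=0.05,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    orient_positive: bool = False,
    seed: int = 0,
) -> SummaryDataset:
    """Summary statistics drawn directly from their sampling model.

    True per-SNP exposure effects are drawn once, then the reported
    associations are the truths plus Gaussian noise at the stated SEs,
    with Gamma_j = beta1 pi1_j + beta2 pi2_j + (optional per-SNP direct
    effect, InSIDE-independent of the instrument strengths). This is the
    idealised regime in which IVW is exactly correctly specified — used
    for calibration experiments (Q, Egger coverage) where cohort-level
    realism is irrelevant.

    ``orient_positive`` draws the first-exposure effects as positive
    magnitudes bounded away from zero — the convention for instruments
    selected at genome-wide significance and reported by their
    trait-increasing allele. Directional pleiotropy only biases IVW under
    that orientation (with signed effects the per-SNP offsets cancel on
    average).
    """
    rng = np.random.default_rng(seed)
    if orient_positive:
        pi1 = pi_scale * (0.3 + np.abs(rng.standard_normal(n_snps)))
    else:
        pi1 = rng.normal(0, pi_scale, n_snps)
    pi2 = rng.normal(0, pi_scale, n_snps)
    se_g = np.full(n_snps, float(se_gamma))
    se_p = np.full(n_snps, float(se_pi))
    direct = (
        rng.normal(pleiotropy_mean, pleiotropy_sd, n_snps)
        if (pleiotropy_mean != 0 or pleiotropy_sd != 0)
        else np.zeros(n_snps)
    )
    gamma_true = beta1 * pi1 + beta2 * pi2 + direct
    return SummaryDataset(
        snp_id=np.array([f"rs{i + 1:05d}" for i in range(n_snps)], dtype=object),
        gamma=gamma_true + rng.normal(0, se_g),
        se_gamma=se_g,
        pi1=pi1 + rng.normal(0, se_p),
        se_pi1=se_p,
        pi2=pi2 + rng.normal(0, se_p),
        se_pi2=se_p,
        harmonised=True,
    )


def apply_selection(cohort: Cohort, params: SimParams):
    """Select individuals with logistic probability in education and
    current smoking; returns (selected cohort, participation probabilities
    for the full cohort) so re-weighting can be tested against truth."""
    sel = params.selection_model
    edu_c = cohort.edu_years - np.mean(cohort.edu_years)
    eta = (
        sel.intercept
        + sel.coef_edu * edu_c
        + sel.coef_smoke * cohort.smoke_current.astype(float)
    )
    prob = 1.0 / (1.0 + np.exp(-eta))
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(9)[-1])
    keep = rng.random(cohort.n) < prob
    if not keep.any():
        raise ValueError("selection removed every individual")
    return cohort.subset(keep), prob
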