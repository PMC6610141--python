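"""Individual-level estimation.

Observational OLS, univariable and multivariable two-stage least squares
with polygenic-score instruments, first-stage and Sanderson–Windmeijer
conditional F diagnostics, SD scaling of risk differences, and
post-stratification weights for selection re-weighting.

Binary smoking outcomes are modelled with a linear probability model, so
effects are risk differences; heteroskedasticity-robust (HC1) standard
errors are used throughout because LPM errors are intrinsically
heteroskedastic. Two-stage estimates use the proper instrumental-variable
variance (sandwich over the projected design), not the naive second-stage
OLS formula, which would ignore first-stage estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MREstimate",
    "ols_estimate",
    "tsls_univariable",
    "tsls_multivariable",
    "conditional_f",
    "sd_scale",
    "selection_weights",
    "WEAK_INSTRUMENT_F",
]

# conventional threshold below which an instrument is flagged as weak
WEAK_INSTRUMENT_F = 10.0


@dataclass
class MREstimate:
    """One estimated causal effect with uncertainty and diagnostics.

    ``effect`` is a risk difference per unit of the exposure (per year of
    education, per SD of cognitive score) for individual-level fits, or
    whatever scale the summary data carry for summary-level fits.
    """

    effect: float
    se: float
    ci95: tuple
    pval: float
    method: str
    n: int
    exposure: str = ""
    outcome: str = ""
    f_stat: float | None = None
    cond_f: float | None = None
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate:
            lo, hi = self.ci95
            if not np.isclose(lo, self.effect - 1.96 * self.se, atol=1e-8):
                raise ValueError("ci95 inconsistent with effect +/- 1.96 se")
            if not (0 < self.pval <= 1):
                raise ValueError("pval must lie in (0, 1]")


def _as_2d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def _colnames(x, prefix: str) -> list[str]:
    if isinstance(x, pd.DataFrame):
        return list(map(str, x.columns))
    if isinstance(x, pd.Series):
        return [str(x.name) if x.name is not None else f"{prefix}1"]
    a = np.asarray(x)
    k = 1 if a.ndim == 1 else a.shape[1]
    return [f"{prefix}{i + 1}" for i in range(k)]


def _with_intercept(W) -> np.ndarray:
    W = _as_2d(W)
    return np.column_stack([np.ones(W.shape[0]), W])


def _wald_estimate(effect, se, n, method, exposure, outcome, df=None, **kw):
    se = float(se)
    effect = float(effect)
    if se == 0:
        return MREstimate(
            effect=effect, se=0.0, ci95=(effect, effect), pval=1.0,
            method=method, n=n, exposure=exposure, outcome=outcome,
            degenerate=True, **kw,
        )
    if df is None:
        p = 2 * stats.norm.sf(abs(effect / se))
    else:
        p = 2 * stats.t.sf(abs(effect / se), df)
    return MREstimate(
        effect=effect,
        se=se,
        ci95=(effect - 1.96 * se, effect + 1.96 * se),
        pval=max(float(p), np.finfo(float).tiny),
        method=method,
        n=n,
        exposure=exposure,
        outcome=outcome,
        **kw,
    )


def ols_estimate(outcome, exposures, covariates, weights=None, outcome_label="outcome"):
    """Weighted linear-probability OLS of the outcome on the exposures and
    the covariate block, with HC1 robust standard errors.

    Returns one :class:`MREstimate` per exposure column. A degenerate fit
    (zero residual variance, e.g. a constant outcome) is flagged rather
    than reported with a spurious p-value.
    """
    y = np.asarray(outcome, dtype=float)
    X = _as_2d(exposures)
    labels = _colnames(exposures, "exposure")
    W = _as_2d(covariates)
    n = y.size
    design = np.column_stack([np.ones(n), X, W])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("analysis weights must be positive")
    fit = sm.WLS(y, design, weights=w).fit(cov_type="HC1")
    out = []
    for j, lab in enumerate(labels, start=1):
        out.append(
            _wald_estimate(
                fit.params[j], fit.bse[j], n, "OLS", lab, outcome_label,
            )
        )
    return out


def _first_stage_f(x, z, W, weights=None):
    """Classical F statistic for the excluded instruments z in the
    first-stage regression x ~ intercept + W + z."""
    x = np.asarray(x, dtype=float)
    Z = _as_2d(z)
    Wi = _with_intercept(W)
    n = x.size
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)
    full = np.column_stack([Wi, Z]) * sw[:, None]
    restr = Wi * sw[:, None]
    xw = x * sw
    rss_f = np.sum((xw - full @ np.linalg.lstsq(full, xw, rcond=None)[0]) ** 2)
    rss_r = np.sum((xw - restr @ np.linalg.lstsq(restr, xw, rcond=None)[0]) ** 2)
    kz = Z.shape[1]
    dof = n - full.shape[1]
    if rss_f <= 0:
        return float("inf")
    return float((rss_r - rss_f) / kz / (rss_f / dof))


def _tsls(y, X_endog, Z_excl, W, weights=None):
    """Two-stage least squares with included covariates.

    Regressors X = [1, W, X_endog]; instruments Z = [1, W, Z_excl].
    Returns (beta, robust covariance, index of endogenous coefficients).
    The covariance is the HC1 sandwich over the projected design with
    structural residuals y - X beta (the proper IV variance).
    """
    y = np.asarray(y, dtype=float)
    Xe = _as_2d(X_endog)
    Ze = _as_2d(Z_excl)
    Wi = _with_intercept(W)
    n = y.size
    if Ze.shape[1] < Xe.shape[1]:
        raise ValueError(
            f"order condition fails: {Ze.shape[1]} excluded instruments for "
            f"{Xe.shape[1]} endogenous regressors"
        )
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)
    X = np.column_stack([Wi, Xe]) * sw[:, None]
    Z = np.column_stack([Wi, Ze]) * sw[:, None]
    yw = y * sw
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("instrument matrix is rank deficient")
    # first stage: project X onto the column space of Z
    Xhat = Z @ np.linalg.lstsq(Z, X, rcond=None)[0]
    xtx = Xhat.T @ Xhat
    # condition check on the scale-equilibrated matrix so raw covariate
    # units (e.g. calendar years) cannot masquerade as singularity
    d = np.sqrt(np.diag(xtx))
    if np.any(d == 0):
        raise ValueError("projected design has a zero column")
    scaled = xtx / np.outer(d, d)
    cond = np.linalg.cond(scaled)
    if not np.isfinite(cond) or cond > 1e10:
        raise ValueError(
            "projected design is (near-)singular: instruments do not "
            "separately predict the endogenous regressors"
        )
    bread = np.linalg.inv(scaled) / np.outer(d, d)
    beta = bread @ (Xhat.T @ yw)
    resid = yw - X @ beta  # structural residuals, actual regressors
    k = X.shape[1]
    meat = (Xhat * resid[:, None] ** 2).T @ Xhat
    cov = bread @ meat @ bread * (n / (n - k))
    endog_idx = np.arange(Wi.shape[1], k)
    return beta, cov, endog_idx


def tsls_univariable(
    outcome,
    exposure,
    instrument_score,
    covariates,
    weights=None,
    exposure_label="exposure",
    outcome_label="outcome",
) -> MREstimate:
    """Univariable MR: just-identified 2SLS with one score instrument.

    The first-stage F for the score (exposure ~ score + covariates) is
    attached; values below 10 trigger a weak-instrument warning. A zero
    first-stage coefficient makes the estimand undefined and is an error.
    """
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument_score, dtype=float)
    if np.std(z) == 0:
        raise ValueError("instrument score does not vary")
    f = _first_stage_f(x, z, covariates, weights)
    Wi = _with_intercept(covariates)
    fs_coef = np.linalg.lstsq(
        np.column_stack([Wi, z]), x, rcond=None
    )[0][-1]
    if abs(fs_coef) < 1e-14:
        raise ValueError("first-stage coefficient is zero; IV undefined")
    if f < WEAK_INSTRUMENT_F:
        warnings.warn(
            f"first-stage F = {f:.2f} < {WEAK_INSTRUMENT_F:g}: weak instrument",
            stacklevel=2,
        )
    beta, cov, idx = _tsls(outcome, x, z, covariates, weights)
    j = idx[0]
    return _wald_estimate(
        beta[j], np.sqrt(cov[j, j]), x.size, "MR-uni",
        exposure_label, outcome_label, f_stat=f,
    )


def tsls_multivariable(
    outcome,
    exposures,
    instrument_scores,
    covariates,
    weights=None,
    exposure_labels=("edu", "cog"),
    outcome_label="outcome",
):
    """Multivariable MR: both exposures predicted from both scores (plus
    covariates); the outcome regressed on the predictions and covariates.

    Returns one :class:`MREstimate` per exposure, each carrying the
    unconditional first-stage F of both scores for that exposure and its
    Sanderson–Windmeijer conditional F. Nearly collinear scores
    (|corr| > 0.999) cannot separately identify the two effects.
    """
    X = _as_2d(exposures)
    Z = _as_2d(instrument_scores)
    if X.shape[1] != 2 or Z.shape[1] != 2:
        raise ValueError("expected exactly two exposures and two scores")
    r = np.corrcoef(Z[:, 0], Z[:, 1])[0, 1]
    if abs(r) > 0.999:
        raise ValueError(
            f"instrument scores are collinear (|corr| = {abs(r):.4f} > 0.999)"
        )
    beta, cov, idx = _tsls(outcome, X, Z, covariates, weights)
    cond_fs = conditional_f(X, Z, covariates, weights)
    out = []
    for pos, j in enumerate(idx):
        f = _first_stage_f(X[:, pos], Z, covariates, weights)
        cf = cond_fs[pos]
        if cf < WEAK_INSTRUMENT_F:
            warnings.warn(
                f"conditional F = {cf:.2f} < {WEAK_INSTRUMENT_F:g} for "
                f"{exposure_labels[pos]}: conditionally weak instruments",
                stacklevel=2,
            )
        out.append(
            _wald_estimate(
                beta[j], np.sqrt(cov[j, j]), X.shape[0], "MR-multi",
                exposure_labels[pos], outcome_label, f_stat=f, cond_f=cf,
            )
        )
    return tuple(out)


def conditional_f(exposures, instruments, covariates, weights=None) -> np.ndarray:
    """Sanderson–Windmeijer conditional F statistic per exposure.

    For target exposure x_t with the other exposures X_o: estimate
    x_t = X_o delta + W gamma by 2SLS (instrumenting X_o with all the
    instruments), regress the structural residual on the instruments and
    covariates, and rescale the joint F of the instruments by
    kz / (kz - kx + 1) so that the statistic is referred to its proper
    degrees of freedom. With a single exposure the residual step is an
    OLS partialling of the covariates and the statistic reduces exactly
    to the standard first-stage F.
    """
    X = _as_2d(exposures)
    Z = _as_2d(instruments)
    kx = X.shape[1]
    kz = Z.shape[1]
    if kz < kx:
        raise ValueError(
            f"order condition fails: {kz} instruments for {kx} exposures"
        )
    out = np.empty(kx)
    for t in range(kx):
        others = np.delete(X, t, axis=1)
        if others.shape[1] == 0:
            Wi = _with_intercept(covariates)
            n = X.shape[0]
            w = np.ones(n) if weights is None else np.asarray(weights, float)
            sw = np.sqrt(w)
            gamma = np.linalg.lstsq(Wi * sw[:, None], X[:, t] * sw, rcond=None)[0]
            u = X[:, t] - Wi @ gamma
        else:
            b, _, _ = _tsls(X[:, t], others, Z, covariates, weights)
            Wi = _with_intercept(covariates)
            full = np.column_stack([Wi, others])
            u = X[:, t] - full @ b
        f_z = _first_stage_f(u, Z, covariates, weights)
        out[t] = f_z * kz / (kz - kx + 1)
    return out


def sd_scale(effect_per_unit: float, sd_of_exposure: float):
    """Rescale a per-unit risk difference to per-SD, with the magnitude as
    a percentage rounded half-up to 1 dp (the presentation convention for
    risk differences)."""
    if sd_of_exposure <= 0:
        raise ValueError("exposure SD must be positive")
    per_sd = effect_per_unit * sd_of_exposure
    pct = float(
        (Decimal(100) * Decimal(repr(abs(per_sd)))).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
    return float(per_sd), pct


def selection_weights(sample_strata, population_strata) -> pd.Series:
    """Post-stratification weights w_s = population share / sample share.

    Both inputs map stratum label -> proportion and must cover the same
    strata and sum to 1. Weighting the sample by the result reproduces
    the population stratum distribution exactly.
    """
    s = pd.Series(sample_strata, dtype=float)
    p = pd.Series(population_strata, dtype=float)
    if set(s.index) != set(p.index):
        raise ValueError("sample and population strata do not match")
    p = p.reindex(s.index)
    for name, v in (("sample", s), ("population", p)):
        if not np.isclose(v.sum(), 1.0, atol=1e-8):
            raise ValueError(f"{name} proportions must sum to 1")
        if (v < 0).any():
            raise ValueError(f"{name} proportions must be non-negative")
    empty = (s == 0) & (p > 0)
    if empty.any():
        raise ValueError(
            f"sample stratum {list(s.index[empty])} is empty but has "
            "population mass; weights undefined"
        )
    w = p / s.replace(0, np.nan)
    return w.fillna(0.0)
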