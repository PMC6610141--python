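"""Two-sample summary-data Mendelian randomisation.

Implements the Wald ratio, univariable inverse-variance-weighted (IVW)
estimation, the multivariable IVW regression

    Gamma_j = beta1 * pi_1j + beta2 * pi_2j + v_j

fitted by weighted least squares with weights 1/se(Gamma_j)^2, MR-Egger
with a free intercept (directional-pleiotropy estimate), and the modified
Cochran Q statistic with per-SNP contributions and one-shot outlier
removal.

Here ``Gamma_j`` is the SNP-outcome association (log-odds or risk
difference), ``pi_1j`` and ``pi_2j`` are the SNP-exposure associations for
education and cognitive ability, each with standard errors from
independent, non-overlapping GWAS samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .individual import MREstimate

__all__ = [
    "SummaryDataset",
    "QReport",
    "wald_ratio",
    "ivw_univariable",
    "mvmr_ivw",
    "mr_egger",
    "modified_q",
    "remove_outliers_and_refit",
    "to_odds_ratio",
]


@dataclass
class SummaryDataset:
    """Harmonised per-SNP associations for one outcome and 1–2 exposures.

    ``pi2``/``se_pi2`` are ``None`` for a univariable dataset. ``scale``
    records whether the outcome associations are log-odds or risk
    differences. Estimation refuses unharmonised data.
    """

    snp_id: np.ndarray
    gamma: np.ndarray
    se_gamma: np.ndarray
    pi1: np.ndarray
    se_pi1: np.ndarray
    pi2: np.ndarray | None = None
    se_pi2: np.ndarray | None = None
    n_exposure: int | None = None
    n_outcome: int | None = None
    scale: str = "risk_difference"
    harmonised: bool = True

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        for name in ("gamma", "se_gamma", "pi1", "se_pi1"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.pi2 is not None:
            self.pi2 = np.asarray(self.pi2, dtype=float)
            self.se_pi2 = np.asarray(self.se_pi2, dtype=float)
        L = self.gamma.size
        for name in ("se_gamma", "pi1", "se_pi1"):
            if getattr(self, name).shape != (L,):
                raise ValueError(f"{name} length mismatch")
        if self.pi2 is not None and (
            self.pi2.shape != (L,) or self.se_pi2.shape != (L,)
        ):
            raise ValueError("pi2/se_pi2 length mismatch")
        ses = [self.se_gamma, self.se_pi1]
        if self.se_pi2 is not None:
            ses.append(self.se_pi2)
        for se in ses:
            if np.any(se <= 0):
                raise ValueError("all standard errors must be > 0")
        if self.scale not in ("risk_difference", "log_odds"):
            raise ValueError("scale must be 'risk_difference' or 'log_odds'")

    @property
    def n_snps(self) -> int:
        return int(self.gamma.size)

    @property
    def n_exposures(self) -> int:
        return 1 if self.pi2 is None else 2

    def subset(self, index) -> "SummaryDataset":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SummaryDataset(
            snp_id=self.snp_id[idx],
            gamma=self.gamma[idx],
            se_gamma=self.se_gamma[idx],
            pi1=self.pi1[idx],
            se_pi1=self.se_pi1[idx],
            pi2=None if self.pi2 is None else self.pi2[idx],
            se_pi2=None if self.se_pi2 is None else self.se_pi2[idx],
            n_exposure=self.n_exposure,
            n_outcome=self.n_outcome,
            scale=self.scale,
            harmonised=self.harmonised,
        )


@dataclass
class QReport:
    """Modified Cochran Q decomposition for an (MV)MR fit."""

    q_total: float
    df: int
    pval: float
    q_per_snp: np.ndarray
    p_per_snp: np.ndarray
    snp_id: np.ndarray
    removed_snps: list
    estimates: tuple


def _check(data: SummaryDataset):
    if not data.harmonised:
        raise ValueError("summary dataset must be harmonised before estimation")


def wald_ratio(gamma_hat, se_gamma, pi_hat, se_pi):
    """Single-SNP causal estimate Gamma/pi with first-order delta-method SE."""
    if pi_hat == 0:
        raise ZeroDivisionError("SNP-exposure association is zero")
    if se_pi > 0 and abs(pi_hat) < 3 * se_pi:
        warnings.warn(
            "weak SNP: |pi| < 3 se(pi); Wald ratio may be unstable", stacklevel=2
        )
    ratio = gamma_hat / pi_hat
    se = np.sqrt(se_gamma**2 / pi_hat**2 + gamma_hat**2 * se_pi**2 / pi_hat**4)
    return float(ratio), float(se)


def _estimate(effect, se, method, n, exposure, outcome):
    effect = float(effect)
    se = float(se)
    z = effect / se if se > 0 else 0.0
    p = 2 * stats.norm.sf(abs(z)) if se > 0 else 1.0
    return MREstimate(
        effect=effect,
        se=se,
        ci95=(effect - 1.96 * se, effect + 1.96 * se),
        pval=max(float(p), np.finfo(float).tiny),
        method=method,
        n=n,
        exposure=exposure,
        outcome=outcome,
    )


def ivw_univariable(data: SummaryDataset, exposure: str = "edu") -> MREstimate:
    """Fixed-effect IVW: WLS of Gamma on pi through the origin, weights
    1/se(Gamma)^2. With one SNP this is exactly the Wald ratio."""
    _check(data)
    if data.n_snps == 0:
        raise ValueError("no SNPs in summary dataset")
    if exposure in ("edu", "exposure1"):
        pi = data.pi1
    elif exposure in ("cog", "exposure2"):
        if data.pi2 is None:
            raise ValueError("dataset has no second exposure")
        pi = data.pi2
    else:
        raise ValueError("exposure must be 'edu' or 'cog'")
    w = 1.0 / data.se_gamma**2
    denom = np.sum(w * pi**2)
    if denom == 0:
        raise ValueError("all SNP-exposure associations are zero")
    beta = np.sum(w * pi * data.gamma) / denom
    se = np.sqrt(1.0 / denom)
    return _estimate(beta, se, "IVW", data.n_snps, exposure, "outcome")


def _wls_no_intercept(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form WLS through the origin: beta, cov, residuals."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    xtx = Xw.T @ Xw
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "exposure associations are collinear across SNPs; the "
            "multivariable model is not identified (conditionally weak "
            "instruments)"
        )
    cov = np.linalg.inv(xtx)
    beta = cov @ (Xw.T @ yw)
    resid = y - X @ beta
    return beta, cov, resid


def mvmr_ivw(data: SummaryDataset):
    """Multivariable IVW: WLS of Gamma on (pi1, pi2) with no intercept,
    weights 1/se(Gamma)^2. Returns (education estimate, cognition estimate).
    """
    _check(data)
    if data.pi2 is None:
        raise ValueError("multivariable IVW needs two exposure columns")
    if data.n_snps < 2:
        raise ValueError("multivariable IVW needs at least 2 SNPs")
    if np.all(data.pi2 == 0):
        raise ValueError(
            "second-exposure associations are all zero; beta2 is not "
            "identified — use univariable IVW"
        )
    if np.all(data.pi1 == 0):
        raise ValueError("first-exposure associations are all zero")
    X = np.column_stack([data.pi1, data.pi2])
    w = 1.0 / data.se_gamma**2
    beta, cov, _ = _wls_no_intercept(X, data.gamma, w)
    ses = np.sqrt(np.diag(cov))
    return (
        _estimate(beta[0], ses[0], "MVMR-IVW", data.n_snps, "edu", "outcome"),
        _estimate(beta[1], ses[1], "MVMR-IVW", data.n_snps, "cog", "outcome"),
    )


def _orient(data: SummaryDataset) -> SummaryDataset:
    """Flip SNP signs so the first exposure association is non-negative.

    Egger's intercept is not invariant to allele-coding sign flips; this
    fixes the conventional orientation before fitting.
    """
    s = np.where(data.pi1 < 0, -1.0, 1.0)
    return replace(
        data,
        gamma=data.gamma * s,
        pi1=data.pi1 * s,
        pi2=None if data.pi2 is None else data.pi2 * s,
    )


def mr_egger(data: SummaryDataset, multivariable: bool = False):
    """(MV)MR-Egger: the IVW regression with an unconstrained intercept.

    The intercept estimates the average directional pleiotropic effect
    per SNP; a slope robust to directional pleiotropy is returned for each
    exposure. Returns ``(slopes, intercept)`` where ``slopes`` is a tuple
    of MREstimate (length 1 univariable, 2 multivariable).
    """
    _check(data)
    k = 2 if multivariable else 1
    min_L = 4 if multivariable else 3
    if multivariable and data.pi2 is None:
        raise ValueError("multivariable Egger needs two exposure columns")
    if data.n_snps < min_L:
        raise ValueError(
            f"MR-Egger with {k} exposure(s) needs at least {min_L} SNPs, "
            f"got {data.n_snps}"
        )
    oriented = _orient(data)
    cols = [np.ones(oriented.n_snps), oriented.pi1]
    if multivariable:
        cols.append(oriented.pi2)
    X = np.column_stack(cols)
    w = 1.0 / oriented.se_gamma**2
    beta, cov, resid = _wls_no_intercept(X, oriented.gamma, w)  # X has its own 1s
    ses = np.sqrt(np.diag(cov))
    intercept = _estimate(
        beta[0], ses[0], "Egger-intercept", data.n_snps, "(pleiotropy)", "outcome"
    )
    labels = ["edu", "cog"]
    slopes = tuple(
        _estimate(
            beta[i + 1],
            ses[i + 1],
            "MVMR-Egger" if multivariable else "Egger",
            data.n_snps,
            labels[i],
            "outcome",
        )
        for i in range(k)
    )
    return slopes, intercept


def modified_q(
    data: SummaryDataset,
    fitted=None,
    alpha: float = 0.05,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> QReport:
    """Modified Cochran Q for an (MV)MR model.

    Per-SNP contribution q_j = w_j (Gamma_j - b1 pi1_j - b2 pi2_j)^2 with
    weights that propagate the SNP-exposure uncertainty,

        w_j = 1 / (se_gamma_j^2 + b1^2 se_pi1_j^2 + b2^2 se_pi2_j^2).

    If ``fitted`` (pair or single estimate / plain floats) is omitted the
    coefficients are estimated internally by iterating WLS with these
    exact weights to convergence. Q_total is referred to chi-squared with
    L - (number of exposures) degrees of freedom, each q_j to chi-squared
    with 1 df; SNPs with per-SNP p below ``alpha`` are listed as removal
    candidates.
    """
    _check(data)
    two = data.pi2 is not None
    X = (
        np.column_stack([data.pi1, data.pi2])
        if two
        else data.pi1[:, None]
    )
    se_pi = (
        np.column_stack([data.se_pi1, data.se_pi2])
        if two
        else data.se_pi1[:, None]
    )

    def weights(b):
        return 1.0 / (data.se_gamma**2 + np.sum((b**2) * se_pi**2, axis=1))

    if fitted is not None:
        if isinstance(fitted, MREstimate):
            b = np.array([fitted.effect])
        elif isinstance(fitted, (tuple, list)):
            b = np.array(
                [f.effect if isinstance(f, MREstimate) else float(f) for f in fitted]
            )
        else:
            b = np.atleast_1d(np.asarray(fitted, dtype=float))
        if b.size != X.shape[1]:
            raise ValueError("fitted estimates do not match number of exposures")
    else:
        # exact-weighting fit: iterate WLS with uncertainty-propagating weights
        b = np.zeros(X.shape[1])
        for _ in range(max_iter):
            w = weights(b)
            b_new, _, _ = _wls_no_intercept(X, data.gamma, w)
            if np.max(np.abs(b_new - b)) < tol:
                b = b_new
                break
            b = b_new

    w = weights(b)
    resid = data.gamma - X @ b
    q_j = w * resid**2
    q_total = float(np.sum(q_j))
    df = data.n_snps - X.shape[1]
    if df <= 0:
        warnings.warn(
            "Q degrees of freedom is zero (just-identified fit); "
            "overall p-value undefined",
            stacklevel=2,
        )
        pval = float("nan")
    else:
        pval = float(stats.chi2.sf(q_total, df))
    p_j = stats.chi2.sf(q_j, 1)
    removed = list(data.snp_id[p_j < alpha])
    return QReport(
        q_total=q_total,
        df=max(df, 0),
        pval=pval,
        q_per_snp=q_j,
        p_per_snp=p_j,
        snp_id=data.snp_id.copy(),
        removed_snps=removed,
        estimates=tuple(float(x) for x in b),
    )


def remove_outliers_and_refit(data: SummaryDataset, alpha: float = 0.05):
    """One-shot pleiotropy-outlier removal and re-estimation.

    Computes the modified Q (internally fitted), drops every SNP whose
    per-SNP Q has p < ``alpha``, then refits once (MVMR-IVW with two
    exposures, univariable IVW with one). Not iterated. Returns
    ``(removed_ids, refitted_estimates, q_report)``.
    """
    report = modified_q(data, fitted=None, alpha=alpha)
    removed = set(report.removed_snps)
    keep = np.array([sid not in removed for sid in data.snp_id])
    if not keep.any():
        raise ValueError("outlier removal excluded every SNP")
    sub = data.subset(keep)
    if data.pi2 is not None:
        refit = mvmr_ivw(sub)
    else:
        refit = (ivw_univariable(sub, "edu"),)
    return sorted(removed, key=str), refit, report


def to_odds_ratio(effect: float, se: float):
    """Exponentiate a log-odds effect: OR with 95% CI."""
    return (
        float(np.exp(effect)),
        (float(np.exp(effect - 1.96 * se)), float(np.exp(effect + 1.96 * se))),
    )
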