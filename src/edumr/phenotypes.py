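"""Deterministic phenotype construction.

Maps highest educational qualification to age completed full-time
education, standardises the verbal-numeric reasoning score, derives the
three binary smoking phenotypes (current, initiation, cessation) and
assembles the covariate design block used by every regression.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "QUALIFICATION_YEARS",
    "qualification_to_years",
    "load_qualification_map",
    "standardize_score",
    "derive_smoking_phenotypes",
    "build_covariates",
    "percent",
]

# Highest qualification -> age (years) at which full-time education is
# assumed to have been completed. Six categories; the map is total on them.
QUALIFICATION_YEARS: dict[str, int] = {
    "none": 15,
    "cse/o level/gcse": 16,
    "nvq/hnd/hnc": 18,
    "a level": 18,
    "other professional qualification": 20,
    "college or university degree": 21,
}


def _normalise_label(label: str) -> str:
    return " ".join(str(label).strip().lower().split())


def qualification_to_years(label: str) -> int:
    """Age at completing education for a highest-qualification category.

    Raises ``KeyError`` naming the valid categories for unknown labels.
    Matching is case- and whitespace-insensitive.
    """
    key = _normalise_label(label)
    try:
        return QUALIFICATION_YEARS[key]
    except KeyError:
        valid = ", ".join(repr(k) for k in QUALIFICATION_YEARS)
        raise KeyError(
            f"unknown qualification {label!r}; valid categories: {valid}"
        ) from None


def load_qualification_map() -> pd.DataFrame:
    """Load the packaged qualification map (label, years, share of sample)."""
    with resources.files("edumr.data").joinpath("qualification_years.tsv").open() as fh:
        # "None" is a category label, not a missing value
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def standardize_score(raw) -> np.ndarray:
    """Standardise a test-score vector to mean 0, SD 1 (sample SD).

    Affine-invariant and idempotent. A constant vector is rejected because
    it carries no information to standardise.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d score vector")
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        raise ValueError("score vector is constant; cannot standardise")
    return (x - x.mean()) / sd


def percent(numerator: float, denominator: float) -> float:
    """Percentage to 1 decimal place with half-up rounding."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def derive_smoking_phenotypes(current_flag, ever_flag):
    """Derive the three smoking outcomes from current/ever report flags.

    Returns ``(current, initiation, cessation, summary)`` where ``cessation``
    is 1 for former smokers, 0 for current smokers and NaN for never
    smokers (it is only defined among ever smokers), and ``summary`` holds
    counts and percentages (1 dp).

    A current smoker who is not an ever smoker is logically impossible;
    such rows abort the derivation with their indices listed.
    """
    current = np.asarray(current_flag, dtype=float)
    ever = np.asarray(ever_flag, dtype=float)
    if current.shape != ever.shape:
        raise ValueError("current and ever flags differ in length")
    bad = np.flatnonzero((current == 1) & (ever == 0))
    if bad.size:
        shown = ", ".join(map(str, bad[:20]))
        more = "" if bad.size <= 20 else f" (+{bad.size - 20} more)"
        raise ValueError(
            f"current=1 with ever=0 at rows [{shown}]{more}: impossible smoking state"
        )

    initiation = ever.astype(float)
    cessation = np.where(ever == 1, 1.0 - current, np.nan)
    n = current.size
    n_current = int(current.sum())
    n_ever = int(ever.sum())
    n_former = int(np.nansum(cessation))
    summary = {
        "n": n,
        "n_current": n_current,
        "n_ever": n_ever,
        "n_former": n_former,
        "pct_current": percent(n_current, n) if n else float("nan"),
        "pct_ever": percent(n_ever, n) if n else float("nan"),
        "pct_former_among_ever": percent(n_former, n_ever) if n_ever else float("nan"),
    }
    return current, initiation, cessation, summary


def build_covariates(covariates: pd.DataFrame, n_pcs: int = 10) -> pd.DataFrame:
    """Assemble the adjustment block: age, sex, year of birth, sex x year
    of birth, and the first ``n_pcs`` genetic principal components.

    The returned frame must be full column rank once an intercept is added;
    a rank-deficient block raises ``ValueError`` naming the offending
    column (e.g. the interaction when sex is constant in a subset).
    """
    required = ["age", "sex", "year_of_birth"]
    missing = [c for c in required if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table missing columns {missing}")
    pc_cols = [f"pc{i}" for i in range(1, n_pcs + 1)]
    missing_pcs = [c for c in pc_cols if c not in covariates.columns]
    if missing_pcs:
        raise ValueError(
            f"requested {n_pcs} PCs but columns {missing_pcs} are absent"
        )
    block = covariates[required].astype(float).copy()
    block["sex_x_year_of_birth"] = block["sex"] * block["year_of_birth"]
    for c in pc_cols:
        block[c] = covariates[c].astype(float)

    # incremental rank check so the first collinear column can be named
    n = len(block)
    design = np.ones((n, 1))
    for name in block.columns:
        cand = np.column_stack([design, block[name].to_numpy()])
        if np.linalg.matrix_rank(cand) <= design.shape[1]:
            raise ValueError(
                f"covariate block is rank deficient: column {name!r} is "
                "collinear with the preceding columns (plus intercept)"
            )
        design = cand
    return block
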