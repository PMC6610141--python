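"""Polygenic-score instruments.

A :class:`SnpPanel` holds the instrument SNPs with per-exposure weights
(the effect sizes from the discovery GWAS), and this module provides
allele harmonisation between a panel and a target dataset, weighted-score
computation, and greedy LD pruning at a pairwise r-squared threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SnpPanel", "harmonise_alleles", "compute_prs", "ld_prune"]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SnpPanel:
    """Instrument SNP set with per-exposure weights and optional LD matrix.

    ``weight_edu`` is the per-allele effect on years of education,
    ``weight_cog`` on the standardised cognitive score. ``ld_corr`` is the
    pairwise correlation matrix r (not r-squared) in panel order.
    """

    snp_id: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    weight_edu: np.ndarray
    weight_cog: np.ndarray
    pval_edu: np.ndarray | None = None
    pval_cog: np.ndarray | None = None
    ld_corr: np.ndarray | None = None
    maf: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.effect_allele = np.asarray(
            [str(a).upper() for a in self.effect_allele], dtype=object
        )
        self.other_allele = np.asarray(
            [str(a).upper() for a in self.other_allele], dtype=object
        )
        self.weight_edu = np.asarray(self.weight_edu, dtype=float)
        self.weight_cog = np.asarray(self.weight_cog, dtype=float)
        if self.pval_edu is not None:
            self.pval_edu = np.asarray(self.pval_edu, dtype=float)
        if self.pval_cog is not None:
            self.pval_cog = np.asarray(self.pval_cog, dtype=float)
        m = self.snp_id.size
        for name in ("effect_allele", "other_allele", "weight_edu", "weight_cog"):
            if getattr(self, name).shape != (m,):
                raise ValueError(f"{name} length does not match snp_id")
        if len(set(self.snp_id)) != m:
            raise ValueError("duplicate SNP ids in panel")
        for ea, oa in zip(self.effect_allele, self.other_allele):
            if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
                raise ValueError(f"invalid allele pair {ea}/{oa}")
            if ea == oa:
                raise ValueError(f"effect and other allele identical ({ea})")
        if self.ld_corr is not None:
            r = np.asarray(self.ld_corr, dtype=float)
            if r.shape != (m, m):
                raise ValueError("ld_corr shape does not match panel size")
            if not np.allclose(r, r.T, atol=1e-10):
                raise ValueError("ld_corr must be symmetric")
            if not np.allclose(np.diag(r), 1.0, atol=1e-10):
                raise ValueError("ld_corr must have unit diagonal")
            if np.any(np.abs(r) > 1 + 1e-10):
                raise ValueError("ld_corr entries must satisfy |r| <= 1")
            self.ld_corr = r

    def __len__(self) -> int:
        return int(self.snp_id.size)

    def subset(self, index) -> "SnpPanel":
        """Panel restricted to a boolean mask or integer index array."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SnpPanel(
            snp_id=self.snp_id[idx],
            effect_allele=self.effect_allele[idx],
            other_allele=self.other_allele[idx],
            weight_edu=self.weight_edu[idx],
            weight_cog=self.weight_cog[idx],
            pval_edu=None if self.pval_edu is None else self.pval_edu[idx],
            pval_cog=None if self.pval_cog is None else self.pval_cog[idx],
            ld_corr=None if self.ld_corr is None else self.ld_corr[np.ix_(idx, idx)],
            maf=None if self.maf is None else np.asarray(self.maf)[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "effect_allele": self.effect_allele,
                "other_allele": self.other_allele,
                "weight_edu": self.weight_edu,
                "weight_cog": self.weight_cog,
            }
        )
        if self.pval_edu is not None:
            df["pval_edu"] = self.pval_edu
        if self.pval_cog is not None:
            df["pval_cog"] = self.pval_cog
        return df


def _is_palindromic(ea: str, oa: str) -> bool:
    return (ea, oa) in _PALINDROMIC


def harmonise_alleles(
    panel: SnpPanel,
    cohort_alleles: pd.DataFrame,
    palindromic: str = "drop",
    max_drop_fraction: float = 0.2,
):
    """Align a weight panel to the allele coding of a target dataset.

    ``cohort_alleles`` needs columns ``snp_id``, ``effect_allele``,
    ``other_allele`` giving the coding under which dosages count the
    cohort's effect allele. Where the panel codes the opposite allele the
    weight signs are flipped (equivalent to reading the dosage as 2 - d);
    strand flips (complementary coding) are resolved via complements.
    Palindromic A/T and C/G SNPs are dropped under the default policy
    (``palindromic="drop"``) because their strand cannot be resolved
    without allele frequencies; ``"keep"`` retains them untouched.

    Returns ``(aligned_panel, flip_log)`` where the log records one action
    per panel SNP: kept / flipped / dropped_palindromic /
    dropped_incompatible / dropped_missing. Dropping more than
    ``max_drop_fraction`` of the panel raises ``ValueError``.
    """
    if palindromic not in ("drop", "keep"):
        raise ValueError("palindromic policy must be 'drop' or 'keep'")
    target = cohort_alleles.set_index("snp_id")
    actions = []
    keep_idx: list[int] = []
    flip_sign = []
    for i, sid in enumerate(panel.snp_id):
        ea, oa = panel.effect_allele[i], panel.other_allele[i]
        if sid not in target.index:
            actions.append((sid, "dropped_missing"))
            continue
        tea = str(target.at[sid, "effect_allele"]).upper()
        toa = str(target.at[sid, "other_allele"]).upper()
        if _is_palindromic(ea, oa) and palindromic == "drop":
            actions.append((sid, "dropped_palindromic"))
            continue
        cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        if (ea, oa) == (tea, toa):
            actions.append((sid, "kept"))
            keep_idx.append(i)
            flip_sign.append(1.0)
        elif (ea, oa) == (toa, tea):
            actions.append((sid, "flipped"))
            keep_idx.append(i)
            flip_sign.append(-1.0)
        elif (cea, coa) == (tea, toa):
            actions.append((sid, "kept"))  # strand flip, same orientation
            keep_idx.append(i)
            flip_sign.append(1.0)
        elif (cea, coa) == (toa, tea):
            actions.append((sid, "flipped"))
            keep_idx.append(i)
            flip_sign.append(-1.0)
        else:
            actions.append((sid, "dropped_incompatible"))
            continue
    flip_log = pd.DataFrame(actions, columns=["snp_id", "action"])
    n_dropped = int((flip_log["action"].str.startswith("dropped")).sum())
    if len(panel) and n_dropped / len(panel) > max_drop_fraction:
        raise ValueError(
            f"harmonisation dropped {n_dropped}/{len(panel)} SNPs "
            f"(> {max_drop_fraction:.0%}); check allele coding"
        )
    idx = np.asarray(keep_idx, dtype=int)
    sign = np.asarray(flip_sign, dtype=float)
    aligned = panel.subset(idx)
    aligned.weight_edu = aligned.weight_edu * sign
    aligned.weight_cog = aligned.weight_cog * sign
    # after flipping, the aligned panel carries the cohort's coding
    flipped = sign < 0
    ea = aligned.effect_allele.copy()
    aligned.effect_allele[flipped] = aligned.other_allele[flipped]
    aligned.other_allele[flipped] = ea[flipped]
    return aligned, flip_log


def compute_prs(dosages, panel: SnpPanel, which: str = "edu") -> np.ndarray:
    """Weighted allele count: score_i = sum_j w_j d_ij.

    ``dosages`` is an n x m matrix whose columns follow panel order.
    Missing dosages are rejected; the generator produces complete data
    and imputation is out of scope.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2 or d.shape[1] != len(panel):
        raise ValueError(
            f"dosage matrix has {d.shape[1] if d.ndim == 2 else '?'} columns, "
            f"panel has {len(panel)} SNPs"
        )
    if np.isnan(d).any():
        raise ValueError("missing dosages are not supported")
    if which == "edu":
        w = panel.weight_edu
    elif which == "cog":
        w = panel.weight_cog
    else:
        raise ValueError("which must be 'edu' or 'cog'")
    return d @ w


def ld_prune(panel: SnpPanel, r2_threshold: float = 0.001, rank_by: str = "min"):
    """Greedy LD pruning at a pairwise r-squared threshold.

    SNPs are visited in ascending p-value order (``rank_by`` selects the
    education p-value, the cognition p-value, or their per-SNP minimum;
    ties broken lexicographically by SNP id) and kept iff their squared
    correlation with every already-kept SNP does not exceed the threshold.
    Returns the kept SNP ids in panel order.
    """
    if panel.ld_corr is None:
        raise ValueError("panel has no LD correlation matrix")
    if rank_by == "edu":
        if panel.pval_edu is None:
            raise ValueError("panel has no education p-values")
        p = panel.pval_edu
    elif rank_by == "cog":
        if panel.pval_cog is None:
            raise ValueError("panel has no cognition p-values")
        p = panel.pval_cog
    elif rank_by == "min":
        if panel.pval_edu is None or panel.pval_cog is None:
            raise ValueError("rank_by='min' needs both p-value columns")
        p = np.minimum(panel.pval_edu, panel.pval_cog)
    else:
        raise ValueError("rank_by must be 'edu', 'cog' or 'min'")
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN; cannot rank for pruning")
    r2 = panel.ld_corr**2
    order = sorted(range(len(panel)), key=lambda i: (p[i], str(panel.snp_id[i])))
    kept: list[int] = []
    for i in order:
        if all(r2[i, j] <= r2_threshold for j in kept):
            kept.append(i)
    kept_mask = np.zeros(len(panel), dtype=bool)
    kept_mask[kept] = True
    return list(panel.snp_id[kept_mask])
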