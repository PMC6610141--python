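"""Tab-delimited input/output.

Panels travel in the GWAS-summary dialect (SNP, effect_allele,
other_allele, beta, se, pval, N — one file per exposure); cohorts as a
phenotype table plus a dosage matrix with a SNP-id header row; summary
datasets are merged from harmonised per-study TSVs on SNP id.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .scores import SnpPanel
from .simulate import Cohort
from .summary import SummaryDataset

__all__ = [
    "write_gwas_tsv",
    "read_gwas_tsv",
    "panel_from_gwas",
    "write_cohort",
    "read_cohort",
    "summary_from_gwas_tables",
]

GWAS_COLUMNS = ["SNP", "effect_allele", "other_allele", "beta", "se", "pval", "N"]


def write_gwas_tsv(panel: SnpPanel, path, which: str = "edu", n: int | None = None):
    """Write one exposure's weights as a GWAS-summary TSV."""
    if which == "edu":
        beta, pval = panel.weight_edu, panel.pval_edu
    elif which == "cog":
        beta, pval = panel.weight_cog, panel.pval_cog
    else:
        raise ValueError("which must be 'edu' or 'cog'")
    df = pd.DataFrame(
        {
            "SNP": panel.snp_id,
            "effect_allele": panel.effect_allele,
            "other_allele": panel.other_allele,
            "beta": beta,
            "se": np.nan,
            "pval": np.nan if pval is None else pval,
            "N": n,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GWAS_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS table {path} missing columns {missing}")
    return df


def panel_from_gwas(edu_path, cog_path=None) -> SnpPanel:
    """Build a weight panel from one or two GWAS-summary TSVs.

    SNPs present in only one file get weight 0 for the other exposure
    (the combined-instrument convention for multivariable analyses)."""
    edu = read_gwas_tsv(edu_path)
    if cog_path is None:
        merged = edu.rename(columns={"beta": "weight_edu", "pval": "pval_edu"})
        merged["weight_cog"] = 0.0
        merged["pval_cog"] = 1.0
    else:
        cog = read_gwas_tsv(cog_path)
        merged = edu.merge(
            cog, on=["SNP", "effect_allele", "other_allele"],
            how="outer", suffixes=("_edu", "_cog"),
        )
        merged = merged.rename(
            columns={"beta_edu": "weight_edu", "beta_cog": "weight_cog"}
        )
        merged["weight_edu"] = merged["weight_edu"].fillna(0.0)
        merged["weight_cog"] = merged["weight_cog"].fillna(0.0)
        merged["pval_edu"] = merged["pval_edu"].fillna(1.0)
        merged["pval_cog"] = merged["pval_cog"].fillna(1.0)
    return SnpPanel(
        snp_id=merged["SNP"].to_numpy(),
        effect_allele=merged["effect_allele"].to_numpy(),
        other_allele=merged["other_allele"].to_numpy(),
        weight_edu=merged["weight_edu"].to_numpy(),
        weight_cog=merged["weight_cog"].to_numpy(),
        pval_edu=merged["pval_edu"].to_numpy(),
        pval_cog=merged["pval_cog"].to_numpy(),
    )


def write_cohort(cohort: Cohort, directory, panel: SnpPanel | None = None):
    """Write a cohort as phenotypes.tsv + dosages.tsv (+ panel TSVs)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pheno = cohort.covariates.copy()
    pheno.insert(0, "edu_years", cohort.edu_years)
    pheno.insert(1, "cog_score", cohort.cog_score)
    pheno["smoke_current"] = cohort.smoke_current
    pheno["smoke_ever"] = cohort.smoke_ever
    pheno["smoke_former"] = cohort.smoke_former
    pheno["weight"] = cohort.weights
    pheno.to_csv(directory / "phenotypes.tsv", sep="\t", index=False)
    snp_ids = (
        panel.snp_id
        if panel is not None
        else [f"snp{i + 1}" for i in range(cohort.dosages.shape[1])]
    )
    pd.DataFrame(cohort.dosages, columns=list(snp_ids)).to_csv(
        directory / "dosages.tsv", sep="\t", index=False
    )
    if panel is not None:
        write_gwas_tsv(panel, directory / "panel_edu.tsv", "edu")
        write_gwas_tsv(panel, directory / "panel_cog.tsv", "cog")


def read_cohort(directory) -> Cohort:
    directory = Path(directory)
    pheno = pd.read_csv(directory / "phenotypes.tsv", sep="\t")
    dosages = pd.read_csv(directory / "dosages.tsv", sep="\t")
    cov_cols = [
        c
        for c in pheno.columns
        if c
        not in (
            "edu_years", "cog_score", "smoke_current",
            "smoke_ever", "smoke_former", "weight",
        )
    ]
    return Cohort(
        dosages=dosages.to_numpy(dtype=np.int8),
        covariates=pheno[cov_cols].reset_index(drop=True),
        edu_years=pheno["edu_years"].to_numpy(float),
        cog_score=pheno["cog_score"].to_numpy(float),
        smoke_current=pheno["smoke_current"].to_numpy(np.int8),
        smoke_ever=pheno["smoke_ever"].to_numpy(np.int8),
        smoke_former=pheno["smoke_former"].to_numpy(float),
        weights=pheno["weight"].to_numpy(float),
    )


def summary_from_gwas_tables(
    outcome: pd.DataFrame,
    exposure1: pd.DataFrame,
    exposure2: pd.DataFrame | None = None,
    scale: str = "risk_difference",
) -> SummaryDataset:
    """Merge harmonised GWAS tables on SNP id into a SummaryDataset.

    All tables must share allele coding (harmonise first); mismatched
    allele rows are dropped with a count in the exception message if all
    rows mismatch.
    """
    m = outcome.merge(exposure1, on="SNP", suffixes=("_out", "_e1"))
    aligned = (m["effect_allele_out"] == m["effect_allele_e1"]) & (
        m["other_allele_out"] == m["other_allele_e1"]
    )
    m = m[aligned]
    if exposure2 is not None:
        e2 = exposure2.rename(
            columns={c: f"{c}_e2" for c in exposure2.columns if c != "SNP"}
        )
        m = m.merge(e2, on="SNP")
        m = m[
            (m["effect_allele_out"] == m["effect_allele_e2"])
            & (m["other_allele_out"] == m["other_allele_e2"])
        ]
    if m.empty:
        raise ValueError("no SNPs shared (with consistent alleles) across tables")
    return SummaryDataset(
        snp_id=m["SNP"].to_numpy(),
        gamma=m["beta_out"].to_numpy(float),
        se_gamma=m["se_out"].to_numpy(float),
        pi1=m["beta_e1"].to_numpy(float),
        se_pi1=m["se_e1"].to_numpy(float),
        pi2=None if exposure2 is None else m["beta_e2"].to_numpy(float),
        se_pi2=None if exposure2 is None else m["se_e2"].to_numpy(float),
        scale=scale,
        harmonised=True,
    )
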