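"""Cross-referencing screen hits with Alzheimer's-risk GWAS loci.

Two steps: intersect the hit list with the genes falling in IGAP
genome-wide-significant risk loci, then filter a per-gene association
summary (lead SNP effect on standardized log CSF Abeta42, with its p-value)
through a gene-wide Bonferroni correction. The packaged fixture holds the
published eight-gene association table for the candidate genes shared
between the screen's top 5% and the IGAP loci; the association regressions
themselves (cohort-level SNP analyses) are consumed as summaries, never
fitted here.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import FixtureFormatError, InputError

ASSOCIATION_COLUMNS = [
    "chromosome", "locus", "gene", "yfp_log2fc", "yfp_log2fc_sd",
    "mcherry_log2fc", "mcherry_log2fc_sd", "snp", "beta", "p_value",
]
LOCUS_COLUMNS = ["chromosome", "locus", "gene"]


@dataclass
class BonferroniResult:
    """Outcome of a gene-wide Bonferroni filter."""

    survivors: pd.DataFrame
    threshold: float          # family_alpha / m, exact
    m: int
    family_alpha: float

    @property
    def threshold_display(self) -> float:
        """Threshold rounded to 3 decimals, as quoted in reports."""
        return round(self.threshold, 3)


def _read_packaged_csv(name: str, columns: list[str]) -> pd.DataFrame:
    with resources.as_file(resources.files("appscreen") / "data" / name) as p:
        return _read_validated_csv(p, columns)


def _read_validated_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FixtureFormatError(f"{path}: missing columns {missing}")
    return df


def load_association_fixture() -> pd.DataFrame:
    """The packaged eight-gene CSF-Abeta42 association table.

    One row per candidate gene: locus, screen fold-change summary (log2
    mean +/- SD per channel), lead variant, effect estimate on standardized
    log CSF Abeta42, and association p-value. Validated on load; a p-value
    outside (0, 1] names the offending row.
    """
    df = _read_packaged_csv("igap_csf_abeta42_associations.csv",
                            ASSOCIATION_COLUMNS)
    return validate_associations(df)


def validate_associations(df: pd.DataFrame) -> pd.DataFrame:
    for i, p in enumerate(df["p_value"]):
        if not (0 < p <= 1):
            raise FixtureFormatError(
                f"association table row {i}: p_value {p} outside (0, 1]")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise FixtureFormatError(f"duplicate genes in association table: {dup}")
    return df


def load_locus_genes() -> pd.DataFrame:
    """Packaged GWAS-locus gene list (the published candidate subset)."""
    return _read_packaged_csv("igap_locus_genes.csv", LOCUS_COLUMNS)


def read_locus_genes(path: str | Path) -> pd.DataFrame:
    return _read_validated_csv(Path(path), LOCUS_COLUMNS)


def crossref_hits(hits: pd.DataFrame, locus_genes: pd.DataFrame
                  ) -> pd.DataFrame:
    """Genes present both in the hit table and in a GWAS-locus gene list.

    Matching is by exact gene id after upper-casing; duplicate locus
    entries collapse to one row (set semantics). The result carries the
    screen scores from the hit table plus the locus annotation.
    """
    if "gene_id" not in hits.columns:
        raise InputError("hit table needs a gene_id column")
    if "gene" not in locus_genes.columns:
        raise InputError("locus gene list needs a gene column")
    h = hits.copy()
    h["_key"] = h["gene_id"].astype(str).str.upper()
    loci = locus_genes.drop_duplicates(subset="gene").copy()
    loci["_key"] = loci["gene"].astype(str).str.upper()
    loci = loci.drop_duplicates(subset="_key")
    merged = h.merge(loci.drop(columns=["gene"]), on="_key", how="inner")
    return (merged.drop(columns=["_key"])
            .sort_values("gene_id")
            .reset_index(drop=True))


def bonferroni_filter(
    records: pd.DataFrame,
    family_alpha: float = 0.05,
    m: int | None = None,
) -> BonferroniResult:
    """Gene-wide Bonferroni filter on an association summary table.

    The threshold is ``family_alpha / m`` with ``m`` defaulting to the
    number of records (candidate genes tested); a record survives iff its
    p-value is strictly below the threshold. With the default alpha and the
    eight-gene table the exact threshold is 0.00625, displayed as 0.006.
    """
    if not 0 < family_alpha < 1:
        raise InputError(f"family_alpha must be in (0, 1), got {family_alpha}")
    m = len(records) if m is None else m
    if m < 1:
        raise InputError("m must be >= 1 (no genes to test)")
    threshold = family_alpha / m
    survivors = records[records["p_value"] < threshold].reset_index(drop=True)
    return BonferroniResult(
        survivors=survivors, threshold=threshold, m=m,
        family_alpha=family_alpha)
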