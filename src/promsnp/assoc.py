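"""Allelic association of SNPs with a binary phenotype.

Inbred diploid lines each contribute two alleles to a 2x2 table
(phenotype class x allele).  The statistic is Pearson's chi-square without
continuity correction on that table (the 1-df allelic test):

    chi2 = N (ad - bc)^2 / (r1 r2 c1 c2)

with N the total allele count and r/c the margins; the p-value comes from
the upper tail of the 1-df chi-square distribution.  Multiple testing over
the tested SNP subset is controlled with the Benjamini-Hochberg step-up
adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_QUAL_DEFAULT = 400.0
FDR_LEVEL_DEFAULT = 0.1

MISSING = -1  # genotype dosage code


@dataclass
class GenotypeMatrix:
    """SNP x line genotype dosages with per-SNP metadata.

    ``genotypes`` holds alternate-allele dosages (0 = hom ref, 1 = het,
    2 = hom alt, -1 = missing), indexed by SNP id with line ids as columns.
    """

    genotypes: pd.DataFrame
    qual: pd.Series
    ref: pd.Series
    alt: pd.Series

    def __post_init__(self) -> None:
        if not self.genotypes.index.equals(self.qual.index):
            raise ValueError("genotypes and qual must share the SNP index")
        if (self.qual.dropna() < 0).any():
            raise ValueError("quality scores must be non-negative")

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, quals, refs, alts, ids = [], [], [], [], []
        n_dropped = 0
        for var in vcf:
            if not var.is_snp or len(var.ALT) != 1:
                n_dropped += 1
                continue
            # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt = var.gt_types
            dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
            rows.append(dosage)
            quals.append(var.QUAL if var.QUAL is not None else 0.0)
            refs.append(var.REF)
            alts.append(var.ALT[0])
            ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        vcf.close()
        if n_dropped:
            logger.info("from_vcf: dropped %d non-biallelic/non-SNP records", n_dropped)
        idx = pd.Index(ids, name="snp_id")
        return cls(
            genotypes=pd.DataFrame(rows, index=idx, columns=samples, dtype=int),
            qual=pd.Series(quals, index=idx, name="qual", dtype=float),
            ref=pd.Series(refs, index=idx, name="ref"),
            alt=pd.Series(alts, index=idx, name="alt"),
        )

    def subset(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.genotypes.index.intersection(pd.Index(snp_ids))
        return GenotypeMatrix(
            self.genotypes.loc[idx], self.qual.loc[idx], self.ref.loc[idx], self.alt.loc[idx]
        )


def quality_filter(gm: GenotypeMatrix, min_qual: float = MIN_QUAL_DEFAULT) -> GenotypeMatrix:
    """Retain SNPs with quality >= min_qual (strictly-below scores excluded)."""
    keep = gm.qual >= min_qual
    logger.info("quality_filter: kept %d / %d SNPs (qual >= %g)", keep.sum(), len(keep), min_qual)
    return GenotypeMatrix(
        gm.genotypes.loc[keep], gm.qual.loc[keep], gm.ref.loc[keep], gm.alt.loc[keep]
    )


def allele_table(dosages: pd.Series | np.ndarray, phenotype: pd.Series) -> np.ndarray:
    """2x2 allele-count table [[low_ref, low_alt], [high_ref, high_alt]].

    Each non-missing diploid line contributes 2 alleles: a heterozygote adds
    one to each allele cell.
    """
    d = pd.Series(np.asarray(dosages), index=phenotype.index)
    table = np.zeros((2, 2), dtype=int)
    for row, cls in enumerate(("low", "high")):
        sub = d[(phenotype == cls) & (d != MISSING)]
        table[row, 1] = int(sub.sum())
        table[row, 0] = int(2 * len(sub) - sub.sum())
    return table


def allelic_chisq(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) and its 1-df p-value.

    A table with a zero row or column margin is monomorphic or one-sided:
    chi2 is defined as 0 and p as 1.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected a non-negative 2x2 allele-count table")
    a, b = table[0]
    c, d = table[1]
    n = table.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0 or n == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), max(p, np.finfo(float).tiny)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def associate(
    gm: GenotypeMatrix,
    phenotype: pd.Series,
    snp_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP allelic chi-square test with BH adjustment over the tested set.

    ``phenotype`` maps line id -> 'low'/'high'.  SNPs with all genotypes
    missing are flagged and excluded from the number of tests.  Results are
    sorted by adjusted value, then p, then id.
    """
    vals = set(phenotype.unique())
    if not vals <= {"low", "high"}:
        raise ValueError(f"phenotype must be binary low/high, got {vals}")
    if snp_subset is not None:
        gm = gm.subset(snp_subset)
    lines = [l for l in gm.genotypes.columns if l in phenotype.index]
    if not lines:
        raise ValueError("no overlap between genotype columns and phenotype lines")
    pheno = phenotype.loc[lines]

    rows = []
    n_all_missing = 0
    for snp_id, dosages in gm.genotypes[lines].iterrows():
        if (dosages == MISSING).all():
            n_all_missing += 1
            logger.info("associate: SNP %s has no called genotypes, excluded", snp_id)
            continue
        table = allele_table(dosages, pheno)
        chi2, p = allelic_chisq(table)
        rows.append(
            {
                "snp_id": snp_id,
                "ref": gm.ref.loc[snp_id],
                "alt": gm.alt.loc[snp_id],
                "low_ref": table[0, 0], "low_alt": table[0, 1],
                "high_ref": table[1, 0], "high_alt": table[1, 1],
                "chi2": chi2,
                "p": p,
            }
        )
    result = pd.DataFrame(
        rows, columns=["snp_id", "ref", "alt", "low_ref", "low_alt",
                       "high_ref", "high_alt", "chi2", "p"],
    )
    if len(result):
        result["fdr_adjusted"] = bh_fdr(result["p"].to_numpy())
        result = result.sort_values(
            ["fdr_adjusted", "p", "snp_id"], kind="stable"
        ).reset_index(drop=True)
    else:
        result["fdr_adjusted"] = pd.Series(dtype=float)
    result.attrs["n_tests"] = len(result)
    result.attrs["n_all_missing"] = n_all_missing
    return result


def read_phenotype(path: str | Path) -> pd.Series:
    """Tab-separated line_id / phenotype(low|high) table -> Series."""
    df = pd.read_csv(str(path), sep="\t")
    if not {"line_id", "phenotype"} <= set(df.columns):
        raise ValueError("phenotype table needs line_id and phenotype columns")
    return df.set_index("line_id")["phenotype"]
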