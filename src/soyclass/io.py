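"""Reading and writing the pipeline's file formats.

Marker matrices travel either as numeric CSV (rows = genotypes, columns =
marker ids, missing cells written as ``NA``) or as plain-text VCF with
biallelic GT records.  Phenotypes are a tidy CSV keyed by genotype x
environment.  By default VCF genotypes are coded with 2 = homozygous
reference; ``ref_as_two=False`` flips to the major-allele convention.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import GenomicRelationshipMatrix, MarkerMatrix

logger = logging.getLogger(__name__)

PHENO_COLUMNS = ["genotype", "location", "year", "env", "maturity_group", "is_check", "yield"]


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy phenotype table has the required columns and types."""
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    out = pheno.copy()
    out["is_check"] = out["is_check"].astype(bool)
    if out["yield"].isna().any():
        raise ValueError("phenotype table contains missing yield values")
    return out


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path))


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(pheno).to_csv(path, index=False)


def read_marker_csv(path: str | Path) -> MarkerMatrix:
    df = pd.read_csv(path, index_col=0, na_values=["NA", ""])
    return MarkerMatrix(df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object), df.to_numpy(dtype=float))


def write_marker_csv(markers: MarkerMatrix, path: str | Path) -> None:
    markers.to_frame().to_csv(path, na_rep="NA")


def write_grm_csv(grm: GenomicRelationshipMatrix, path: str | Path) -> None:
    grm.to_frame().to_csv(path)


def read_grm_csv(path: str | Path, denom: float = 1.0) -> GenomicRelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return GenomicRelationshipMatrix(df.index.to_numpy(dtype=object), df.to_numpy(dtype=float), denom)


_GT_BY_CODE = {2.0: "0/0", 1.0: "0/1", 0.0: "1/1"}


def write_vcf(markers: MarkerMatrix, path: str | Path) -> None:
    """Write biallelic GT records; code 2 is emitted as homozygous reference."""
    meta = markers.marker_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(g) for g in markers.genotype_ids)
            + "\n"
        )
        for j, mid in enumerate(markers.marker_ids):
            if meta is not None and {"chrom", "pos"} <= set(meta.columns):
                chrom, pos = meta.iloc[j]["chrom"], meta.iloc[j]["pos"]
            else:
                chrom, pos = 1, j + 1
            gts = [
                _GT_BY_CODE.get(c, "./.") if not np.isnan(c) else "./."
                for c in markers.codes[:, j]
            ]
            fh.write(f"{chrom}\t{pos}\t{mid}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path: str | Path, ref_as_two: bool = True) -> MarkerMatrix:
    """Read biallelic GT records into a genotypes x markers code matrix.

    With ``ref_as_two`` (default) the homozygous reference is coded 2; set it
    to ``False`` to orient codes to the major allele per marker instead.
    Requires ``cyvcf2``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    marker_ids, rows, chroms, poss = [], [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning("skipping non-biallelic site %s", variant.ID)
            continue
        alt_counts = np.array(
            [a + b if a >= 0 and b >= 0 else np.nan for a, b, *_ in variant.genotypes],
            dtype=float,
        )
        rows.append(2.0 - alt_counts)
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
    codes = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    if not ref_as_two and codes.size:
        means = np.nanmean(codes, axis=0)
        flip = means < 1.0  # reference allele is the minor allele at this marker
        codes[:, flip] = 2.0 - codes[:, flip]
    meta = pd.DataFrame({"chrom": chroms, "pos": poss}, index=marker_ids)
    return MarkerMatrix(samples, np.asarray(marker_ids, dtype=object), codes, marker_meta=meta)


def aggregate_to_blues(pheno: pd.DataFrame) -> pd.DataFrame:
    """Reduce plot-level records to one record per genotype x environment.

    The per-environment adjusted mean of a genotype's replicates is used as
    its BLUE-level yield response.
    """
    pheno = validate_phenotypes(pheno)
    keys = ["genotype", "location", "year", "env", "maturity_group", "is_check"]
    return pheno.groupby(keys, as_index=False, sort=False)["yield"].mean()
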