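"""Readers and writers for the pipeline's tab-separated formats.

All tables are plain TSV.  The variant table carries ``variant_id, chrom,
pos, gene_id, ref, alt, damage_prob``; the dosage matrix is individuals x
variants with the individual id in the first column; the phenotype table is
PLINK-style, one row per individual with cases coded 1 and controls 0.
Genotypes may also come from a VCF, using the DS FORMAT field when present
and the GT allele count otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_variant_table",
    "read_dosage_tsv",
    "read_vcf_dosages",
    "read_genotypes",
    "read_phenotypes",
    "read_gene_coords",
]

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "gene_id", "damage_prob"]


def read_variant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    bad = df[(df.damage_prob < 0) | (df.damage_prob > 1)]
    if len(bad):
        raise ValueError(
            f"damage_prob outside [0, 1] for variants: {list(bad.variant_id)}"
        )
    return df


def read_dosage_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "individual_id"
    return df


def read_vcf_dosages(path) -> pd.DataFrame:
    """Individuals x variants dosages from a VCF (DS if present, else GT)."""
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(path))
    samples = vcf.samples
    cols, data = [], []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            vals = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            gts = rec.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
            vals = np.where(
                gts == 3, 2.0, np.where(gts == 2, np.nan, gts.astype(float))
            )
        cols.append(vid)
        data.append(vals)
    out = pd.DataFrame(
        np.column_stack(data) if data else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="individual_id"),
        columns=cols,
    )
    return out


def read_genotypes(path) -> pd.DataFrame:
    """Dispatch on extension: .vcf/.vcf.gz via cyvcf2, otherwise dosage TSV."""
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return read_vcf_dosages(p)
    return read_dosage_tsv(p)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "individual_id"
    return df


def read_gene_coords(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("gene_id", "chrom", "cds_start", "cds_end") if c not in df.columns]
    if missing:
        raise ValueError(f"gene coordinate table missing columns: {missing}")
    return df
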