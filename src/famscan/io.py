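"""Readers and writers for the pipeline's file formats.

Genotypes arrive as VCF (GT or DS fields, read through cyvcf2) or as a
variants-by-individuals dosage TSV.  Per-locus IBD sharing arrives as
pairwise lists (chrom, pos, id1, id2, pi_hat); pairs not listed default to
twice the pedigree kinship within a family and zero across families, the
expected sharing under no linkage information.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .linkage import IBDMatrix
from .pedigree import KinshipMatrix
from .qc import GenotypeMatrix

__all__ = [
    "read_phenotypes",
    "read_dosage_tsv",
    "read_vcf",
    "read_genotypes",
    "read_ibd_file",
    "read_ibd_dir",
]

_META_COLS = ["chrom", "pos", "ref", "alt"]


def read_phenotypes(path, missing_token: str = "") -> pd.DataFrame:
    """Long-format phenotype CSV with header; needs columns id, visit,
    trait, time; extra columns are covariates."""
    df = pd.read_csv(path, na_values=[missing_token], keep_default_na=True)
    required = {"id", "visit", "trait", "time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["id"] = df["id"].astype(str)
    return df


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Variants-by-individuals dosage TSV.

    First column variant_id, then chrom, pos, ref, alt metadata, then one
    column per individual with dosages in [0, 2]; empty cells are missing.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "variant_id" not in df.columns:
        raise ValueError(f"{path}: missing variant_id column")
    meta_present = [c for c in _META_COLS if c in df.columns]
    sample_cols = [c for c in df.columns if c != "variant_id" and c not in _META_COLS]
    variants = df[["variant_id"] + meta_present].copy()
    for c in _META_COLS:
        if c not in variants.columns:
            variants[c] = "." if c in ("ref", "alt") else 0
    dosages = df[sample_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(ids=[str(c) for c in sample_cols], variants=variants, dosages=dosages)


def read_vcf(path, prefer_dosage: bool = True) -> GenotypeMatrix:
    """Read genotypes from a VCF; uses the DS FORMAT field when present,
    otherwise additive counts from GT.  Missing calls become NaN."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = [str(s) for s in vcf.samples]
    rows, dosage_cols = [], []
    for var in vcf:
        rows.append(
            {
                "variant_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
        ds = None
        if prefer_dosage:
            try:
                ds = var.format("DS")
            except KeyError:
                ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
            col = np.where(gts == 3, 2.0, gts)
            col[gts == 2] = np.nan
        rows[-1]["_dosage"] = col
        dosage_cols.append(col)
    if not rows:
        raise ValueError(f"{path}: no variants")
    variants = pd.DataFrame(rows).drop(columns="_dosage")
    dosages = np.column_stack(dosage_cols)
    return GenotypeMatrix(ids=ids, variants=variants, dosages=dosages)


def read_genotypes(path) -> GenotypeMatrix:
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return read_vcf(path)
    return read_dosage_tsv(path)


def read_ibd_file(path, kinship: KinshipMatrix) -> IBDMatrix:
    """One per-locus pairwise IBD list; unlisted pairs default to 2*phi."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id1": str, "id2": str})
    required = {"chrom", "pos", "id1", "id2", "pi_hat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty IBD file")
    chrom = str(df["chrom"].iloc[0])
    pos = int(df["pos"].iloc[0])
    values = kinship.kin2.copy()
    np.fill_diagonal(values, 1.0)  # default self-sharing for non-inbred subjects
    index = {iid: k for k, iid in enumerate(kinship.ids)}
    for id1, id2, pi in zip(df["id1"], df["id2"], df["pi_hat"]):
        if id1 not in index or id2 not in index:
            continue  # pairs outside the analysis set are ignored
        i, j = index[id1], index[id2]
        values[i, j] = values[j, i] = float(pi)
    return IBDMatrix(chrom=chrom, pos=pos, ids=list(kinship.ids), values=values)


_IBD_NAME = re.compile(r"chr(?P<chrom>[^_]+)_(?P<pos>\d+)\.ibd\.tsv$")


def read_ibd_dir(path, kinship: KinshipMatrix) -> list[IBDMatrix]:
    """All chr<k>_<pos>.ibd.tsv files in a directory, ordered by locus."""
    files = sorted(Path(path).glob("chr*_*.ibd.tsv"))
    if not files:
        raise FileNotFoundError(f"no IBD files under {path}")
    mats = [read_ibd_file(f, kinship) for f in files]
    mats.sort(key=lambda m: (m.chrom, m.pos))
    return mats
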