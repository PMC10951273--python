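"""Readers and writers for the tabular interchange formats.

CSV/TSV with explicit headers are canonical; VCF is supported on ingestion
only (biallelic sites, GT field mapped to dosage).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .pedigree import Pedigree
from .relmat import GenotypeMatrix, RelationshipMatrix

log = logging.getLogger("ssbreed")

__all__ = [
    "read_pedigree", "write_pedigree",
    "read_genotypes", "write_genotypes",
    "read_map", "write_map",
    "read_phenotypes", "write_phenotypes",
    "read_relmatrix", "write_relmatrix",
    "read_gebvs", "write_gebvs",
]


def read_pedigree(path) -> Pedigree:
    """Pedigree CSV (id,sire,dam,birth_year; 0/empty = unknown parent).
    Rows may appear in any order; a topological sort restores parent-first
    order, and cycles or duplicate ids raise a validation error."""
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    return Pedigree.from_frame(df)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    """Genotype TSV: rows individuals, columns markers, NA for missing."""
    df = geno.to_frame()
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_genotypes(path, fmt: str = "tsv") -> GenotypeMatrix:
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        vals = df.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and not np.allclose(finite, np.round(finite)):
            raise ValueError("non-integer dosage in genotype TSV")
        return GenotypeMatrix([str(i) for i in df.index], [str(c) for c in df.columns], vals)
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path) -> GenotypeMatrix:
    """Biallelic VCF to dosages: 0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> NA.
    Multiallelic records are skipped with a logged count."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    markers, rows = [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        gts = rec.gt_types.astype(float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.where(gts == 3, 2.0, gts)
        dos[gts == 2] = np.nan
        markers.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        rows.append(dos)
    if n_skipped:
        log.warning("skipped %d multiallelic VCF records", n_skipped)
    dosages = np.array(rows).T if rows else np.zeros((len(ids), 0))
    return GenotypeMatrix(ids, markers, dosages)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    return GeneticMap.from_frame(pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str}))


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"hybrid": str, "block": str, "year": str})
    required = {"hybrid", "block", "year", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype CSV must have columns {sorted(required)}")
    return df


def write_relmatrix(mat: RelationshipMatrix, path, sidecar: bool = True) -> None:
    """Id-indexed TSV plus an optional .npz sidecar for fast reload."""
    path = Path(path)
    df = mat.to_frame()
    df.index.name = "id"
    df.to_csv(path, sep="\t")
    if sidecar:
        np.savez_compressed(path.with_suffix(".npz"), kind=mat.kind,
                            ids=np.array(mat.ids), values=mat.values)


def read_relmatrix(path, kind: str | None = None) -> RelationshipMatrix:
    path = Path(path)
    npz = path.with_suffix(".npz")
    if npz.exists():
        z = np.load(npz, allow_pickle=False)
        return RelationshipMatrix(str(z["kind"]), [str(i) for i in z["ids"]], z["values"])
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(kind or "A", [str(i) for i in df.index], df.to_numpy(dtype=float))


def write_gebvs(tbl: pd.DataFrame, path) -> None:
    tbl.to_csv(path, index=True, index_label="id")


def read_gebvs(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id", dtype={"id": str})
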