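"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as uncompressed VCF (autosomal biallelic records, GT
field, REF = major allele so ALT counts equal minor-allele counts in the
files this package writes); annotation and ranked-gene tables as TSV;
phenotypes as CSV.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    GenotypeMatrix,
    RankedGeneSets,
    validate_annotation,
    validate_phenotypes,
)

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(genotypes: GenotypeMatrix, annotation: pd.DataFrame, path) -> Path:
    """Write genotypes as a VCFv4.2 text file, sorted by (chrom, pos).

    REF is the major allele and ALT the minor allele, so the written GT
    alt-allele counts equal the in-memory minor-allele counts.
    """
    annot = validate_annotation(annotation)
    path = Path(path)
    order = sorted(
        genotypes.variant_ids,
        key=lambda v: (int(annot.at[v, "chrom"]), int(annot.at[v, "pos"])),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=enrichprs\n")
        for c in sorted({int(annot.at[v, "chrom"]) for v in order}):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in genotypes.individual_ids)
            + "\n"
        )
        for v in order:
            row = annot.loc[v]
            calls = genotypes.calls_at(v)
            gts = "\t".join(_GT_CODE[int(c)] for c in calls)
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{v}\t{row['major_allele']}\t"
                f"{row['minor_allele']}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return path


def read_genotypes(vcf_path, annotation: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a VCF into a minor-allele-count GenotypeMatrix.

    ALT-allele counts are flipped to minor-allele counts wherever the
    annotation declares the minor allele to be the REF allele; without an
    annotation the ALT allele is assumed minor (true for files written by
    :func:`write_vcf`).
    """
    from cyvcf2 import VCF

    annot = validate_annotation(annotation) if annotation is not None else None
    vcf = VCF(str(vcf_path), gts012=True)
    individuals = list(vcf.samples)
    variant_ids, columns = [], []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        counts = np.asarray(rec.gt_types, dtype=np.int8)  # 0/1/2, 3=missing
        counts[counts == 3] = MISSING
        if annot is not None and vid in annot.index:
            if annot.at[vid, "minor_allele"] == rec.REF:
                ok = counts != MISSING
                counts[ok] = 2 - counts[ok]
        variant_ids.append(vid)
        columns.append(counts)
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(individuals, variant_ids, calls)


def write_annotation(annotation: pd.DataFrame, path) -> Path:
    path = Path(path)
    annotation.to_csv(path, sep="\t", index=False)
    return path


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    return validate_annotation(df).reset_index(drop=True)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> Path:
    path = Path(path)
    phenotypes.to_csv(path, index=False)
    return path


def read_phenotypes(path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path))


def write_ranked_genes(ranked: RankedGeneSets, path) -> Path:
    rows = [{"gene": g, "role": "training", "rank": ""} for g in ranked.training_genes]
    rows += [
        {"gene": g, "role": "candidate", "rank": r}
        for r, g in enumerate(ranked.candidate_genes, start=1)
    ]
    rows += [{"gene": g, "role": "control", "rank": ""} for g in ranked.control_genes]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_ranked_genes(path) -> RankedGeneSets:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "role": str})
    cand = df[df["role"] == "candidate"].copy()
    cand["rank"] = cand["rank"].astype(int)
    cand = cand.sort_values("rank")
    return RankedGeneSets(
        training_genes=tuple(df.loc[df["role"] == "training", "gene"]),
        candidate_genes=tuple(cand["gene"]),
        control_genes=tuple(df.loc[df["role"] == "control", "gene"]),
    )
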