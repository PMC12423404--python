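"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF 4.2 with a ``DS`` (dosage) FORMAT field, read back
through cyvcf2; phenotypes and summary statistics are tab-delimited tables;
known-locus interval lists use BED (0-based half-open on disk, converted to
1-based inclusive in memory); gene annotation is a TSV of
(chrom, start, end, strand, symbol, biotype).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, VariantRecord

__all__ = [
    "write_vcf", "read_vcf_dosages",
    "write_phenotypes", "read_phenotypes",
    "read_truth", "read_bed", "read_gene_table",
    "write_summary_stats", "read_summary_stats",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">
##INFO=<ID=IS,Number=1,Type=Float,Description="Imputation info score">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Genotype dosage">
"""


def write_vcf(genos: GenotypeMatrix, path: str | Path) -> Path:
    """Write dosages as an uncompressed VCF with DS format (4 decimals)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genos.sample_ids) + "\n")
        af = genos.allele_freq()
        for j, v in enumerate(genos.variants):
            col = genos.dosages[:, j]
            ds = np.where(np.isnan(col), ".", np.char.mod("%.4f", col))
            info = f"AF={af[j]:.6g};IS={v.info:.6g}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t{info}\tDS\t"
                + "\t".join(ds) + "\n"
            )
    return path


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Read a VCF with a DS FORMAT field into a :class:`GenotypeMatrix`.

    Missing dosages ('.') become NaN; per-variant MAF and call rate are
    recomputed from the data, the info score is taken from the ``IS`` INFO
    tag when present (1.0 otherwise).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    cols: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise ValueError(f"variant {var.ID} has no DS field")
        col = np.asarray(ds, dtype=float).reshape(-1)
        col[(col < 0) | (col > 2) | ~np.isfinite(col)] = np.nan
        cols.append(col)
        info_score = var.INFO.get("IS")
        alt = ",".join(var.ALT) if var.ALT else ""
        variants.append(VariantRecord(
            chrom=str(var.CHROM), pos=int(var.POS), id=str(var.ID),
            ref=str(var.REF), alt=alt,
            info=float(info_score) if info_score is not None else 1.0,
        ))
    vcf.close()
    if not cols:
        raise ValueError(f"no variants in {path}")
    genos = GenotypeMatrix(dosages=np.column_stack(cols), variants=variants,
                           sample_ids=sample_ids)
    af = genos.allele_freq()
    cr = genos.call_rate()
    for j, v in enumerate(genos.variants):
        v.maf = float(min(af[j], 1.0 - af[j])) if np.isfinite(af[j]) else np.nan
        v.call_rate = float(cr[j])
    return genos


_CATEGORICAL_PHENO_COLS = (
    "smoking", "alcohol", "diet_oily_fish", "diet_fruit", "diet_vegetable",
    "diet_processed_meat", "diet_red_meat", "rs429358", "rs7412",
)


def write_phenotypes(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in _CATEGORICAL_PHENO_COLS:
        if col in table.columns:
            table[col] = table[col].astype(object)
    return table


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals, converting 0-based half-open to 1-based inclusive."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            out.append((chrom, start + 1, end))
    return out


def read_gene_table(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t",
                        dtype={"chrom": str, "symbol": str, "biotype": str})
    required = {"chrom", "start", "end", "symbol", "biotype"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    return genes


def write_summary_stats(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
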