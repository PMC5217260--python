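"""Readers and writers for the pipeline's on-disk formats.

Matrices travel as TSV with probes (or control probes) as rows and a
header row of sample ids; sample/probe metadata as plain TSV tables;
genotypes as VCF v4.2 with GT fields from which allele-count dosages are
recovered. TSV floats are written with Python's shortest round-trip
representation, so write→read is lossless.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GenotypeData:
    """Allele-count dosages plus per-SNP metadata.

    ``dosage`` is samples x SNPs with values in [0, 2] (hard calls here,
    fractional dosages are accepted); ``snps`` carries snp_id, chrom,
    pos (1-based, VCF convention), ref, alt and maf columns.
    """

    dosage: np.ndarray
    sample_ids: list[str]
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        self.snps = self.snps.reset_index(drop=True)
        if self.dosage.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError("dosage shape does not match sample/SNP counts")
        if self.dosage.size and (self.dosage.min() < 0 or self.dosage.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if (self.snps["pos"] <= 0).any():
            raise ValueError("VCF positions are 1-based and positive")
        maf = self.snps["maf"].to_numpy(float)
        if ((maf <= 0) | (maf > 0.5)).any():
            raise ValueError("MAF must lie in (0, 0.5]")

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp_id"].tolist()

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=self.sample_ids, columns=self.snps["snp_id"]
        )


def write_matrix_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "id")


def read_matrix_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(geno: GenotypeData, path: str) -> None:
    """Emit genotypes as a minimal, standards-conforming VCF v4.2."""
    snps = geno.snps.sort_values(["chrom", "pos"], kind="stable")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=methylong\n")
        for chrom in pd.unique(snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            '##INFO=<ID=MAF,Number=1,Type=Float,Description='
            '"Alternate (minor) allele frequency">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        dosage = np.rint(geno.dosage).astype(int)
        for j, row in zip(snps.index, snps.itertuples(index=False)):
            col = dosage[:, geno.snps.index.get_loc(j)]
            gts = "\t".join(gt_map[int(g)] for g in col)
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\tMAF={row.maf:.6g}\tGT\t{gts}\n"
            )


def read_vcf(path: str) -> GenotypeData:
    """Read a VCF back into dosages (alternate-allele counts from GT)."""
    from cyvcf2 import VCF  # deferred: htslib import is slow

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    rows = []
    dosages = []
    for var in vcf:
        rows.append(
            {
                "snp_id": var.ID,
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "maf": float(var.INFO.get("MAF")),
            }
        )
        gts = var.genotypes  # [allele0, allele1, phased] per sample
        dosages.append([g[0] + g[1] for g in gts])
    vcf.close()
    snps = pd.DataFrame(rows)
    dosage = np.array(dosages, dtype=np.int8).T if dosages else np.zeros((len(sample_ids), 0), np.int8)
    return GenotypeData(dosage=dosage, sample_ids=sample_ids, snps=snps)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
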