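"""File exchange: VCF v4.2 genotypes, sample/catalog/frequency TSVs.

Genotypes are written as uncompressed biallelic VCF (chromosome "1", 1-based
positions, unphased GT) and read back through cyvcf2 into ALT-dosage matrices.
Tables are plain TSV with a header, via pandas, with deterministic float
formatting so identical inputs produce identical bytes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .aims import FrequencyTable
from .simulate import Cohort

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_samples_tsv",
    "read_samples_tsv",
    "write_frequency_tsv",
    "read_frequency_tsv",
    "write_catalog_tsv",
    "read_catalog_tsv",
    "write_summary_tsv",
    "read_summary_tsv",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path, genotypes, snp_ids, sample_ids, ref=None, alt=None) -> None:
    """Write an (n_individuals, n_snps) dosage matrix as VCF v4.2."""
    g = np.asarray(genotypes)
    snp_ids = np.asarray(snp_ids, dtype=str)
    sample_ids = np.asarray(sample_ids, dtype=str)
    m = snp_ids.size
    if ref is None:
        ref = np.array(["A"] * m)
    if alt is None:
        alt = np.array(["G"] * m)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for j in range(m):
            calls = "\t".join(
                _GT[int(d)] if not np.isnan(float(d)) else "./." for d in g[:, j]
            )
            fh.write(f"1\t{j + 1}\t{snp_ids[j]}\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path):
    """Read a biallelic VCF into (dosages, snp_ids, sample_ids, ref, alt).

    Dosages count ALT alleles; missing genotypes become NaN.
    """
    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=str)
    rows, ids, refs, alts = [], [], [], []
    for var in vcf:
        gts = np.asarray(var.genotypes, dtype=object)
        dose = np.empty(len(samples))
        for i, gt in enumerate(gts):
            a = [x for x in gt[:-1]]  # last entry is the phase flag
            dose[i] = np.nan if any(x < 0 for x in a) else float(sum(a))
        rows.append(dose)
        ids.append(var.ID)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else "N")
    vcf.close()
    g = np.array(rows).T if rows else np.empty((len(samples), 0))
    return g, np.asarray(ids, dtype=str), samples, np.asarray(refs), np.asarray(alts)


def write_samples_tsv(path, cohort: Cohort) -> None:
    """Sample table: status, covariates, strata labels and true ancestry."""
    if cohort.phenotypes is None:
        raise ValueError("cohort has no phenotypes; run simulate_outcome first")
    df = cohort.phenotypes.copy()
    for i, pop in enumerate(cohort.pop_names):
        df[f"true_q_{pop}"] = cohort.true_q[:, i]
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_samples_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_frequency_tsv(path, table: FrequencyTable) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_frequency_tsv(path) -> FrequencyTable:
    return FrequencyTable.from_frame(pd.read_csv(path, sep="\t"))


def write_catalog_tsv(path, catalog: pd.DataFrame) -> None:
    catalog.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_catalog_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_summary_tsv(path, stats: pd.DataFrame) -> None:
    """GWAS-style summary statistics TSV (exposure or outcome scan)."""
    stats.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_summary_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
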