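"""Readers and writers for reference genotype input.

Two genotype dialects are supported: standard VCF (biallelic autosomal
SNP records; diploid genotypes become alternative-allele dosages) and a
tab-separated dosage matrix with a SNP metadata sidecar.  The dosage
matrix has one row per SNP and one column per individual (header row of
sample ids, values 0/1/2 or NA); the sidecar carries chrom, pos, ref,
alt aligned row-for-row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import AUTOSOMES


def read_genotypes_vcf(path):
    """Read biallelic autosomal SNPs from a VCF.

    Returns ``(genotypes, snps, sample_ids)`` with genotypes an
    (n_individuals, n_snps) float array of dosages (NaN = missing).
    Non-autosomal, multi-allelic and non-SNP records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = np.asarray(vcf.samples)
    rows = []
    dosages = []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        chrom_str = v.CHROM.replace("chr", "")
        if not chrom_str.isdigit() or int(chrom_str) not in AUTOSOMES:
            continue
        # with gts012: 0/1/2 = dosage, 3 = unknown
        g = v.gt_types.astype(float)
        g[g == 3] = np.nan
        rows.append((int(chrom_str), v.POS, v.REF, v.ALT[0]))
        dosages.append(g)
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    G = np.array(dosages, dtype=float).T if dosages else np.empty((len(sample_ids), 0))
    return G, snps, sample_ids


def read_dosage_matrix(dosage_path, snps_path):
    """Read a dosage matrix and its SNP metadata sidecar."""
    snps = pd.read_csv(snps_path, sep="\t")
    dos = pd.read_csv(dosage_path, sep="\t")
    if len(dos) != len(snps):
        raise ValueError("dosage matrix and SNP sidecar have different row counts")
    sample_ids = np.asarray(dos.columns)
    G = dos.to_numpy(dtype=float).T
    bad = ~(np.isnan(G) | np.isin(G, (0.0, 1.0, 2.0)))
    if bad.any():
        raise ValueError("dosage matrix entries must be 0, 1, 2 or NA")
    return G, snps, sample_ids


def write_dosage_matrix(G, snps: pd.DataFrame, sample_ids, dosage_path, snps_path):
    """Write the dosage-matrix dialect read by :func:`read_dosage_matrix`."""
    snps[["chrom", "pos", "ref", "alt"]].to_csv(snps_path, sep="\t", index=False)
    pd.DataFrame(np.asarray(G).T, columns=list(sample_ids)).to_csv(
        dosage_path, sep="\t", index=False, na_rep="NA")


def read_outgroup_freqs(path) -> pd.DataFrame:
    """Read per-SNP outgroup alternative-allele frequencies (chrom, pos, alt_freq)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos", "alt_freq"):
        if col not in df.columns:
            raise ValueError(f"outgroup frequency table missing column: {col}")
    return df
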