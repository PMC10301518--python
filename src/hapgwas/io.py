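"""Readers and writers for the pipeline's file formats.

Genotypes come in as VCF v4.2 (via cyvcf2) or PLINK bed/bim/fam; under the
inbred contract heterozygous calls become missing (with a logged count) and
multiallelic records are skipped.  Coordinates are 1-based in VCF/GFF3 at
the boundary and 0-based internally.  Tables are tab- or comma-separated
UTF-8 with '.' or empty for missing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import HapMatrix
from .panel import GenotypePanel
from .traits import OBS_COLUMNS

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# genotypes

def read_vcf(path: str | Path) -> GenotypePanel:
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    lines = np.asarray(vcf.samples, dtype=object)
    chroms, poss, ids, rows = [], [], [], []
    n_multi = n_het = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(v.gt_types, dtype=float)   # 0 hom-ref,1 het,2 missing,3 hom-alt
        dose = np.full(gt.shape, np.nan)
        dose[gt == 0] = 0.0
        dose[gt == 3] = 2.0
        n_het += int(np.sum(gt == 1))
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        rows.append(dose)
    if n_multi:
        log.info("skipped %d multiallelic records", n_multi)
    if n_het:
        log.info("set %d heterozygous calls missing (inbred contract)", n_het)
    return GenotypePanel(
        dosages=np.asarray(rows).T if rows else np.empty((len(lines), 0)),
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        snp_ids=np.asarray(ids, dtype=object),
        line_ids=lines,
    )


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Minimal VCF v4.2 with GT-only genotypes (0/0, 1/1 or ./.)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(panel.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, panel.line_ids)) + "\n")
        for j in range(panel.n_snps):
            col = panel.dosages[:, j]
            gts = np.where(np.isnan(col), "./.",
                           np.where(col > 0, "1/1", "0/0"))
            fh.write(f"{panel.chrom[j]}\t{panel.pos[j] + 1}\t{panel.snp_ids[j]}"
                     f"\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_plink(prefix: str | Path) -> GenotypePanel:
    """PLINK bed/bim/fam triple (SNP-major .bed, 2-bit codes)."""
    prefix = str(prefix)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"])
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"])
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[0] != 0x6C or raw[1] != 0x1B or raw[2] != 0x01:
        raise ValueError("not a SNP-major PLINK .bed file")
    bpf = (n + 3) // 4  # bytes per SNP
    body = raw[3:].reshape(m, bpf)
    codes = np.zeros((m, bpf * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body >> (2 * shift)) & 0b11
    codes = codes[:, :n]
    # 00 -> hom a1 (2 ALT copies under a1=ALT), 01 -> missing, 10 -> het, 11 -> hom a2
    dose = np.full(codes.shape, np.nan)
    dose[codes == 0b00] = 2.0
    dose[codes == 0b11] = 0.0
    n_het = int(np.sum(codes == 0b10))
    if n_het:
        log.info("set %d heterozygous calls missing (inbred contract)", n_het)
    order = np.lexsort((bim["pos"].to_numpy(), bim["chrom"].astype(str)))
    return GenotypePanel(
        dosages=dose.T[:, order],
        chrom=bim["chrom"].astype(str).to_numpy(dtype=object)[order],
        pos=bim["pos"].to_numpy(dtype=np.int64)[order] - 1,
        snp_ids=bim["snp"].to_numpy(dtype=object)[order],
        line_ids=fam["iid"].to_numpy(dtype=object),
    )


def read_genotypes(path: str | Path) -> GenotypePanel:
    """Dispatch on extension: .vcf[.gz] via cyvcf2, else a PLINK prefix."""
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz")):
        return read_vcf(p)
    return read_plink(p.removesuffix(".bed"))


# --------------------------------------------------------------------------
# annotations and tables

def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene features from a GFF3 file: gene_id, chrom, start, end (0-based)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("gene_id") or f"{f[0]}:{f[3]}"
            rows.append({"gene_id": gid, "chrom": f[0],
                         "start": int(f[3]) - 1, "end": int(f[4])})
    if not rows:
        raise ValueError(f"no gene features in {path}")
    return pd.DataFrame(rows)


def read_go_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "go_id"])
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    obs = pd.read_csv(path)
    missing = set(OBS_COLUMNS) - set(obs.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing columns: {sorted(missing)}")
    return obs


def read_prior_qtl(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "start", "end"}.issubset(df.columns):
        raise ValueError("prior QTL table needs chrom, start, end columns")
    return df


# --------------------------------------------------------------------------
# module outputs

def write_blocks_bed(blocks, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_snps\tn_hapalleles\n")
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start_bp}\t{b.end_bp}\t{b.n_snps}\t"
                     f"{len(b.hapalleles)}\n")


def write_hap_matrix(hap: HapMatrix, path: str | Path) -> None:
    """Hap-matrix TSV: first columns metadata, then one column per line."""
    meta = hap.column_table()
    dose = pd.DataFrame(hap.dosages.T, columns=hap.line_ids)
    pd.concat([meta, dose], axis=1).to_csv(path, sep="\t", index=False,
                                           na_rep=".")


def read_hap_matrix_dosages(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path, sep="\t", na_values=".")
    meta_cols = ["hapallele", "block", "chrom", "midpoint_bp", "allele",
                 "frequency"]
    meta = df[meta_cols]
    dose = df.drop(columns=meta_cols).to_numpy(dtype=float).T
    return meta, dose
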