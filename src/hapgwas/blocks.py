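"""LD-based haplotype blocks and the hapallele pseudo-marker matrix.

Blocks are called per chromosome with the confidence-interval method of
Gabriel et al.: a pair is in *strong LD* when the 90% CI of |D'| has lower
bound >= 0.70 and upper bound >= 0.98, and shows *strong recombination* when
the upper bound is < 0.90.  A candidate interval must have its outermost
pair in strong LD, span at most 1 MB, and at least 95% of its informative
pairs in strong LD.  Candidates are accepted greedily by decreasing bp span
(leftmost wins ties), discarding overlaps, so LD that extends beyond the
span cap surfaces as multiple blocks.

Within each accepted block, the distinct SNP-allele strings carried by lines
with complete calls are the *hapalleles*; each becomes an additive 0/1/2
pseudo-marker column positioned at the block midpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .ld import pairwise_ld
from .panel import GenotypePanel

log = logging.getLogger(__name__)


@dataclass
class HapBlock:
    chrom: str
    start_bp: int
    end_bp: int
    snp_indices: np.ndarray
    hapalleles: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        self.snp_indices = np.asarray(self.snp_indices, dtype=int)
        if len(self.snp_indices) < 2:
            raise ValueError("a haplotype block needs at least 2 SNPs")
        if self.end_bp - self.start_bp > 1_000_000:
            raise ValueError("block span exceeds 1 MB")

    @property
    def midpoint_bp(self) -> float:
        return (self.start_bp + self.end_bp) / 2.0

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class HapMatrix:
    """Hapallele dosages (lines x pseudo-markers) with per-column block metadata."""

    dosages: np.ndarray
    block_index: np.ndarray     # column -> index into .blocks
    allele: np.ndarray          # column -> SNP-allele string
    frequency: np.ndarray       # column -> carrier frequency among complete lines
    chrom: np.ndarray
    midpoint_bp: np.ndarray
    blocks: list[HapBlock]
    line_ids: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.dosages.shape[1]

    def column_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "hapallele": [f"blk{b}_{a}" for b, a in zip(self.block_index, self.allele)],
            "block": self.block_index,
            "chrom": self.chrom,
            "midpoint_bp": self.midpoint_bp,
            "allele": self.allele,
            "frequency": self.frequency,
        })


def _classify_pairs(X, pos, lo_strong, hi_strong, hi_recomb):
    """Pair LD classes within the 1 MB window: +1 strong LD, -1 strong
    recombination, 0 uninformative, computed lazily into a dict."""
    cls = {}
    n = X.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            if pos[j] - pos[i] > 1_000_000:
                break
            s = pairwise_ld(X[:, i], X[:, j])
            if s is None:
                cls[(i, j)] = 0
            elif s.d_prime_ci_low >= lo_strong and s.d_prime_ci_high >= hi_strong:
                cls[(i, j)] = 1
            elif s.d_prime_ci_high < hi_recomb:
                cls[(i, j)] = -1
            else:
                cls[(i, j)] = 0
    return cls


def detect_blocks(panel: GenotypePanel,
                  max_span_bp: int = 1_000_000,
                  ci_low_strong: float = 0.70,
                  ci_high_strong: float = 0.98,
                  ci_high_recomb: float = 0.90,
                  informative_fraction: float = 0.95) -> list[HapBlock]:
    """Gabriel-style block detection over a genotype panel.

    Returns blocks sorted by (chromosome, start).  A chromosome without any
    qualifying interval contributes no blocks.
    """
    out: list[HapBlock] = []
    for c in pd.unique(panel.chrom):
        idx = np.where(panel.chrom == c)[0]
        X = panel.dosages[:, idx]
        pos = panel.pos[idx]
        cls = _classify_pairs(X, pos, ci_low_strong, ci_high_strong, ci_high_recomb)
        n = len(idx)
        candidates = []
        for i in range(n):
            for j in range(i + 1, n):
                if pos[j] - pos[i] > max_span_bp:
                    break
                if cls.get((i, j), 0) != 1:
                    continue
                strong = informative = 0
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        k = cls.get((a, b), 0)
                        if k == 1:
                            strong += 1
                            informative += 1
                        elif k == -1:
                            informative += 1
                if informative > 0 and strong / informative >= informative_fraction:
                    candidates.append((pos[j] - pos[i], pos[i], i, j))
        candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
        used = np.zeros(n, dtype=bool)
        kept = []
        for span, start, i, j in candidates:
            if used[i:j + 1].any():
                continue
            used[i:j + 1] = True
            kept.append((i, j))
        for i, j in sorted(kept):
            out.append(HapBlock(chrom=str(c), start_bp=int(pos[i]), end_bp=int(pos[j]),
                                snp_indices=idx[i:j + 1]))
    out.sort(key=lambda b: (b.chrom, b.start_bp))
    return out


def build_hap_matrix(panel: GenotypePanel, blocks: list[HapBlock],
                     min_hap_maf: float = 0.01) -> HapMatrix:
    """Enumerate hapalleles per block and assemble the additive Hap-matrix.

    Lines missing any call inside a block are missing (NaN) for every
    hapallele column of that block; columns with carrier frequency below
    ``min_hap_maf`` are dropped; blocks that end up monomorphic (fewer than
    two retained alleles) are dropped with a warning.
    """
    cols, meta, kept_blocks = [], [], []
    for blk in blocks:
        G = panel.dosages[:, blk.snp_indices]
        complete = ~np.isnan(G).any(axis=1)
        if complete.sum() == 0:
            log.warning("block %s:%d-%d has no complete lines; dropped",
                        blk.chrom, blk.start_bp, blk.end_bp)
            continue
        codes = (G[complete] > 0).astype(int)
        strings = ["".join("A" if a else "R" for a in row) for row in codes]
        uniq, counts = np.unique(strings, return_counts=True)
        freqs = counts / complete.sum()
        keep = freqs >= min_hap_maf
        if keep.sum() < 2:
            log.warning("block %s:%d-%d monomorphic after frequency filter; dropped",
                        blk.chrom, blk.start_bp, blk.end_bp)
            continue
        bi = len(kept_blocks)
        blk.hapalleles = [(str(u), float(f)) for u, f in zip(uniq[keep], freqs[keep])]
        for u, f in zip(uniq[keep], freqs[keep]):
            col = np.full(panel.n_lines, np.nan)
            col[complete] = np.where(np.asarray(strings) == u, 2.0, 0.0)
            cols.append(col)
            meta.append((bi, str(u), float(f), blk.chrom, blk.midpoint_bp))
        kept_blocks.append(blk)
    if not cols:
        raise ValueError("no polymorphic haplotype blocks")
    meta_arr = list(zip(*meta))
    return HapMatrix(
        dosages=np.column_stack(cols),
        block_index=np.asarray(meta_arr[0], dtype=int),
        allele=np.asarray(meta_arr[1], dtype=object),
        frequency=np.asarray(meta_arr[2], dtype=float),
        chrom=np.asarray(meta_arr[3], dtype=object),
        midpoint_bp=np.asarray(meta_arr[4], dtype=float),
        blocks=kept_blocks,
        line_ids=panel.line_ids,
    )


def block_stats(blocks: list[HapBlock], hap: HapMatrix | None = None) -> dict:
    """Summary statistics over detected blocks (and the Hap-matrix if given)."""
    if not blocks:
        raise ValueError("no blocks to summarise")
    sizes = np.array([b.size_bp for b in blocks], dtype=float)
    nsnps = np.array([b.n_snps for b in blocks], dtype=float)
    stats = {
        "n_blocks": len(blocks),
        "size_min_bp": float(sizes.min()),
        "size_mean_bp": float(sizes.mean()),
        "size_max_bp": float(sizes.max()),
        "snps_min": float(nsnps.min()),
        "snps_mean": float(nsnps.mean()),
        "snps_max": float(nsnps.max()),
        "frac_blocks_lt15_snps": float(np.mean(nsnps < 15)),
    }
    if hap is not None:
        per_block = np.bincount(hap.block_index, minlength=len(hap.blocks))
        stats.update({
            "n_hapalleles": int(hap.n_columns),
            "alleles_per_block_mean": float(per_block.mean()),
            "alleles_per_block_min": int(per_block.min()),
            "alleles_per_block_max": int(per_block.max()),
        })
    return stats


class HaplotypeBlockFinder(BaseEstimator, TransformerMixin):
    """Estimator wrapper: fit detects blocks, transform builds hapallele dosages.

    Parameters mirror :func:`detect_blocks` / :func:`build_hap_matrix`; the
    genomic map (chrom, pos) is passed at construction since sklearn's X
    carries no coordinates.
    """

    def __init__(self, chrom=None, pos=None, max_span_bp: int = 1_000_000,
                 ci_low_strong: float = 0.70, ci_high_strong: float = 0.98,
                 ci_high_recomb: float = 0.90, informative_fraction: float = 0.95,
                 min_hap_maf: float = 0.01):
        self.chrom = chrom
        self.pos = pos
        self.max_span_bp = max_span_bp
        self.ci_low_strong = ci_low_strong
        self.ci_high_strong = ci_high_strong
        self.ci_high_recomb = ci_high_recomb
        self.informative_fraction = informative_fraction
        self.min_hap_maf = min_hap_maf

    def _panel(self, X) -> GenotypePanel:
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        chrom = np.asarray(self.chrom if self.chrom is not None else ["1"] * m)
        pos = np.asarray(self.pos if self.pos is not None else np.arange(m))
        return GenotypePanel(X, chrom, pos,
                             np.array([f"snp{i}" for i in range(m)], dtype=object),
                             np.array([f"line{i}" for i in range(n)], dtype=object))

    def fit(self, X, y=None):
        panel = self._panel(X)
        self.blocks_ = detect_blocks(
            panel, self.max_span_bp, self.ci_low_strong, self.ci_high_strong,
            self.ci_high_recomb, self.informative_fraction)
        self.hap_matrix_ = build_hap_matrix(panel, self.blocks_, self.min_hap_maf)
        return self

    def transform(self, X=None):
        return self.hap_matrix_.dosages
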