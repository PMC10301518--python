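"""Genotype panel container and marker-level quality filtering.

The panel holds biallelic SNP dosages for fully inbred lines: non-missing
dosages are 0 or 2 ALT copies, missing calls are NaN.  Heterozygous calls are
not part of the inbred contract; readers convert them to missing and the
filter removes markers where they were frequent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class GenotypePanel:
    """Biallelic SNP dosages (lines x SNPs) with physical coordinates.

    Attributes
    ----------
    dosages : float ndarray, shape (n_lines, n_snps)
        ALT-allele dosage in {0, 2}; NaN for missing calls.
    chrom : str ndarray, shape (n_snps,)
    pos : int ndarray, shape (n_snps,)
        0-based physical positions, sorted within chromosome.
    snp_ids, line_ids : object ndarrays
    truth : dict or None
        Optional simulation ground truth (planted blocks / founder mosaics);
        absent for panels read from files.
    """

    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    snp_ids: np.ndarray
    line_ids: np.ndarray
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        if self.dosages.shape != (len(self.line_ids), len(self.pos)):
            raise ValueError("dosage matrix shape does not match ids/positions")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions unsorted on chromosome {c}")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def take_snps(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        truth = self.truth
        if truth is not None and "blocks" in truth:
            # remap simulation-truth SNP indices onto the subset
            new_of_old = {int(o): k for k, o in enumerate(idx)}
            blocks = []
            for bt in truth["blocks"]:
                kept = [new_of_old[i] for i in bt["snp_indices"] if i in new_of_old]
                if len(kept) >= 2:
                    blocks.append({**bt, "snp_indices": kept})
            truth = {**truth, "blocks": blocks}
        return replace(
            self,
            dosages=self.dosages[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            snp_ids=self.snp_ids[idx],
            truth=truth,
        )

    def take_lines(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return replace(self, dosages=self.dosages[idx], line_ids=self.line_ids[idx])

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def alt_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class SnpFilterParams:
    """Marker QC thresholds: call rate >= 60%, MAF >= 1%, heterozygosity <= 5%."""

    min_call_rate: float = 0.60
    min_maf: float = 0.01
    max_het: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "max_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


class SNPFilter(BaseEstimator, TransformerMixin):
    """Remove SNPs failing call-rate, MAF or heterozygosity thresholds.

    Expects a dosage matrix where heterozygous calls are coded 1 (or have
    already been set to NaN by the reader).  Het calls are set missing before
    the call rate is computed, then markers with too many of them are dropped.

    Fitted attributes: ``support_`` (bool mask over columns) and ``report_``
    (counts removed per criterion; a marker failing several criteria is
    counted once under each).
    """

    def __init__(self, min_call_rate: float = 0.60, min_maf: float = 0.01,
                 max_het: float = 0.05):
        self.min_call_rate = min_call_rate
        self.min_maf = min_maf
        self.max_het = max_het

    def fit(self, X: np.ndarray, y: Any = None) -> "SNPFilter":
        X = np.asarray(X, dtype=float)
        SnpFilterParams(self.min_call_rate, self.min_maf, self.max_het)
        n = X.shape[0]
        het = X == 1
        het_rate = het.sum(axis=0) / n
        Xm = np.where(het, np.nan, X)
        call_rate = 1.0 - np.mean(np.isnan(Xm), axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nanmean(Xm, axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
        maf = np.where(np.isnan(maf), 0.0, maf)
        bad_call = call_rate < self.min_call_rate
        bad_maf = maf < self.min_maf
        bad_het = het_rate > self.max_het
        self.support_ = ~(bad_call | bad_maf | bad_het)
        self.report_ = {
            "n_input": int(X.shape[1]),
            "removed_call_rate": int(bad_call.sum()),
            "removed_maf": int(bad_maf.sum()),
            "removed_het": int(bad_het.sum()),
            "n_retained": int(self.support_.sum()),
        }
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xm = np.where(X == 1, np.nan, X)
        return Xm[:, self.support_]


def filter_snps(panel: GenotypePanel,
                params: SnpFilterParams | None = None) -> tuple[GenotypePanel, dict]:
    """Apply marker QC to a panel; returns (filtered panel, filter report).

    Raises ``ValueError`` if no SNP survives.
    """
    params = params or SnpFilterParams()
    f = SNPFilter(params.min_call_rate, params.min_maf, params.max_het).fit(panel.dosages)
    if f.report_["n_retained"] == 0:
        raise ValueError(f"all SNPs removed by QC filter: {f.report_}")
    out = panel.take_snps(np.where(f.support_)[0])
    out.dosages = np.where(out.dosages == 1, np.nan, out.dosages)
    return out, f.report_
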