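"""Pairwise linkage disequilibrium between biallelic SNPs in inbred lines.

Because lines are fully inbred, two-locus haplotypes are read directly off
the genotypes (each line contributes one haplotype class).  D' confidence
intervals follow the classic block-calling approach: the multinomial
likelihood of the four haplotype counts is evaluated on a grid of |D'| with
allele frequencies fixed at their observed values, normalised, and the 90%
interval taken by trimming cumulative 5% tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: |D'| likelihood grid: 1001 points, step 0.001.
DPRIME_GRID = np.linspace(0.0, 1.0, 1001)


@dataclass(frozen=True)
class LdStats:
    r2: float
    d_prime: float
    d_prime_ci_low: float
    d_prime_ci_high: float

    def __post_init__(self):
        if self.d_prime_ci_low > self.d_prime_ci_high + 1e-12:
            raise ValueError("CI bounds inverted")


def haplotype_counts(gi: np.ndarray, gj: np.ndarray) -> tuple[int, int, int, int]:
    """Two-locus haplotype counts (AB, Ab, aB, ab) from inbred dosages.

    A/B denote the ALT allele at each locus; each line with non-missing calls
    at both loci contributes one haplotype.
    """
    gi = np.asarray(gi, dtype=float)
    gj = np.asarray(gj, dtype=float)
    ok = ~np.isnan(gi) & ~np.isnan(gj)
    a = gi[ok] > 0
    b = gj[ok] > 0
    n_ab = int(np.sum(a & b))
    n_aB = int(np.sum(a & ~b))
    n_Ab = int(np.sum(~a & b))
    n_oo = int(np.sum(~a & ~b))
    return n_ab, n_aB, n_Ab, n_oo


def _dprime_ci(nAB: int, nAb: int, naB: int, nab: int) -> tuple[float, float]:
    """90% CI of |D'| by normalised likelihood over :data:`DPRIME_GRID`."""
    n = nAB + nAb + naB + nab
    pA = (nAB + nAb) / n
    pB = (nAB + naB) / n
    D = nAB / n - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
        sign = 1.0
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
        sign = -1.0
    if dmax <= 0:  # one locus monomorphic among informative lines
        return 0.0, 1.0
    d = sign * DPRIME_GRID * dmax
    fAB = np.clip(pA * pB + d, 1e-12, None)
    fAb = np.clip(pA - pA * pB - d, 1e-12, None)
    faB = np.clip(pB - pA * pB - d, 1e-12, None)
    fab = np.clip(1 - pA - pB + pA * pB + d, 1e-12, None)
    ll = (nAB * np.log(fAB) + nAb * np.log(fAb)
          + naB * np.log(faB) + nab * np.log(fab))
    like = np.exp(ll - ll.max())
    like /= like.sum()
    cum = np.cumsum(like)
    # discrete quantiles trimming strictly less than 5% per tail: the lower
    # bound uses the right-continuous CDF, the upper the left-continuous one
    # (so a point mass at |D'| = 1 keeps the upper bound at 1)
    lo = DPRIME_GRID[min(int(np.searchsorted(cum, 0.05)), 1000)]
    hi = DPRIME_GRID[min(int(np.searchsorted(cum - like, 0.95)), 1000)]
    return float(lo), float(hi)


def pairwise_ld(gi: np.ndarray, gj: np.ndarray) -> LdStats | None:
    """LD statistics for one SNP pair; ``None`` if LD is undefined.

    Undefined when fewer than 2 lines are informative at both loci or either
    locus is monomorphic among them.
    """
    nAB, nAb, naB, nab = haplotype_counts(gi, gj)
    n = nAB + nAb + naB + nab
    if n < 2:
        return None
    pA = (nAB + nAb) / n
    pB = (nAB + naB) / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return None
    D = nAB / n - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    lo, hi = _dprime_ci(nAB, nAb, naB, nab)
    return LdStats(r2=float(r2), d_prime=float(min(d_prime, 1.0)),
                   d_prime_ci_low=lo, d_prime_ci_high=hi)


def r2_matrix(X: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, NaN mean-imputed.

    Used for LD pruning and the gene set test; constant columns give r2 = 0
    with themselves excluded by callers.
    """
    X = np.asarray(X, dtype=float)
    mu = np.nanmean(X, axis=0)
    Xi = np.where(np.isnan(X), mu, X)
    Xc = Xi - Xi.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = np.inf
    Z = Xc / sd
    r = (Z.T @ Z) / Z.shape[0]
    return r * r
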