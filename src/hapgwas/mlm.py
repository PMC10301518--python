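"""Population-structure-aware mixed-model association over pseudo-markers.

The scan uses the P3D/EMMAX scheme: a single-component REML fit on the null
model (intercept + principal components + polygenic term with a VanRaden
genomic relationship matrix) fixes the variance ratio, after which each
marker is tested by generalized least squares in the eigenbasis of the GRM.
The per-marker Wald test uses the marker-model weighted residual variance
with n - p - 1 degrees of freedom, so with an identity kinship the scan is
exactly OLS ANCOVA.

Also here: greedy LD pruning, genomic PCA, GREML heritability and a
Haseman-Elston genetic correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .panel import GenotypePanel

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# kinship

@dataclass
class Kinship:
    matrix: np.ndarray
    source: str = "snp"

    def __post_init__(self):
        K = np.asarray(self.matrix, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        self.matrix = (K + K.T) / 2.0


def mean_impute(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mu = np.nanmean(X, axis=0)
    return np.where(np.isnan(X), mu, X)


def compute_grm(X: np.ndarray, source: str = "snp") -> Kinship:
    """VanRaden GRM from a dosage matrix (columns coded 0..2, NaN allowed).

    Columns are centred by twice their allele frequency and the matrix is
    scaled by sum 2p(1-p)(1+F), where F is the panel-level inbreeding
    coefficient estimated from the heterozygote deficit.  For fully inbred
    lines (no heterozygotes) this is sum 4p(1-p), which keeps the mean
    diagonal near 1 so the REML h2 parameter stays on the trait scale.
    """
    X = np.asarray(X, dtype=float)
    Xi = mean_impute(X)
    p = Xi.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers monomorphic; GRM undefined")
    het_obs = float(np.nanmean(X == 1))
    het_exp = float(np.mean(2.0 * p[poly] * (1.0 - p[poly])))
    F = 1.0 - het_obs / het_exp if het_exp > 0 else 1.0
    F = float(np.clip(F, 0.0, 1.0))
    W = Xi[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly]))) * (1.0 + F)
    K = (W @ W.T) / denom
    return Kinship(matrix=K, source=source)


# --------------------------------------------------------------------------
# LD pruning

class LDPruner(BaseEstimator):
    """Greedy left-to-right LD pruning within a physical window.

    A SNP is dropped when its squared correlation with any previously kept
    SNP closer than ``window_bp`` exceeds ``r2_max``.  Fitted attribute
    ``support_`` is a boolean column mask.
    """

    def __init__(self, chrom=None, pos=None, window_bp: int = 5_000_000,
                 r2_max: float = 0.2):
        self.chrom = chrom
        self.pos = pos
        self.window_bp = window_bp
        self.r2_max = r2_max

    def fit(self, X, y=None):
        X = mean_impute(X)
        m = X.shape[1]
        chrom = np.asarray(self.chrom if self.chrom is not None else ["1"] * m)
        pos = np.asarray(self.pos if self.pos is not None else np.arange(m))
        Xc = X - X.mean(axis=0)
        sd = Xc.std(axis=0)
        keep = np.zeros(m, dtype=bool)
        for c in np.unique(chrom):
            cols = np.where(chrom == c)[0]
            cols = cols[np.argsort(pos[cols], kind="stable")]
            kept: list[int] = []
            for j in cols:
                if sd[j] == 0:
                    continue
                start = pos[j] - self.window_bp
                ok = True
                for i in reversed(kept):
                    if pos[i] < start:
                        break
                    r = np.dot(Xc[:, i], Xc[:, j]) / (len(Xc) * sd[i] * sd[j])
                    if r * r > self.r2_max:
                        ok = False
                        break
                if ok:
                    kept.append(j)
            keep[kept] = True
        self.support_ = keep
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.support_]


def ld_prune(panel: GenotypePanel, window_bp: int = 5_000_000,
             r2_max: float = 0.2) -> GenotypePanel:
    pruner = LDPruner(chrom=panel.chrom, pos=panel.pos,
                      window_bp=window_bp, r2_max=r2_max).fit(panel.dosages)
    return panel.take_snps(np.where(pruner.support_)[0])


# --------------------------------------------------------------------------
# PCA

def compute_pca(X: np.ndarray | None = None, n_components: int = 4,
                gram: np.ndarray | None = None) -> np.ndarray:
    """Principal-component scores of a centred/scaled genotype matrix.

    Either a dosage matrix ``X`` (NaN mean-imputed, constant columns
    excluded, columns standardised) or a precomputed Gram matrix of
    standardised genotypes may be supplied.  Sign convention for ``X``
    input: the largest-magnitude loading of each component is positive.
    """
    if gram is None:
        if X is None:
            raise ValueError("need X or gram")
        Xi = mean_impute(X)
        Xc = Xi - Xi.mean(axis=0)
        sd = Xc.std(axis=0)
        Z = Xc[:, sd > 0] / sd[sd > 0]
        if Z.shape[0] <= n_components:
            raise ValueError("need more lines than components")
        G = Z @ Z.T
    else:
        G = np.asarray(gram, dtype=float)
        n = G.shape[0]
        H = np.eye(n) - 1.0 / n
        G = H @ G @ H
        Z = None
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.clip(vals[order], 0, None)
    scores = vecs[:, order] * np.sqrt(vals)
    if Z is not None:
        for k in range(scores.shape[1]):
            s = np.sqrt(vals[k])
            if s > 0:
                loading = Z.T @ scores[:, k]
                if loading[np.argmax(np.abs(loading))] < 0:
                    scores[:, k] = -scores[:, k]
    return scores


# --------------------------------------------------------------------------
# REML

@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    degenerate: bool = False

    def __post_init__(self):
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")


def _reml_neg_loglik(h2, S, yt, Xt):
    n, p = Xt.shape
    w = 1.0 / (h2 * S + (1.0 - h2))
    Xw = Xt * w[:, None]
    M = Xt.T @ Xw
    Mi = np.linalg.inv(M)
    beta = Mi @ (Xw.T @ yt)
    resid = yt - Xt @ beta
    rss = float(np.sum(w * resid * resid))
    sigma2 = rss / (n - p)
    _, logdetM = np.linalg.slogdet(M)
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1)
                 - np.sum(np.log(w)) + logdetM)
    return -ll, sigma2


def reml_variance(y: np.ndarray, X: np.ndarray | None,
                  K: Kinship | np.ndarray,
                  eig: tuple[np.ndarray, np.ndarray] | None = None
                  ) -> VarianceComponents:
    """Single-component REML (EMMA-style) via eigendecomposition of the GRM.

    Profiles the restricted likelihood in h2 = sigma_g2/(sigma_g2+sigma_e2)
    on (0,1) after rotating data into the GRM eigenbasis.  ``eig`` may carry
    a precomputed (eigenvalues, eigenvectors) pair of K.  An (almost)
    identity kinship leaves the two components non-identifiable; the result
    is flagged ``degenerate``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if eig is None:
        K = K.matrix if isinstance(K, Kinship) else np.asarray(K, dtype=float)
        S, U = np.linalg.eigh(K)
    else:
        S, U = eig
    S = np.clip(S, 0, None)
    yt, Xt = U.T @ y, U.T @ X
    degenerate = float(S.max() - S.min()) < 1e-8

    grid = np.linspace(0.001, 0.999, 21)
    vals = [_reml_neg_loglik(h, S, yt, Xt)[0] for h in grid]
    h0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        lambda h: _reml_neg_loglik(h, S, yt, Xt)[0],
        bounds=(max(h0 - 0.05, 1e-6), min(h0 + 0.05, 1 - 1e-6)), method="bounded",
        options={"xatol": 1e-8})
    h2 = float(res.x)
    nll, sigma2 = _reml_neg_loglik(h2, S, yt, Xt)
    return VarianceComponents(sigma_g2=h2 * sigma2, sigma_e2=(1 - h2) * sigma2,
                              h2=h2, loglik=-nll, degenerate=degenerate)


def heritability_gate(h2_by_trait: dict[str, float],
                      min_h2: float = 0.2) -> list[str]:
    """Traits retained for the scan: genomic h2 >= min_h2 (boundary kept)."""
    kept = [t for t, h in h2_by_trait.items() if h >= min_h2]
    for t, h in h2_by_trait.items():
        if h < min_h2:
            log.info("trait %s excluded: genomic h2 = %.3f < %.2f", t, h, min_h2)
    return kept


# --------------------------------------------------------------------------
# association scan

class MixedModelScan(BaseEstimator):
    """EMMAX/P3D association scan of marker columns against one trait.

    fit(X, y) estimates variance components once on the null model
    (intercept + ``covariates`` + polygenic term with ``kinship``) and tests
    each column of X by GLS.  Fitted attributes: ``beta_``, ``se_``,
    ``pvalues_``, ``logp_``, ``vc_`` (null VarianceComponents), ``tested_``.
    Zero-variance columns (after mean imputation) are skipped (NaN).
    """

    def __init__(self, kinship: Kinship | np.ndarray | None = None,
                 covariates: np.ndarray | None = None,
                 marker_dtype=np.float64):
        self.kinship = kinship
        self.covariates = covariates
        self.marker_dtype = marker_dtype

    def fit(self, X, y):
        X = mean_impute(X)
        y = np.asarray(y, dtype=float)
        n, m = X.shape
        K = self.kinship
        K = K.matrix if isinstance(K, Kinship) else (
            np.eye(n) if K is None else np.asarray(K, dtype=float))
        C = np.ones((n, 1)) if self.covariates is None else np.column_stack(
            [np.ones(n), np.asarray(self.covariates, dtype=float)])
        S, U = np.linalg.eigh(K)
        S = np.clip(S, 0, None)
        self.vc_ = reml_variance(y, C, K, eig=(S, U))
        h2 = self.vc_.h2

        w = 1.0 / (h2 * S + (1.0 - h2))
        yt = U.T @ y
        At = U.T @ C
        # the marker rotation dominates the scan cost; a float32 product is
        # ample for threshold decisions in CV runs
        Gt = (U.astype(self.marker_dtype).T
              @ X.astype(self.marker_dtype)).astype(float)

        Aw = At * w[:, None]
        M = At.T @ Aw
        Mi = np.linalg.inv(M)
        Ay = Aw.T @ yt
        yy = float(np.sum(w * yt * yt))
        rss0 = yy - float(Ay @ Mi @ Ay)

        gw = Gt * w[:, None]
        gg = np.einsum("ij,ij->j", Gt, gw)
        gA = gw.T @ At                       # (m, p)
        gy = gw.T @ yt                       # (m,)
        gAMi = gA @ Mi
        denom = gg - np.einsum("ij,ij->i", gAMi, gA)
        num = gy - gAMi @ Ay

        p_cov = C.shape[1]
        df = n - p_cov - 1
        tested = denom > 1e-10
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        pval = np.full(m, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta[tested] = num[tested] / denom[tested]
            rss = rss0 - num[tested] ** 2 / denom[tested]
            rss = np.clip(rss, 1e-300, None)
            sigma2 = rss / df
            se[tested] = np.sqrt(sigma2 / denom[tested])
            tstat = beta[tested] / se[tested]
            pval[tested] = 2.0 * stats.t.sf(np.abs(tstat), df)
        pval[tested] = np.clip(pval[tested], np.finfo(float).tiny, 1.0)
        n_skip = int(m - tested.sum())
        if n_skip:
            log.info("scan skipped %d zero-variance columns", n_skip)
        self.tested_ = tested
        self.beta_, self.se_, self.pvalues_ = beta, se, pval
        with np.errstate(divide="ignore", invalid="ignore"):
            self.logp_ = -np.log10(pval)
        return self


def mlm_scan(X: np.ndarray, y: np.ndarray, pcs: np.ndarray | None,
             K: Kinship | np.ndarray) -> MixedModelScan:
    """Functional wrapper around :class:`MixedModelScan`."""
    return MixedModelScan(kinship=K, covariates=pcs).fit(X, y)


# --------------------------------------------------------------------------
# genetic correlation

def genetic_correlation(y1: np.ndarray, y2: np.ndarray,
                        K: Kinship | np.ndarray) -> tuple[float, float]:
    """Genetic correlation via cross-product regression plus per-trait REML.

    The genetic covariance is a Haseman-Elston-style moment estimator
    evaluated in the GRM eigenbasis: with K = U S U' and rotated, centred
    traits, E[y1_i y2_i] = sigma_g12 S_i + sigma_e12, estimated by least
    squares weighted by the per-trait fitted variances (the eigenbasis form
    is robust to strong population structure, which inflates the variance
    of the classic pairwise off-diagonal regression).  Per-trait genetic
    variances come from single-trait REML.  Returns (r_g, r_g**2); NaNs
    when either genetic variance is (near) zero.
    """
    K = K.matrix if isinstance(K, Kinship) else np.asarray(K, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    S, U = np.linalg.eigh(K)
    S = np.clip(S, 0, None)
    v1 = reml_variance(y1, None, K, eig=(S, U))
    v2 = reml_variance(y2, None, K, eig=(S, U))
    if v1.sigma_g2 < 1e-8 * (v1.sigma_g2 + v1.sigma_e2) or \
       v2.sigma_g2 < 1e-8 * (v2.sigma_g2 + v2.sigma_e2):
        return float("nan"), float("nan")
    a = U.T @ (y1 - y1.mean())
    b = U.T @ (y2 - y2.mean())
    w = 1.0 / ((v1.sigma_g2 * S + v1.sigma_e2)
               * (v2.sigma_g2 * S + v2.sigma_e2))
    X = np.column_stack([S, np.ones_like(S)])
    Xw = X * w[:, None]
    coef = np.linalg.solve(X.T @ Xw, Xw.T @ (a * b))
    sg12 = float(coef[0])
    rg = sg12 / np.sqrt(v1.sigma_g2 * v2.sigma_g2)
    rg = float(np.clip(rg, -1.0, 1.0))
    return rg, rg * rg
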