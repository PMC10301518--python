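"""Repeated k-fold cross-validation stability selection for the scan.

Each of k x repeats runs holds out one fold and rescans the remaining ~80%
of lines; a hapallele is *stable* when its -log10 p exceeds the threshold in
strictly more than ``min_runs`` of the runs (50 of 100 at the defaults).
The full-data scan p-value then decides the modified-Bonferroni flag, where
the effective number of independent tests is the number of haplotype
blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .mlm import MixedModelScan, compute_pca, mean_impute

log = logging.getLogger(__name__)


@dataclass
class CvConfig:
    k: int = 5
    repeats: int = 20
    logp_threshold: float = 5.0
    min_runs: int = 50          # strict: stable needs runs_passed > min_runs
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def total_runs(self) -> int:
        return self.k * self.repeats


def cv_partitions(n_lines: int, k: int, repeats: int,
                  seed: int) -> list[np.ndarray]:
    """Per repeat, a random fold assignment of lines into k near-equal groups.

    Fold sizes differ by at most one; identical seeds give identical
    partitions.
    """
    if n_lines < k:
        raise ValueError("fewer lines than folds")
    rng = np.random.default_rng([seed, 101])
    parts = []
    for _ in range(repeats):
        perm = rng.permutation(n_lines)
        fold = np.empty(n_lines, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, k)):
            fold[chunk] = f
        parts.append(fold)
    return parts


def bonferroni_threshold(alpha: float, n_blocks: int) -> float:
    """Modified Bonferroni p-value threshold: alpha over the block count."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    return alpha / n_blocks


class StabilitySelector(BaseEstimator):
    """CV stability selection over marker columns for one trait.

    fit(X, y) runs k x repeats EMMAX scans on row subsamples.  PCs and
    variance components are re-estimated inside every run; kinship is the
    row/column subset of the full-data GRM; per-run PCs come from the
    double-centred subset of the full-panel standardized-genotype Gram.

    Fitted attributes: ``runs_passed_``, ``stable_``, ``full_scan_``
    (MixedModelScan on all lines), ``n_runs_``.
    """

    def __init__(self, kinship=None, pca_gram=None, n_pcs: int = 4, k: int = 5,
                 repeats: int = 20, logp_threshold: float = 5.0,
                 min_runs: int = 50, seed: int = 0):
        self.kinship = kinship
        self.pca_gram = pca_gram
        self.n_pcs = n_pcs
        self.k = k
        self.repeats = repeats
        self.logp_threshold = logp_threshold
        self.min_runs = min_runs
        self.seed = seed

    def fit(self, X, y):
        cfg = CvConfig(self.k, self.repeats, self.logp_threshold,
                       self.min_runs, self.seed)
        X = mean_impute(X)
        y = np.asarray(y, dtype=float)
        n, m = X.shape
        K = np.asarray(self.kinship.matrix if hasattr(self.kinship, "matrix")
                       else self.kinship, dtype=float)
        gram = np.asarray(self.pca_gram, dtype=float)

        pcs_full = compute_pca(gram=gram, n_components=self.n_pcs)
        self.full_scan_ = MixedModelScan(kinship=K, covariates=pcs_full).fit(X, y)

        counts = np.zeros(m, dtype=int)
        for fold in cv_partitions(n, cfg.k, cfg.repeats, cfg.seed):
            for f in range(cfg.k):
                idx = np.where(fold != f)[0]
                try:
                    pcs = compute_pca(gram=gram[np.ix_(idx, idx)],
                                      n_components=self.n_pcs)
                    scan = MixedModelScan(
                        kinship=K[np.ix_(idx, idx)],
                        covariates=pcs,
                        marker_dtype=np.float32).fit(X[idx], y[idx])
                    counts += (np.nan_to_num(scan.logp_, nan=0.0)
                               > cfg.logp_threshold)
                except (np.linalg.LinAlgError, ValueError) as exc:
                    log.warning("CV run failed (%s); counted as not passing", exc)
        self.runs_passed_ = counts
        self.stable_ = counts > cfg.min_runs
        self.n_runs_ = cfg.total_runs
        return self


def stability_scan(X: np.ndarray, y: np.ndarray, kinship, pca_gram,
                   config: CvConfig | None = None,
                   n_pcs: int = 4) -> StabilitySelector:
    config = config or CvConfig()
    return StabilitySelector(
        kinship=kinship, pca_gram=pca_gram, n_pcs=n_pcs, k=config.k,
        repeats=config.repeats, logp_threshold=config.logp_threshold,
        min_runs=config.min_runs, seed=config.seed).fit(X, y)


def stability_records(sel: StabilitySelector, trait: str,
                      column_table: pd.DataFrame,
                      bonferroni_p: float) -> pd.DataFrame:
    """Stable hapalleles annotated with the full-data Bonferroni flag.

    Stable-but-not-Bonferroni associations are retained and distinguished;
    unstable hapalleles are absent regardless of full-data p.
    """
    df = column_table.copy()
    df["trait"] = trait
    df["runs_passed"] = sel.runs_passed_
    df["n_runs"] = sel.n_runs_
    df["p_full"] = sel.full_scan_.pvalues_
    df["logp_full"] = sel.full_scan_.logp_
    df["beta_full"] = sel.full_scan_.beta_
    df["se_full"] = sel.full_scan_.se_
    df["stable"] = sel.stable_
    df["bonferroni_pass"] = df["stable"] & (df["p_full"] < bonferroni_p)
    return df[df["stable"]].reset_index(drop=True)


def flag_significance(records: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """(Re-)annotate stable records with a Bonferroni flag from full-data p."""
    out = records.copy()
    out["bonferroni_pass"] = out["p_full"] < threshold
    return out
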