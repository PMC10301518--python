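"""Independent brute-force oracles used by the test suite."""

import numpy as np

from hapgwas.ld import pairwise_ld


def gabriel_blocks_exhaustive(panel, max_span_bp=1_000_000,
                              ci_low_strong=0.70, ci_high_strong=0.98,
                              ci_high_recomb=0.90, informative_fraction=0.95):
    """All-intervals evaluation of the confidence-interval block rules.

    Enumerates every interval on every chromosome, checks the outer-pair
    strong-LD rule, the span cap and the informative-pair fraction, then
    greedily keeps non-overlapping candidates by decreasing bp span with
    leftmost tie-break.  Returns a set of (chrom, first snp index, last snp
    index) using panel-global indices.
    """
    out = set()
    for c in sorted(set(panel.chrom)):
        idx = np.where(panel.chrom == c)[0]
        pos = panel.pos[idx]
        n = len(idx)

        def klass(a, b):
            s = pairwise_ld(panel.dosages[:, idx[a]], panel.dosages[:, idx[b]])
            if s is None:
                return 0
            if (s.d_prime_ci_low >= ci_low_strong
                    and s.d_prime_ci_high >= ci_high_strong):
                return 1
            if s.d_prime_ci_high < ci_high_recomb:
                return -1
            return 0

        cands = []
        for i in range(n):
            for j in range(i + 1, n):
                if pos[j] - pos[i] > max_span_bp:
                    continue
                if klass(i, j) != 1:
                    continue
                strong = informative = 0
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        k = klass(a, b)
                        if k != 0:
                            informative += 1
                        if k == 1:
                            strong += 1
                if informative and strong / informative >= informative_fraction:
                    cands.append((pos[j] - pos[i], pos[i], i, j))
        cands.sort(key=lambda t: (-t[0], t[1], t[2]))
        used = set()
        for _, _, i, j in cands:
            if any(k in used for k in range(i, j + 1)):
                continue
            used.update(range(i, j + 1))
            out.add((str(c), int(idx[i]), int(idx[j])))
    return out


def ols_ancova_pvalues(X, y, covariates):
    """Per-marker OLS ANCOVA p-values (two-sided t on the marker term)."""
    from scipy import stats
    n, m = X.shape
    C = np.column_stack([np.ones(n), covariates])
    out = np.empty(m)
    for j in range(m):
        D = np.column_stack([C, X[:, j]])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ beta
        df = n - D.shape[1]
        s2 = resid @ resid / df
        cov = s2 * np.linalg.inv(D.T @ D)
        t = beta[-1] / np.sqrt(cov[-1, -1])
        out[j] = 2 * stats.t.sf(abs(t), df)
    return out
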