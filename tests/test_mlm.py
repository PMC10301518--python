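import numpy as np
import pytest
from scipy import stats

import hapgwas as h
from hapgwas.ld import r2_matrix
from hapgwas.mlm import mean_impute

from tests.oracles import ols_ancova_pvalues


@pytest.fixture(scope="module")
def structured():
    """Shared panel with subpopulations, hap matrix, GRM and PCs."""
    cfg = h.SimConfig(n_lines=300, n_chromosomes=3, n_blocks_per_chrom=40,
                      chrom_length_bp=100_000_000, subpop_count=2,
                      subpop_divergence=0.1, seed=21)
    panel = h.simulate_genotypes(cfg)
    hap = h.hap_matrix_from_truth(panel)
    G = mean_impute(hap.dosages)
    K = h.compute_grm(panel.dosages).matrix
    pcs = h.compute_pca(panel.dosages, 4)
    return panel, hap, G, K, pcs


class TestLdPrune:
    def _panel(self, cols, pos):
        return h.GenotypePanel(
            np.column_stack(cols), np.array(["1"] * len(pos), dtype=object),
            np.array(pos), np.array([f"s{i}" for i in range(len(pos))],
                                    dtype=object),
            np.array([f"l{i}" for i in range(len(cols[0]))], dtype=object))

    def test_window_semantics(self):
        g = np.array([0.0, 2.0] * 30)
        near = self._panel([g, g], [0, 1_000_000])
        far = self._panel([g, g], [0, 6_000_000])
        assert h.ld_prune(near).n_snps == 1
        assert h.ld_prune(far).n_snps == 2

    def test_postcondition_no_close_pair_above_threshold(self, structured):
        panel = structured[0]
        pruned = h.ld_prune(panel)
        r2 = r2_matrix(pruned.dosages)
        for i in range(pruned.n_snps):
            for j in range(i + 1, pruned.n_snps):
                same = pruned.chrom[i] == pruned.chrom[j]
                if same and pruned.pos[j] - pruned.pos[i] <= 5_000_000:
                    assert r2[i, j] <= 0.2 + 1e-9


class TestPca:
    def test_orthogonal_scores(self, structured):
        pcs = structured[4]
        off = pcs.T @ pcs - np.diag(np.diag(pcs.T @ pcs))
        assert np.abs(off).max() < 1e-6

    def test_separates_subpopulations(self, structured):
        panel, _, _, _, pcs = structured
        r = np.corrcoef(pcs[:, 0], panel.truth["subpop"])[0, 1]
        assert abs(r) > 0.9

    def test_duplicating_lines_preserves_geometry(self):
        rng = np.random.default_rng(0)
        X = rng.choice([0.0, 2.0], (40, 60))
        p1 = h.compute_pca(X, 2)
        p2 = h.compute_pca(np.vstack([X, X]), 2)
        # same geometry up to overall scale and sign
        for k in range(2):
            c = np.corrcoef(p1[:, k], p2[:40, k])[0, 1]
            assert abs(c) > 0.9999


class TestGrm:
    def test_clones_and_opposites(self):
        rng = np.random.default_rng(3)
        base = rng.choice([0.0, 2.0], 100)
        X = np.vstack([base, base, 2.0 - base])
        K = h.compute_grm(X).matrix
        assert K[0, 1] == pytest.approx(K[0, 0])
        # p = 0.5-ish columns: opposite homozygotes approach relationship -1
        X2 = np.vstack([np.tile([0.0, 2.0], 50), np.tile([2.0, 0.0], 50)])
        K2 = h.compute_grm(X2).matrix
        assert K2[0, 1] == pytest.approx(-1.0)
        assert K2[0, 0] == pytest.approx(1.0)

    def test_diagonal_scaling(self, structured):
        K = structured[3]
        assert 0.9 <= np.diag(K).mean() <= 1.1

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            h.compute_grm(np.zeros((10, 5)))


class TestReml:
    def test_identity_kinship_flagged_degenerate(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(100)
        vc = h.reml_variance(y, None, np.eye(100))
        assert vc.degenerate

    def test_null_trait_low_h2(self, structured):
        _, _, _, K, _ = structured
        rng = np.random.default_rng(7)
        h2s = [h.reml_variance(rng.standard_normal(300), None, K).h2
               for _ in range(5)]
        assert np.mean(h2s) <= 0.1

    def test_h2_recovery(self, structured):
        panel, _, _, K, _ = structured
        L = np.linalg.cholesky(K + 1e-6 * np.eye(len(K)))
        rng = np.random.default_rng(11)
        ests = []
        for _ in range(5):
            g = L @ rng.standard_normal(len(K))
            g = g / g.std()
            y = np.sqrt(0.5) * g + np.sqrt(0.5) * rng.standard_normal(len(K))
            ests.append(h.reml_variance(y, None, K).h2)
        assert 0.4 <= np.mean(ests) <= 0.6

    def test_gate_boundary(self):
        kept = h.heritability_gate({"a": 0.19, "b": 0.20, "c": 0.5})
        assert kept == ["b", "c"]
        assert h.heritability_gate({"a": 0.0, "b": 0.1}) == []


class TestScan:
    def test_identity_kinship_equals_ols_ancova(self):
        rng = np.random.default_rng(5)
        n, m = 150, 80
        X = rng.choice([0.0, 2.0], (n, m))
        pcs = rng.standard_normal((n, 3))
        y = rng.standard_normal(n) + 0.4 * X[:, 3]
        scan = h.mlm_scan(X, y, pcs, np.eye(n))
        oracle = ols_ancova_pvalues(X, y, pcs)
        np.testing.assert_allclose(scan.pvalues_, oracle, rtol=1e-8)

    def test_zero_variance_column_skipped(self):
        rng = np.random.default_rng(5)
        X = rng.choice([0.0, 2.0], (60, 4))
        X[:, 2] = 2.0
        scan = h.mlm_scan(X, rng.standard_normal(60), None, np.eye(60))
        assert np.isnan(scan.pvalues_[2])
        assert not np.isnan(scan.pvalues_[[0, 1, 3]]).any()

    def test_planted_effect_detected_and_killed_by_permutation(self,
                                                               structured):
        panel, hap, G, K, pcs = structured
        rng = np.random.default_rng(13)
        W = G - G.mean(axis=0)
        gpoly = W @ rng.standard_normal(G.shape[1])
        gpoly /= gpoly.std()
        d = G[:, 50]
        dz = (d - d.mean()) / d.std()
        y = np.sqrt(0.15) * dz + np.sqrt(0.3) * gpoly \
            + np.sqrt(0.55) * rng.standard_normal(len(d))
        scan = h.mlm_scan(G, y, pcs, K)
        assert scan.logp_[50] > 5
        yperm = rng.permutation(y)
        perm = h.mlm_scan(G, yperm, pcs, K)
        assert perm.logp_[50] < 5

    def test_structure_confounding_controlled(self, structured):
        panel, hap, G, K, pcs = structured
        rng = np.random.default_rng(17)
        sub = panel.truth["subpop"].astype(float)
        y = sub + rng.standard_normal(len(sub))

        def gif(p):
            p = p[~np.isnan(p)]
            return np.median(stats.chi2.isf(p, 1)) / stats.chi2.isf(0.5, 1)

        naive = ols_ancova_pvalues(G, y, np.zeros((len(y), 0)))
        corrected = h.mlm_scan(G, y, pcs, K)
        assert gif(naive) > 1.3
        assert 0.9 <= gif(corrected.pvalues_) <= 1.1


class TestGeneticCorrelation:
    def test_identical_traits(self, structured):
        _, _, _, K, _ = structured
        rng = np.random.default_rng(19)
        L = np.linalg.cholesky(K + 1e-6 * np.eye(len(K)))
        g = L @ rng.standard_normal(len(K))
        y = np.sqrt(0.5) * g / g.std() + np.sqrt(0.5) * \
            rng.standard_normal(len(K))
        rg, rg2 = h.genetic_correlation(y, y, K)
        assert rg == pytest.approx(1.0)
        assert rg2 == pytest.approx(1.0)

    def test_shared_architecture_recovered(self, structured):
        _, _, _, K, _ = structured
        rng = np.random.default_rng(23)
        L = np.linalg.cholesky(K + 1e-6 * np.eye(len(K)))
        ests = []
        for _ in range(5):
            z1 = L @ rng.standard_normal(len(K))
            z2 = L @ rng.standard_normal(len(K))
            g1 = z1 / z1.std()
            g2 = (0.8 * z1 + 0.6 * z2)
            g2 /= g2.std()
            y1 = np.sqrt(0.5) * g1 + np.sqrt(0.5) * rng.standard_normal(len(K))
            y2 = np.sqrt(0.5) * g2 + np.sqrt(0.5) * rng.standard_normal(len(K))
            ests.append(h.genetic_correlation(y1, y2, K)[0])
        assert 0.65 <= np.mean(ests) <= 0.95

    def test_independent_traits_near_zero(self, structured):
        _, _, _, K, _ = structured
        rng = np.random.default_rng(29)
        L = np.linalg.cholesky(K + 1e-6 * np.eye(len(K)))
        ests = []
        for _ in range(5):
            ys = []
            for _ in range(2):
                g = L @ rng.standard_normal(len(K))
                ys.append(np.sqrt(0.5) * g / g.std()
                          + np.sqrt(0.5) * rng.standard_normal(len(K)))
            ests.append(h.genetic_correlation(*ys, K)[0])
        assert abs(np.mean(ests)) <= 0.2
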