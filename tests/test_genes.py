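import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hapgwas.genes import (_imhof_sf, _saddlepoint_sf, flag_significant_genes,
                           gene_set_test, go_enrichment, select_genes,
                           wchi2_sf)
from hapgwas.qtl import QTLRegion


class TestWeightedChi2:
    def test_closed_form_limits(self):
        # independent SNPs: chi2 with m df; rank-1: chi2_1 at T/m
        for T in (2.0, 11.07, 25.0):
            assert wchi2_sf(T, np.ones(5)) == pytest.approx(
                stats.chi2.sf(T, 5), abs=1e-10)
            assert wchi2_sf(T, np.array([5.0, 0, 0, 0, 0])) == pytest.approx(
                stats.chi2.sf(T / 5, 1), abs=1e-10)

    def test_imhof_matches_chi2_on_near_equal_spectrum(self):
        lam = np.array([1.0, 1.0 + 1e-6, 1.0 - 1e-6, 1.0])
        p = _imhof_sf(9.49, lam)
        assert p == pytest.approx(stats.chi2.sf(9.49, 4), abs=1e-7)

    def test_backends_agree(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            m = int(rng.integers(3, 12))
            lam = rng.uniform(0.05, 3, m)
            T = float(lam.sum() * rng.uniform(1.2, 6))
            pi = _imhof_sf(T, lam)
            ps = _saddlepoint_sf(T, lam)
            if pi is not None and pi > 1e-10:
                assert ps == pytest.approx(pi, rel=0.08)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(3)
        miss = 0
        for _ in range(20):
            m = int(rng.integers(3, 10))
            lam = rng.uniform(0.1, 3, m)
            T = float(lam.sum() * rng.uniform(0.8, 2.5))
            draws = (rng.chisquare(1, (50_000, m)) * lam).sum(axis=1)
            phat = draws.mean() * 0 + (draws > T).mean()
            se = np.sqrt(phat * (1 - phat) / 50_000)
            if abs(wchi2_sf(T, lam) - phat) > 3 * se + 1e-12:
                miss += 1
        assert miss <= 1

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            wchi2_sf(1.0, np.zeros(3))
        assert wchi2_sf(-1.0, np.ones(3)) == 1.0


class TestGeneSetTest:
    def _stats_and_panel(self, rng, m, n=200, chrom="1A", start=5_000):
        X = rng.choice([0.0, 2.0], (n, m))
        pos = start + np.arange(m) * 100
        snp = pd.DataFrame({"chrom": chrom, "pos": pos,
                            "p": rng.uniform(0, 1, m), "trait": "t"})
        return snp, X

    def test_pad_window_and_exclusion(self):
        rng = np.random.default_rng(1)
        snp, X = self._stats_and_panel(rng, 10)
        gene = pd.Series({"gene_id": "g1", "chrom": "1A",
                          "start": 5_000, "end": 5_900})
        rec = gene_set_test(gene, snp, X)
        assert rec.n_snps_used == 10
        far = pd.Series({"gene_id": "g2", "chrom": "1A",
                         "start": 50_000, "end": 51_000})
        rec2 = gene_set_test(far, snp, X)
        assert rec2.reason == "insufficient SNPs"
        assert rec2.p is None

    def test_invariance_to_order_and_sign(self):
        rng = np.random.default_rng(5)
        snp, X = self._stats_and_panel(rng, 8)
        gene = pd.Series({"gene_id": "g", "chrom": "1A",
                          "start": 5_000, "end": 6_000})
        p1 = gene_set_test(gene, snp, X).p
        perm = rng.permutation(8)
        p2 = gene_set_test(gene, snp.iloc[perm].reset_index(drop=True),
                           X[:, perm]).p
        p3 = gene_set_test(gene, snp, 2.0 - X).p  # allele flip
        assert p2 == pytest.approx(p1, rel=1e-9)
        assert p3 == pytest.approx(p1, rel=1e-9)

    def test_null_uniformity_independent_snps(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(400):
            snp, X = self._stats_and_panel(rng, 6, n=500)
            gene = pd.Series({"gene_id": "g", "chrom": "1A",
                              "start": 5_000, "end": 6_000})
            ps.append(gene_set_test(gene, snp, X).p)
        ks = stats.kstest(ps, "uniform")
        assert ks.statistic < 0.05

    def test_significance_threshold_strict(self):
        recs = []
        for gid, p in (("a", 0.0009), ("b", 0.001), ("c", None)):
            r = pd.Series({"gene_id": gid, "chrom": "1", "start": 0,
                           "end": 10})
            from hapgwas.genes import GeneRecord
            recs.append(GeneRecord(gene_id=gid, chrom="1", start=0, end=10,
                                   trait="t", n_snps_used=2 if p else 1, p=p,
                                   reason=None if p else "insufficient SNPs"))
        table = flag_significant_genes(recs)
        assert table["significant"].tolist() == [True, False, False]


class TestSelectGenes:
    def _gff(self, spacing=50_000, length=10_000_000):
        n = length // spacing
        return pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(n)],
            "chrom": "2B",
            "start": np.arange(n) * spacing,
            "end": np.arange(n) * spacing + 3_000,
        })

    def test_flank_inclusion(self):
        region = QTLRegion("2B", 24_000_000, 27_000_000,
                           members=pd.DataFrame())
        gff = pd.DataFrame({
            "gene_id": ["near", "far"], "chrom": ["2B", "2B"],
            "start": [22_500_000, 21_000_000],
            "end": [22_503_000, 21_003_000]})
        got = select_genes([region], gff)
        assert got["gene_id"].tolist() == ["near"]

    def test_tiling_arithmetic(self):
        region = QTLRegion("2B", 3_000_000, 6_000_000,
                           members=pd.DataFrame())
        got = select_genes([region], self._gff())
        # (3 + 2 + 2) MB of tiling at 50 kb
        assert abs(len(got) - 140) <= 1

    def test_no_genes_raises(self):
        region = QTLRegion("2B", 0, 1, members=pd.DataFrame())
        with pytest.raises(ValueError):
            select_genes([region], pd.DataFrame())


class TestGoEnrichment:
    def test_exact_enrichment_and_zero_hit(self):
        ref = [f"g{i}" for i in range(100)]
        ann = pd.DataFrame({
            "gene_id": ref,
            "go_id": ["GO:X"] * 10 + ["GO:Y"] * 90})
        study = [f"g{i}" for i in range(10)]      # exactly the GO:X carriers
        out = go_enrichment(study, ann, ref).set_index("go_id")
        assert out.loc["GO:X", "fold_enrichment"] == pytest.approx(10.0)
        assert out.loc["GO:X", "p"] == pytest.approx(
            stats.hypergeom.sf(9, 100, 10, 10), rel=1e-6, abs=0)
        assert out.loc["GO:Y", "k"] == 0
        assert out.loc["GO:Y", "fold_enrichment"] == 0.0
        assert out.loc["GO:Y", "p"] == pytest.approx(1.0)

    def test_random_subset_calibration(self):
        rng = np.random.default_rng(21)
        ref = [f"g{i}" for i in range(400)]
        ann = pd.DataFrame({
            "gene_id": rng.choice(ref, 1200),
            "go_id": rng.choice([f"GO:{i}" for i in range(40)], 1200)})
        fracs = []
        for _ in range(10):
            study = rng.choice(ref, 60, replace=False)
            out = go_enrichment(study, ann, ref)
            fracs.append((out["p"] < 0.05).mean())
        assert np.mean(fracs) <= 0.10
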