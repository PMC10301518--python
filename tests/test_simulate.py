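import numpy as np
import pandas as pd
import pytest

import hapgwas as h
from hapgwas.ld import r2_matrix
from hapgwas.traits import derive_trait_table


class TestGenotypeSimulation:
    def test_determinism_bit_identical(self, small_cfg):
        a = h.simulate_genotypes(small_cfg)
        b = h.simulate_genotypes(small_cfg)
        assert np.array_equal(a.dosages, b.dosages, equal_nan=True)
        assert np.array_equal(a.pos, b.pos)

    def test_inbred_dosage_domain(self, small_panel):
        d = small_panel.dosages
        assert set(np.unique(d[~np.isnan(d)])) <= {0.0, 2.0}

    def test_founder_count_validation(self):
        with pytest.raises(ValueError):
            h.SimConfig(n_founder_haplotypes_per_block=1)

    def test_two_founders_give_perfect_dprime(self):
        cfg = h.SimConfig(n_lines=80, n_chromosomes=1, n_blocks_per_chrom=3,
                          chrom_length_bp=12_000_000, snps_per_block=(4, 4),
                          n_founder_haplotypes_per_block=2, missing_rate=0.0,
                          seed=5)
        panel = h.simulate_genotypes(cfg)
        for bt in panel.truth["blocks"]:
            idx = bt["snp_indices"]
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    s = h.pairwise_ld(panel.dosages[:, idx[a]],
                                      panel.dosages[:, idx[b]])
                    if s is not None:
                        assert s.d_prime == pytest.approx(1.0)

    def test_within_block_ld_exceeds_between(self, small_panel):
        X = np.where(np.isnan(small_panel.dosages), 1.0, small_panel.dosages)
        r2 = r2_matrix(X)
        blocks = small_panel.truth["blocks"]
        within, between = [], []
        for bi, bt in enumerate(blocks):
            ii = np.array(bt["snp_indices"])
            within.extend(r2[np.ix_(ii, ii)][np.triu_indices(len(ii), 1)])
            for other in blocks[bi + 1:]:
                jj = np.array(other["snp_indices"])
                between.extend(r2[np.ix_(ii, jj)].ravel())
        assert np.mean(within) > np.mean(between)

    def test_block_spans_below_cap(self, small_panel):
        for bt in small_panel.truth["blocks"]:
            assert bt["end_bp"] - bt["start_bp"] <= 1_000_000

    def test_subpop_divergence_shows_in_pc1(self):
        cfg = h.SimConfig(n_lines=300, n_chromosomes=3, n_blocks_per_chrom=40,
                          chrom_length_bp=100_000_000, subpop_count=2,
                          subpop_divergence=0.1, seed=9)
        panel = h.simulate_genotypes(cfg)
        pcs = h.compute_pca(np.where(np.isnan(panel.dosages), 1.0,
                                     panel.dosages), 2)
        lab = panel.truth["subpop"]
        r = np.corrcoef(pcs[:, 0], lab)[0, 1]
        assert abs(r) > 0.9


class TestPhenotypeSimulation:
    def test_timepoint_validation(self):
        with pytest.raises(ValueError):
            h.SimConfig(timepoints=(0, 5))

    def test_zero_genetics_zero_noise_flat_ssi(self, small_panel):
        cfg = h.SimConfig(
            n_lines=120, n_chromosomes=2, n_blocks_per_chrom=8,
            chrom_length_bp=40_000_000, snps_per_block=(4, 6), seed=11,
            heritability_targets={k: 0.0 for k in
                                  list(h.simulate.DEFAULT_H2)},
            trait_noise={"area": 0.0, "ion": 0.0, "biomass": 0.0,
                         "latent": 0.0},
            death_fraction=0.0)
        # no genetic variance, no noise: all salt slopes scale identically
        # and every accession sits exactly at the population-average response
        sim = h.simulate_phenotypes(small_panel, cfg)
        assert sim.truth.latents["susceptibility"].std() == pytest.approx(0.0)
        t = derive_trait_table(sim.observations)
        np.testing.assert_allclose(t["dSGR_SSI"], 1.0, atol=1e-8)

    def test_observation_invariants(self, small_sim):
        obs = small_sim.observations
        comp = ((obs.area_side_0deg + obs.area_side_90deg) / 2) ** 2 \
            * obs.area_top
        assert (obs[["area_side_0deg", "area_side_90deg", "area_top",
                     "nongreen_area"]] >= 0).all().all()
        assert (obs.nongreen_area <= comp + 1e-6).all()
        last_day = obs.day.max()
        assert obs.loc[obs.day < last_day, "dry_biomass"].isna().all()
        assert obs.loc[obs.day == last_day, "dry_biomass"].notna().all()

    def test_planted_qtl_variance_share(self, default_sim):
        cfg, panel, sim = default_sim
        t = derive_trait_table(sim.observations).reindex(
            [str(x) for x in panel.line_ids])
        y = t["dSGR_SSI"].to_numpy()
        d = sim.truth.qtl_dosages.iloc[:, 0].to_numpy()
        r2 = np.corrcoef(d, y)[0, 1] ** 2
        assert 0.05 <= r2 <= 0.15

    def test_salt_growth_vs_old_leaf_sodium(self, default_sim):
        cfg, panel, sim = default_sim
        t = derive_trait_table(sim.observations)
        r = t["dSGR_salt"].corr(t["Na_4th_salt"])
        assert -0.67 <= r <= -0.37

    def test_biomass_tracks_digital_area(self, default_sim):
        cfg, panel, sim = default_sim
        t = derive_trait_table(sim.observations)
        pooled = pd.concat([
            t[["endpoint_area_control", "BioM_control"]].set_axis(
                ["area", "bm"], axis=1),
            t[["endpoint_area_salt", "BioM_salt"]].set_axis(
                ["area", "bm"], axis=1)])
        assert pooled["area"].corr(pooled["bm"]) > 0.9

    def test_dead_fraction_dies_to_zero_area(self, default_sim):
        cfg, panel, sim = default_sim
        obs = sim.observations
        dead = sim.truth.dead_accessions
        assert len(dead) == round(cfg.death_fraction * cfg.n_lines)
        last = obs[(obs.accession.isin(dead)) & (obs.treatment == "salt")
                   & (obs.day == obs.day.max())]
        assert (last.area_side_0deg == 0).all()


class TestFixtures:
    def test_roundtrip_and_annotation_contracts(self, tmp_path, small_cfg,
                                                small_panel, small_sim):
        paths = h.write_fixtures(small_panel, small_sim, tmp_path, small_cfg,
                                 gene_spacing_bp=500_000)
        back = h.io.read_vcf(paths["vcf"])
        assert np.array_equal(back.dosages, small_panel.dosages,
                              equal_nan=True)
        assert np.array_equal(back.pos, small_panel.pos)
        genes = h.io.read_gff3_genes(paths["gff"])
        per_chrom = genes.groupby("chrom").size()
        expected = small_cfg.chrom_length_bp // 500_000
        assert (per_chrom == expected).all()
        ann = h.io.read_go_annotation(paths["go"])
        assert set(genes.gene_id) == set(ann.gene_id)  # every gene annotated
        assert ann.groupby("gene_id").size().min() >= 1

    def test_fixture_determinism(self, tmp_path, small_cfg, small_panel,
                                 small_sim):
        p1 = h.write_fixtures(small_panel, small_sim, tmp_path / "a", small_cfg)
        p2 = h.write_fixtures(small_panel, small_sim, tmp_path / "b", small_cfg)
        for k in ("vcf", "phenotypes", "go"):
            assert p1[k].read_bytes() == p2[k].read_bytes()
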