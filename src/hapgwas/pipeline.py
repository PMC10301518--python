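"""End-to-end orchestration: traits -> blocks -> scan -> stability -> QTL -> genes.

`run_pipeline` wires every stage with the published defaults (1 MB block
cap, 95% informative-pair rule, 1% hapallele MAF, 5 MB / r2 0.2 pruning,
4 PCs, h2 >= 0.2 gate, 5-fold x 20-repeat CV at -log10 p > 5 in > 50 runs,
alpha 0.05 over the block count, 4/8 MB QTL chaining, 2 MB gene flank, 2 kb
pad, gene alpha 0.001, GO alpha 0.05) and writes per-stage tables plus a
run manifest mirroring the headline counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .blocks import block_stats, build_hap_matrix, detect_blocks
from .genes import flag_significant_genes, gene_set_test, go_enrichment, select_genes
from .mlm import (MixedModelScan, compute_grm, compute_pca, heritability_gate,
                  ld_prune, mean_impute, reml_variance)
from .panel import SnpFilterParams, filter_snps
from .qtl import (allele_enrichment_test, categorize_traits,
                  cross_reference_adjacent, delineate_qtl, overlap_prior_qtl)
from .stability import (CvConfig, StabilitySelector, bonferroni_threshold,
                        stability_records)
from .traits import classify_tolerance, derive_trait_table, trait_correlations

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genotypes: str = ""
    phenotypes: str = ""
    gff: str = ""
    go: str = ""
    prior_qtl: str | None = None
    outdir: str = "hapgwas_out"
    traits: list[str] = field(default_factory=lambda: [
        "dSGR_SSI", "dSR_salt", "Na_4th_salt"])
    location: str = ""
    # marker QC
    min_call_rate: float = 0.60
    min_maf: float = 0.01
    max_het: float = 0.05
    # blocks
    block_max_span_bp: int = 1_000_000
    informative_fraction: float = 0.95
    min_hap_maf: float = 0.01
    ci_low_strong: float = 0.70
    ci_high_strong: float = 0.98
    ci_high_recomb: float = 0.90
    # scan
    prune_window_bp: int = 5_000_000
    prune_r2: float = 0.2
    n_pcs: int = 4
    min_h2: float = 0.2
    # stability
    cv_k: int = 5
    cv_repeats: int = 20
    logp_threshold: float = 5.0
    min_runs: int = 50
    alpha: float = 0.05
    # QTL and genes
    qtl_gap_bp: float = 4e6
    qtl_max_span_bp: float = 8e6
    gene_flank_bp: float = 2e6
    gene_pad_bp: int = 2_000
    gene_alpha: float = 0.001
    go_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        CvConfig(self.cv_k, self.cv_repeats, self.logp_threshold,
                 self.min_runs, self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_pipeline(config: PipelineConfig, panel=None, obs=None) -> dict:
    """Execute the full analysis; returns the result bundle as a dict.

    ``panel``/``obs`` may be passed in-memory (e.g. fresh from the
    generator); otherwise they are read from the configured paths.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        if panel is None:
            panel = hio.read_genotypes(config.genotypes)
        if obs is None:
            obs = hio.read_phenotypes(config.phenotypes)

        stage = "traits"
        table = derive_trait_table(obs, location=config.location)
        table = table.reindex([str(x) for x in panel.line_ids])
        corr, corr_n = trait_correlations(table)
        table.to_csv(out / "trait_table.csv")
        corr.to_csv(out / "trait_correlations.csv")

        stage = "snp_filter"
        fpanel, filter_report = filter_snps(panel, SnpFilterParams(
            config.min_call_rate, config.min_maf, config.max_het))

        stage = "blocks"
        blocks = detect_blocks(fpanel, config.block_max_span_bp,
                               config.ci_low_strong, config.ci_high_strong,
                               config.ci_high_recomb, config.informative_fraction)
        hap = build_hap_matrix(fpanel, blocks, config.min_hap_maf)
        hio.write_blocks_bed(hap.blocks, out / "blocks.tsv")
        hio.write_hap_matrix(hap, out / "hap_matrix.tsv")
        stats_blocks = block_stats(hap.blocks, hap)

        stage = "structure"
        pruned = ld_prune(fpanel, config.prune_window_bp, config.prune_r2)
        Z = mean_impute(pruned.dosages)
        Zc = Z - Z.mean(axis=0)
        sd = Zc.std(axis=0)
        Zs = Zc[:, sd > 0] / sd[sd > 0]
        pca_gram = Zs @ Zs.T
        K_scan = compute_grm(pruned.dosages, source="pruned-snp")
        K_greml = compute_grm(hap.dosages, source="hap-matrix")

        stage = "heritability"
        ids = [str(x) for x in panel.line_ids]
        h2 = {}
        for t in config.traits:
            y = table[t].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if ok.sum() < 30:
                raise ValueError(f"too few phenotyped lines for {t}")
            vc = reml_variance(y[ok], None, K_greml.matrix[np.ix_(ok, ok)])
            h2[t] = vc.h2
        kept_traits = heritability_gate(h2, config.min_h2)
        if not kept_traits:
            raise RuntimeError("no trait passed the heritability gate")

        stage = "stability"
        bonf = bonferroni_threshold(config.alpha, len(hap.blocks))
        col_table = hap.column_table()
        all_records = []
        selectors = {}
        for t in kept_traits:
            y = table[t].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            sel = StabilitySelector(
                kinship=K_scan.matrix[np.ix_(ok, ok)],
                pca_gram=pca_gram[np.ix_(ok, ok)], n_pcs=config.n_pcs,
                k=config.cv_k, repeats=config.cv_repeats,
                logp_threshold=config.logp_threshold, min_runs=config.min_runs,
                seed=config.seed).fit(hap.dosages[ok], y[ok])
            selectors[t] = sel
            all_records.append(stability_records(sel, t, col_table, bonf))
        records = pd.concat(all_records, ignore_index=True)
        records.to_csv(out / "stable_associations.tsv", sep="\t", index=False)

        stage = "qtl"
        regions = delineate_qtl(records, config.qtl_gap_bp, config.qtl_max_span_bp)
        qtl_table = categorize_traits(regions)
        prior = (hio.read_prior_qtl(config.prior_qtl)
                 if config.prior_qtl else pd.DataFrame())
        novelty = overlap_prior_qtl(regions, prior)
        qtl_table = qtl_table.merge(novelty[["qtl", "novel"]], on="qtl",
                                    how="left")
        qtl_table.to_csv(out / "qtl.tsv", sep="\t", index=False)
        cross_reference_adjacent(regions).to_csv(out / "qtl_adjacent.tsv",
                                                 sep="\t", index=False)

        ssi_col = f"{config.location}_dSGR_SSI" if config.location else "dSGR_SSI"
        groups = classify_tolerance(table[[ssi_col]])
        enrich = pd.DataFrame()
        if len(records):
            hap_df = pd.DataFrame(
                hap.dosages, index=ids,
                columns=col_table["hapallele"])
            cols = records["hapallele"].unique()
            enrich = allele_enrichment_test(hap_df[cols], groups)
            enrich.to_csv(out / "allele_enrichment.tsv", sep="\t", index=False)

        stage = "genes"
        gff = hio.read_gff3_genes(config.gff)
        genes = select_genes(regions, gff, config.gene_flank_bp)
        gene_records = []
        if len(genes):
            # auxiliary SNP-level scan restricted to candidate gene regions
            for t in kept_traits:
                y = table[t].to_numpy(dtype=float)
                ok = ~np.isnan(y)
                use = np.zeros(fpanel.n_snps, dtype=bool)
                for _, gn in genes.iterrows():
                    use |= ((fpanel.chrom == gn["chrom"])
                            & (fpanel.pos >= gn["start"] - config.gene_pad_bp)
                            & (fpanel.pos <= gn["end"] + config.gene_pad_bp))
                sub = fpanel.take_snps(np.where(use)[0])
                pcs = compute_pca(gram=pca_gram[np.ix_(ok, ok)],
                                  n_components=config.n_pcs)
                scan = MixedModelScan(kinship=K_scan.matrix[np.ix_(ok, ok)],
                                      covariates=pcs).fit(sub.dosages[ok], y[ok])
                snp_stats = pd.DataFrame({
                    "chrom": sub.chrom, "pos": sub.pos, "p": scan.pvalues_,
                    "trait": t})
                dose = sub.dosages[ok]
                for _, gn in genes.iterrows():
                    gene_records.append(gene_set_test(
                        gn, snp_stats, dose, config.gene_pad_bp))
        gene_table = flag_significant_genes(gene_records, config.gene_alpha)
        gene_table.to_csv(out / "gene_tests.tsv", sep="\t", index=False)

        stage = "go"
        go_table = pd.DataFrame()
        sig_genes = (gene_table[gene_table["significant"]]["gene_id"].unique()
                     if len(gene_table) else [])
        if len(sig_genes):
            ann = hio.read_go_annotation(config.go)
            go_table = go_enrichment(sig_genes, ann, ann["gene_id"].unique(),
                                     config.go_alpha)
            go_table.to_csv(out / "go_enrichment.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "counts": {
            "lines": int(panel.n_lines),
            "snps_input": int(panel.n_snps),
            "snps_filtered": filter_report["n_retained"],
            "blocks": len(hap.blocks),
            "hapalleles": int(hap.n_columns),
            "pruned_snps": int(pruned.n_snps),
            "traits_scanned": kept_traits,
            "stable_associations": int(len(records)),
            "bonferroni_pass": int(records["bonferroni_pass"].sum())
            if len(records) else 0,
            "qtl": len(regions),
            "genes_selected": int(len(genes)),
            "genes_tested": int(gene_table["p"].notna().sum())
            if len(gene_table) else 0,
            "genes_significant": int(gene_table["significant"].sum())
            if len(gene_table) else 0,
        },
        "heritability": h2,
        "bonferroni_threshold": bonf,
        "block_stats": stats_blocks,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return {
        "panel": panel, "trait_table": table, "correlations": corr,
        "blocks": hap.blocks, "hap_matrix": hap, "heritability": h2,
        "records": records, "regions": regions, "qtl_table": qtl_table,
        "gene_table": gene_table, "go_table": go_table,
        "enrichment": enrich, "manifest": manifest, "selectors": selectors,
    }
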