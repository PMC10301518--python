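"""Synthetic genotype panels and salt-response phenotypes.

The generator emulates the study design every downstream stage assumes:
inbred lines drawn from diverged subpopulations, LD organised in founder-
haplotype blocks no wider than 1 MB with free recombination between blocks,
planted small-effect hapallele QTL, and control/salt growth trajectories
whose derived traits carry a target correlation structure (salt growth rate
negatively correlated with senescence rate and old-leaf Na+, positively
with young-leaf K+/Na+) at configurable heritabilities.

All randomness flows from one master seed through named substreams, so a
config reproduces its panel and observations bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import HapBlock, HapMatrix, build_hap_matrix
from .panel import GenotypePanel

#: latent salt-response traits the generator models, in matrix order
LATENTS = ["dSGR_SSI", "dSR_salt", "Na_4th_salt", "KNa_2nd_salt", "Na_2nd_salt"]

#: default target Pearson correlations among the *measured* salt traits
#: (dSGR_salt row carries the published values; the dSGR_SSI latent is the
#: negated salt-growth deviate, handled internally)
DEFAULT_COR_TARGETS = np.array([
    #  growth  dSR    Na4    KNa2   Na2
    [1.00, -0.61, -0.52,  0.43, -0.20],
    [-0.61, 1.00,  0.45, -0.35,  0.25],
    [-0.52, 0.45,  1.00, -0.50,  0.40],
    [0.43, -0.35, -0.50,  1.00, -0.55],
    [-0.20, 0.25,  0.40, -0.55,  1.00],
])

DEFAULT_H2 = {"dSGR_SSI": 0.5, "dSR_salt": 0.4, "Na_4th_salt": 0.4,
              "KNa_2nd_salt": 0.4, "Na_2nd_salt": 0.3, "dSGR_control": 0.3}


@dataclass
class PlantedQTL:
    """A hapallele with a planted effect on one derived trait.

    ``effect_size`` is the fraction of phenotypic variance the hapallele
    dosage explains; per-trait effects must sum to less than that trait's
    heritability target.
    """
    chrom: str
    block_index: int
    hapallele_index: int
    affected_trait: str
    effect_size: float

    def __post_init__(self):
        if not 0 <= self.effect_size < 1:
            raise ValueError("effect_size must be in [0, 1)")
        if self.affected_trait not in LATENTS:
            raise ValueError(f"unknown trait {self.affected_trait!r}; "
                             f"one of {LATENTS}")


@dataclass
class SimConfig:
    n_lines: int = 500
    n_chromosomes: int = 5
    chrom_length_bp: int = 250_000_000
    n_blocks_per_chrom: int = 100
    snps_per_block: tuple[int, int] = (8, 12)
    n_founder_haplotypes_per_block: int = 4
    subpop_count: int = 3
    subpop_divergence: float = 0.10
    missing_rate: float = 0.01
    qtl_specs: list[PlantedQTL] = field(default_factory=list)
    trait_noise: dict = field(default_factory=lambda: {
        "area": 0.04, "ion": 0.05, "biomass": 0.05})
    heritability_targets: dict = field(default_factory=lambda: dict(DEFAULT_H2))
    trait_cor_targets: np.ndarray = field(
        default_factory=lambda: DEFAULT_COR_TARGETS.copy())
    #: imaging days after treatment (every second or third day over ~3 weeks)
    timepoints: tuple = (0, 3, 5, 7, 10, 12, 14, 17, 19, 21)
    replicates: int = 2
    #: total NaCl concentration applied in split doses, mM
    salt_dose_mM: tuple[int, ...] = (41, 42, 42)
    death_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.n_founder_haplotypes_per_block < 2:
            raise ValueError("need at least 2 founder haplotypes per block")
        if not 0 <= self.subpop_divergence < 1:
            raise ValueError("subpop_divergence must be in [0, 1)")
        C = np.asarray(self.trait_cor_targets, dtype=float)
        if C.shape != (len(LATENTS),) * 2 or not np.allclose(C, C.T):
            raise ValueError("trait_cor_targets must be a symmetric 5x5 matrix")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("trait_cor_targets needs a unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("trait_cor_targets must be positive semi-definite")
        for t, h in self.heritability_targets.items():
            if not 0 <= h <= 1:
                raise ValueError(f"h2 target for {t} outside [0, 1]")
        if len(self.timepoints) < 3:
            raise ValueError("need at least 3 imaging timepoints")
        tot = {}
        for q in self.qtl_specs:
            tot[q.affected_trait] = tot.get(q.affected_trait, 0.0) + q.effect_size
        for t, v in tot.items():
            if v >= self.heritability_targets.get(t, 0.0):
                raise ValueError(
                    f"planted effects on {t} ({v}) must sum below its h2 target")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _chrom_names(n: int) -> list[str]:
    return [f"{i // 3 + 1}{'ABD'[i % 3]}" for i in range(n)]


def _founder_haplotypes(rng: np.random.Generator, nf: int, L: int) -> np.ndarray:
    """Distinct founder haplotypes under an infinite-sites model.

    Each SNP arises once on a random founder genealogy (its carriers form a
    clade), so any within-block SNP pair shows at most three of the four
    two-locus haplotypes and |D'| = 1 among founders -- the structure the
    confidence-interval block caller is built to recover.
    """
    groups = [frozenset([i]) for i in range(nf)]
    clades = [set(g) for g in groups]
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        merged = groups[i] | groups[j]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
        groups.append(merged)
        if len(merged) < nf:
            clades.append(set(merged))
    for _ in range(200):
        H = np.zeros((nf, L), dtype=np.int8)
        for s in range(L):
            clade = clades[int(rng.integers(len(clades)))]
            H[list(clade), s] = 1
        if len({h.tobytes() for h in H}) == nf:
            return H
    raise RuntimeError("could not draw distinct founder haplotypes")


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Founder-haplotype mosaic panel of fully inbred lines.

    Within a block every line carries one of the founder haplotypes (no
    recombination); founder frequencies diverge across subpopulations by a
    Balding-Nichols-style Dirichlet draw; blocks recombine freely.  Block
    truth (spans, SNP indices, founder assignment per line) is stored on
    ``panel.truth`` for recovery tests.
    """
    rng = config.rng(1)
    n = config.n_lines
    subpop = rng.integers(0, config.subpop_count, size=n)
    alpha_scale = ((1.0 - config.subpop_divergence) / config.subpop_divergence
                   if config.subpop_divergence > 0 else None)

    slot = config.chrom_length_bp // config.n_blocks_per_chrom
    lo, hi = config.snps_per_block
    dose_cols, chroms, poss, blocks_truth = [], [], [], []
    snp_counter = 0
    for c in _chrom_names(config.n_chromosomes):
        for b in range(config.n_blocks_per_chrom):
            L = int(rng.integers(lo, hi + 1))
            nf = config.n_founder_haplotypes_per_block
            H = _founder_haplotypes(rng, nf, L)
            base = rng.dirichlet(np.full(nf, 3.0))
            if alpha_scale is None:
                freqs = np.tile(base, (config.subpop_count, 1))
            else:
                freqs = np.vstack([
                    rng.dirichlet(np.clip(base * alpha_scale, 1e-3, None))
                    for _ in range(config.subpop_count)])
            u = rng.random(n)
            cum = np.cumsum(freqs, axis=1)
            founder = (u[:, None] > cum[subpop]).sum(axis=1)
            G = 2.0 * H[founder]                       # (n, L) dosages in {0,2}
            span_max = int(min(800_000, max(100_000, slot - 1_050_000)))
            span = int(rng.integers(50_000, max(span_max, 50_001)))
            start = b * slot + int(rng.integers(0, max(slot - span - 1_050_000, 1)))
            if L > 2:
                inner = np.sort(rng.choice(
                    np.arange(start + 1, start + span), size=L - 2, replace=False))
                pos = np.concatenate([[start], inner, [start + span]])
            else:
                pos = np.array([start, start + span])
            dose_cols.append(G)
            chroms.extend([c] * L)
            poss.extend(pos.tolist())
            blocks_truth.append({
                "chrom": c, "block_index": b,
                "start_bp": int(start), "end_bp": int(start + span),
                "snp_indices": list(range(snp_counter, snp_counter + L)),
                "founder": founder,
                "founder_strings": ["".join("A" if a else "R" for a in h)
                                    for h in H],
            })
            snp_counter += L
    D = np.concatenate(dose_cols, axis=1).astype(float)
    if config.missing_rate > 0:
        mask = config.rng(2).random(D.shape) < config.missing_rate
        D[mask] = np.nan
    m = D.shape[1]
    return GenotypePanel(
        dosages=D,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        snp_ids=np.asarray([f"snp{i}" for i in range(m)], dtype=object),
        line_ids=np.asarray([f"L{i:04d}" for i in range(config.n_lines)],
                            dtype=object),
        truth={"blocks": blocks_truth, "subpop": subpop},
    )


def hap_matrix_from_truth(panel: GenotypePanel,
                          min_hap_maf: float = 0.01) -> HapMatrix:
    """Hap-matrix built on the generator's true block boundaries.

    Bypasses LD-based detection; used where the object under test is a
    downstream stage, not the block caller.
    """
    if panel.truth is None:
        raise ValueError("panel carries no simulation truth")
    blocks = [HapBlock(chrom=bt["chrom"], start_bp=bt["start_bp"],
                       end_bp=bt["end_bp"], snp_indices=np.array(bt["snp_indices"]))
              for bt in panel.truth["blocks"]]
    return build_hap_matrix(panel, blocks, min_hap_maf=min_hap_maf)


def _qtl_dosage(panel: GenotypePanel, q: PlantedQTL) -> np.ndarray:
    for bt in panel.truth["blocks"]:
        if bt["chrom"] == q.chrom and bt["block_index"] == q.block_index:
            if q.hapallele_index >= len(bt["founder_strings"]):
                raise ValueError("hapallele_index beyond founder count")
            return 2.0 * (bt["founder"] == q.hapallele_index)
    raise ValueError(f"planted QTL references unknown block "
                     f"{q.chrom}:{q.block_index}")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


@dataclass
class PhenotypeTruth:
    latents: pd.DataFrame          # accession x measured-trait-scale latents
    genetic_values: pd.DataFrame
    qtl_dosages: pd.DataFrame      # accession x planted-QTL dosage columns
    dead_accessions: list[str]


@dataclass
class PhenoSim:
    observations: pd.DataFrame
    truth: PhenotypeTruth


def simulate_phenotypes(panel: GenotypePanel, config: SimConfig) -> PhenoSim:
    """Plant-level observations under control and salt treatment.

    Control composite area grows linearly; the salt growth slope is the
    control slope scaled down by a genetically determined susceptibility;
    leaf ion traits share the same latent structure; a configurable
    fraction of the most susceptible accessions dies (salt area forced to 0
    from a random timepoint).
    """
    if len(config.timepoints) < 3:
        raise ValueError("slope unidentifiable with fewer than 3 timepoints")
    rng = config.rng(3)
    n = config.n_lines
    C = np.asarray(config.trait_cor_targets, dtype=float)
    chol = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))

    # polygenic scores with cross-trait correlation C, drawn on the centred
    # founder-haplotype (hapallele) dosage scale so the VanRaden GRM model
    # used downstream for GREML is correctly specified
    if panel.truth is None:
        raise ValueError("panel carries no simulation truth")
    fcols = []
    for bt in panel.truth["blocks"]:
        for f in range(len(bt["founder_strings"])):
            col = 2.0 * (bt["founder"] == f)
            if 0.0 < col.mean() < 2.0:
                fcols.append(col - col.mean())
    W = np.column_stack(fcols)
    m = W.shape[1]
    effects = rng.standard_normal((m, len(LATENTS))) @ chol.T / np.sqrt(m)
    g = _standardize(W @ effects)
    g_control = _standardize(W @ rng.standard_normal(m) / np.sqrt(m))
    # "latent" scales the non-genetic component of the accession latents
    # (1 = unit environmental variance; 0 = purely genetic latents)
    e = _standardize(rng.standard_normal((n, len(LATENTS))) @ chol.T) \
        * config.trait_noise.get("latent", 1.0)

    # planted hapallele effects replace part of the polygenic signal
    qtl_cols = {}
    per_trait_v: dict[str, float] = {}
    for q in config.qtl_specs:
        per_trait_v[q.affected_trait] = per_trait_v.get(q.affected_trait, 0) \
            + q.effect_size
    for ti, t in enumerate(LATENTS):
        h2 = config.heritability_targets[t]
        vtot = per_trait_v.get(t, 0.0)
        if vtot > 0:
            gq = np.zeros(n)
            D = []
            for q in config.qtl_specs:
                if q.affected_trait != t:
                    continue
                d = _qtl_dosage(panel, q)
                qtl_cols[f"{q.chrom}.b{q.block_index}.h{q.hapallele_index}"] = d
                D.append(_standardize(d))
                gq = gq + np.sqrt(q.effect_size / h2) * D[-1]
            # orthogonalise the polygenic part against the planted dosages so
            # each planted effect realises its nominal variance share
            Dm = np.column_stack(D)
            coef, *_ = np.linalg.lstsq(Dm, g[:, ti], rcond=None)
            g[:, ti] = (np.sqrt((h2 - vtot) / h2)
                        * _standardize(g[:, ti] - Dm @ coef) + gq)

    h2v = np.array([config.heritability_targets[t] for t in LATENTS])
    lat = np.sqrt(h2v) * g + np.sqrt(1 - h2v) * e   # (n, 5) standardized-ish

    z_growth, z_dsr, z_na4, z_kna2, z_na2 = lat.T
    h2c = config.heritability_targets.get("dSGR_control", 0.3)
    x_c = np.sqrt(h2c) * g_control + np.sqrt(1 - h2c) * rng.standard_normal(n)

    b_c = 19_500.0 * (1 + 0.08 * x_c)
    susc = np.clip(0.38 - 0.12 * z_growth, 0.02, 0.95)
    b_s = b_c * (1 - susc)
    sr_salt = np.clip(3_000.0 * (1 + 0.35 * z_dsr), 50.0, None)
    sr_ctrl = np.clip(300.0 * (1 + 0.10 * rng.standard_normal(n)), 10.0, None)
    na4_s = np.clip(400.0 * (1 + 0.45 * z_na4), 20.0, None)
    na2_s = np.clip(60.0 * (1 + 0.45 * z_na2), 5.0, None)
    kna2_s = np.clip(25.0 * (1 + 0.50 * z_kna2), 1.5, None)
    k2_s = kna2_s * na2_s
    k4_s = np.clip(250.0 * (1 + 0.20 * rng.standard_normal(n)), 20.0, None)
    na4_c = 25.0 * (1 + 0.2 * rng.standard_normal(n)).clip(0.3)
    na2_c = 12.0 * (1 + 0.2 * rng.standard_normal(n)).clip(0.3)
    k2_c = 1_500.0 * (1 + 0.1 * rng.standard_normal(n)).clip(0.5)
    k4_c = 1_200.0 * (1 + 0.1 * rng.standard_normal(n)).clip(0.5)

    n_dead = int(round(config.death_fraction * n))
    dead_idx = np.argsort(susc)[::-1][:n_dead] if n_dead else np.array([], int)
    dead = np.zeros(n, dtype=bool)
    dead[dead_idx] = True

    days = np.asarray(config.timepoints, dtype=float)
    sd_area = config.trait_noise.get("area", 0.04)
    sd_ion = config.trait_noise.get("ion", 0.05)
    sd_bm = config.trait_noise.get("biomass", 0.05)
    rows = []
    for i, acc in enumerate(panel.line_ids):
        for rep in range(config.replicates):
            for trt in ("control", "salt"):
                slope = b_c[i] if trt == "control" else b_s[i]
                sr = sr_ctrl[i] if trt == "control" else sr_salt[i]
                a0 = 30_000.0 * (1 + 0.10 * rng.standard_normal())
                top = 200.0 * (1 + 0.05 * rng.standard_normal())
                comp = (a0 + slope * days) * np.exp(
                    sd_area * rng.standard_normal(len(days)))
                comp = np.clip(comp, 0.0, None)
                ng = np.clip(sr * days * (1 + sd_ion * rng.standard_normal(len(days))),
                             0.0, comp)
                if trt == "salt" and dead[i]:
                    kd = int(rng.integers(3, len(days)))
                    comp[kd:] = 0.0
                    ng[kd:] = 0.0
                side = np.sqrt(comp / top)
                bm = 1e-5 * comp[-1] * (1 + sd_bm * rng.standard_normal())
                ion = (na2_c[i], na4_c[i], k2_c[i], k4_c[i]) if trt == "control" \
                    else (na2_s[i], na4_s[i], k2_s[i], k4_s[i])
                ion = tuple(v * (1 + sd_ion * rng.standard_normal()) for v in ion)
                for k, d in enumerate(days):
                    last = k == len(days) - 1
                    rows.append((
                        acc, rep, trt, d, side[k], side[k], top, ng[k],
                        bm if last else np.nan,
                        ion[0] if last else np.nan, ion[1] if last else np.nan,
                        ion[2] if last else np.nan, ion[3] if last else np.nan))
    obs = pd.DataFrame(rows, columns=[
        "accession", "replicate", "treatment", "day",
        "area_side_0deg", "area_side_90deg", "area_top", "nongreen_area",
        "dry_biomass", "na_2nd", "na_4th", "k_2nd", "k_4th"])

    acc_index = pd.Index(panel.line_ids, name="accession")
    truth = PhenotypeTruth(
        latents=pd.DataFrame({
            "dSGR_control": b_c, "dSGR_salt": b_s, "susceptibility": susc,
            "dSR_salt": sr_salt, "Na_4th_salt": na4_s, "Na_2nd_salt": na2_s,
            "KNa_2nd_salt": kna2_s}, index=acc_index),
        genetic_values=pd.DataFrame(g, index=acc_index, columns=LATENTS),
        qtl_dosages=pd.DataFrame(qtl_cols, index=acc_index),
        dead_accessions=[str(a) for a in panel.line_ids[dead]],
    )
    return PhenoSim(observations=obs, truth=truth)


# --------------------------------------------------------------------------
# fixture writing

def write_fixtures(panel: GenotypePanel, sim: PhenoSim, outdir: str | Path,
                   config: SimConfig, gene_spacing_bp: int = 50_000,
                   n_go_terms: int = 50) -> dict[str, Path]:
    """Write VCF + phenotype CSV + synthetic gene GFF3 + GO TSV + truth JSON.

    Genes are tiled every ``gene_spacing_bp`` along each chromosome (so the
    gene count per chromosome is floor(length / spacing)); every gene gets
    1-3 GO terms from a fixed universe.  All files round-trip through the
    package's own readers.
    """
    from . import io as hio
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.csv",
        "gff": out / "genes.gff3",
        "go": out / "gene_go.tsv",
        "truth": out / "truth.json",
    }
    hio.write_vcf(panel, paths["vcf"])
    sim.observations.to_csv(paths["phenotypes"], index=False)

    rng = config.rng(4)
    genes = []
    for c in _chrom_names(config.n_chromosomes):
        n_genes = config.chrom_length_bp // gene_spacing_bp
        for i in range(n_genes):
            start = i * gene_spacing_bp
            genes.append((c, start, start + 3_000, f"GENE.{c}.{i:05d}"))
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for c, s, e2, gid in genes:
            fh.write(f"{c}\thapgwas_sim\tgene\t{s + 1}\t{e2}\t.\t+\t.\t"
                     f"ID={gid}\n")
    terms = [f"GO:{i + 1:07d}" for i in range(n_go_terms)]
    with open(paths["go"], "w") as fh:
        for _, _, _, gid in genes:
            k = int(rng.integers(1, 4))
            for t in rng.choice(terms, size=k, replace=False):
                fh.write(f"{gid}\t{t}\n")
    qtl_truth = []
    for q in config.qtl_specs:
        bt = next(b for b in panel.truth["blocks"]
                  if b["chrom"] == q.chrom and b["block_index"] == q.block_index)
        qtl_truth.append({
            "chrom": q.chrom, "block_index": q.block_index,
            "hapallele_index": q.hapallele_index,
            "affected_trait": q.affected_trait, "effect_size": q.effect_size,
            "start_bp": bt["start_bp"], "end_bp": bt["end_bp"],
        })
    truth_obj = {
        "qtl": qtl_truth,
        "dead_accessions": sim.truth.dead_accessions,
        "seed": config.seed,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_obj, fh, indent=1)
    return paths
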