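import numpy as np
import pytest
from hypothesis import settings

import hapgwas as h

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg():
    """Small but fully structured simulation: 120 lines, 2 chromosomes."""
    return h.SimConfig(n_lines=120, n_chromosomes=2, n_blocks_per_chrom=8,
                       chrom_length_bp=40_000_000, snps_per_block=(4, 6),
                       seed=11)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return h.simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def small_sim(small_cfg, small_panel):
    return h.simulate_phenotypes(small_panel, small_cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The generator's default study conditions with two planted QTL."""
    cfg = h.SimConfig(seed=42, qtl_specs=[
        h.PlantedQTL("1A", 10, 0, "dSGR_SSI", 0.10),
        h.PlantedQTL("2B", 40, 1, "dSGR_SSI", 0.08)])
    panel = h.simulate_genotypes(cfg)
    sim = h.simulate_phenotypes(panel, cfg)
    return cfg, panel, sim


def random_ld_panel(rng, n_lines=60, max_snps=12, span_bp=2_000_000):
    """Random inbred panel with block-ish LD for oracle comparisons."""
    m = int(rng.integers(3, max_snps + 1))
    n_groups = int(rng.integers(1, 4))
    bounds = np.sort(rng.choice(np.arange(1, m), size=n_groups - 1,
                                replace=False)) if n_groups > 1 else []
    group_of = np.zeros(m, dtype=int)
    for g, b in enumerate(bounds):
        group_of[b:] = g + 1
    X = np.empty((n_lines, m))
    for g in range(n_groups):
        cols = np.where(group_of == g)[0]
        nf = int(rng.integers(2, 5))
        H = (rng.random((nf, len(cols))) < rng.uniform(0.2, 0.8)).astype(float)
        founder = rng.integers(0, nf, n_lines)
        X[:, cols] = 2.0 * H[founder]
    noise = rng.random(X.shape) < 0.05
    X[noise] = 2.0 - X[noise]
    X[rng.random(X.shape) < 0.03] = np.nan
    pos = np.sort(rng.choice(np.arange(span_bp), size=m, replace=False))
    return h.GenotypePanel(
        X, np.array(["1"] * m, dtype=object), pos,
        np.array([f"s{i}" for i in range(m)], dtype=object),
        np.array([f"l{i}" for i in range(n_lines)], dtype=object))
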