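"""QTL delineation from stable associations, trait categories, enrichment.

Associations on a chromosome are chained while the gap between neighbouring
hapallele midpoints is at most 4 MB; a chain may extend to a total span of
8 MB, beyond which it is split recursively at its largest internal gap
(leftmost on ties).  Region names use whole-MB bounds, e.g. QTL.2B.24_27.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, floor

import numpy as np
import pandas as pd
from scipy import stats

TRAIT_CATEGORIES = {"growth", "leaf_ion", "stress_index"}


@dataclass
class QTLRegion:
    chrom: str
    start_bp: float
    end_bp: float
    members: pd.DataFrame = field(repr=False)   # stable-association rows
    trait_categories: set = field(default_factory=set)

    @property
    def name(self) -> str:
        s = floor(self.start_bp / 1e6)
        e = ceil(self.end_bp / 1e6)
        label = str(s) if e - s <= 1 else f"{s}_{e}"
        return f"QTL.{self.chrom}.{label}"

    @property
    def n_associations(self) -> int:
        return len(self.members)

    @property
    def span_bp(self) -> float:
        return self.end_bp - self.start_bp


def _split_chain(idx: np.ndarray, pos: np.ndarray,
                 max_span: float) -> list[np.ndarray]:
    """Recursively split an index chain at its largest gap until spans fit."""
    if pos[idx[-1]] - pos[idx[0]] <= max_span or len(idx) == 1:
        return [idx]
    gaps = np.diff(pos[idx])
    cut = int(np.argmax(gaps))  # argmax takes the leftmost maximal gap
    return (_split_chain(idx[:cut + 1], pos, max_span)
            + _split_chain(idx[cut + 1:], pos, max_span))


def delineate_qtl(associations: pd.DataFrame, gap_bp: float = 4e6,
                  max_span_bp: float = 8e6) -> list[QTLRegion]:
    """Merge stable associations into QTL regions.

    ``associations`` needs columns chrom, midpoint_bp (plus anything to
    carry through, e.g. trait, hapallele).  Every association lands in
    exactly one region.
    """
    regions: list[QTLRegion] = []
    for c, g in associations.groupby("chrom", sort=True):
        g = g.sort_values("midpoint_bp", kind="stable")
        pos = g["midpoint_bp"].to_numpy(dtype=float)
        chain_bounds = np.where(np.diff(pos) > gap_bp)[0]
        start = 0
        chains = []
        for cut in chain_bounds:
            chains.append(np.arange(start, cut + 1))
            start = cut + 1
        chains.append(np.arange(start, len(pos)))
        for chain in chains:
            for piece in _split_chain(chain, pos, max_span_bp):
                lo, hi = pos[piece[0]], pos[piece[-1]]
                sel = g.iloc[piece]
                regions.append(QTLRegion(chrom=str(c), start_bp=float(lo),
                                         end_bp=float(hi),
                                         members=sel.reset_index(drop=True)))
    regions.sort(key=lambda r: (r.chrom, r.start_bp))
    return regions


def trait_category(trait: str) -> str:
    """Registry lookup: growth-related, leaf salt ion, or salt stress index."""
    t = trait.split("_", 1)[1] if trait[:2] in ("B_", "H_") else trait
    if t.endswith("_SSI"):
        return "stress_index"
    base = t.split("_")[0]
    if base in ("dSGR", "dSR", "BioM", "biomass", "endpoint"):
        return "growth"
    if base in ("Na", "K", "KNa"):
        return "leaf_ion"
    raise ValueError(f"unknown trait id {trait!r}")


def categorize_traits(regions: list[QTLRegion]) -> pd.DataFrame:
    """Label every region with the union of its member trait categories."""
    rows = []
    for r in regions:
        cats = {trait_category(t) for t in r.members["trait"].unique()}
        r.trait_categories = cats
        rows.append({"qtl": r.name, "chrom": r.chrom,
                     "start_bp": r.start_bp, "end_bp": r.end_bp,
                     "n_associations": r.n_associations,
                     "categories": ",".join(sorted(cats)),
                     "all_three_categories": cats == TRAIT_CATEGORIES})
    return pd.DataFrame(rows, columns=["qtl", "chrom", "start_bp", "end_bp",
                                       "n_associations", "categories",
                                       "all_three_categories"])


def allele_enrichment_test(hap_dosages: pd.DataFrame,
                           groups: pd.Series,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-hapallele Fisher exact test of carrier status vs tolerance group.

    2x2 table: carrier/non-carrier x tolerant/susceptible, two-sided; a
    Bonferroni-adjusted summary flag is reported over the tested hapalleles.
    Hapalleles with an empty group are skipped.
    """
    keep = groups.isin(["tolerant", "susceptible"])
    groups = groups[keep]
    rows = []
    for col in hap_dosages.columns:
        d = hap_dosages.loc[groups.index, col]
        ok = d.notna()
        if ok.sum() == 0:
            continue
        carrier = d[ok] > 0
        tol = groups[ok] == "tolerant"
        table = [[int((carrier & tol).sum()), int((carrier & ~tol).sum())],
                 [int((~carrier & tol).sum()), int((~carrier & ~tol).sum())]]
        if sum(table[0]) + sum(table[1]) == 0 or tol.sum() == 0 or (~tol).sum() == 0:
            continue
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"hapallele": col, "carriers_tolerant": table[0][0],
                     "carriers_susceptible": table[0][1], "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["significant_bonferroni"] = out["p"] < alpha / len(out)
    return out


def overlap_prior_qtl(regions: list[QTLRegion], prior: pd.DataFrame,
                      window_bp: float = 10e6) -> pd.DataFrame:
    """Novelty flags: a region is *known* iff a prior interval on the same
    chromosome lies within ``window_bp`` edge-to-edge, else *novel*."""
    if len(prior) and not {"chrom", "start", "end"}.issubset(prior.columns):
        raise ValueError("prior QTL table needs chrom, start, end columns")
    rows = []
    for r in regions:
        known = False
        if len(prior):
            same = prior[prior["chrom"].astype(str) == r.chrom]
            for _, p in same.iterrows():
                gap = max(p["start"] - r.end_bp, r.start_bp - p["end"], 0.0)
                if gap <= window_bp:
                    known = True
                    break
        rows.append({"qtl": r.name, "chrom": r.chrom, "start_bp": r.start_bp,
                     "end_bp": r.end_bp, "novel": not known})
    return pd.DataFrame(rows, columns=["qtl", "chrom", "start_bp", "end_bp",
                                       "novel"])


def cross_reference_adjacent(regions: list[QTLRegion],
                             window_bp: float = 20e6) -> pd.DataFrame:
    """Pairs of distinct QTL on a chromosome closer than 20 MB edge-to-edge;
    reported as possibly the same locus, never merged."""
    rows = []
    by_chrom: dict[str, list[QTLRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for c, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start_bp)
        for a, b in zip(rs, rs[1:]):
            gap = b.start_bp - a.end_bp
            if 0 <= gap < window_bp:
                rows.append({"chrom": c, "qtl_a": a.name, "qtl_b": b.name,
                             "gap_bp": float(gap)})
    return pd.DataFrame(rows)
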