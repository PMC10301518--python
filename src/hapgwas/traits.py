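"""Derivation of digital and index traits from plant-level observations.

Measured series (side/top pixel areas, non-green areas) become composite
shoot area, per-day growth (dSGR) and senescence (dSR) slopes; endpoint
biomass and leaf Na+/K+ concentrations become accession BLUEs; salt
susceptibility indices (SSI) compare the salt response of each accession to
the population-average response; tolerance groups are assigned from SSI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: observation CSV schema (one row per plant x timepoint)
OBS_COLUMNS = [
    "accession", "replicate", "treatment", "day",
    "area_side_0deg", "area_side_90deg", "area_top", "nongreen_area",
    "dry_biomass", "na_2nd", "na_4th", "k_2nd", "k_4th",
]

#: base traits for which an SSI column is derived
SSI_BASE_TRAITS = ["dSGR", "BioM", "Na_2nd", "Na_4th", "K_2nd", "K_4th",
                   "KNa_2nd", "KNa_4th"]


def digital_shoot_area(area_side_0deg, area_side_90deg, area_top,
                       squared_side: bool = True):
    """Composite digital shoot area: (mean of the two side views)^2 x top view.

    The squared side-view term follows the published composite-area formula
    and behaves like a volume proxy; ``squared_side=False`` gives the plain
    (mean side) x top product for users who read the squaring as a typo.
    All areas must be non-negative.
    """
    s0 = np.asarray(area_side_0deg, dtype=float)
    s90 = np.asarray(area_side_90deg, dtype=float)
    top = np.asarray(area_top, dtype=float)
    if np.any(s0 < 0) or np.any(s90 < 0) or np.any(top < 0):
        raise ValueError("pixel areas must be non-negative")
    side = (s0 + s90) / 2.0
    return (side ** 2 if squared_side else side) * top


def _ols_slope(days: np.ndarray, values: np.ndarray) -> float:
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(days) < 3:
        raise ValueError("need at least 3 timepoints for a slope")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    xc = days - days.mean()
    denom = float(np.sum(xc * xc))
    if denom == 0:
        raise ValueError("all days identical; slope unidentifiable")
    return float(np.sum(xc * (values - values.mean())) / denom)


def growth_rate(series) -> float:
    """OLS slope (area per day) of composite shoot area on day, one plant."""
    days, vals = zip(*series)
    return _ols_slope(np.asarray(days), np.asarray(vals))


def senescence_rate(series) -> float:
    """OLS slope (area per day) of non-green pixel area on day, one plant."""
    return growth_rate(series)


def ssi(T_t, T_c, mu_t, mu_c):
    """Salt susceptibility index (1 - T_t/T_c) / (1 - mu_t/mu_c).

    0 means no response, 1 the population-average response.  Dead plants are
    passed with T_t = 0 (a 100% loss).  Undefined combinations (zero control
    value, population means equal) yield NaN with a log record rather than an
    exception.
    """
    T_t = np.asarray(T_t, dtype=float)
    T_c = np.asarray(T_c, dtype=float)
    scalar = T_t.ndim == 0
    T_t, T_c = np.atleast_1d(T_t), np.atleast_1d(T_c)
    out = np.full(T_t.shape, np.nan)
    if mu_c == 0 or mu_t / mu_c == 1.0:
        log.warning("SSI undefined: population mean ratio term is zero")
    else:
        ok = T_c != 0
        if np.any(~ok):
            log.warning("SSI undefined for %d entries with zero control value",
                        int(np.sum(~ok)))
        out[ok] = (1.0 - T_t[ok] / T_c[ok]) / (1.0 - mu_t / mu_c)
    return float(out[0]) if scalar else out


def plant_slopes(obs: pd.DataFrame) -> pd.DataFrame:
    """Per-plant dSGR, dSR, endpoint biomass/ion values from the tidy table.

    A plant whose final composite area is zero is flagged dead; its growth
    rate is set to 0 (the dead-plant 100%-loss convention), and all growth
    rates are floored at 0.  The senescence slope of a dead plant uses only
    the timepoints while it was alive (composite area > 0) and is missing
    when fewer than 3 such timepoints exist.
    """
    obs = obs.copy()
    obs["composite"] = digital_shoot_area(
        obs["area_side_0deg"], obs["area_side_90deg"], obs["area_top"])
    rows = []
    for (acc, rep, trt), g in obs.groupby(["accession", "replicate", "treatment"],
                                          sort=True):
        g = g.sort_values("day")
        days = g["day"].to_numpy(dtype=float)
        dead = g["composite"].iloc[-1] == 0
        dsgr = 0.0 if dead else max(_ols_slope(days, g["composite"].to_numpy()), 0.0)
        if dead:
            alive = g["composite"].to_numpy() > 0
            dsr = (_ols_slope(days[alive], g["nongreen_area"].to_numpy()[alive])
                   if alive.sum() >= 3 else np.nan)
        else:
            dsr = _ols_slope(days, g["nongreen_area"].to_numpy())
        last = g.iloc[-1]
        rows.append({
            "accession": acc, "replicate": rep, "treatment": trt,
            "dSGR": dsgr, "dSR": dsr, "dead": bool(dead),
            "BioM": last["dry_biomass"],
            "Na_2nd": last["na_2nd"], "Na_4th": last["na_4th"],
            "K_2nd": last["k_2nd"], "K_4th": last["k_4th"],
            "endpoint_area": last["composite"],
        })
    df = pd.DataFrame(rows)
    df["KNa_2nd"] = df["K_2nd"] / df["Na_2nd"].replace(0, np.nan)
    df["KNa_4th"] = df["K_4th"] / df["Na_4th"].replace(0, np.nan)
    return df


def compute_blues(values: pd.DataFrame, trait_cols: list[str],
                  batch: str | None = None) -> pd.DataFrame:
    """Accession BLUEs per treatment from a fixed-accession-effect model.

    With a balanced design and no batch covariate this is the replicate
    mean; with ``batch`` naming a column, a two-way fixed-effects least
    squares fit removes the batch term and the BLUE is the accession least
    squares mean.  Accessions with no observations for a treatment are
    missing with a warning.
    """
    out = {}
    for trt, g in values.groupby("treatment"):
        accs = pd.Categorical(g["accession"])
        A = pd.get_dummies(accs, dtype=float).to_numpy()
        design = [A]
        if batch is not None:
            B = pd.get_dummies(pd.Categorical(g[batch]), dtype=float,
                               drop_first=True).to_numpy()
            design.append(B)
        Xd = np.column_stack(design)
        blues = {}
        for t in trait_cols:
            yv = g[t].to_numpy(dtype=float)
            ok = ~np.isnan(yv)
            coef, *_ = np.linalg.lstsq(Xd[ok], yv[ok], rcond=None)
            est = coef[: A.shape[1]].astype(float)
            # least-squares mean: accession effect at average batch level
            if batch is not None:
                nb = Xd.shape[1] - A.shape[1]
                est = est + float(np.mean(Xd[ok, A.shape[1]:] @ coef[A.shape[1]:])) \
                    if nb else est
            seen = pd.Series(g.loc[ok, "accession"]).unique()
            blues[t] = pd.Series(est, index=accs.categories).where(
                pd.Index(accs.categories).isin(seen))
        out[trt] = pd.DataFrame(blues)
    missing = [a for trt, df in out.items() for a in df.index[df.isna().all(axis=1)]]
    if missing:
        log.warning("accessions with no observations in a treatment: %s", missing)
    return pd.concat(out, axis=1)  # columns: (treatment, trait)


def derive_trait_table(obs: pd.DataFrame, location: str = "") -> pd.DataFrame:
    """Full accession x trait table: BLUEs per treatment plus SSI columns.

    Column names follow the ``<prefix><trait>_<treatment>`` convention
    (e.g. ``B_dSGR_salt``) plus ``<prefix><trait>_SSI``; dSR is reported
    under salt only.  Dead plants enter SSI with a zero treatment value and
    the resulting SSI is capped at the largest SSI among surviving
    accessions.
    """
    prefix = f"{location}_" if location else ""
    per_plant = plant_slopes(obs)
    trait_cols = ["dSGR", "dSR", "BioM", "Na_2nd", "Na_4th", "K_2nd", "K_4th",
                  "KNa_2nd", "KNa_4th", "endpoint_area"]
    blues = compute_blues(per_plant, trait_cols)
    table = pd.DataFrame(index=blues.index)
    for trt in ("control", "salt"):
        if trt not in blues.columns.get_level_values(0):
            continue
        for t in trait_cols:
            if t == "dSR" and trt == "control":
                continue
            table[f"{prefix}{t}_{trt}"] = blues[(trt, t)]
    dead_share = per_plant[per_plant["treatment"] == "salt"].groupby(
        "accession")["dead"].mean().reindex(table.index).fillna(0.0)
    for t in SSI_BASE_TRAITS:
        ct, st = f"{prefix}{t}_control", f"{prefix}{t}_salt"
        if ct not in table or st not in table:
            continue
        T_c = table[ct].to_numpy()
        T_t = table[st].to_numpy()
        mu_t, mu_c = np.nanmean(T_t), np.nanmean(T_c)
        vals = ssi(np.where(np.isnan(T_t), np.nan, T_t), T_c, mu_t, mu_c)
        if t == "dSGR":
            alive = dead_share.to_numpy() == 0
            if np.any(~alive) and np.any(alive):
                cap = np.nanmax(vals[alive])
                vals = np.minimum(vals, cap)
        table[f"{prefix}{t}_SSI"] = vals
    return table


def classify_tolerance(ssi_by_location: pd.DataFrame,
                       tolerant_below: float = 1.0,
                       susceptible_above: float = 1.5) -> pd.Series:
    """Tolerance groups from SSI at one or more locations.

    tolerant iff SSI < 1.0 at every observed location; susceptible iff
    SSI > 1.5 at every location; otherwise moderate.  Accessions missing an
    SSI value at any location are unclassified.
    """
    df = pd.DataFrame(ssi_by_location)
    labels = []
    for _, row in df.iterrows():
        if row.isna().any():
            labels.append("unclassified")
        elif (row < tolerant_below).all():
            labels.append("tolerant")
        elif (row > susceptible_above).all():
            labels.append("susceptible")
        else:
            labels.append("moderate")
    return pd.Series(labels, index=df.index, name="tolerance_group")


def trait_correlations(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations and the n used per pair.

    Constant traits (zero variance) are reported as missing.
    """
    r = table.corr(method="pearson", min_periods=3)
    notna = table.notna().astype(int)
    n = pd.DataFrame(notna.T.to_numpy() @ notna.to_numpy(),
                     index=table.columns, columns=table.columns)
    sd = table.std()
    const = sd[sd == 0].index
    r.loc[const, :] = np.nan
    r.loc[:, const] = np.nan
    return r, n
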