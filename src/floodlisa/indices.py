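"""Tract-level analysis variables.

Implements every variable entering the spatial analysis:

* the Index of Concentration at the Extremes, ICE = (A − P) / T, in three
  variants — income (households ≤ $25k vs ≥ $125k), race (Black or
  non-white-Hispanic vs white residents), and the race × income cross —
  with the sign-inversion that makes *high* values mean *high inequality*;
* proportions of low (FF ≤ 2), moderate (FF 3–6) and high (FF ≥ 7) flood-risk
  properties per tract, plus single-level proportions (FF exactly 7/8/9/10)
  for sensitivity runs;
* a grouped-data Gini coefficient over household income brackets;
* the Index of Dissimilarity D = ½ Σ_k |b_k/B − w_k/W| computed over tract
  subunits within enclosing regions;
* prevalence passthrough.

Missing data (zero population, zero properties) is carried as NaN and
excluded downstream with a logged count — never imputed as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IndexVector", "ice", "invert", "flood_risk_proportions",
    "flood_risk_level_proportion", "gini_grouped", "dissimilarity_index",
    "compute_index_table", "FF_LOW_MAX", "FF_HIGH_MIN",
]

logger = logging.getLogger(__name__)

FF_LOW_MAX = 2    # FloodFactor ≤ 2 → low risk
FF_HIGH_MIN = 7   # FloodFactor ≥ 7 → high risk

#: Valuation of the open-top income bracket: 1.5 × its lower bound.
OPEN_TOP_FACTOR = 1.5


@dataclass
class IndexVector:
    """One named tract-level variable ready for LISA."""

    name: str
    values: np.ndarray
    inverted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def ice(deprived: float, privileged: float, total: float) -> float:
    """Index of Concentration at the Extremes.

    The canonical formula (A − P)/T contrasts the privileged extreme A
    against the deprived extreme P within total T, so the score is −1 when
    the whole population sits in the deprived extreme (100% nonwhite or
    low-income) and +1 when it is entirely privileged (100% white and
    affluent). Arguments here are named by group role to keep callers
    honest about which count is which.
    """
    if total <= 0:
        raise ValueError("ICE undefined for zero total (T = 0)")
    if deprived < 0 or privileged < 0 or deprived + privileged > total:
        raise ValueError("ICE requires non-negative extremes summing to at most the total")
    return (privileged - deprived) / total


def invert(iv: IndexVector) -> IndexVector:
    """Multiply an index by −1 so higher values mean greater inequality.

    Raises on double inversion — the flag exists precisely so the LISA
    stage can trust the sign convention.
    """
    if iv.inverted:
        raise ValueError(f"index {iv.name!r} is already inverted")
    return IndexVector(name=iv.name, values=-iv.values, inverted=True)


def _as_scores(ff_scores) -> np.ndarray:
    s = np.asarray(list(ff_scores), dtype=int)
    if s.size and (s.min() < 1 or s.max() > 10):
        raise ValueError("FloodFactor scores must lie in 1..10")
    return s


def flood_risk_proportions(ff_scores):
    """(p_low, p_moderate, p_high) shares of a tract's property scores.

    Low is FF ≤ 2, moderate FF 3–6, high FF ≥ 7; the three shares sum to 1.
    A tract with no properties yields ``(nan, nan, nan)`` — flagged missing,
    not zero.
    """
    s = _as_scores(ff_scores)
    if s.size == 0:
        return (float("nan"),) * 3
    n = s.size
    p_low = float((s <= FF_LOW_MAX).sum()) / n
    p_high = float((s >= FF_HIGH_MIN).sum()) / n
    return p_low, 1.0 - p_low - p_high, p_high


def flood_risk_level_proportion(ff_scores, level: int) -> float:
    """Share of properties with FloodFactor exactly ``level`` (7..10)."""
    if level not in (7, 8, 9, 10):
        raise ValueError("sensitivity levels are FF 7, 8, 9 or 10")
    s = _as_scores(ff_scores)
    if s.size == 0:
        return float("nan")
    return float((s == level).sum()) / s.size


def gini_grouped(bracket_counts, bracket_bounds) -> float:
    """Gini coefficient from grouped (bracketed) income counts.

    Uses the Lorenz-curve trapezoid estimator with each bracket valued at
    its midpoint; an open-top bracket (upper bound ``None``) is valued at
    ``OPEN_TOP_FACTOR`` × its lower bound. Returns a value in [0, 1).
    """
    counts = np.asarray(bracket_counts, dtype=float)
    if counts.size != len(bracket_bounds):
        raise ValueError("counts and brackets length mismatch")
    if np.any(counts < 0):
        raise ValueError("negative bracket count")
    total = counts.sum()
    if total <= 0:
        raise ValueError("Gini undefined when all bracket counts are zero")
    mids = np.array(
        [
            (lo + hi) / 2.0 if hi is not None else OPEN_TOP_FACTOR * lo
            for lo, hi in bracket_bounds
        ]
    )
    income = counts * mids
    if income.sum() == 0:  # everyone in a zero-income bracket
        return 0.0
    pop_cum = np.concatenate([[0.0], np.cumsum(counts) / total])
    inc_cum = np.concatenate([[0.0], np.cumsum(income) / income.sum()])
    # area under Lorenz curve by trapezoids
    area = float(np.sum((pop_cum[1:] - pop_cum[:-1]) * (inc_cum[1:] + inc_cum[:-1])) / 2.0)
    return 1.0 - 2.0 * area


def dissimilarity_index(group_a_counts, group_b_counts) -> float:
    """Index of Dissimilarity over subunits: ½ Σ_k |a_k/A − b_k/B|.

    The share of either group that would need to relocate across subunits
    for the two distributions to be even; in [0, 1].
    """
    a = np.asarray(group_a_counts, dtype=float)
    b = np.asarray(group_b_counts, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need >= 2 aligned subunits")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("negative subunit count")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("a group has zero total across subunits")
    return float(0.5 * np.abs(a / a.sum() - b / b.sum()).sum())


# ---------------------------------------------------------------------------
# table-level assembly
# ---------------------------------------------------------------------------

_FF_COLS = [f"ff_count_{lev}" for lev in range(1, 11)]


def _region_labels(df: pd.DataFrame) -> pd.Series:
    """Enclosing region per tract for the dissimilarity index.

    Uses an explicit ``region`` column when present; otherwise splits the
    study area into quadrants ("synthetic counties") at the median tract
    centroid, so D has subunits to aggregate over.
    """
    if "region" in df.columns:
        return df["region"].astype(str)
    if {"row", "col"}.issubset(df.columns):
        xs, ys = df["col"].to_numpy(float), df["row"].to_numpy(float)
    else:
        cents = [g.centroid for g in df["geometry"]]
        xs = np.array([c.x for c in cents])
        ys = np.array([c.y for c in cents])
    ew = np.where(xs < np.median(xs), "W", "E")
    ns = np.where(ys < np.median(ys), "S", "N")
    return pd.Series([f"{a}{b}" for a, b in zip(ns, ew)], index=df.index)


def compute_index_table(df: pd.DataFrame, income_brackets=None) -> pd.DataFrame:
    """Augment a tract table with every analysis variable.

    Adds inverted ICE columns (``ice_income``, ``ice_race``,
    ``ice_race_income``), flood-risk proportions (``p_flood_low/mod/high``),
    per-level shares (``p_ff7`` ... ``p_ff10``), ``gini`` and ``iod``.
    Tracts with zero totals or zero properties receive NaN and are counted
    in the log.
    """
    out = df.copy()
    if income_brackets is None:
        income_brackets = df.attrs.get("income_brackets")

    for variant in ("income", "race", "race_income"):
        a = df[f"ice_{variant}_a"].to_numpy(float)
        p = df[f"ice_{variant}_p"].to_numpy(float)
        t = df[f"ice_{variant}_t"].to_numpy(float)
        vals = np.full(len(df), np.nan)
        ok = t > 0
        vals[ok] = (p[ok] - a[ok]) / t[ok]  # raw score: −1 = all deprived
        n_missing = int((~ok).sum())
        if n_missing:
            logger.warning("ice_%s: %d tracts with zero total marked missing", variant, n_missing)
        # stored post-inversion: high = high inequality, matching the HH reading
        out[f"ice_{variant}"] = -vals
        out[f"ice_{variant}_raw"] = vals

    ff = df[_FF_COLS].to_numpy(float)
    n_props = ff.sum(axis=1)
    empty = n_props == 0
    if empty.any():
        logger.warning("%d tracts with zero properties marked missing", int(empty.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = ff / n_props[:, None]
    shares[empty] = np.nan
    out["p_flood_low"] = shares[:, :FF_LOW_MAX].sum(axis=1)
    out["p_flood_mod"] = shares[:, FF_LOW_MAX:FF_HIGH_MIN - 1].sum(axis=1)
    out["p_flood_high"] = shares[:, FF_HIGH_MIN - 1:].sum(axis=1)
    for lev in (7, 8, 9, 10):
        out[f"p_ff{lev}"] = shares[:, lev - 1]

    if income_brackets is not None:
        hh_cols = [f"hh_inc_{b}" for b in range(len(income_brackets))]
        gini_vals = np.full(len(df), np.nan)
        for i, (_, r) in enumerate(df.iterrows()):
            counts = r[hh_cols].to_numpy(float)
            if counts.sum() > 0:
                gini_vals[i] = gini_grouped(counts, income_brackets)
        out["gini"] = gini_vals

    # regional dissimilarity, assigned back to each member tract
    region = _region_labels(df)
    iod_vals = np.full(len(df), np.nan)
    for reg, idx in df.groupby(region).groups.items():
        sub = df.loc[idx]
        if len(sub) >= 2 and sub["n_nonwhite"].sum() > 0 and sub["n_white"].sum() > 0:
            d = dissimilarity_index(sub["n_nonwhite"], sub["n_white"])
            iod_vals[df.index.get_indexer(idx)] = d
        else:
            logger.warning("region %s lacks subunits or group totals for IOD", reg)
    out["iod"] = iod_vals
    return out
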