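"""Cluster profiling: membership tallies, demographic contrasts, RUCA mix.

Turns a set of LISA cluster labels into the three standard report tables:
per-cluster tract counts, population sums and population density; cluster
vs statewide demographic means with Welch t-tests and significance stars;
and rural / suburban / urban cross-tabulations from RUCA codes (urban 1–3,
suburban 4–7, rural 8–10).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ruca_class", "crosstab_ruca", "cluster_population_summary",
    "demographic_comparison", "significance_stars", "RUCA_CLASSES",
]

RUCA_CLASSES = ("rural", "suburban", "urban")

_P_FLOOR = 1e-300  # reported p when group means differ but variances vanish


def ruca_class(code: int) -> str:
    """Map a RUCA code (1..10) to urban / suburban / rural."""
    code = int(code)
    if not 1 <= code <= 10:
        raise ValueError(f"RUCA code {code} outside 1..10")
    if code <= 3:
        return "urban"
    if code <= 7:
        return "suburban"
    return "rural"


def significance_stars(p: float) -> str:
    """Conventional stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def crosstab_ruca(labels, ruca_classes, cluster_type: str) -> pd.DataFrame:
    """Counts and percentages of rural/suburban/urban tracts in one cluster.

    Percentages are 100·count/cluster-size rounded to one decimal; an empty
    cluster reports zero counts and missing percentages.
    """
    labels = np.asarray(labels, dtype=object)
    classes = np.asarray(ruca_classes, dtype=object)
    if labels.shape != classes.shape:
        raise ValueError("labels and ruca_classes must align")
    member = classes[labels == cluster_type]
    total = member.size
    rows = []
    for cls in RUCA_CLASSES:
        cnt = int((member == cls).sum())
        pct = round(100.0 * cnt / total, 1) if total else float("nan")
        rows.append({"ruca_class": cls, "count": cnt, "percent": pct})
    return pd.DataFrame(rows)


def cluster_population_summary(labels, table: pd.DataFrame, cluster_type: str) -> dict:
    """Tract count, population sum, and density (persons / sq mi) of a cluster.

    Density is ratio-of-sums: Σ population / Σ land area over member tracts.
    """
    labels = np.asarray(labels, dtype=object)
    member = table.loc[labels == cluster_type]
    count = int(len(member))
    population = int(member["population"].sum()) if count else 0
    area = float(member["land_area_sqmi"].sum()) if count else 0.0
    if count == 0 or area == 0:
        density = float("nan")
    else:
        density = population / area
    return {
        "cluster": cluster_type,
        "tracts": count,
        "population": population,
        "density": density,
    }


def demographic_comparison(
    labels,
    table: pd.DataFrame,
    cluster_type: str,
    indicators,
    alpha: float = 0.05,
    mode: str = "two-sample",
    weighted: bool = False,
) -> pd.DataFrame:
    """Cluster-vs-state contrast per indicator, with t-tests and stars.

    ``delta`` is cluster mean minus the mean over ALL tracts (the
    statewide average, cluster included) — the parenthetical of the
    demographic-profile table. Inference is a Welch two-sample t-test of
    member tracts against all non-member tracts by default, or a
    one-sample test against the statewide mean (``mode="one-sample"``).
    Means are unweighted tract averages unless ``weighted`` requests
    population weighting. Indicators that are constant within a group
    report a missing t (or the numeric p floor when the means differ but
    both variances are zero).
    """
    if mode not in ("two-sample", "one-sample"):
        raise ValueError("mode must be 'two-sample' or 'one-sample'")
    labels = np.asarray(labels, dtype=object)
    in_cluster = labels == cluster_type
    if in_cluster.sum() < 2:
        raise ValueError(f"cluster {cluster_type!r} has fewer than two member tracts")

    def _mean(series, mask):
        vals = series.to_numpy(float)[mask]
        if weighted:
            wts = table["population"].to_numpy(float)[mask]
            return float(np.average(vals, weights=wts))
        return float(vals.mean())

    rows = []
    everyone = np.ones(len(table), dtype=bool)
    for ind in indicators:
        col = table[ind]
        cluster_mean = _mean(col, in_cluster)
        state_mean = _mean(col, everyone)
        member = col.to_numpy(float)[in_cluster]
        rest = col.to_numpy(float)[~in_cluster]
        if mode == "one-sample":
            tstat, p = _safe_ttest_1samp(member, state_mean)
        else:
            tstat, p = _safe_welch(member, rest)
        rows.append(
            {
                "indicator": ind,
                "cluster_mean": cluster_mean,
                "state_mean": state_mean,
                "delta": cluster_mean - state_mean,
                "t": tstat,
                "p": p,
                "stars": significance_stars(p),
                "significant": bool(np.isfinite(p) and p < alpha),
            }
        )
    return pd.DataFrame(rows)


def _safe_welch(a: np.ndarray, b: np.ndarray):
    if a.std() == 0 and b.std() == 0:
        if math.isclose(a.mean(), b.mean()):
            return float("nan"), float("nan")
        return float("inf") * np.sign(a.mean() - b.mean()), _P_FLOOR
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _safe_ttest_1samp(a: np.ndarray, popmean: float):
    if a.std() == 0:
        if math.isclose(a.mean(), popmean):
            return float("nan"), float("nan")
        return float("inf") * np.sign(a.mean() - popmean), _P_FLOOR
    t, p = stats.ttest_1samp(a, popmean)
    return float(t), float(p)
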