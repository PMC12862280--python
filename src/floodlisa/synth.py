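"""Synthetic census-tract generator.

Emulates the statistical structure of the study's real inputs — per-property
ordinal flood-risk scores, ACS-style demographic and household-income counts,
chronic-condition prevalences, and rural-urban commuting-area (RUCA) codes —
on a square polygon lattice, with controllable spatial autocorrelation and
optional planted rectangular blocks of jointly elevated flood risk and
inequality. The planted blocks are the ground truth against which cluster
recovery is measured.

Spatial structure comes from simultaneous-autoregressive (SAR) latent fields
u = (I − ρW)⁻¹ ε with ε iid standard normal and W the same row-standardized
queen weights the analysis itself uses, so the generator's autocorrelation
parameter ρ acts directly on the quantity the Moran statistics measure.

All randomness flows from ``SimConfig.seed``; identical configs produce
bit-identical tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm
from shapely.geometry import box

from .weights import SpatialWeights, build_queen_weights, row_standardize

__all__ = ["PlantedBlock", "SimConfig", "make_lattice", "sar_field", "synthesize_tracts",
           "DEFAULT_INCOME_BRACKETS", "PREVALENCE_BASE_RATES"]

logger = logging.getLogger(__name__)

#: ACS-style household income brackets (annual $); ``None`` = open top.
#: The first bracket (≤ $25,000) and the last (≥ $125,000) are the extremes
#: entering the economic concentration index.
DEFAULT_INCOME_BRACKETS = (
    (0, 25_000),
    (25_000, 50_000),
    (50_000, 75_000),
    (75_000, 100_000),
    (100_000, 125_000),
    (125_000, None),
)

#: Tract-level baseline prevalences for the five flood-sensitive chronic
#: conditions, ordered as in the analysis output columns.
PREVALENCE_BASE_RATES = {
    "asthma": 0.10,
    "copd": 0.07,
    "depression": 0.22,
    "diabetes": 0.12,
    "kidney_disease": 0.03,
}

# Fixed split of the middle income mass over the four interior brackets.
_MIDDLE_BRACKET_SHARES = np.array([0.30, 0.30, 0.20, 0.20])

# Latent propensities are clipped here before any logistic transform.
_PROPENSITY_CLIP = 8.0

# Correlation between a tract's flood propensity and its individual
# property scores: score latent = w·z_tract + sqrt(1−w²)·noise.
_PROPERTY_LOADING = 0.7


@dataclass(frozen=True)
class PlantedBlock:
    """Rectangular block of tracts carrying a planted joint signal.

    Rows/cols are half-open lattice index ranges; effects are additive
    shifts, in latent standard-deviation units, applied to the flood
    propensity (``flood_effect``) and to both inequality propensities —
    nonwhite share and low-income share (``inequality_effect``).
    """

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    flood_effect: float = 2.5
    inequality_effect: float = 2.5

    def mask(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return (
            (rows >= self.row_start) & (rows < self.row_stop)
            & (cols >= self.col_start) & (cols < self.col_stop)
        )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic realization.

    Defaults are the package's reference conditions: a 20×20 tract lattice
    with moderate spatial autocorrelation (ρ = 0.6) and one 6×6 planted
    block of jointly extreme flood risk and inequality.
    """

    n_rows: int = 20
    n_cols: int = 20
    cell_size: float = 1.0
    rho: float = 0.6
    planted_blocks: tuple = (PlantedBlock(4, 10, 4, 10),)
    income_brackets: tuple = DEFAULT_INCOME_BRACKETS
    n_properties_per_tract: int = 50
    tract_population: int = 4000
    persons_per_household: float = 2.6
    stochastic_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1); the SAR inverse requires rho < 1")
        if self.rho > 0.99:
            raise ValueError("rho must not exceed 0.99")
        if self.n_properties_per_tract < 1:
            raise ValueError("n_properties_per_tract must be positive")
        for b in self.planted_blocks:
            if not (0 <= b.row_start < b.row_stop <= self.n_rows
                    and 0 <= b.col_start < b.col_stop <= self.n_cols):
                raise ValueError(f"planted block {b} falls outside the lattice")
        lows = [lo for lo, _ in self.income_brackets]
        if lows != sorted(lows):
            raise ValueError("income brackets must be ordered")


def make_lattice(n_rows: int, n_cols: int, cell_size: float = 1.0):
    """Tile a rectangle with ``n_rows × n_cols`` square tract polygons.

    Returns ``(polygons, ids, rows, cols)`` in stable row-major order; each
    cell's land area is ``cell_size**2`` (square miles by convention).
    Row index increases southward so id order reads like a raster scan.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be positive")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    polys, ids, rows, cols = [], [], [], []
    width = max(len(str(n_rows - 1)), len(str(n_cols - 1)), 2)
    for r in range(n_rows):
        for c in range(n_cols):
            x0, y0 = c * cell_size, -r * cell_size
            polys.append(box(x0, y0 - cell_size, x0 + cell_size, y0))
            ids.append(f"T{r:0{width}d}{c:0{width}d}")
            rows.append(r)
            cols.append(c)
    return polys, ids, np.array(rows), np.array(cols)


def sar_field(w: SpatialWeights, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one simultaneous-autoregressive field u = (I − ρW)⁻¹ ε.

    ``w`` must be row-standardized, which bounds the spectral radius by 1 and
    guarantees the inverse exists for ρ < 1.
    """
    if not w.standardized:
        raise ValueError("sar_field requires row-standardized weights")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    n = w.n
    eps = rng.standard_normal(n)
    if rho == 0.0:
        return eps
    a = np.eye(n) - rho * w.to_dense()
    try:
        return np.linalg.solve(a, eps)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rho<1 prevents this
        raise ValueError("singular (I - rho*W) system") from exc


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _clip_propensity(x: np.ndarray, name: str) -> np.ndarray:
    if np.any(np.abs(x) > _PROPENSITY_CLIP):
        logger.warning(
            "%s propensity exceeded ±%.0f in %d tracts; clipping",
            name, _PROPENSITY_CLIP, int((np.abs(x) > _PROPENSITY_CLIP).sum()),
        )
        x = np.clip(x, -_PROPENSITY_CLIP, _PROPENSITY_CLIP)
    return x


def _largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` by ``shares`` (sum to 1)."""
    raw = shares * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _ruca_codes(rows: np.ndarray, cols: np.ndarray, n_rows: int, n_cols: int) -> np.ndarray:
    """Concentric-ring RUCA assignment: urban core, suburban ring, rural edge.

    Normalized Chebyshev distance from the lattice center is split in thirds
    (urban codes 1–3, suburban 4–7, rural 8–10), and the code within each
    class increases with distance, so the classification is spatially
    coherent and deterministic.
    """
    rc, cc = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    dr = np.abs(rows - rc) / max(rc, 0.5)
    dc = np.abs(cols - cc) / max(cc, 0.5)
    d = np.maximum(dr, dc)  # in [0, 1]
    codes = np.empty(len(rows), dtype=int)
    urban = d < 1 / 3
    suburb = (d >= 1 / 3) & (d < 2 / 3)
    rural = d >= 2 / 3
    codes[urban] = 1 + np.minimum((d[urban] * 3 * 3).astype(int), 2)
    codes[suburb] = 4 + np.minimum(((d[suburb] - 1 / 3) * 3 * 4).astype(int), 3)
    codes[rural] = 8 + np.minimum(((d[rural] - 2 / 3) * 3 * 3).astype(int), 2)
    return codes


def synthesize_tracts(config: SimConfig):
    """Generate a full synthetic tract table.

    Returns
    -------
    (pandas.DataFrame, SpatialWeights)
        The tract table (geometry in column ``geometry``) and the
        row-standardized queen weights of the lattice. Columns cover
        population/household totals, race counts, per-bracket household
        income counts (``hh_inc_0`` ...), the A/P/T counts of all three
        concentration-index variants, FloodFactor score counts
        (``ff_count_1`` ... ``ff_count_10``), five chronic-condition
        prevalences (``prev_*``), RUCA code, lattice row/col, and land area.
    """
    cfg = config
    polys, ids, rows, cols = make_lattice(cfg.n_rows, cfg.n_cols, cfg.cell_size)
    n = len(polys)
    w = row_standardize(build_queen_weights(polys, ids))

    ss = np.random.SeedSequence(cfg.seed)
    rng_flood, rng_race, rng_inc, rng_prev, rng_prop, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    # -- latent SAR fields, standardized so planted effects are in SD units
    if n >= 2:
        z_flood = _zscore(sar_field(w, cfg.rho, rng_flood))
        z_race = _zscore(sar_field(w, cfg.rho, rng_race))
        z_inc = _zscore(sar_field(w, cfg.rho, rng_inc))
        z_prev = _zscore(sar_field(w, cfg.rho, rng_prev))
    else:  # single tract: no spatial structure to standardize
        z_flood = z_race = z_inc = z_prev = np.zeros(1)

    for blk in cfg.planted_blocks:
        m = blk.mask(rows, cols)
        z_flood = z_flood + blk.flood_effect * m
        z_race = z_race + blk.inequality_effect * m
        z_inc = z_inc + blk.inequality_effect * m

    z_flood = _clip_propensity(z_flood, "flood")
    z_race = _clip_propensity(z_race, "nonwhite-share")
    z_inc = _clip_propensity(z_inc, "low-income")
    z_prev = _clip_propensity(z_prev, "prevalence")

    # -- FloodFactor scores: monotone decile binning of property latents
    edges = norm.ppf(np.arange(1, 10) / 10.0)
    k = cfg.n_properties_per_tract
    prop_noise = rng_prop.standard_normal((n, k))
    prop_latent = (_PROPERTY_LOADING * z_flood[:, None]
                   + math.sqrt(1 - _PROPERTY_LOADING**2) * prop_noise)
    scores = np.searchsorted(edges, prop_latent) + 1  # (n, k) ints in 1..10
    ff_counts = np.stack(
        [(scores == lev).sum(axis=1) for lev in range(1, 11)], axis=1
    )

    # -- demographic composition via logistic transforms of the latents
    pop = np.full(n, cfg.tract_population, dtype=int)
    households = np.round(pop / cfg.persons_per_household).astype(int)

    s_nonwhite = expit(logit(0.30) + 1.0 * z_race)
    p_low = expit(logit(0.22) + 0.8 * z_inc)
    p_high = expit(logit(0.18) - 0.8 * z_inc)

    if cfg.stochastic_counts:
        n_nonwhite = rng_counts.binomial(pop, s_nonwhite)
    else:
        n_nonwhite = np.round(pop * s_nonwhite).astype(int)
    n_white = pop - n_nonwhite

    n_brackets = len(cfg.income_brackets)
    if n_brackets < 3:
        raise ValueError("need at least a low, a middle, and a top income bracket")
    hh_counts = np.zeros((n, n_brackets), dtype=int)
    mid_shares = _MIDDLE_BRACKET_SHARES
    if n_brackets - 2 != len(mid_shares):
        mid_shares = np.full(n_brackets - 2, 1.0 / (n_brackets - 2))
    for i in range(n):
        shares = np.empty(n_brackets)
        shares[0] = p_low[i]
        shares[-1] = p_high[i]
        shares[1:-1] = (1.0 - p_low[i] - p_high[i]) * mid_shares
        if cfg.stochastic_counts:
            hh_counts[i] = rng_counts.multinomial(households[i], shares / shares.sum())
        else:
            hh_counts[i] = _largest_remainder(int(households[i]), shares / shares.sum())

    # -- A/P/T triplets for the three concentration-index variants
    ice_income_a = hh_counts[:, 0]
    ice_income_p = hh_counts[:, -1]
    ice_income_t = households
    ice_race_a = n_nonwhite
    ice_race_p = n_white
    ice_race_t = pop
    joint_a = pop * s_nonwhite * p_low
    joint_p = pop * (1 - s_nonwhite) * p_high
    if cfg.stochastic_counts:
        ice_ri_a = rng_counts.binomial(pop, s_nonwhite * p_low)
        ice_ri_p = rng_counts.binomial(pop, (1 - s_nonwhite) * p_high)
    else:
        ice_ri_a = np.round(joint_a).astype(int)
        ice_ri_p = np.round(joint_p).astype(int)
    ice_ri_t = pop

    # -- flood-sensitive chronic-condition prevalences
    prev_cols = {}
    for j, (cond, base) in enumerate(PREVALENCE_BASE_RATES.items()):
        # small per-condition offset decorrelates the five outcomes while
        # keeping them on the same spatial surface
        prev = expit(logit(base) + 0.4 * z_prev + 0.15 * rng_counts.standard_normal(n))
        prev_cols[f"prev_{cond}"] = np.clip(prev, 0.0, 1.0)

    df = pd.DataFrame(
        {
            "tract_id": ids,
            "row": rows,
            "col": cols,
            "land_area_sqmi": cfg.cell_size**2,
            "population": pop,
            "households": households,
            "n_nonwhite": n_nonwhite,
            "n_white": n_white,
            **{f"hh_inc_{b}": hh_counts[:, b] for b in range(n_brackets)},
            "ice_income_a": ice_income_a,
            "ice_income_p": ice_income_p,
            "ice_income_t": ice_income_t,
            "ice_race_a": ice_race_a,
            "ice_race_p": ice_race_p,
            "ice_race_t": ice_race_t,
            "ice_race_income_a": ice_ri_a,
            "ice_race_income_p": ice_ri_p,
            "ice_race_income_t": ice_ri_t,
            **{f"ff_count_{lev}": ff_counts[:, lev - 1] for lev in range(1, 11)},
            **prev_cols,
            "ruca": _ruca_codes(rows, cols, cfg.n_rows, cfg.n_cols),
        }
    )
    df["geometry"] = polys
    df.attrs["income_brackets"] = tuple(cfg.income_brackets)
    return df, w
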