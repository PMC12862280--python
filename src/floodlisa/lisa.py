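"""Global and local Moran's I with conditional-permutation inference.

The inferential engine of the package. For a focal variable x (flood risk)
and a lag variable y (an inequality index or a prevalence), both
population-standardized to z-scores:

* global (bivariate) Moran's I = (n / S₀) · Σ_ij w_ij z_x,i z_y,j / Σ_i z_x,i²,
  which with row-standardized weights reduces to the mean over tracts of
  z_x,i · lag_i(z_y); the univariate statistic is the special case y = x;
* local Moran's I_i = z_x,i · Σ_j w_ij z_y,j (Anselin's LISA decomposition);
* significance by conditional permutation: tract i's own value is held
  fixed while the y-values of all other tracts are randomly reassigned to
  its neighbor positions, giving a pseudo p-value (R + 1)/(M + 1) with R
  the number of permuted statistics at least as extreme as the observed
  one in the observed direction (the GeoDa convention; a two-sided option
  is exposed);
* significant tracts are classified HH / LL / LH / HL from the signs of
  z_x,i and the lag; non-significant tracts are NS; tracts without
  neighbors are ISLAND and never receive a p-value.

Per-tract permutation streams are derived from (seed, tract index), so
results do not depend on iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weights import SpatialWeights

__all__ = [
    "LisaResult", "standardize", "global_moran", "local_moran",
    "permutation_inference", "classify", "run_lisa", "run_bivariate_lisa",
    "QUADRANTS",
]

QUADRANTS = ("HH", "LL", "LH", "HL", "NS", "ISLAND")

DEFAULT_PERMUTATIONS = 9999
DEFAULT_ALPHAS = (0.05, 0.01, 0.001)


class DegenerateVariableError(ValueError):
    """Raised when a variable cannot be standardized (zero variance)."""


def standardize(values) -> np.ndarray:
    """Population z-scores: (x − mean) / sd with the divide-by-n sd.

    After standardization mean(z) = 0 and mean(z²) = 1, which is what makes
    Σ z² = n and lets the Moran formulas simplify.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector of at least two values")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing or non-finite values; filter before standardizing")
    sd = x.std()  # population (ddof=0)
    if sd == 0 or np.unique(x).size < 2:
        raise DegenerateVariableError("variable is constant; Moran's I undefined")
    return (x - x.mean()) / sd


def global_moran(z_x: np.ndarray, w: SpatialWeights, z_y: np.ndarray | None = None) -> float:
    """Bivariate global Moran's I; univariate when ``z_y`` is omitted.

    Islands contribute nothing to either sum. ``z_x`` / ``z_y`` must be
    standardized over the non-island tract set (see :func:`run_lisa`).
    """
    if z_y is None:
        z_y = z_x
    z_x = np.asarray(z_x, float)
    z_y = np.asarray(z_y, float)
    s0 = w.s0()
    if s0 == 0:
        raise ValueError("all tracts are islands; Moran's I undefined")
    num = 0.0
    ssx = 0.0
    for i, (nb, wt) in enumerate(zip(w.neighbors, w.weights)):
        if len(nb) == 0:
            continue
        num += z_x[i] * float(wt @ z_y[nb])
        ssx += z_x[i] ** 2
    n_eff = sum(1 for nb in w.neighbors if len(nb))
    return (n_eff / s0) * num / ssx


def local_moran(z_x: np.ndarray, w: SpatialWeights, z_y: np.ndarray | None = None):
    """Per-tract local Moran statistics I_i = z_x,i · lag_i(z_y).

    Returns ``(local_i, lag)``; both are NaN for islands.
    """
    if z_y is None:
        z_y = z_x
    lag = w.lag(z_y)
    return np.asarray(z_x, float) * lag, lag


def _tract_rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def permutation_inference(
    z_x: np.ndarray,
    w: SpatialWeights,
    z_y: np.ndarray | None = None,
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    alternative: str = "directed",
) -> np.ndarray:
    """Conditional-permutation pseudo p-values for the local statistics.

    For each non-island tract i, ``permutations`` random draws of |N(i)|
    values from the other tracts' z_y are assigned to i's neighbor
    positions while z_x,i stays fixed. ``alternative="directed"`` counts
    permuted statistics at least as extreme as the observed one on the
    observed side (one-sided, GeoDa style); ``"two-sided"`` doubles and
    caps the directed p. Islands get NaN.

    The pseudo p is (R + 1)/(M + 1), so its floor is 1/(M + 1).
    """
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    if alternative not in ("directed", "two-sided"):
        raise ValueError("alternative must be 'directed' or 'two-sided'")
    if z_y is None:
        z_y = z_x
    z_x = np.asarray(z_x, float)
    z_y = np.asarray(z_y, float)
    n = w.n
    obs, _ = local_moran(z_x, w, z_y)
    rngs = _tract_rngs(seed, n)
    pvals = np.full(n, np.nan)
    m = permutations
    # the permutation pool is the connected (non-island, finite-z) tract set
    pool = np.where(np.isfinite(z_y))[0]
    for i in range(n):
        nb = w.neighbors[i]
        k = len(nb)
        if k == 0:
            continue
        others = z_y[pool[pool != i]]
        wt = w.weights[i]
        # Random k-subsets via argpartition of uniform keys. Within-row
        # weights are equal for queen binary/row-standardized matrices, so
        # the (non-uniform) ordering inside each subset is irrelevant.
        n_others = others.size
        if k > n_others:
            raise ValueError("more neighbors than available donor tracts")
        if k == n_others:
            # tract adjacent to every other tract: the conditional lag is
            # permutation-invariant, so the null is degenerate — not extreme
            pvals[i] = 1.0
            continue
        keys = rngs[i].random((m, n_others))
        sel = np.argpartition(keys, k, axis=1)[:, :k]
        perm_lag = others[sel] @ wt
        perm_i = z_x[i] * perm_lag
        larger = int((perm_i >= obs[i]).sum())
        if m - larger < larger:
            larger = m - larger
        pvals[i] = (larger + 1.0) / (m + 1.0)
    if alternative == "two-sided":
        pvals = np.minimum(2.0 * pvals, 1.0)
    return pvals


def classify(z_x, lag, pvals, alpha: float = 0.05) -> np.ndarray:
    """HH / LL / LH / HL / NS / ISLAND labels per tract.

    Sign reference is the standardized mean (z = 0). A tract is labeled a
    cluster/outlier only when its pseudo p is below ``alpha``; exact-zero
    z or lag is NS by the deterministic tie rule.
    """
    z_x = np.asarray(z_x, float)
    lag = np.asarray(lag, float)
    pvals = np.asarray(pvals, float)
    labels = np.full(z_x.shape, "NS", dtype=object)
    island = np.isnan(lag) | np.isnan(pvals)
    sig = ~island & (pvals < alpha) & (z_x != 0) & (lag != 0)
    labels[island] = "ISLAND"
    labels[sig & (z_x > 0) & (lag > 0)] = "HH"
    labels[sig & (z_x < 0) & (lag < 0)] = "LL"
    labels[sig & (z_x < 0) & (lag > 0)] = "LH"
    labels[sig & (z_x > 0) & (lag < 0)] = "HL"
    return labels


@dataclass
class LisaResult:
    """Everything one LISA run produces.

    ``table`` has one row per tract: ``tract_id``, ``local_i``, ``lag``,
    ``p``, and one ``cluster_pXXX`` label column per significance level.
    """

    x_name: str
    y_name: str
    global_i: float
    permutations: int
    seed: int
    alphas: tuple
    table: pd.DataFrame

    def labels(self, alpha: float = 0.05) -> pd.Series:
        return self.table[_alpha_col(alpha)]

    def counts(self, alpha: float = 0.05) -> dict:
        lab = self.labels(alpha)
        return {q: int((lab == q).sum()) for q in QUADRANTS}


def _alpha_col(alpha: float) -> str:
    return "cluster_p" + f"{alpha:g}".replace("0.", "")


def run_lisa(
    df: pd.DataFrame,
    x: str,
    w: SpatialWeights,
    y: str | None = None,
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    alphas=DEFAULT_ALPHAS,
    alternative: str = "directed",
) -> LisaResult:
    """Full LISA pipeline on named columns of a tract table.

    Standardizes x (and y) over non-island tracts, computes global and
    local Moran's I, runs conditional-permutation inference, and labels
    quadrants at each level in ``alphas``. Univariate when ``y`` is
    omitted; in the bivariate case x is the focal variable and y supplies
    the neighbor lag, matching the study's construction (flood risk
    surrounded by inequality).
    """
    if x not in df.columns:
        raise KeyError(f"variable {x!r} not in table")
    if y is not None and y not in df.columns:
        raise KeyError(f"variable {y!r} not in table")
    if list(df["tract_id"]) != list(w.ids):
        raise ValueError("tract order of table and weights disagree")
    xvals = df[x].to_numpy(float)
    yvals = df[y].to_numpy(float) if y is not None else xvals
    if np.any(~np.isfinite(xvals)) or np.any(~np.isfinite(yvals)):
        raise ValueError("missing values present; drop flagged tracts before LISA")

    islands = w.islands
    mask = np.ones(w.n, dtype=bool)
    mask[islands] = False
    if mask.sum() < 2:
        raise ValueError("fewer than two connected tracts")

    z_x = np.full(w.n, np.nan)
    z_y = np.full(w.n, np.nan)
    z_x[mask] = standardize(xvals[mask])
    z_y[mask] = standardize(yvals[mask]) if y is not None else z_x[mask]

    gi = global_moran(z_x, w, z_y)
    li, lag = local_moran(z_x, w, z_y)
    pvals = permutation_inference(
        z_x, w, z_y, permutations=permutations, seed=seed, alternative=alternative
    )
    out = pd.DataFrame(
        {"tract_id": list(w.ids), "local_i": li, "lag": lag, "p": pvals}
    )
    for a in alphas:
        out[_alpha_col(a)] = classify(z_x, lag, pvals, a)
    return LisaResult(
        x_name=x, y_name=y if y is not None else x, global_i=gi,
        permutations=permutations, seed=seed, alphas=tuple(alphas), table=out,
    )


def run_bivariate_lisa(df, x, y, w, permutations=DEFAULT_PERMUTATIONS, seed=0,
                       alphas=DEFAULT_ALPHAS, alternative="directed") -> LisaResult:
    """Bivariate LISA of focal ``x`` against the spatial lag of ``y``."""
    return run_lisa(df, x, w, y=y, permutations=permutations, seed=seed,
                    alphas=alphas, alternative=alternative)
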