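"""Queen-contiguity spatial weights.

Builds the neighbor structure used by every Moran statistic in the package:
two polygons are queen neighbors when their boundaries share at least one
point (an edge or a single corner). The diagonal is always zero — a tract is
never its own neighbor — and tracts with no neighbors are tracked as islands
and excluded from autocorrelation inference rather than silently given
zero lags.

Weights are binary on construction and row-standardized by default in the
rest of the pipeline (each non-island row sums to 1), which is the GeoDa
convention and yields the identity mean(local Moran) = global Moran used
throughout the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely import STRtree
from shapely.geometry.base import BaseGeometry

__all__ = ["SpatialWeights", "build_queen_weights", "row_standardize", "read_gal", "write_gal"]


class WeightsError(ValueError):
    """Invalid input to weights construction."""


@dataclass
class SpatialWeights:
    """Neighbor lists plus per-pair weights over an ordered set of tracts.

    Attributes
    ----------
    ids : list of str
        Tract identifiers, in analysis row order.
    neighbors : list of numpy integer arrays
        ``neighbors[i]`` holds the positional indices of tract *i*'s
        neighbors (sorted ascending). Empty for islands.
    weights : list of numpy float arrays
        ``weights[i][k]`` is w_ij for ``j = neighbors[i][k]``.
    standardized : bool
        True once rows have been normalized to sum to one.
    """

    ids: list
    neighbors: list
    weights: list
    standardized: bool = False

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.neighbors) == len(self.weights)):
            raise WeightsError("ids, neighbors and weights must be parallel")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def islands(self) -> np.ndarray:
        """Positional indices of tracts with no neighbors."""
        return np.array([i for i, nb in enumerate(self.neighbors) if len(nb) == 0], dtype=np.intp)

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=np.intp)

    def to_dense(self) -> np.ndarray:
        """Dense (n, n) weights matrix; zero diagonal by construction."""
        w = np.zeros((self.n, self.n))
        for i, (nb, wt) in enumerate(zip(self.neighbors, self.weights)):
            w[i, nb] = wt
        return w

    def lag(self, y: np.ndarray) -> np.ndarray:
        """Spatial lag Σ_j w_ij y_j; islands get NaN."""
        y = np.asarray(y, dtype=float)
        out = np.full(self.n, np.nan)
        for i, (nb, wt) in enumerate(zip(self.neighbors, self.weights)):
            if len(nb):
                out[i] = float(wt @ y[nb])
        return out

    def s0(self) -> float:
        """Sum of all weights (the S₀ of Moran's I)."""
        return float(sum(wt.sum() for wt in self.weights))


def build_queen_weights(polygons, ids=None, tolerance: float = 0.0) -> SpatialWeights:
    """Binary queen-contiguity weights from a polygon collection.

    Parameters
    ----------
    polygons : sequence of shapely geometries
        Pairwise non-overlapping tract polygons in analysis order.
    ids : sequence of str, optional
        Tract ids; defaults to stringified positions.
    tolerance : float
        Boundary-sharing is tested with exact geometry predicates when 0
        (the default); a positive value treats polygons within that
        distance as neighbors, for dirty real-world geometry.

    Returns
    -------
    SpatialWeights
        Binary (0/1) weights; symmetric adjacency; islands recorded as
        empty rows.
    """
    polygons = list(polygons)
    if len(polygons) == 0:
        raise WeightsError("empty polygon collection")
    for k, g in enumerate(polygons):
        if not isinstance(g, BaseGeometry) or g.is_empty or not g.is_valid:
            raise WeightsError(f"invalid geometry at position {k}")
    if ids is None:
        ids = [str(i) for i in range(len(polygons))]
    ids = list(ids)
    if len(ids) != len(polygons):
        raise WeightsError("ids and polygons length mismatch")
    if len(set(ids)) != len(ids):
        raise WeightsError("duplicate tract ids")

    tree = STRtree(polygons)
    if tolerance > 0:
        left, right = tree.query(polygons, predicate="dwithin", distance=tolerance)
    else:
        # interiors are disjoint by precondition, so any intersection is a
        # shared boundary point — exactly the queen criterion
        left, right = tree.query(polygons, predicate="intersects")
    adj = [set() for _ in polygons]
    for i, j in zip(left, right):
        if i != j:
            adj[int(i)].add(int(j))
            adj[int(j)].add(int(i))
    neighbors = [np.array(sorted(s), dtype=np.intp) for s in adj]
    wts = [np.ones(len(nb)) for nb in neighbors]
    return SpatialWeights(ids=ids, neighbors=neighbors, weights=wts, standardized=False)


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Return a copy with each non-island row scaled to sum to 1.

    Island rows remain all-zero (empty); they never acquire weights.
    """
    new_wts = []
    for wt in w.weights:
        if len(wt):
            new_wts.append(wt / wt.sum())
        else:
            new_wts.append(wt.copy())
    return SpatialWeights(
        ids=list(w.ids),
        neighbors=[nb.copy() for nb in w.neighbors],
        weights=new_wts,
        standardized=True,
    )


# ---------------------------------------------------------------------------
# GAL neighbor-list text format
# ---------------------------------------------------------------------------

def write_gal(w: SpatialWeights, path) -> None:
    """Write adjacency in GAL format (ids on header lines, neighbor ids below)."""
    lines = [str(w.n)]
    for i, nb in enumerate(w.neighbors):
        lines.append(f"{w.ids[i]} {len(nb)}")
        lines.append(" ".join(w.ids[j] for j in nb))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gal(path) -> SpatialWeights:
    """Read a GAL file written by :func:`write_gal` (binary weights)."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    n = int(tokens[0].split()[-1])
    ids: list = []
    raw: dict = {}
    line = 1
    for _ in range(n):
        ident, card = tokens[line].split()
        nbr_ids = tokens[line + 1].split() if int(card) else []
        if len(nbr_ids) != int(card):
            raise WeightsError(f"GAL cardinality mismatch for id {ident}")
        ids.append(ident)
        raw[ident] = nbr_ids
        line += 2
    pos = {ident: i for i, ident in enumerate(ids)}
    neighbors = [np.array(sorted(pos[j] for j in raw[ident]), dtype=np.intp) for ident in ids]
    wts = [np.ones(len(nb)) for nb in neighbors]
    return SpatialWeights(ids=ids, neighbors=neighbors, weights=wts, standardized=False)
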