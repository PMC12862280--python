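import numpy as np
import pytest

import floodlisa as fl


@pytest.fixture(scope="session")
def lattice_5x5():
    polys, ids, rows, cols = fl.make_lattice(5, 5)
    return polys, ids, rows, cols


@pytest.fixture(scope="session")
def weights_5x5(lattice_5x5):
    polys, ids, *_ = lattice_5x5
    return fl.build_queen_weights(polys, ids)


@pytest.fixture(scope="session")
def default_table():
    """One default-condition synthetic realization (seed 0) with indices."""
    df, w = fl.synthesize_tracts(fl.SimConfig(seed=0))
    return fl.compute_index_table(df), w


@pytest.fixture(scope="session")
def small_null_table():
    """10x10 CSR table (no autocorrelation, no planted blocks)."""
    cfg = fl.SimConfig(n_rows=10, n_cols=10, rho=0.0, planted_blocks=(), seed=7)
    df, w = fl.synthesize_tracts(cfg)
    return fl.compute_index_table(df), w


def brute_force_global_moran(zx, zy, wdense):
    """Naive O(n^2) double-sum oracle for (bivariate) global Moran's I."""
    n = len(zx)
    s0 = wdense.sum()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += wdense[i, j] * zx[i] * zy[j]
    return (n / s0) * num / float(np.sum(np.asarray(zx) ** 2))


def brute_force_local_moran(zx, zy, wdense):
    n = len(zx)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            acc += wdense[i, j] * zy[j]
        out[i] = zx[i] * acc
    return out
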