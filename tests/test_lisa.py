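"""Moran statistics, permutation inference, and quadrant classification.

Oracles: a naive O(n²) double-sum for global/local Moran's I, full
enumeration of label permutations for the analytic null mean −1/(n−1),
and exact enumeration of all conditional arrangements for pseudo p-values
on a tiny lattice.
"""

import itertools
import math

import numpy as np
import pytest

import floodlisa as fl
from floodlisa.lisa import DegenerateVariableError
from conftest import brute_force_global_moran, brute_force_local_moran


def standardized_random_fields(seed, n):
    rng = np.random.default_rng(seed)
    return fl.standardize(rng.normal(size=n)), fl.standardize(rng.normal(size=n))


class TestStandardize:
    def test_two_points(self):
        assert fl.standardize([0.0, 1.0]) == pytest.approx([-1.0, 1.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateVariableError):
            fl.standardize([3.0, 3.0, 3.0])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            fl.standardize([1.0, float("nan"), 2.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_population_moments(self, seed):
        z = fl.standardize(np.random.default_rng(seed).gamma(2, size=40))
        assert abs(z.mean()) < 1e-9
        assert abs((z**2).mean() - 1.0) < 1e-9


class TestGlobalMoran:
    def test_gradient_field_is_positively_autocorrelated(self):
        polys, ids, rows, cols = fl.make_lattice(10, 10)
        w = fl.row_standardize(fl.build_queen_weights(polys, ids))
        z = fl.standardize(np.arange(100, dtype=float))  # smooth row-major gradient
        i_obs = fl.global_moran(z, w)
        assert i_obs > 0
        assert i_obs == pytest.approx(
            brute_force_global_moran(z, z, w.to_dense()), abs=1e-12
        )

    def test_permutation_mean_is_analytic_null(self):
        # classical identity: averaging I over every relabeling gives -1/(n-1)
        polys, ids, *_ = fl.make_lattice(2, 3)
        w = fl.row_standardize(fl.build_queen_weights(polys, ids))
        z = fl.standardize(np.array([0.3, -1.2, 2.0, 0.7, -0.5, -1.3]))
        vals = [
            fl.global_moran(z[list(perm)], w)
            for perm in itertools.permutations(range(6))
        ]
        assert np.mean(vals) == pytest.approx(-1.0 / 5.0, abs=1e-12)

    def test_all_island_matrix_rejected(self):
        from shapely.geometry import box

        w = fl.build_queen_weights([box(0, 0, 1, 1), box(5, 5, 6, 6)])
        with pytest.raises(ValueError):
            fl.global_moran(np.array([1.0, -1.0]), w)

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_random_instances(self, seed):
        polys, ids, *_ = fl.make_lattice(10, 10)
        w = fl.row_standardize(fl.build_queen_weights(polys, ids))
        zx, zy = standardized_random_fields(seed, 100)
        dense = w.to_dense()
        assert fl.global_moran(zx, w, zy) == pytest.approx(
            brute_force_global_moran(zx, zy, dense), abs=1e-10
        )
        li, _ = fl.local_moran(zx, w, zy)
        assert li == pytest.approx(brute_force_local_moran(zx, zy, dense), abs=1e-10)


class TestLocalMoran:
    def test_zero_focal_value_zero_statistic(self):
        polys, ids, *_ = fl.make_lattice(1, 3)
        w = fl.row_standardize(fl.build_queen_weights(polys, ids))
        zx = np.array([0.0, 1.0, -1.0])
        li, _ = fl.local_moran(zx, w, fl.standardize([5.0, 1.0, 9.0]))
        assert li[0] == 0.0

    def test_hand_worked_1x3_gradient(self):
        # standardized (0,1,2) = (-1.2247, 0, 1.2247); middle lag = 0 -> I_mid = 0
        polys, ids, *_ = fl.make_lattice(1, 3)
        w = fl.row_standardize(fl.build_queen_weights(polys, ids))
        z = fl.standardize([0.0, 1.0, 2.0])
        li, lag = fl.local_moran(z, w)
        assert lag[1] == pytest.approx(0.0, abs=1e-12)
        assert li[1] == pytest.approx(0.0, abs=1e-12)
        assert li[0] == pytest.approx(z[0] * z[1], abs=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_mean_local_equals_global_under_row_standardization(self, seed):
        polys, ids, *_ = fl.make_lattice(7, 8)
        w = fl.row_standardize(fl.build_queen_weights(polys, ids))
        zx, zy = standardized_random_fields(seed, 56)
        li, _ = fl.local_moran(zx, w, zy)
        assert np.mean(li) == pytest.approx(fl.global_moran(zx, w, zy), abs=1e-9)

    def test_islands_get_nan(self):
        from shapely.geometry import box

        polys = [box(0, 0, 1, 1), box(1, 0, 2, 1), box(9, 9, 10, 10)]
        w = fl.row_standardize(fl.build_queen_weights(polys))
        li, lag = fl.local_moran(np.array([1.0, -1.0, 0.5]), w)
        assert math.isnan(li[2]) and math.isnan(lag[2])
        assert np.isfinite(li[:2]).all()


def exact_conditional_pvalues(z, w):
    """Enumerate all (n-1)! conditional arrangements per tract.

    Returns, for each tract, the exact fraction of arrangements whose
    local statistic is at least as extreme as the observed one on the
    observed side (taking the smaller tail, as the directed pseudo-p does).
    """
    n = w.n
    obs, _ = fl.local_moran(z, w)
    out = np.zeros(n)
    for i in range(n):
        nb = w.neighbors[i]
        wt = w.weights[i]
        others = np.delete(z, i)
        stats = [
            z[i] * float(wt @ np.array(perm[: len(nb)]))
            for perm in itertools.permutations(others)
        ]
        stats = np.array(stats)
        larger = int((stats >= obs[i]).sum())
        larger = min(larger, stats.size - larger)
        out[i] = larger / stats.size
    return out


class TestPermutationInference:
    def test_pseudo_p_floor(self):
        polys, ids, *_ = fl.make_lattice(3, 3)
        w = fl.row_standardize(fl.build_queen_weights(polys, ids))
        z = fl.standardize(np.arange(9.0))
        p = fl.permutation_inference(z, w, permutations=999, seed=0)
        assert np.nanmin(p) >= 1.0 / 1000.0
        assert np.nanmax(p) <= 1.0

    def test_same_seed_identical(self):
        polys, ids, *_ = fl.make_lattice(4, 4)
        w = fl.row_standardize(fl.build_queen_weights(polys, ids))
        z, zy = standardized_random_fields(3, 16)
        p1 = fl.permutation_inference(z, w, zy, permutations=499, seed=11)
        p2 = fl.permutation_inference(z, w, zy, permutations=499, seed=11)
        assert np.array_equal(p1, p2)

    def test_too_few_permutations_rejected(self):
        polys, ids, *_ = fl.make_lattice(2, 2)
        w = fl.row_standardize(fl.build_queen_weights(polys, ids))
        with pytest.raises(ValueError):
            fl.permutation_inference(np.ones(4), w, permutations=50)

    def test_matches_exact_enumeration_on_1x6(self):
        # a path lattice keeps every neighborhood a strict subset of the
        # others, so the conditional null is non-degenerate for all tracts;
        # dyadic row weights (1, 1/2) make permutation ties bit-exact
        polys, ids, *_ = fl.make_lattice(1, 6)
        w = fl.row_standardize(fl.build_queen_weights(polys, ids))
        z = fl.standardize(np.array([1.8, -0.4, 0.9, -1.1, 0.2, -1.6]))
        exact = exact_conditional_pvalues(z, w)
        mc = fl.permutation_inference(z, w, permutations=99_999, seed=5)
        assert mc == pytest.approx(exact, abs=0.005)

    def test_complete_neighborhood_is_degenerate_null(self):
        # 2x3 queen lattice: the two middle tracts touch all five others,
        # the permuted lag never moves, and the tract must come back NS
        polys, ids, *_ = fl.make_lattice(2, 3)
        w = fl.row_standardize(fl.build_queen_weights(polys, ids))
        z = fl.standardize(np.array([1.8, -0.4, 0.9, -1.1, 0.2, -1.6]))
        p = fl.permutation_inference(z, w, permutations=999, seed=0)
        assert p[1] == 1.0 and p[4] == 1.0

    def test_two_sided_doubles_directed(self):
        polys, ids, *_ = fl.make_lattice(3, 3)
        w = fl.row_standardize(fl.build_queen_weights(polys, ids))
        z, zy = standardized_random_fields(9, 9)
        d = fl.permutation_inference(z, w, zy, permutations=999, seed=2)
        ts = fl.permutation_inference(z, w, zy, permutations=999, seed=2,
                                      alternative="two-sided")
        assert np.allclose(ts, np.minimum(2 * d, 1.0))


class TestClassify:
    @pytest.mark.parametrize(
        "z,lag,p,expected",
        [
            (2.0, 1.0, 0.001, "HH"),
            (2.0, 1.0, 0.20, "NS"),
            (-1.0, 1.0, 0.01, "LH"),
            (-1.0, -1.0, 0.01, "LL"),
            (2.0, -1.0, 0.01, "HL"),
            (0.0, 1.0, 0.001, "NS"),  # exact-zero tie rule
            (1.0, 0.0, 0.001, "NS"),
        ],
    )
    def test_quadrant_rules(self, z, lag, p, expected):
        out = fl.classify(np.array([z]), np.array([lag]), np.array([p]), alpha=0.05)
        assert out[0] == expected

    def test_island_label(self):
        out = fl.classify(np.array([1.0]), np.array([np.nan]), np.array([np.nan]))
        assert out[0] == "ISLAND"


class TestRunLisa:
    def test_bivariate_with_itself_reduces_to_univariate(self, small_null_table):
        table, w = small_null_table
        uni = fl.run_lisa(table, "p_flood_high", w, permutations=199, seed=4)
        biv = fl.run_bivariate_lisa(table, "p_flood_high", "p_flood_high", w,
                                    permutations=199, seed=4)
        assert biv.global_i == pytest.approx(uni.global_i)
        assert biv.table.equals(uni.table)

    def test_label_pvalue_consistency(self, default_table):
        table, w = default_table
        res = fl.run_bivariate_lisa(table, "p_flood_high", "ice_income", w,
                                    permutations=499, seed=0)
        lab = res.labels(0.05)
        p = res.table["p"]
        assert ((p < 0.05) == lab.isin(["HH", "LL", "LH", "HL"])).all()
        assert ((p >= 0.05) == (lab == "NS")).all()
        assert res.counts(0.05)["ISLAND"] == 0

    def test_labels_nested_across_alphas(self, default_table):
        table, w = default_table
        res = fl.run_bivariate_lisa(table, "p_flood_high", "ice_race", w,
                                    permutations=499, seed=1)
        strict = res.labels(0.001) != "NS"
        loose = res.labels(0.05) != "NS"
        assert (loose | ~strict).all()  # significant at 0.001 => at 0.05

    def test_missing_variable_rejected(self, small_null_table):
        table, w = small_null_table
        with pytest.raises(KeyError):
            fl.run_lisa(table, "no_such_column", w)

    def test_missing_values_rejected(self, small_null_table):
        table, w = small_null_table
        bad = table.copy()
        bad.loc[0, "p_flood_high"] = np.nan
        with pytest.raises(ValueError):
            fl.run_lisa(bad, "p_flood_high", w)

    def test_two_sided_null_calibration(self):
        """The two-sided pseudo-p is calibrated: ~5% of CSR tracts at p<.05.

        (The directed GeoDa-style default selects its tail after seeing the
        statistic, so its effective level is ~2x nominal; see docs.)
        """
        fracs = []
        for s in range(10):
            cfg = fl.SimConfig(n_rows=10, n_cols=10, rho=0.0, planted_blocks=(), seed=s)
            df, w = fl.synthesize_tracts(cfg)
            table = fl.compute_index_table(df)
            res = fl.run_bivariate_lisa(table, "p_flood_high", "ice_income", w,
                                        permutations=499, seed=s,
                                        alternative="two-sided")
            fracs.append((res.table["p"] < 0.05).mean())
        assert 0.02 <= np.mean(fracs) <= 0.08
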