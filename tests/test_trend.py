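"""Trend-filter solver, CV penalty selection, cyclic fits, permutation test.

The solver is cross-checked against an independent convex-programming route:
the dual of the trend-filter objective is a box-constrained least-squares
problem, solved here densely with scipy.optimize.lsq_linear.
"""

import numpy as np
import pytest
from scipy.optimize import lsq_linear
from scipy.stats import kstest

from cyclephase.trend import (
    compute_pve,
    cv_fold_assignment,
    cv_select_lambda,
    enrichment_odds_ratio,
    fit_cyclic_trend,
    lambda_max,
    permutation_test,
    trendfilter_solve,
    _diff_stencil,
)


def dense_diff_matrix(n, order=2):
    c = _diff_stencil(order)
    m = n - (order + 1)
    D = np.zeros((m, n))
    for r in range(m):
        D[r, r : r + order + 2] = c
    return D


def oracle_solve(y, lam, order=2):
    """Box-QP dual of the trend-filter objective via scipy lsq_linear."""
    D = dense_diff_matrix(len(y), order)
    res = lsq_linear(D.T, y, bounds=(-lam, lam), tol=1e-14, max_iter=2000)
    return y - D.T @ res.x


class TestTrendFilterSolve:
    def test_zero_penalty_is_identity(self):
        y = np.random.default_rng(0).normal(size=25)
        np.testing.assert_array_equal(trendfilter_solve(y, 0.0), y)

    def test_large_penalty_is_quadratic_fit(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=40)
        fitted = trendfilter_solve(y, 1e6 * np.linalg.norm(y))
        x = np.arange(40)
        poly = np.polyval(np.polyfit(x, y, 2), x)
        assert np.max(np.abs(fitted - poly)) < 1e-4

    @pytest.mark.parametrize("lam", [0.1, 1.0, 10.0])
    def test_matches_convex_oracle(self, lam):
        rng = np.random.default_rng(int(lam * 10))
        for _ in range(5):
            n = int(rng.integers(8, 61))
            y = rng.normal(size=n) * rng.uniform(0.5, 3)
            got = trendfilter_solve(y, lam)
            want = oracle_solve(y, lam)
            assert np.max(np.abs(got - want)) < 1e-4

    def test_penalty_monotonicity(self):
        # ||D3 fitted||_1 is nonincreasing in lambda
        rng = np.random.default_rng(2)
        y = rng.normal(size=50)
        D = dense_diff_matrix(50)
        norms = [
            np.abs(D @ trendfilter_solve(y, lam)).sum()
            for lam in [0.01, 0.1, 1.0, 10.0, 100.0]
        ]
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="nonfinite"):
            trendfilter_solve(np.array([1.0, np.nan, 2.0, 3.0, 4.0]), 1.0)

    def test_lambda_max_reaches_polynomial(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        lam = lambda_max(y)
        fitted = trendfilter_solve(y, lam * 1.001)
        x = np.arange(30)
        poly = np.polyval(np.polyfit(x, y, 2), x)
        assert np.max(np.abs(fitted - poly)) < 1e-4


class TestCVSelect:
    def test_ordered_fold_assignment(self):
        np.testing.assert_array_equal(
            cv_fold_assignment(10, 5), [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        )

    def test_pure_quadratic_selects_largest_lambda(self):
        x = np.arange(40, dtype=float)
        y = 0.02 * x**2 - 0.3 * x + 1.0
        lam, table = cv_select_lambda(y)
        assert lam == table["lambda"].max()

    def test_sinusoid_beats_grid_extremes(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 4 * np.pi, 300)
        y = np.sin(x) + rng.normal(0, 0.3, 300)
        lam, table = cv_select_lambda(y)
        chosen = table.loc[np.isclose(table["lambda"], lam), "cv_error"].iloc[0]
        assert chosen < table["cv_error"].iloc[0]
        assert chosen < table["cv_error"].iloc[-1]

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="point"):
            cv_select_lambda(np.arange(7, dtype=float), n_folds=5)


class TestFitCyclicTrend:
    def test_noiseless_cosine_recovery_and_seam(self):
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        ct = fit_cyclic_trend(np.cos(theta), theta)
        assert np.max(np.abs(ct.fitted_values - np.cos(ct.train_thetas))) < 0.1
        assert abs(ct.fitted_values[0] - ct.fitted_values[-1]) < 0.1
        assert ct.pve > 0.99

    def test_constant_gene(self):
        theta = np.linspace(0, 2 * np.pi, 30, endpoint=False)
        ct = fit_cyclic_trend(np.full(30, 2.5), theta)
        assert ct.pve == 0.0
        assert ct.sigma >= 1e-3
        np.testing.assert_allclose(ct.fitted_values, 2.5, atol=1e-6)

    def test_middle_third_length(self):
        rng = np.random.default_rng(5)
        theta = rng.uniform(0, 2 * np.pi, 41)
        ct = fit_cyclic_trend(rng.normal(size=41), theta)
        assert ct.fitted_values.size == 41
        assert ct.train_thetas.size == 41
        assert np.all(np.diff(ct.train_thetas) > 0)


class TestPVE:
    @pytest.mark.parametrize(
        "y,fitted,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [2, 2, 2], 0.0),
            ([1, 2, 3], [1.5, 2, 2.5], 0.75),
        ],
    )
    def test_examples(self, y, fitted, expected):
        assert compute_pve(np.array(y, float), np.array(fitted, float)) == pytest.approx(expected)

    def test_zero_variance_is_zero(self):
        assert compute_pve(np.ones(5), np.zeros(5)) == 0.0


class TestPermutationTest:
    def test_add_one_convention(self):
        # a strongly cyclic gene beats every permutation of a null template
        rng = np.random.default_rng(6)
        theta = sim_phases = rng.uniform(0, 2 * np.pi, 60)
        cyclic = np.cos(theta)
        nulls = rng.normal(size=(3, 60))
        values = np.vstack([cyclic, nulls])
        B = 19
        rep = permutation_test(values, theta, B=B, seed=0)
        top = rep.iloc[0]
        assert top.gene_id == "gene_0"
        assert top.empirical_p == pytest.approx(1 / (B + 1))
        assert rep["rank"].tolist() == [1, 2, 3, 4]

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError, match="B"):
            permutation_test(np.zeros((2, 20)), np.zeros(20), B=0)

    def test_detection_eligibility_enforced(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(3, 30))
        with pytest.raises(ValueError, match="90%"):
            permutation_test(
                values, rng.uniform(0, 2 * np.pi, 30), B=5,
                detection_rates=np.array([0.5, 0.2, 0.9]),
            )


class TestEnrichment:
    def test_arithmetic(self):
        universe = [f"g{i}" for i in range(1000)]
        annot = universe[:11]
        hits = universe[:10] + universe[11:101]
        odds, p = enrichment_odds_ratio(hits, annot, universe)
        assert odds == pytest.approx(10 * 899 / (90 * 1), rel=1e-12)
        assert p < 1e-6

    def test_independence_is_near_one(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(2000)]
        hits = list(rng.choice(universe, 1000, replace=False))
        annot = list(rng.choice(universe, 1000, replace=False))
        odds, p = enrichment_odds_ratio(hits, annot, universe)
        assert 0.7 < odds < 1.4

    def test_disjoint_sets_depleted(self):
        universe = [f"g{i}" for i in range(100)]
        odds, _ = enrichment_odds_ratio(universe[:20], universe[20:40], universe)
        assert odds < 1

    def test_empty_universe(self):
        with pytest.raises(ValueError, match="universe"):
            enrichment_odds_ratio([], [], [])

    def test_haldane_correction_on_zero_cell(self):
        universe = [f"g{i}" for i in range(50)]
        hits = universe[:10]
        annot = universe[:10]  # hit & not-annotated cell is zero
        odds, _ = enrichment_odds_ratio(hits, annot, universe)
        assert np.isfinite(odds) and odds > 1
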