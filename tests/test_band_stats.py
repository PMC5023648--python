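"""Moran's I, correlograms, polynomial OLS/SAR fits, and method comparison."""

import numpy as np
import pandas as pd
import pytest

import altiband as ab
from altiband.band_stats import _sar_profile_loglik


def brute_force_morans(x, raw):
    """Literal double-sum evaluation of the Moran statistic."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xbar = x.mean()
    num = sum(raw[i, j] * (x[i] - xbar) * (x[j] - xbar)
              for i in range(n) for j in range(n))
    S = raw.sum()
    return n / S * num / ((x - xbar) ** 2).sum()


def sar_simulate(rng, W_std, lam, beta, x):
    n = len(x)
    u = np.linalg.solve(np.eye(n) - lam * W_std, rng.normal(0, 1, n))
    return beta[0] + beta[1] * x + u


class TestSpatialWeights:
    def test_row_standardization(self):
        w = ab.rank_adjacency_weights(5)
        sums = w.standardized.sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert w.S == 8  # 4 links, counted both ways

    def test_isolated_rows_stay_zero(self):
        raw = np.zeros((3, 3))
        raw[0, 1] = raw[1, 0] = 1
        w = ab.SpatialWeights(raw)
        assert w.standardized[2].sum() == 0

    def test_asymmetric_rejected(self):
        raw = np.zeros((2, 2))
        raw[0, 1] = 1
        with pytest.raises(ValueError):
            ab.SpatialWeights(raw)

    def test_distance_class_links(self):
        w = ab.distance_band_weights([0.0, 100.0, 200.0, 450.0], 100.0)
        assert w.raw[0, 1] == 1 and w.raw[1, 2] == 1
        assert w.raw[0, 2] == 0 and w.raw[2, 3] == 0

    def test_eigenvalues_match_dense(self):
        w = ab.rank_adjacency_weights(6)
        direct = np.sort(np.linalg.eigvals(w.standardized).real)
        assert np.allclose(np.sort(w.eigenvalues()), direct, atol=1e-10)


class TestMoransI:
    def test_two_point_antithesis(self):
        w = ab.distance_band_weights([100.0, 200.0], 100.0)
        assert ab.morans_i([1.0, -1.0], w) == pytest.approx(-1.0)

    def test_zero_middle_deviation(self):
        w = ab.distance_band_weights([100.0, 200.0, 300.0], 100.0)
        assert ab.morans_i([1.0, 2.0, 3.0], w) == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(4, 30)
            pos = np.sort(rng.choice(np.arange(100), size=n, replace=False)) * 100.0
            x = rng.normal(0, 1, n)
            w = ab.distance_band_weights(pos, 100.0)
            if w.S == 0:
                continue
            assert ab.morans_i(x, w) == pytest.approx(
                brute_force_morans(x, w.raw), abs=1e-12)

    def test_constant_values_rejected(self):
        w = ab.rank_adjacency_weights(4)
        with pytest.raises(ValueError, match="constant"):
            ab.morans_i([2.0, 2.0, 2.0, 2.0], w)

    def test_no_pairs_rejected(self):
        w = ab.distance_band_weights([0.0, 1000.0], 100.0)
        with pytest.raises(ValueError, match="pairs"):
            ab.morans_i([1.0, 2.0], w)


class TestCorrelogram:
    positions = np.arange(37) * 100.0 + 1400.0

    def test_classes_are_multiples_of_step(self):
        rng = np.random.default_rng(1)
        cg = ab.correlogram(rng.normal(0, 1, 37), self.positions, step=100.0,
                            max_lag=5, n_perm=99, seed=0)
        assert cg["class_m"].tolist() == [100.0, 200.0, 300.0, 400.0, 500.0]

    def test_perfect_gradient_positive_lag1(self):
        cg = ab.correlogram(self.positions.copy(), self.positions, step=100.0,
                            max_lag=3, n_perm=99, seed=0)
        assert cg.loc[cg["class_m"] == 100.0, "I"].iloc[0] > 0
        assert cg.loc[cg["class_m"] == 100.0, "p"].iloc[0] < 0.05

    def test_permutation_null_mean(self):
        """Mean of Moran's I over permutations is about -1/(n-1)."""
        rng = np.random.default_rng(2)
        n = 20
        x = rng.normal(0, 1, n)
        w = ab.rank_adjacency_weights(n)
        perms = np.array([ab.morans_i(rng.permutation(x), w) for _ in range(999)])
        se = perms.std(ddof=1) / np.sqrt(len(perms))
        assert abs(perms.mean() - (-1 / (n - 1))) <= 3 * se

    def test_positions_must_increase(self):
        with pytest.raises(ValueError):
            ab.correlogram([1.0, 2.0, 3.0], [0.0, 0.0, 100.0])


class TestFitPolynomial:
    def test_exact_line(self):
        x = np.linspace(0, 10, 12)
        fit = ab.fit_polynomial(2 * x + 1, x, 1)
        assert fit.coef_S == pytest.approx(2.0)
        assert fit.coef_C == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coef_Q is None

    def test_exact_parabola(self):
        x = np.linspace(-3, 5, 15)
        fit = ab.fit_polynomial(-x**2 + 4 * x, x, 2)
        assert fit.coef_Q == pytest.approx(-1.0)
        assert fit.coef_S == pytest.approx(4.0)
        assert fit.coef_C == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 5, 25)
        y = 1 + 0.5 * x - 0.2 * x**2 + rng.normal(0, 0.3, 25)
        fit = ab.fit_polynomial(y, x, 2)
        X = np.column_stack([np.ones_like(x), x, x**2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coef_C == pytest.approx(beta[0], abs=1e-8)
        assert fit.coef_S == pytest.approx(beta[1], abs=1e-8)
        assert fit.coef_Q == pytest.approx(beta[2], abs=1e-8)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            ab.fit_polynomial([1.0, 2, 3, 4], [1.0, 1, 1, 1], 1)


class TestFitSarError:
    x37 = np.arange(37) / 10.0
    w37 = ab.rank_adjacency_weights(37)

    def test_lambda_zero_reduces_to_ols(self):
        """At lambda = 0 the concentrated fit is exactly OLS."""
        rng = np.random.default_rng(4)
        y = 1 + 2 * self.x37 + rng.normal(0, 1, 37)
        X = np.column_stack([np.ones(37), self.x37])
        _, beta, _ = _sar_profile_loglik(0.0, y, X, self.w37.standardized,
                                         self.w37.eigenvalues())
        ols = ab.fit_polynomial(y, self.x37, 1)
        assert beta[0] == pytest.approx(ols.coef_C, abs=1e-10)
        assert beta[1] == pytest.approx(ols.coef_S, abs=1e-10)

    def test_nonspatial_data_gives_small_lambda(self):
        rng = np.random.default_rng(5)
        y = 1 + 2 * self.x37 + rng.normal(0, 1, 37)
        fit = ab.fit_sar_error(y, self.x37, 1, self.w37)
        assert abs(fit.lam) <= max(2 * fit.lam_se, 0.35)
        ols = ab.fit_polynomial(y, self.x37, 1)
        assert fit.coef_S == pytest.approx(ols.coef_S, abs=0.3)

    def test_loglik_nests_ols(self):
        rng = np.random.default_rng(6)
        y = sar_simulate(rng, self.w37.standardized, 0.5, (1.0, 2.0), self.x37)
        sar = ab.fit_sar_error(y, self.x37, 1, self.w37)
        ols = ab.fit_polynomial(y, self.x37, 1)
        assert sar.loglik >= ols.loglik - 1e-9

    def test_pseudo_r2_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for lam in (0.0, 0.4, 0.8):
            y = sar_simulate(rng, self.w37.standardized, lam, (0.0, 1.0), self.x37)
            fit = ab.fit_sar_error(y, self.x37, 1, self.w37)
            assert 0.0 <= fit.r2 <= 1.0
            assert 0.0 <= fit.trend_r2 <= 1.0

    def test_pseudo_r2_close_to_ols_r2_without_spatial_signal(self):
        rng = np.random.default_rng(8)
        diffs = []
        for _ in range(30):
            y = 1 + 2 * self.x37 + rng.normal(0, 1, 37)
            sar = ab.fit_sar_error(y, self.x37, 1, self.w37)
            ols = ab.fit_polynomial(y, self.x37, 1)
            diffs.append(abs(sar.r2 - ols.r2))
        assert np.mean(diffs) < 0.02

    def test_recovers_known_lambda(self):
        rng = np.random.default_rng(9)
        lams = [ab.fit_sar_error(
            sar_simulate(rng, self.w37.standardized, 0.6, (1.0, 2.0), self.x37),
            self.x37, 1, self.w37).lam for _ in range(200)]
        assert abs(np.mean(lams) - 0.6) < 0.1

    def test_isolated_weights_rejected(self):
        w = ab.SpatialWeights(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            ab.fit_sar_error(np.arange(5.0), np.arange(5.0), 1, w)


class TestSelectOrder:
    @staticmethod
    def make_fit(order, aicc_val):
        return ab.PolynomialModelFit(
            response_name="y", predictor_name="x", order=order, engine="OLS",
            coef_Q=0.0 if order == 2 else None, coef_S=1.0, coef_C=0.0,
            r2=0.5, p_value=0.01, loglik=0.0, aicc=aicc_val, n_used=30)

    def test_clear_improvement_selects_order2(self):
        chosen = ab.select_order(self.make_fit(1, 50.0), self.make_fit(2, 45.0))
        assert chosen.order == 2 and chosen.selected

    def test_small_improvement_prefers_simplicity(self):
        chosen = ab.select_order(self.make_fit(1, 50.0), self.make_fit(2, 49.0))
        assert chosen.order == 1

    def test_tie_prefers_first_order(self):
        chosen = ab.select_order(self.make_fit(1, 50.0), self.make_fit(2, 50.0))
        assert chosen.order == 1

    def test_symmetric_in_argument_order(self):
        a, b = self.make_fit(1, 50.0), self.make_fit(2, 40.0)
        assert ab.select_order(a, b).order == ab.select_order(b, a).order == 2

    def test_mismatched_fits_rejected(self):
        a = self.make_fit(1, 50.0)
        b = self.make_fit(2, 45.0)
        b.predictor_name = "other"
        with pytest.raises(ValueError):
            ab.select_order(a, b)


class TestCompareMethods:
    @staticmethod
    def make_fit(response, predictor, r2):
        return ab.PolynomialModelFit(
            response_name=response, predictor_name=predictor, order=1, engine="SAR",
            coef_Q=None, coef_S=1.0, coef_C=0.0, r2=r2, p_value=0.01,
            loglik=0.0, aicc=0.0, n_used=37, lam=0.1)

    def test_winner_flags(self):
        fits = [self.make_fit("species_obs", "MAT", 0.9),
                self.make_fit("species_cor1", "MAT", 0.3),
                self.make_fit("species_cor2", "MAT", 0.7)]
        table = ab.compare_methods(fits)
        row = table[table["richness_kind"] == "cor2"].iloc[0]
        assert row["winner"] == "method2"
        assert table[table["richness_kind"] == "obs"].iloc[0]["winner"] == ""

    def test_tie_flag(self):
        fits = [self.make_fit("species_cor1", "MDE", 0.5),
                self.make_fit("species_cor2", "MDE", 0.5)]
        table = ab.compare_methods(fits)
        assert (table["winner"] == "tie").all()
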