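import numpy as np
import pytest
from scipy.integrate import quad
from scipy.interpolate import splev

from dalyvol import spline as sp
from dalyvol.synthetic import gen_sdi_daly_series, true_volatility

from conftest import cox_de_boor


@pytest.fixture(scope="module")
def spec9():
    return sp.choose_knots(np.arange(1.0, 10.0), n_interior=3, degree=3)


def _full_coefficients(fit):
    """Map drop-first coefficients back to the full clamped basis."""
    gamma = fit.coefficients
    full = np.full(fit.design.spec.n_basis, gamma[0])
    full[1:] += gamma[1:]
    return full


def _fitted_derivative(fit):
    t = fit.design.spec.knot_vector
    c = _full_coefficients(fit)
    return lambda u: splev(u, (t, c, 3), der=1)


class TestChooseKnots:
    def test_equally_spaced_quantiles_of_1_to_9(self, spec9):
        assert spec9.interior_knots == (3.0, 5.0, 7.0)
        assert spec9.boundary == (1.0, 9.0)
        assert spec9.n_basis == 7

    def test_zero_interior_knots_gives_plain_cubic_basis(self):
        spec = sp.choose_knots(np.linspace(0, 1, 20), n_interior=0)
        assert spec.interior_knots == ()
        assert spec.n_basis == 4

    def test_boundary_knots_are_exact_min_max(self):
        x = np.array([0.17, 0.9, 0.33, 0.55, 0.42, 0.61, 0.78, 0.05, 0.25])
        spec = sp.choose_knots(x)
        assert spec.boundary == (0.05, 0.9)

    def test_too_few_distinct_values_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            sp.choose_knots([1.0, 2.0, 3.0, 1.0, 2.0, 3.0, 1.0, 2.0])

    def test_duplicate_quantiles_collapse_with_warning(self):
        x = np.array([0.0] * 10 + [0.5] * 10 + [1.0] * 10 + [0.2, 0.4, 0.6, 0.8, 0.3])
        with pytest.warns(RuntimeWarning, match="collapsed"):
            spec = sp.choose_knots(x)
        assert len(spec.interior_knots) < 3


class TestDesign:
    def test_clamped_endpoint_property(self, spec9):
        full = sp._full_basis(np.array([1.0]), spec9)
        assert full[0, 0] == 1.0
        assert np.all(full[0, 1:] == 0.0)

    def test_partition_of_unity(self, spec9):
        x = np.linspace(1, 9, 101)
        full = sp._full_basis(x, spec9)
        assert np.allclose(full.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_brute_force_cox_de_boor(self, spec9):
        rng = np.random.default_rng(3)
        x = rng.uniform(1.0, 9.0, 50)
        full = sp._full_basis(x, spec9)
        t = spec9.knot_vector
        for i, xi in enumerate(x):
            for j in range(spec9.n_basis):
                assert full[i, j] == pytest.approx(
                    cox_de_boor(t, j, 3, xi), abs=1e-12
                )

    def test_no_extrapolation(self, spec9):
        with pytest.raises(ValueError, match="boundary"):
            sp.build_design([0.5, 5.0], spec9)

    def test_drop_first_design_shape(self, spec9):
        d = sp.build_design(np.linspace(1, 9, 30), spec9)
        assert d.X.shape == (30, 7)  # intercept + 6 retained columns
        assert np.all(d.X[:, 0] == 1.0)


class TestPenaltyMatrix:
    def test_symmetric_with_zero_intercept_row_and_column(self, spec9):
        P = sp.penalty_matrix(spec9).P
        assert np.array_equal(P, P.T)
        assert np.all(P[0, :] == 0.0)
        assert np.all(P[:, 0] == 0.0)

    def test_positive_semidefinite(self, spec9):
        P = sp.penalty_matrix(spec9).P
        assert np.linalg.eigvalsh(P).min() >= -1e-10

    def test_annihilates_constant_functions(self, spec9):
        # drop-first: a constant is the intercept coordinate alone
        P = sp.penalty_matrix(spec9).P
        e0 = np.zeros(7); e0[0] = 1.0
        assert np.allclose(P @ e0, 0.0, atol=1e-14)
        # spline-only: a constant is the all-ones coefficient vector
        G = sp.penalty_matrix(spec9, "spline-only").P
        assert np.allclose(G @ np.ones(7), 0.0, atol=1e-10)

    def test_entries_match_adaptive_integration(self, spec9):
        G = sp.derivative_gram(spec9)
        t = spec9.knot_vector
        pts = list(np.unique(t))
        for j in range(7):
            for jp in range(j, 7):
                cj, cjp = np.eye(7)[j], np.eye(7)[jp]
                ref, _ = quad(
                    lambda u: splev(u, (t, cj, 3), der=1) * splev(u, (t, cjp, 3), der=1),
                    1.0, 9.0, points=pts, limit=200,
                )
                assert G[j, jp] == pytest.approx(ref, abs=1e-8)


class TestFitPenalized:
    def test_zero_lambda_equals_ols(self, noisy_sdi_data):
        x, y = noisy_sdi_data
        spec = sp.choose_knots(x)
        d = sp.build_design(x, spec)
        P = sp.penalty_matrix(spec)
        fit = sp.fit_penalized(d, y, 0.0, P)
        ols = np.linalg.lstsq(d.X, y, rcond=None)[0]
        assert np.allclose(fit.coefficients, ols, rtol=1e-8)
        assert fit.df == pytest.approx(d.X.shape[1], abs=1e-8)

    @pytest.mark.parametrize("lam", [0.0, 1.0, 1e4])
    def test_constant_response_is_reproduced_at_any_lambda(self, lam):
        x = np.linspace(0, 1, 28)
        spec = sp.choose_knots(x)
        d = sp.build_design(x, spec)
        P = sp.penalty_matrix(spec)
        fit = sp.fit_penalized(d, np.full(28, 7.5), lam, P)
        assert np.allclose(fit.fitted, 7.5, atol=1e-9)
        assert sp.volatility(fit, P) == pytest.approx(0.0, abs=1e-12)

    def test_huge_lambda_collapses_to_mean(self, noisy_sdi_data):
        x, y = noisy_sdi_data
        spec = sp.choose_knots(x)
        d = sp.build_design(x, spec)
        P = sp.penalty_matrix(spec)
        fit = sp.fit_penalized(d, y, 1e8, P)
        assert np.max(np.abs(fit.fitted - y.mean())) <= 1e-3 * abs(y.mean())
        assert fit.df == pytest.approx(1.0, abs=0.01)

    def test_noiseless_cubic_polynomial_is_exact_at_zero_lambda(self):
        # p(x) = 2 - 3x + 0.5x^2 + 4x^3 lies in the spline space
        x = np.linspace(0, 1, 28)
        y = 2 - 3 * x + 0.5 * x**2 + 4 * x**3
        spec = sp.choose_knots(x)
        d = sp.build_design(x, spec)
        P = sp.penalty_matrix(spec)
        fit = sp.fit_penalized(d, y, 0.0, P)
        assert np.allclose(fit.fitted, y, rtol=1e-8)
        truth = true_volatility("cubic", {"c0": 2, "c1": -3, "c2": 0.5, "c3": 4}, (0, 1))
        assert sp.volatility(fit, P) == pytest.approx(truth, rel=1e-6)

    def test_parametrizations_agree(self, noisy_sdi_data):
        x, y = noisy_sdi_data
        spec = sp.choose_knots(x)
        dA = sp.build_design(x, spec, "drop-first")
        dB = sp.build_design(x, spec, "spline-only")
        PA = sp.penalty_matrix(spec, "drop-first")
        PB = sp.penalty_matrix(spec, "spline-only")
        for lam in (0.0, 3.7, 1e3):
            fA = sp.fit_penalized(dA, y, lam, PA)
            fB = sp.fit_penalized(dB, y, lam, PB)
            assert np.allclose(fA.fitted, fB.fitted, rtol=1e-7)
            assert sp.volatility(fA, PA) == pytest.approx(
                sp.volatility(fB, PB), rel=1e-6
            )


class TestBicAndSelection:
    def test_bic_formula_and_monotonicities(self, noisy_sdi_data):
        x, y = noisy_sdi_data
        spec = sp.choose_knots(x)
        d = sp.build_design(x, spec)
        P = sp.penalty_matrix(spec)
        fit = sp.fit_penalized(d, y, 1.0, P)
        m = len(y)
        assert sp.bic_of_fit(fit) == pytest.approx(
            m * np.log(fit.rss / m) + fit.df * np.log(m)
        )
        # monotone in df at fixed RSS and in RSS at fixed df
        mk = lambda rss, df: sp.PenalizedFit(
            coefficients=fit.coefficients, lam=1.0, fitted=fit.fitted,
            rss=rss, df=df, bic=m * np.log(rss / m) + df * np.log(m), design=d,
        )
        assert sp.bic_of_fit(mk(50.0, 3.0)) < sp.bic_of_fit(mk(50.0, 5.0))
        assert sp.bic_of_fit(mk(40.0, 3.0)) < sp.bic_of_fit(mk(50.0, 3.0))

    def test_interpolating_fit_has_undefined_bic(self):
        x = np.linspace(0, 1, 28)
        y = 1.0 + 2.0 * x  # noiseless: lambda=0 interpolates within rounding
        spec = sp.choose_knots(x)
        d = sp.build_design(x, spec)
        P = sp.penalty_matrix(spec)
        fit = sp.fit_penalized(d, y, 0.0, P)
        with pytest.raises(sp.InterpolationError):
            sp.bic_of_fit(fit)

    def test_grid_scan_minimum_is_interior_on_noisy_cubic(self):
        xg = np.linspace(0, 1, 28)
        fg = 2 - 3 * xg + 0.5 * xg**2 + 4 * xg**3
        sigma = 0.05 * (fg.max() - fg.min())  # 5% of the response range
        x, y, _ = gen_sdi_daly_series(
            "cubic", {"c0": 2.0, "c1": -3.0, "c2": 0.5, "c3": 4.0},
            28, sigma=sigma, seed=5,
        )
        spec = sp.choose_knots(x)
        d = sp.build_design(x, spec)
        P = sp.penalty_matrix(spec)
        grid = sp.default_lambda_grid()
        lam, _ = sp.select_lambda(d, y, P, grid)
        assert grid[0] < lam < grid[-1]

    def test_singleton_grid(self, noisy_sdi_data):
        x, y = noisy_sdi_data
        spec = sp.choose_knots(x)
        d = sp.build_design(x, spec)
        P = sp.penalty_matrix(spec)
        lam, fits = sp.select_lambda(d, y, P, [0.37])
        assert lam == 0.37 and len(fits) == 1

    def test_bic_tie_broken_toward_larger_lambda(self, noisy_sdi_data):
        x, y = noisy_sdi_data
        spec = sp.choose_knots(x)
        d = sp.build_design(x, spec)
        # a zero penalty makes every lambda give the identical fit: a tie
        P0 = sp.PenaltySpec(P=np.zeros((7, 7)), spec=spec, parametrization="drop-first")
        lam, _ = sp.select_lambda(d, y, P0, [0.1, 1.0, 10.0])
        assert lam == 10.0

    def test_df_nonincreasing_and_rss_nondecreasing_along_grid(self, noisy_sdi_data):
        x, y = noisy_sdi_data
        spec = sp.choose_knots(x)
        d = sp.build_design(x, spec)
        P = sp.penalty_matrix(spec)
        _, fits = sp.select_lambda(d, y, P)
        dfs = [f.df for f in fits]
        rsss = [f.rss for f in fits]
        assert all(b <= a + 1e-9 for a, b in zip(dfs, dfs[1:]))
        assert all(b >= a - 1e-9 * max(1, a) for a, b in zip(rsss, rsss[1:]))

    def test_grid_path_agrees_with_direct_solver(self, noisy_sdi_data):
        x, y = noisy_sdi_data
        spec = sp.choose_knots(x)
        d = sp.build_design(x, spec)
        P = sp.penalty_matrix(spec)
        _, fits = sp.select_lambda(d, y, P)
        for f in fits[::12]:
            ref = sp.fit_penalized(d, y, f.lam, P)
            assert np.allclose(f.coefficients, ref.coefficients, rtol=1e-7, atol=1e-9)
            assert f.df == pytest.approx(ref.df, abs=1e-7)


class TestVolatility:
    def test_noiseless_linear_recovers_b_squared_L(self):
        # slope 3 over an interval of length 1: integral of 9 dx = 9
        x, y, truth = gen_sdi_daly_series(
            "linear", {"intercept": 2.0, "slope": 3.0}, 28, 0.0, seed=1
        )
        spec = sp.choose_knots(x)
        d = sp.build_design(x, spec)
        P = sp.penalty_matrix(spec)
        fit = sp.fit_penalized(d, y, 1e-8, P)
        assert sp.volatility(fit, P) == pytest.approx(truth, rel=1e-3)

    def test_unit_convention_equals_direct_integration(self, noisy_sdi_data):
        x, y = noisy_sdi_data
        spec = sp.choose_knots(x)
        d = sp.build_design(x, spec)
        P = sp.penalty_matrix(spec)
        fit = sp.fit_penalized(d, y, 2.5, P)
        deriv = _fitted_derivative(fit)
        ref, _ = quad(
            lambda u: deriv(u) ** 2, spec.boundary[0], spec.boundary[1],
            points=list(np.unique(spec.knot_vector)), limit=200,
        )
        assert sp.volatility(fit, P) == pytest.approx(ref, rel=1e-6)

    def test_literal_convention_scales_by_lambda(self, noisy_sdi_data):
        x, y = noisy_sdi_data
        spec = sp.choose_knots(x)
        d = sp.build_design(x, spec)
        P = sp.penalty_matrix(spec)
        fit = sp.fit_penalized(d, y, 4.0, P)
        unit = sp.volatility(fit, P, "unit-penalty")
        assert sp.volatility(fit, P, "literal-lambda") == pytest.approx(4.0 * unit)
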