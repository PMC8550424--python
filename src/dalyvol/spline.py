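"""Penalized cubic B-spline regression and the volatility functional.

The model is ``Y_i = f(x_i) + eps_i`` with ``f`` expanded in a clamped
(open-uniform) cubic B-spline basis with 3 interior knots at equally
spaced quantiles of ``x``:

    f(x) = gamma_0 + sum_j B_j(x) gamma_j .

Roughness is penalized through the first-derivative Gram matrix
``P[j,j'] = ∫ B_j'(x) B_{j'}'(x) dx`` (zero in the intercept row and
column), giving the ridge-type closed form

    gamma_hat(lambda) = (B'B + lambda P)^{-1} B'Y .

The penalty weight is selected by minimizing a Gaussian-profile BIC,
``m log(RSS/m) + df(lambda) log m`` with ``df = tr S_lambda`` the trace of
the smoother matrix.  The headline statistic is the volatility functional
``∫ {f'(x)}^2 dx`` — the total squared rate of change of the fitted curve
over its support — estimated by the quadratic form ``gamma' P gamma``
(unit-penalty convention) or ``lambda* gamma' P gamma`` (literal-lambda
convention), with percentile-bootstrap confidence intervals.

A full clamped basis plus a separate intercept column is exactly
collinear (the basis sums to one), so the design drops the first spline
column; the equivalent no-intercept parametrization that keeps all basis
functions is available and yields identical fits and volatility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import linalg
from scipy.interpolate import BSpline

__all__ = [
    "SplineBasisSpec",
    "DesignMatrix",
    "PenaltySpec",
    "PenalizedFit",
    "VolatilityEstimate",
    "SingularDesignError",
    "InterpolationError",
    "default_lambda_grid",
    "choose_knots",
    "build_design",
    "penalty_matrix",
    "fit_penalized",
    "bic_of_fit",
    "select_lambda",
    "volatility",
    "bootstrap_volatility",
    "volatility_report",
]


class SingularDesignError(np.linalg.LinAlgError):
    """The penalized normal equations are singular (degenerate abscissae)."""


class InterpolationError(ValueError):
    """RSS is (numerically) zero; the Gaussian-profile BIC is undefined."""


def default_lambda_grid(num: int = 61) -> np.ndarray:
    """61 logarithmically spaced penalty weights from 1e-6 to 1e6."""
    return np.logspace(-6.0, 6.0, num)


@dataclass(frozen=True)
class SplineBasisSpec:
    """Degree, interior knots and boundary knots of a clamped B-spline basis."""

    degree: int
    interior_knots: tuple[float, ...]
    boundary: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.boundary
        ks = self.interior_knots
        if not all(lo < k < hi for k in ks):
            raise ValueError("interior knots must lie strictly inside the boundary")
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("interior knots must be strictly increasing")

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        k = self.degree
        return np.array([lo] * (k + 1) + list(self.interior_knots) + [hi] * (k + 1))

    @property
    def n_basis(self) -> int:
        """Number of B-spline basis functions J = #interior + degree + 1."""
        return len(self.interior_knots) + self.degree + 1


@dataclass(frozen=True)
class DesignMatrix:
    """Model matrix: intercept + retained spline columns (or spline-only)."""

    X: np.ndarray
    x: np.ndarray
    spec: SplineBasisSpec
    parametrization: str  # "drop-first" | "spline-only"

    @property
    def m(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class PenaltySpec:
    """Unit first-derivative penalty matrix aligned with a DesignMatrix."""

    P: np.ndarray
    spec: SplineBasisSpec
    parametrization: str

    def scaled(self, lam: float) -> np.ndarray:
        return lam * self.P


@dataclass(frozen=True)
class PenalizedFit:
    coefficients: np.ndarray
    lam: float
    fitted: np.ndarray
    rss: float
    df: float
    bic: float | None
    design: DesignMatrix

    @property
    def m(self) -> int:
        return self.design.m


@dataclass(frozen=True)
class VolatilityEstimate:
    """Point estimate of ∫{f'(x)}^2 dx with a percentile-bootstrap CI."""

    point: float
    convention: str
    ci: tuple[float, float]
    replicates: int
    seed: int
    lambda_policy: str
    redraws: int
    replicate_values: np.ndarray = field(repr=False, default=None)
    lambda_star: float = float("nan")


def choose_knots(x: Sequence[float], n_interior: int = 3, degree: int = 3) -> SplineBasisSpec:
    """Interior knots at equally spaced quantiles of ``x``, boundary at min/max.

    Quantiles use linear interpolation between order statistics (the
    conventional "type 7" definition).  Duplicate knots after placement are
    collapsed with a warning.
    """
    if n_interior < 0:
        raise ValueError("interior knot count must be >= 0")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    xa = np.asarray(x, dtype=float)
    distinct = np.unique(xa)
    needed = degree + n_interior + 2
    if distinct.size < needed:
        raise ValueError(
            f"need at least {needed} distinct x values for degree {degree} "
            f"with {n_interior} interior knots, got {distinct.size}"
        )
    lo, hi = float(xa.min()), float(xa.max())
    if n_interior == 0:
        return SplineBasisSpec(degree, (), (lo, hi))
    probs = np.arange(1, n_interior + 1) / (n_interior + 1)
    knots = np.quantile(xa, probs, method="linear")
    keep = [k for k in np.unique(knots) if lo < k < hi]
    if len(keep) < n_interior:
        warnings.warn(
            f"collapsed {n_interior - len(keep)} duplicate/boundary interior knot(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    return SplineBasisSpec(degree, tuple(float(k) for k in keep), (lo, hi))


def _full_basis(x: np.ndarray, spec: SplineBasisSpec) -> np.ndarray:
    """Evaluate all J clamped basis functions at x (m x J, rows sum to 1)."""
    t = spec.knot_vector
    return BSpline.design_matrix(x, t, spec.degree, extrapolate=False).toarray()


def _deriv_basis(x: np.ndarray, spec: SplineBasisSpec) -> np.ndarray:
    """First derivatives of all J basis functions at x, via the standard
    degree-lowering recurrence B'_{j,k} = k (B_{j,k-1}/(t_{j+k}-t_j)
    - B_{j+1,k-1}/(t_{j+k+1}-t_{j+1}))."""
    t = spec.knot_vector
    k = spec.degree
    J = spec.n_basis
    lower = BSpline.design_matrix(x, t, k - 1, extrapolate=False).toarray()  # m x (J+1)
    # At x == hi the degree-(k-1) basis on the clamped vector is degenerate:
    # scipy puts the unit mass on the last (zero-width) function, whereas the
    # left limit — the value consistent with the derivative on [lo, hi] —
    # assigns it to the previous one.
    at_hi = x == t[-1]
    if np.any(at_hi):
        lower[at_hi] = 0.0
        lower[at_hi, J - 1] = 1.0
    out = np.zeros((x.size, J))
    for j in range(J):
        d1 = t[j + k] - t[j]
        d2 = t[j + k + 1] - t[j + 1]
        if d1 > 0:
            out[:, j] += k * lower[:, j] / d1
        if d2 > 0:
            out[:, j] -= k * lower[:, j + 1] / d2
    return out


def build_design(
    x: Sequence[float], spec: SplineBasisSpec, parametrization: str = "drop-first"
) -> DesignMatrix:
    """Evaluate the model matrix at ``x`` (no extrapolation allowed).

    ``drop-first``: intercept column followed by basis functions 2..J; the
    first basis function is dropped because the full clamped basis sums to
    one and would be collinear with the intercept.  ``spline-only``: all J
    basis functions, no intercept — the same column space.
    """
    xa = np.asarray(x, dtype=float)
    lo, hi = spec.boundary
    if xa.min() < lo or xa.max() > hi:
        raise ValueError(f"abscissae outside the boundary interval [{lo}, {hi}]")
    full = _full_basis(xa, spec)
    if parametrization == "drop-first":
        X = np.column_stack([np.ones(xa.size), full[:, 1:]])
    elif parametrization == "spline-only":
        X = full
    else:
        raise ValueError(f"unknown parametrization {parametrization!r}")
    return DesignMatrix(X=X, x=xa, spec=spec, parametrization=parametrization)


def derivative_gram(spec: SplineBasisSpec) -> np.ndarray:
    """J x J matrix of ∫ B_j'(x) B_{j'}'(x) dx over the boundary interval.

    Gauss-Legendre quadrature per inter-knot interval; the integrand is a
    piecewise polynomial of degree 2(degree-1), so a 4-point rule (exact
    through degree 7) is exact for the cubic case.
    """
    breaks = np.unique(spec.knot_vector)
    nodes, weights = leggauss(max(4, spec.degree))
    J = spec.n_basis
    G = np.zeros((J, J))
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        xq = a + half * (nodes + 1.0)
        D = _deriv_basis(xq, spec)
        G += half * (D.T * weights) @ D
    return G


def penalty_matrix(spec: SplineBasisSpec, parametrization: str = "drop-first") -> PenaltySpec:
    """Unit penalty matrix aligned with :func:`build_design`'s columns.

    Under ``drop-first`` the intercept row and column are identically zero
    and the spline block is the derivative Gram restricted to the retained
    functions; a constant function is in the null space in both
    parametrizations.
    """
    G = derivative_gram(spec)
    if parametrization == "drop-first":
        p = G.shape[0]  # intercept + (J-1) retained columns
        P = np.zeros((p, p))
        P[1:, 1:] = G[1:, 1:]
    elif parametrization == "spline-only":
        P = G
    else:
        raise ValueError(f"unknown parametrization {parametrization!r}")
    P = 0.5 * (P + P.T)
    return PenaltySpec(P=P, spec=spec, parametrization=parametrization)


def _rss_floor(y: np.ndarray) -> float:
    scale = max(1.0, float(np.max(np.abs(y))))
    return y.size * (1e-8 * scale) ** 2


def fit_penalized(
    design: DesignMatrix,
    y: Sequence[float],
    lam: float,
    penalty: PenaltySpec,
) -> PenalizedFit:
    """Solve the penalized normal equations (B'B + lambda P) gamma = B'Y."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if penalty.parametrization != design.parametrization:
        raise ValueError("penalty and design use different parametrizations")
    ya = np.asarray(y, dtype=float)
    X = design.X
    if ya.size != X.shape[0]:
        raise ValueError("length of Y must match the design row count")
    XtX = X.T @ X
    Xty = X.T @ ya
    A = XtX + lam * penalty.P
    try:
        c, low = linalg.cho_factor(A)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(
            "penalized normal equations are singular; degenerate abscissae?"
        ) from exc
    coef = linalg.cho_solve((c, low), Xty)
    df = float(np.trace(linalg.cho_solve((c, low), XtX)))
    fitted = X @ coef
    rss = float(np.sum((ya - fitted) ** 2))
    bic = None
    if rss > _rss_floor(ya):
        m = ya.size
        bic = m * np.log(rss / m) + df * np.log(m)
    return PenalizedFit(
        coefficients=coef, lam=float(lam), fitted=fitted, rss=rss, df=df,
        bic=bic, design=design,
    )


def bic_of_fit(fit: PenalizedFit) -> float:
    """Gaussian-profile BIC m log(RSS/m) + df log m; undefined at RSS = 0."""
    if fit.bic is None:
        raise InterpolationError(
            "residual sum of squares is numerically zero (interpolating fit); "
            "BIC is undefined under the Gaussian profile form"
        )
    return fit.bic


def select_lambda(
    design: DesignMatrix,
    y: Sequence[float],
    penalty: PenaltySpec,
    grid: Sequence[float] | None = None,
) -> tuple[float, list[PenalizedFit]]:
    """Grid-minimize BIC over penalty weights; ties go to the larger lambda.

    The whole grid is profiled through one generalized eigendecomposition
    of (P, B'B): with B'B = R'R and R^{-T} P R^{-1} = Q diag(mu) Q',
    the coefficients are U diag(1/(1 + lambda mu)) U' B'Y with U = R^{-1} Q
    and df(lambda) = sum_i 1/(1 + lambda mu_i), so each grid point costs a
    couple of small matrix-vector products.  This is algebraically the same
    estimator as :func:`fit_penalized`.
    """
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    if np.any(grid < 0):
        raise ValueError("lambda grid must be nonnegative")
    grid = np.sort(grid)
    ya = np.asarray(y, dtype=float)
    X = design.X
    m = ya.size
    XtX = X.T @ X
    Xty = X.T @ ya
    try:
        R = np.linalg.cholesky(XtX).T
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(
            "normal equations are singular; degenerate abscissae?"
        ) from exc
    Rinv = linalg.solve_triangular(R, np.eye(R.shape[0]))
    W = Rinv.T @ penalty.P @ Rinv
    mu, Q = np.linalg.eigh(0.5 * (W + W.T))
    mu = np.clip(mu, 0.0, None)
    U = Rinv @ Q
    c = U.T @ Xty                      # rotated coefficients at lambda = 0
    M = X @ U                          # m x p, fitted = M @ (c / (1 + lam*mu))
    shrink = 1.0 / (1.0 + np.outer(mu, grid))        # p x L
    coefs = U @ (c[:, None] * shrink)                # p x L
    fitted = M @ (c[:, None] * shrink)               # m x L
    rss = np.sum((ya[:, None] - fitted) ** 2, axis=0)
    dfs = shrink.sum(axis=0)
    floor = _rss_floor(ya)
    fits = []
    for i, lam in enumerate(grid):
        bic = None
        if rss[i] > floor:
            bic = m * np.log(rss[i] / m) + dfs[i] * np.log(m)
        fits.append(
            PenalizedFit(
                coefficients=coefs[:, i], lam=float(lam), fitted=fitted[:, i],
                rss=float(rss[i]), df=float(dfs[i]), bic=bic, design=design,
            )
        )
    bics = [bic_of_fit(f) for f in fits]
    best = min(bics)
    # ascending grid: the last index attaining the minimum is the largest lambda
    idx = max(i for i, b in enumerate(bics) if b == best)
    return fits[idx].lam, fits


def volatility(fit: PenalizedFit, penalty: PenaltySpec, convention: str = "unit-penalty") -> float:
    """The volatility quadratic form of a fitted curve.

    ``unit-penalty`` returns gamma' P gamma, which equals
    ∫ {f_hat'(x)}^2 dx exactly; ``literal-lambda`` returns
    lambda * gamma' P gamma, the quadratic form with the fitted penalty
    weight left in place.
    """
    if penalty.parametrization != fit.design.parametrization:
        raise ValueError("penalty and fit use different parametrizations")
    q = float(fit.coefficients @ penalty.P @ fit.coefficients)
    q = max(q, 0.0)
    if convention == "unit-penalty":
        return q
    if convention == "literal-lambda":
        return fit.lam * q
    raise ValueError(f"unknown convention {convention!r}")


def _fit_and_volatility(
    x: np.ndarray,
    y: np.ndarray,
    *,
    degree: int,
    n_interior: int,
    grid,
    convention: str,
) -> tuple[float, float, PenalizedFit, PenaltySpec]:
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    spec = choose_knots(xs, n_interior=n_interior, degree=degree)
    design = build_design(xs, spec)
    penalty = penalty_matrix(spec)
    lam_star, fits = select_lambda(design, ys, penalty, grid)
    best = next(f for f in fits if f.lam == lam_star)
    return volatility(best, penalty, convention), lam_star, best, penalty


def bootstrap_volatility(
    x: Sequence[float],
    y: Sequence[float],
    *,
    degree: int = 3,
    n_interior: int = 3,
    grid: Sequence[float] | None = None,
    convention: str = "unit-penalty",
    replicates: int = 1000,
    seed: int = 0,
    resample: str = "pairs",
) -> VolatilityEstimate:
    """Volatility point estimate with a 95% percentile-bootstrap CI.

    ``pairs`` resampling draws (x_i, Y_i) pairs with replacement; each
    replicate re-chooses knots on its resampled abscissae and re-selects
    lambda by BIC before computing the volatility.  A replicate whose
    resampled x has too few distinct values to support the basis is
    redrawn (counted in ``redraws``); more than ``100 * replicates``
    redraws is an error.  ``residual`` resampling keeps x fixed and
    resamples centered residuals of the full-data fit.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if resample not in ("pairs", "residual"):
        raise ValueError(f"unknown resampling scheme {resample!r}")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = xa.size
    if ya.size != n:
        raise ValueError("x and Y must have equal length")
    min_distinct = degree + n_interior + 2
    if np.unique(xa).size < min_distinct:
        raise ValueError(f"need at least {min_distinct} distinct x values")

    point, lam_star, full_fit, _ = _fit_and_volatility(
        xa, ya, degree=degree, n_interior=n_interior, grid=grid, convention=convention
    )

    rng = np.random.default_rng(seed)
    values = np.empty(replicates)
    redraws = 0
    max_redraws = 100 * replicates
    if resample == "residual":
        resid = ya - np.interp(xa, full_fit.design.x, full_fit.fitted)
        resid = resid - resid.mean()
        fitted_at_x = np.interp(xa, full_fit.design.x, full_fit.fitted)
    b = 0
    while b < replicates:
        if resample == "pairs":
            idx = rng.integers(0, n, size=n)
            xb, yb = xa[idx], ya[idx]
            if np.unique(xb).size < min_distinct:
                redraws += 1
                if redraws > max_redraws:
                    raise RuntimeError(
                        f"exceeded {max_redraws} bootstrap redraws; abscissae "
                        "cannot support the basis under pairs resampling"
                    )
                continue
        else:
            xb = xa
            yb = fitted_at_x + rng.choice(resid, size=n, replace=True)
        values[b], _, _, _ = _fit_and_volatility(
            xb, yb, degree=degree, n_interior=n_interior, grid=grid, convention=convention
        )
        b += 1
    lo, hi = np.percentile(values, [2.5, 97.5])
    return VolatilityEstimate(
        point=point,
        convention=convention,
        ci=(float(lo), float(hi)),
        replicates=replicates,
        seed=seed,
        lambda_policy="reselect-per-replicate",
        redraws=redraws,
        replicate_values=values,
        lambda_star=lam_star,
    )


def volatility_report(
    x: Sequence[float],
    y: Sequence[float],
    *,
    degree: int = 3,
    n_interior: int = 3,
    grid: Sequence[float] | None = None,
    convention: str = "unit-penalty",
    bootstrap_reps: int = 1000,
    seed: int = 0,
    eval_points: int = 200,
) -> dict:
    """End-to-end fit report: selected lambda, df, BIC, both volatility
    conventions, bootstrap CI, and fitted values on an evaluation grid."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    vol_unit, lam_star, best, penalty = _fit_and_volatility(
        xa, ya, degree=degree, n_interior=n_interior, grid=grid, convention="unit-penalty"
    )
    est = bootstrap_volatility(
        xa, ya, degree=degree, n_interior=n_interior, grid=grid,
        convention=convention, replicates=bootstrap_reps, seed=seed,
    )
    spec = best.design.spec
    xg = np.linspace(spec.boundary[0], spec.boundary[1], eval_points)
    yg = build_design(xg, spec).X @ best.coefficients
    return {
        "lambda_star": lam_star,
        "df": best.df,
        "bic": best.bic,
        "coefficients": best.coefficients.tolist(),
        "knots": list(spec.interior_knots),
        "boundary": list(spec.boundary),
        "degree": degree,
        "volatility_unit": vol_unit,
        "volatility_literal": lam_star * vol_unit,
        "convention": convention,
        "ci_low": est.ci[0],
        "ci_high": est.ci[1],
        "B": bootstrap_reps,
        "seed": seed,
        "fit_grid_x": xg.tolist(),
        "fit_grid_y": yg.tolist(),
    }
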