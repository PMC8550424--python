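# Methods

## Model

The volatility analysis treats the annual DALY rate `Y` as a smooth function
of the socio-demographic index `x` plus noise, `Y_i = f(x_i) + eps_i`, with
`eps_i` independent and homoscedastic. `f` is represented in a clamped
(open-uniform) cubic B-spline basis: degree 3, three interior knots at the
25/50/75% quantiles of the observed `x` (linear-interpolation quantiles, the
common "type 7" convention), boundary knots at min(x) and max(x). That gives
J = 7 basis functions plus an intercept.

A full clamped basis partitions unity, so intercept + all 7 spline columns
is exactly collinear and the penalized normal matrix would be singular at
every penalty weight. The design therefore drops the first spline column and
keeps the intercept. The equivalent `spline-only` parametrization (all 7
basis functions, no intercept) spans the same space and is exposed as an
option; fitted values and the volatility statistic are identical between the
two, which the test suite asserts.

## Penalty, estimator, degrees of freedom

Roughness is penalized by `lambda * integral(f'(x)^2) dx`, a quadratic form
in the coefficients with matrix `P[j,j'] = ∫ B_j'(x) B_{j'}'(x) dx`. The
intercept row and column of `P` are zero, and any coefficient vector
representing a constant function lies in its null space. Entries are
computed by Gauss–Legendre quadrature per inter-knot interval (4 nodes;
the integrand is piecewise polynomial of degree 4, so the rule is exact, and
the tests confirm agreement with adaptive integration to 1e-8). Derivative
basis values come from the standard degree-lowering recurrence; at the right
boundary the degenerate zero-width basis function is replaced by the left
limit so that derivatives are those of the curve on the closed interval.

The estimator is the ridge-type closed form
`gamma_hat = (B'B + lambda*P)^{-1} B'Y`. Effective degrees of freedom are
the trace of the smoother matrix, `df(lambda) = tr{B (B'B+lambda*P)^{-1} B'}`,
which decreases from the column count at `lambda = 0` to 1 (the constant
fit) as `lambda` grows.

## Penalty selection

`lambda*` minimizes the Gaussian-profile Schwarz criterion

    BIC(lambda) = m * ln(RSS/m) + df(lambda) * ln(m),

the standard effective-dimension BIC for linear smoothers. This choice
matters: the selected `lambda*`, and hence the literal-lambda volatility,
depend on the BIC form, so it is stated here prominently. The default grid
is 61 logarithmically spaced values from 1e-6 to 1e6, which spans df from
essentially full rank to essentially 1 for data on the unit SDI scale; ties
are broken toward the larger `lambda` (more smoothing). When RSS is
numerically zero (an interpolating fit, e.g. noiseless data at
`lambda = 0`, detected against a scale-aware floor of `m * (1e-8 * max(1,
max|Y|))^2`), BIC is undefined and selection raises a diagnostic error
rather than returning an arbitrary value.

The grid profile is computed through one generalized eigendecomposition of
`(P, B'B)` — with `B'B = R'R` and `R^{-T} P R^{-1} = Q diag(mu) Q'`, each
grid point costs a couple of small matrix-vector products and
`df = sum 1/(1 + lambda*mu_i)`. This is algebraically identical to the
direct solve, and a test pins the two routes together.

## The volatility statistic and its conventions

The quadratic form `gamma_hat' P gamma_hat` equals `∫ {f_hat'(x)}^2 dx`
exactly (unit-penalty convention, the default). The form with the selected
penalty weight left in place, `gamma_hat' (lambda* P) gamma_hat`, is
`lambda*` times that integral (literal-lambda convention). Because published
volatility figures can be stated under either reading, both values are
always reported side by side; only the unit-penalty value is a consistent
estimator of the named integral. No standardization of `x` or `Y` is applied,
so the statistic carries raw units of (rate per 100,000)^2 per unit SDI.

## Bootstrap

Confidence intervals use pairs (case) resampling of `(x_i, Y_i)` with
replacement — the scheme with the weakest assumptions — re-choosing knots on
each resampled `x` and re-selecting `lambda` by BIC per replicate, then
taking the 2.5/97.5 percentiles over B = 1,000 replicates by default. A
replicate whose resampled abscissae have too few distinct values to support
the basis (fewer than degree + interior knots + 2 = 8) is redrawn and
counted; exceeding 100·B redraws aborts. Residual resampling (fixed `x`,
resampled centered residuals) is available as an alternative. All draws
derive from one `numpy` generator seeded by the caller, so results are
bit-reproducible.

## Aggregation statistics

The per-year group "total" is the plain sum of member countries' age-
standardized rates — the quantity stacked per-country bar charts display —
not a population-weighted mean. Percent change is `100*(v1 - v0)/v0`;
"a is p% higher than b" is the same formula with the reference in the
denominator. Average annual percent change is the arithmetic mean of the 27
year-over-year percent changes of a 28-point series (a CAGR variant is
exposed under a flag); the arithmetic mean is what "+x% per year on
average" reproduces most directly. Values are carried at full precision and
rounded only for display, two decimals, half away from zero on the decimal
representation. Countries missing from a table contribute zero to sums and
are always reported; in the sex-dominance fraction, countries lacking one
sex row are removed from the denominator and reported. Sums use `math.fsum`,
so they are correctly rounded independently of accumulation order.

## Synthetic data

`gen_sdi_daly_series` draws `Y = f_true(x) + N(0, sigma^2)` for four
families (linear, quadratic, cubic, logistic) whose true volatility
`∫ f_true'^2` has a closed form (for the logistic, the substitution
`u = sigmoid` gives `A^2 k [u^2/2 - u^3/3]` between the endpoint sigmoid
values); additive Gaussian noise matches the spline model's assumption.

`gen_burden_table` builds a world mirroring the study conditions: 31
low-income countries on an exponential decline calibrated so the group sum
starts at ~244,252 per 100,000 and falls 58.7% over 1990–2017, and 58
high-income countries on a U-shaped trend with vertex 1998 ending 2.49%
below its 1990 level (two parabolic arcs sharing the vertex, since a single
symmetric parabola cannot have its minimum at 1998 and still end below the
1990 value). Sex-specific rates are `base*(1±delta)` with `delta = 0.10`,
planted so that a fixed fraction of countries (50% high-income, 40%
low-income) is strictly female-dominant; "Both" is the average of the sex
rates and equals the base rate. Count records follow a bimodal age profile
peaking in the under-5 and elderly groups. Rate noise is multiplicative
log-normal (keeps positivity); with noise off, every aggregate statistic is
recorded exactly in a ground-truth ledger that the pipeline must reproduce
bit-for-bit. Uncertainty fields are a fixed ±15% band around the value —
they exist to exercise interval-ordering validation and carry no
statistical meaning.

What the generator does **not** emulate: real GBD uncertainty propagation,
correlation of rates across years or countries, income-class migration over
time, or etiology structure. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to the messiness of real surveillance data.

## Benchmark conditions

The bootstrap calibration study uses a cubic SDI–DALY curve
`f(x) = 3200 - 3000x - 1000x^2 + 1800x^3` on [0, 1] — declining steeply at
low SDI with a mild upturn at high SDI, the shape seen in income-group DALY
curves — with n = 28 annual points and noise at one tenth of the signal's
standard deviation (signal-to-noise 10, the regime where the plug-in
estimator's relative bias is expected within ±15%). 200 datasets with
B = 500 pairs-bootstrap replicates each keep the study a couple of minutes
on one CPU; the empirical 95% interval coverage is required to lie in
[0.88, 0.99].

## Known limitations

- The volatility plug-in inherits smoothing bias: heavy penalization biases
  it downward. BIC selection keeps this small at SNR ≥ 10 but it grows as
  noise increases.
- The percentile bootstrap at n = 28 is first-order accurate only; no BCa
  or studentized refinement is provided.
- Knot placement at sample quantiles makes the basis data-dependent;
  bootstrap intervals account for this by re-choosing knots per replicate,
  but fits are not comparable across datasets with very different x
  distributions.
- Income-group membership is a fixed 1990–2017 classification; no
  reclassification over time.
- Uncertainty intervals attached to input tables are validated and carried
  through, never propagated into group sums (no propagation rule is
  defined for summed age-standardized rates).
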