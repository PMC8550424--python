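"""Synthetic GBD-like burden tables and (SDI, DALY) series with known truth.

Two generators back the test surface of the whole package:

* :func:`gen_sdi_daly_series` draws ``Y = f_true(x) + N(0, sigma^2)`` for a
  named smooth family (linear, quadratic, cubic, logistic) and returns the
  closed-form true volatility ``∫ {f_true'(x)}^2 dx`` alongside the data,
  so spline estimates can be checked against analytic ground truth.

* :func:`gen_burden_table` builds a small world mirroring the study
  conditions: 31 low-income countries on a monotone exponential decline,
  58 high-income countries on a U-shaped trend with its minimum at 1998,
  28 annual estimates (1990-2017), sex-specific offsets with a planted
  share of female-dominant countries, a bimodal age profile peaking in the
  under-5 and elderly groups, and multiplicative log-normal noise.  Every
  quantity the aggregation layer computes is also recorded exactly in a
  ground-truth ledger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly

from .gbd_io import BurdenRecord, load_income_groups

__all__ = [
    "TrendSpec",
    "PopulationSpec",
    "FAMILIES",
    "true_volatility",
    "gen_sdi_daly_series",
    "gen_burden_table",
    "default_world",
]

#: GBD age-group labels used for the count (metric=Number) rows, with a
#: bimodal weight profile: infant/under-5 peak and an elderly peak.
AGE_GROUPS: tuple[tuple[str, float], ...] = (
    ("28-364 days", 0.24),
    ("1 to 4", 0.22),
    ("5 to 9", 0.05),
    ("10 to 14", 0.02),
    ("15 to 19", 0.02),
    ("20 to 24", 0.04),
    ("25 to 29", 0.02),
    ("30 to 34", 0.03),
    ("40 to 44", 0.02),
    ("50 to 54", 0.03),
    ("60 to 64", 0.07),
    ("70 to 74", 0.09),
    ("75 to 79", 0.08),
    ("80 to 84", 0.07),
)


@dataclass(frozen=True)
class TrendSpec:
    """Group-level trend of the age-standardized rate across years.

    ``exponential-decline``: value(t) = start * exp(-rate * (t - t0)).
    ``u-shape``: two parabolic arcs sharing the vertex (turn_year, floor);
    the declining arc passes through ``start`` at the first year, the
    rising arc through ``end`` at the last year (``end`` defaults to a
    symmetric parabola).  ``flat``: constant ``start``.  ``sigma`` is the
    multiplicative log-normal noise on country-year rates.
    """

    shape: str
    start: float
    rate: float = 0.0
    floor: float = 0.0
    turn_year: int = 1998
    end: float | None = None
    sigma: float = 0.0

    def __post_init__(self):
        if self.shape not in ("exponential-decline", "u-shape", "flat"):
            raise ValueError(f"unknown trend shape {self.shape!r}")
        if self.start <= 0:
            raise ValueError("start value must be positive")
        if self.shape == "u-shape":
            if not 0 < self.floor <= self.start:
                raise ValueError("u-shape floor must satisfy 0 < floor <= start")
            if self.end is not None and self.end < self.floor:
                raise ValueError("u-shape end must be >= floor")

    def value(self, year: int, first_year: int, last_year: int | None = None) -> float:
        if self.shape == "flat":
            return self.start
        if self.shape == "exponential-decline":
            return self.start * math.exp(-self.rate * (year - first_year))
        # u-shape: vertex (turn_year, floor); declining arc through
        # (first_year, start), rising arc through (last_year, end)
        if year <= self.turn_year or self.end is None or last_year is None:
            denom = (first_year - self.turn_year) ** 2
            curv = (self.start - self.floor) / denom
        else:
            denom = (last_year - self.turn_year) ** 2
            curv = (self.end - self.floor) / denom
        return self.floor + curv * (year - self.turn_year) ** 2


@dataclass(frozen=True)
class PopulationSpec:
    """Country counts, sex offsets, age profile and SDI trajectories."""

    n_low: int = 31
    n_high: int = 58
    #: fraction of countries per class planted as strictly female-dominant;
    #: the rest are strictly male-dominant (no ties unless sex_gap == 0)
    female_dominant_frac: dict = field(
        default_factory=lambda: {"low": 0.40, "high": 0.50}
    )
    #: half-gap delta: female = rate*(1+delta), male = rate*(1-delta) for
    #: female-dominant countries, mirrored otherwise; Both = (F+M)/2 = rate
    sex_gap: float = 0.10
    age_weights: tuple = AGE_GROUPS
    #: per-class SDI endpoints (1990 -> 2017), linear and nondecreasing
    sdi_span: dict = field(
        default_factory=lambda: {"low": (0.20, 0.42), "high": (0.75, 0.88)}
    )
    base_count: float = 5.0e5  # scale of the per-country DALY counts

    def __post_init__(self):
        if any(w < 0 for _, w in self.age_weights):
            raise ValueError("age weights must be nonnegative")
        for lo, hi in self.sdi_span.values():
            if not (0 <= lo <= hi <= 1):
                raise ValueError("SDI trajectories must be nondecreasing within [0, 1]")


# ---------------------------------------------------------------------------
# (SDI, DALY) test series with analytic volatility


def _poly_volatility(coefs: Sequence[float], lo: float, hi: float) -> float:
    """Exact ∫ p'(x)^2 dx for a polynomial with coefficients in increasing order."""
    dp = npoly.polyder(list(coefs))
    sq = npoly.polymul(dp, dp)
    anti = npoly.polyint(sq)
    return float(npoly.polyval(hi, anti) - npoly.polyval(lo, anti))


def _logistic_volatility(amplitude, steepness, midpoint, lo, hi) -> float:
    # f = base + A * u, u = sigmoid(k (x - x0)); f' = A k u (1 - u);
    # substituting du = k u (1-u) dx gives  A^2 k [u^2/2 - u^3/3]_{u(lo)}^{u(hi)}
    def u(x):
        return 1.0 / (1.0 + math.exp(-steepness * (x - midpoint)))

    g = lambda v: v * v / 2.0 - v**3 / 3.0
    return amplitude**2 * steepness * (g(u(hi)) - g(u(lo)))


FAMILIES = ("linear", "quadratic", "cubic", "logistic")


def _f_true(family: str, params: dict):
    if family == "linear":
        a, b = params["intercept"], params["slope"]
        return lambda x: a + b * x
    if family == "quadratic":
        c = [params.get("c0", 0.0), params.get("c1", 0.0), params["c2"]]
        return lambda x: npoly.polyval(x, c)
    if family == "cubic":
        c = [params.get("c0", 0.0), params.get("c1", 0.0),
             params.get("c2", 0.0), params["c3"]]
        return lambda x: npoly.polyval(x, c)
    if family == "logistic":
        base, A = params.get("base", 0.0), params["amplitude"]
        k, x0 = params["steepness"], params["midpoint"]
        return lambda x: base + A / (1.0 + np.exp(-k * (np.asarray(x) - x0)))
    raise ValueError(f"unknown function family {family!r}; known: {FAMILIES}")


def true_volatility(family: str, params: dict, interval: tuple[float, float]) -> float:
    """Closed-form ∫ {f'(x)}^2 dx for a shipped family over ``interval``."""
    lo, hi = interval
    if family == "linear":
        return params["slope"] ** 2 * (hi - lo)
    if family == "quadratic":
        c = [params.get("c0", 0.0), params.get("c1", 0.0), params["c2"]]
        return _poly_volatility(c, lo, hi)
    if family == "cubic":
        c = [params.get("c0", 0.0), params.get("c1", 0.0),
             params.get("c2", 0.0), params["c3"]]
        return _poly_volatility(c, lo, hi)
    if family == "logistic":
        return _logistic_volatility(
            params["amplitude"], params["steepness"], params["midpoint"], lo, hi
        )
    raise ValueError(f"unknown function family {family!r}; known: {FAMILIES}")


def gen_sdi_daly_series(
    family: str,
    params: dict,
    n: int,
    sigma: float,
    seed: int,
    *,
    interval: tuple[float, float] = (0.0, 1.0),
    spacing: str = "equal",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Draw (x, Y) with Y = f_true(x) + N(0, sigma^2); return the true volatility.

    ``spacing`` is "equal" (deterministic grid over ``interval``) or
    "uniform" (random abscissae).  Fully reproducible from ``seed``.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = interval
    if spacing == "equal":
        x = np.linspace(lo, hi, n)
    elif spacing == "uniform":
        x = np.sort(rng.uniform(lo, hi, size=n))
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    f = _f_true(family, params)
    y = np.asarray(f(x), dtype=float) + rng.normal(0.0, sigma, size=n)
    return x, y, true_volatility(family, params, interval)


# ---------------------------------------------------------------------------
# burden-table world


def default_world() -> tuple[PopulationSpec, dict]:
    """The study conditions: 31 low + 58 high countries, 1990-2017 trends.

    Trend magnitudes mirror the group-sum scale of the source data: the
    low-income sum starts near 244,000 per 100,000 and declines to ~41% of
    its start over 28 years; the high-income sum is U-shaped with its
    minimum at 1998 and ends 2.49% below its 1990 level.
    """
    pop = PopulationSpec()
    trends = {
        # start per-country rate ~ 244,252/31; exp decline to 0.413 of start
        "low": TrendSpec("exponential-decline", start=7879.1, rate=math.log(1 / 0.413) / 27),
        # start per-country rate ~ 7,000/58; shallow asymmetric U with
        # minimum at 1998, ending 2.49% below the start
        "high": TrendSpec("u-shape", start=120.7, floor=95.0, turn_year=1998,
                          end=120.7 * (1 - 0.0249)),
    }
    return pop, trends


def gen_burden_table(
    pop: PopulationSpec,
    trends: dict,
    years: tuple[int, int] = (1990, 2017),
    seed: int = 0,
    *,
    cause: str = "Diarrheal diseases",
    measure: str = "DALYs",
) -> tuple[list[BurdenRecord], dict]:
    """Generate a burden table plus an exact ground-truth ledger.

    One age-standardized Rate record per (country, year, sex in {Male,
    Female, Both}) and one Number record per (country, year, age group).
    "Both" is the average of the sex-specific rates.  Uncertainty fields
    are a fixed +/-15% band around ``val`` (non-statistical; they exist to
    exercise interval-ordering validation).  The ledger records, exactly
    as generated: per-(country, year, sex) true rates, per-(class, year,
    sex) sums, and the planted sex-dominance pattern.
    """
    first, last = years
    if last <= first:
        raise ValueError("year span must contain at least 2 years")
    for cls in ("low", "high"):
        if cls not in trends:
            raise ValueError(f"missing trend for class {cls!r}")

    fixture = load_income_groups()
    countries = {
        "low": fixture.members("low")[: pop.n_low],
        "high": fixture.members("high")[: pop.n_high],
    }
    if len(countries["low"]) < pop.n_low or len(countries["high"]) < pop.n_high:
        # beyond the packaged 31+58: synthesize extra names
        for cls, n_want in (("low", pop.n_low), ("high", pop.n_high)):
            k = len(countries[cls])
            countries[cls] += [f"Synthetica {cls.title()} {i}" for i in range(k, n_want)]

    rng = np.random.default_rng(seed)
    records: list[BurdenRecord] = []
    ledger: dict = {
        "seed": seed,
        "years": list(range(first, last + 1)),
        "countries": countries,
        "rates": {},          # (class, country, year, sex) -> true rate, flattened keys
        "group_sums": {},     # "class|year|sex" -> exact sum
        "female_dominant": {},  # class -> sorted list of planted F>M countries
        "sdi": {},            # "class|year" -> SDI value
        "sex_gap": pop.sex_gap,
    }

    n_years = last - first + 1
    for cls in ("low", "high"):
        names = countries[cls]
        trend: TrendSpec = trends[cls]
        n_dom = int(round(pop.female_dominant_frac[cls] * len(names)))
        # deterministic planting: first n_dom names alphabetically are F-dominant
        dominant = sorted(names)[:n_dom]
        ledger["female_dominant"][cls] = dominant
        dom_set = set(dominant)

        lo_sdi, hi_sdi = pop.sdi_span[cls]
        for j, year in enumerate(range(first, last + 1)):
            ledger["sdi"][f"{cls}|{year}"] = lo_sdi + (hi_sdi - lo_sdi) * j / (n_years - 1)

        sums: dict[tuple[int, str], list[float]] = {}
        for name in names:
            for year in range(first, last + 1):
                base = trend.value(year, first, last)
                if trend.sigma > 0:
                    base *= rng.lognormal(mean=0.0, sigma=trend.sigma)
                d = pop.sex_gap if name in dom_set else -pop.sex_gap
                female = base * (1.0 + d)
                male = base * (1.0 - d)
                both = 0.5 * (female + male)  # == base
                for sex, rate in (("Male", male), ("Female", female), ("Both", both)):
                    records.append(
                        BurdenRecord(
                            measure=measure, location=name, sex=sex,
                            age="Age-standardized", cause=cause, metric="Rate",
                            year=year, val=rate,
                            upper=rate * 1.15, lower=rate * 0.85,
                        )
                    )
                    ledger["rates"][f"{cls}|{name}|{year}|{sex}"] = rate
                    sums.setdefault((year, sex), []).append(rate)
                # count rows over the age profile (Both sexes)
                year_scale = base / trend.start
                for age_label, w in pop.age_weights:
                    count = pop.base_count * w * year_scale
                    records.append(
                        BurdenRecord(
                            measure=measure, location=name, sex="Both",
                            age=age_label, cause=cause, metric="Number",
                            year=year, val=count,
                            upper=count * 1.15, lower=count * 0.85,
                        )
                    )
        # fsum gives the correctly rounded sum regardless of accumulation
        # order, so these entries match sum_group_rate bit-for-bit
        for (year, sex), vals in sums.items():
            ledger["group_sums"][f"{cls}|{year}|{sex}"] = math.fsum(vals)
    return records, ledger
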