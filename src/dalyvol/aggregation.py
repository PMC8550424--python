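"""Descriptive burden statistics over income groups.

The group-level "total" rate for a year is the plain sum of the member
countries' age-standardized rates — the quantity the stacked per-country
bar charts of GBD-style income-group comparisons display.  On top of that
sum this module provides relative-change statistics (percent change,
percent higher, group ratios), the fraction of countries in a group where
one sex's rate strictly exceeds the other's, and the average annual
percent change of an annual series (arithmetic mean of year-over-year
percent changes, with a compound-growth alternative).

Missing countries never vanish silently: group sums carry an explicit
missing list, and countries lacking one sex row are excluded from the
sex-dominance denominator but reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .gbd_io import AnnualSeries, BurdenRecord, IncomeGroupTable

__all__ = [
    "GroupYearSum",
    "SexDominance",
    "sum_group_rate",
    "percent_change",
    "percent_higher",
    "group_ratio",
    "sex_dominance_fraction",
    "average_annual_pct_change",
    "round_display",
]


@dataclass(frozen=True)
class GroupYearSum:
    """Sum of member-country rates for one (income class, year, sex)."""

    income_class: str
    year: int
    sex: str
    summed_rate: float
    contributing: int
    missing: tuple[str, ...] = ()


@dataclass(frozen=True)
class SexDominance:
    """Fraction of a group's countries where the directional inequality holds."""

    fraction: float
    qualifying: tuple[str, ...]
    denominator: int
    excluded: tuple[str, ...] = ()


def round_display(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, for display at the conventional 2 decimals.

    Operates on the shortest decimal representation of ``x`` so that a
    value printed as 34.205 rounds to 34.21 even though its binary float
    lies a hair below the tie.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def sum_group_rate(
    records: Iterable[BurdenRecord],
    groups: IncomeGroupTable,
    income_class: str,
    year: int,
    sex: str = "Both",
) -> GroupYearSum:
    """Sum member countries' rates for one year and sex.

    ``records`` should already be filtered to one measure, metric=Rate and
    age="Age-standardized".  Member countries absent from the table
    contribute 0 and are listed in ``missing``; a duplicate (location,
    year, sex) row is ambiguous input and an error.
    """
    members = set(groups.members(income_class))
    seen: dict[str, float] = {}
    for r in records:
        if r.year != year or r.sex != sex or r.location not in members:
            continue
        if r.location in seen:
            raise ValueError(
                f"duplicate row for ({r.location!r}, {year}, {sex!r}); "
                "ambiguous input — filter to a single measure/metric/age first"
            )
        seen[r.location] = r.val
    missing = tuple(sorted(members - set(seen)))
    return GroupYearSum(
        income_class=income_class,
        year=year,
        sex=sex,
        summed_rate=math.fsum(seen.values()),
        contributing=len(seen),
        missing=missing,
    )


def percent_change(value_from: float, value_to: float) -> float:
    """Signed percent change from ``value_from`` to ``value_to``."""
    if value_from <= 0:
        raise ValueError(f"baseline must be positive, got {value_from}")
    return 100.0 * (value_to - value_from) / value_from


def percent_higher(a: float, b: float) -> float:
    """How many percent ``a`` is above ``b`` (signed; same formula as percent_change)."""
    if b <= 0:
        raise ValueError(f"reference must be positive, got {b}")
    return 100.0 * (a - b) / b


def group_ratio(sum_a: float, sum_b: float) -> float:
    """Ratio of two positive group sums (e.g. low-income : high-income)."""
    if sum_a <= 0 or sum_b <= 0:
        raise ValueError("group sums must be positive")
    return sum_a / sum_b


def sex_dominance_fraction(
    records: Iterable[BurdenRecord],
    groups: IncomeGroupTable,
    income_class: str,
    year: int,
    direction: str = "female>male",
) -> SexDominance:
    """Fraction of member countries where one sex's rate strictly exceeds the other's.

    Countries with only one sex row present are excluded from the
    denominator and reported in ``excluded``.  Ties count for neither
    direction (the inequality is strict).
    """
    if direction not in ("female>male", "male>female"):
        raise ValueError(f"unknown direction {direction!r}")
    members = set(groups.members(income_class))
    by_sex: dict[str, dict[str, float]] = {}
    for r in records:
        if r.year != year or r.location not in members:
            continue
        if r.sex not in ("Male", "Female"):
            continue
        slot = by_sex.setdefault(r.location, {})
        if r.sex in slot:
            raise ValueError(f"duplicate ({r.location!r}, {year}, {r.sex!r}) row")
        slot[r.sex] = r.val
    excluded = tuple(sorted(c for c, s in by_sex.items() if len(s) < 2))
    complete = {c: s for c, s in by_sex.items() if len(s) == 2}
    if direction == "female>male":
        qualifying = tuple(sorted(c for c, s in complete.items() if s["Female"] > s["Male"]))
    else:
        qualifying = tuple(sorted(c for c, s in complete.items() if s["Male"] > s["Female"]))
    denom = len(complete)
    fraction = len(qualifying) / denom if denom else 0.0
    return SexDominance(fraction, qualifying, denom, excluded)


def average_annual_pct_change(series: AnnualSeries, method: str = "arithmetic") -> float:
    """Average annual percent change of a positive annual series.

    ``arithmetic`` (default) is the mean of the consecutive year-over-year
    percent changes; ``cagr`` is the compound annual growth rate
    ``100 * ((v_T / v_0)**(1/(T-0)) - 1)`` over the full span.
    """
    values = series.values
    years = series.years
    if len(values) < 2:
        raise ValueError("series needs at least 2 points")
    if any(v <= 0 for v in values):
        raise ValueError("all series values must be positive")
    if method == "arithmetic":
        steps = [100.0 * (b - a) / a for a, b in zip(values, values[1:])]
        return math.fsum(steps) / len(steps)
    if method == "cagr":
        span = years[-1] - years[0]
        return 100.0 * ((values[-1] / values[0]) ** (1.0 / span) - 1.0)
    raise ValueError(f"unknown method {method!r}")
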