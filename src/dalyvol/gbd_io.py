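"""Reading, validating and filtering GBD-results-style burden tables.

The Global Burden of Disease (GBD) results tool exports long-format CSV
tables in which each row carries one estimate: a measure (DALYs, YLLs,
YLDs, incidence, prevalence) for one location, sex, age group, cause,
metric (count or rate per 100,000) and calendar year, together with a 95%
uncertainty interval.  This module parses that dialect into typed records,
enforces the row invariants (``lower <= val <= upper``, year inside the
study window, nonnegative values), and ships the World Bank income-group
classification used to partition countries into the 31 low-income and 58
high-income constituents analysed here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "BurdenRecord",
    "AnnualSeries",
    "IncomeGroupTable",
    "ReadResult",
    "SchemaError",
    "RowError",
    "MEASURES",
    "SEXES",
    "METRICS",
    "INCOME_CLASSES",
    "DEFAULT_YEAR_SPAN",
    "read_burden_table",
    "write_burden_table",
    "load_income_groups",
    "filter_records",
]

MEASURES = ("DALYs", "YLLs", "YLDs", "Incidence", "Prevalence")
SEXES = ("Both", "Male", "Female")
METRICS = ("Number", "Rate")
INCOME_CLASSES = ("low", "high")

#: The study window of the GBD2017 cycle: 28 annual estimates.
DEFAULT_YEAR_SPAN = (1990, 2017)

# GHDx exports use suffixed column names; the short forms are accepted too.
_CANONICAL_COLUMNS = (
    "measure_name", "location_name", "sex_name", "age_name",
    "cause_name", "metric_name", "year", "val", "upper", "lower",
)
_ALIASES = {
    "measure": "measure_name",
    "location": "location_name",
    "sex": "sex_name",
    "age": "age_name",
    "cause": "cause_name",
    "metric": "metric_name",
}
# Long-form labels occasionally seen in GHDx exports.
_MEASURE_SYNONYMS = {
    "DALYs (Disability-Adjusted Life Years)": "DALYs",
    "YLLs (Years of Life Lost)": "YLLs",
    "YLDs (Years Lived with Disability)": "YLDs",
}


class SchemaError(ValueError):
    """The table is structurally unusable (e.g. a mandatory column is missing)."""


class RowError(ValueError):
    """A row violates a record invariant; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class BurdenRecord:
    """One row of a GBD-style results table."""

    measure: str
    location: str
    sex: str
    age: str
    cause: str
    metric: str
    year: int
    val: float
    upper: float
    lower: float

    def validate(self, year_span: tuple[int, int] = DEFAULT_YEAR_SPAN) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        lo, hi = year_span
        if not lo <= self.year <= hi:
            raise ValueError(f"year {self.year} outside span [{lo}, {hi}]")
        if self.val < 0:
            raise ValueError(f"negative val {self.val}")
        if not self.lower <= self.val <= self.upper:
            raise ValueError(
                "uncertainty interval must satisfy lower <= val <= upper, got "
                f"lower={self.lower}, val={self.val}, upper={self.upper}"
            )


@dataclass(frozen=True)
class AnnualSeries:
    """An ordered (year, value) series for one group/statistic."""

    label: str
    points: tuple[tuple[int, float], ...]

    def __post_init__(self):
        years = [y for y, _ in self.points]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")

    @property
    def years(self) -> list[int]:
        return [y for y, _ in self.points]

    @property
    def values(self) -> list[float]:
        return [v for _, v in self.points]


@dataclass(frozen=True)
class IncomeGroupTable:
    """Mapping of location name to World Bank income class (low/high)."""

    entries: dict[str, str]

    def __post_init__(self):
        bad = {c for c in self.entries.values() if c not in INCOME_CLASSES}
        if bad:
            raise ValueError(f"unknown income class(es): {sorted(bad)}")

    def members(self, income_class: str) -> list[str]:
        if income_class not in INCOME_CLASSES:
            raise ValueError(f"unknown income class {income_class!r}")
        return sorted(k for k, v in self.entries.items() if v == income_class)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ReadResult:
    """Parsed records plus row-indexed diagnostics for rejected rows."""

    records: list[BurdenRecord]
    diagnostics: list[RowError] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _normalise_header(columns: Iterable[str]) -> dict[str, str]:
    mapping = {}
    for col in columns:
        key = col.strip()
        mapping[col] = _ALIASES.get(key, key)
    return mapping


def read_burden_table(
    source,
    *,
    delimiter: str = ",",
    year_span: tuple[int, int] = DEFAULT_YEAR_SPAN,
) -> ReadResult:
    """Parse a GBD-results-dialect CSV into :class:`BurdenRecord` rows.

    Rows violating a record invariant are rejected individually and reported
    in ``ReadResult.diagnostics``; a missing mandatory column aborts the
    parse with :class:`SchemaError`.  Row order is preserved.
    """
    try:
        frame = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SchemaError(f"unparseable tabular input: {exc}") from exc

    frame = frame.rename(columns=_normalise_header(frame.columns))
    missing = [c for c in _CANONICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[BurdenRecord] = []
    diagnostics: list[RowError] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        r = row._asdict()
        try:
            try:
                year = int(r["year"])
            except ValueError:
                raise ValueError(f"non-integer year {r['year']!r}") from None
            try:
                val, upper, lower = (float(r[k]) for k in ("val", "upper", "lower"))
            except ValueError:
                raise ValueError("non-numeric val/upper/lower") from None
            measure = r["measure_name"].strip()
            measure = _MEASURE_SYNONYMS.get(measure, measure)
            rec = BurdenRecord(
                measure=measure,
                location=r["location_name"].strip(),
                sex=r["sex_name"].strip(),
                age=r["age_name"].strip(),
                cause=r["cause_name"].strip(),
                metric=r["metric_name"].strip(),
                year=year,
                val=val,
                upper=upper,
                lower=lower,
            )
            rec.validate(year_span)
        except ValueError as exc:
            diagnostics.append(RowError(idx, str(exc)))
            continue
        records.append(rec)
    return ReadResult(records, diagnostics)


def write_burden_table(records: Sequence[BurdenRecord], dest) -> None:
    """Write records in the canonical GHDx CSV dialect (UTF-8, full precision)."""
    frame = pd.DataFrame(
        {
            "measure_name": [r.measure for r in records],
            "location_name": [r.location for r in records],
            "sex_name": [r.sex for r in records],
            "age_name": [r.age for r in records],
            "cause_name": [r.cause for r in records],
            "metric_name": [r.metric for r in records],
            "year": [r.year for r in records],
            "val": [r.val for r in records],
            "upper": [r.upper for r in records],
            "lower": [r.lower for r in records],
        }
    )
    frame.to_csv(dest, index=False, float_format="%.17g")


def load_income_groups(override=None) -> IncomeGroupTable:
    """Load the World Bank income classification.

    With no ``override``, returns the packaged table of the 31 low-income
    and 58 high-income constituents.  An override is a two-column CSV
    (location, income_class); duplicate locations are an error.
    """
    if override is None:
        text = (resources.files("dalyvol") / "data" / "income_groups.csv").read_text()
        source = io.StringIO(text)
    elif isinstance(override, (str, Path)):
        source = override
    else:
        source = override
    frame = pd.read_csv(source, dtype=str)
    frame.columns = [c.strip() for c in frame.columns]
    if list(frame.columns) != ["location", "income_class"]:
        raise SchemaError(
            "income-group table must have columns (location, income_class), "
            f"got {list(frame.columns)}"
        )
    entries: dict[str, str] = {}
    for loc, cls in zip(frame["location"], frame["income_class"]):
        loc, cls = loc.strip(), cls.strip()
        if loc in entries:
            raise ValueError(f"duplicate location in income-group table: {loc!r}")
        entries[loc] = cls
    return IncomeGroupTable(entries)


def filter_records(
    records: Iterable[BurdenRecord],
    *,
    measure: str | None = None,
    metric: str | None = None,
    sex: str | None = None,
    age: str | None = None,
    cause: str | None = None,
    years: tuple[int, int] | None = None,
    locations: Iterable[str] | None = None,
) -> list[BurdenRecord]:
    """Return exactly the records matching every supplied predicate.

    Unsupplied predicates match everything; an empty result is valid.
    """
    loc_set = set(locations) if locations is not None else None
    out = []
    for r in records:
        if measure is not None and r.measure != measure:
            continue
        if metric is not None and r.metric != metric:
            continue
        if sex is not None and r.sex != sex:
            continue
        if age is not None and r.age != age:
            continue
        if cause is not None and r.cause != cause:
            continue
        if years is not None and not years[0] <= r.year <= years[1]:
            continue
        if loc_set is not None and r.location not in loc_set:
            continue
        out.append(r)
    return out
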