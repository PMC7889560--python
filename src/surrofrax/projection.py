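"""National hip-fracture burden projection.

Expected annual fracture counts are rate x exposure sums: the age- and
sex-specific incidence (held fixed over calendar time) applied to each
year's population pyramid, treating mid-year person counts as
person-years at risk.  Growth in counts over years therefore reflects
population growth and ageing only, not secular incidence trends.

Counts are reported rounded to the nearest integer but totals and
percent increases are always computed from the unrounded values; a
percent increase re-derived from already-rounded counts can differ by
a point.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .rates_io import HazardTable, PopulationTable, SexPair
from .surrogate import AlignmentError

__all__ = ["BurdenTable", "expected_counts", "percent_increase", "project_burden"]


@dataclass(frozen=True)
class SexCounts:
    """Expected annual fracture counts for one year (unrounded)."""

    male: float
    female: float

    @property
    def total(self) -> float:
        return self.male + self.female


def expected_counts(
    incidence: SexPair[HazardTable], population: PopulationTable, year: int
) -> SexCounts:
    """Expected fractures in *year*: sum over bands of rate x persons, per sex."""
    out = {}
    for sex in ("male", "female"):
        table = incidence[sex]
        if table.bands != population.bands:
            raise AlignmentError("incidence and population tables disagree on banding")
        out[sex] = float(np.dot(table.rate, population.slice(year, sex)))
    return SexCounts(male=out["male"], female=out["female"])


def percent_increase(baseline_count: float, later_count: float) -> tuple[float, int]:
    """Percent change vs baseline: ``100 * (later/baseline - 1)``.

    Returns ``(exact, rounded)`` where ``rounded`` is the half-up
    integer used for reporting.
    """
    if baseline_count <= 0:
        raise ValueError("baseline count must be > 0")
    exact = 100.0 * (later_count / baseline_count - 1.0)
    if float(baseline_count).is_integer() and float(later_count).is_integer():
        # exact rational arithmetic so e.g. a true 50.5 rounds up, not to 50
        pct = 100 * (Decimal(int(later_count)) / Decimal(int(baseline_count)) - 1)
    else:
        pct = Decimal(repr(exact))
    rounded = int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return exact, rounded


@dataclass(frozen=True)
class BurdenTable:
    """Year-by-year burden: counts per sex, totals and percent increases.

    ``data`` columns: year, men, women, total (unrounded floats),
    men_rounded, women_rounded, total_rounded (nearest-integer report
    values), pct_increase (exact, vs baseline), pct_increase_rounded.
    """

    baseline_year: int
    data: pd.DataFrame


def project_burden(
    incidence: SexPair[HazardTable],
    population: PopulationTable,
    baseline_year: int,
    years: list[int] | tuple[int, ...],
) -> BurdenTable:
    """Burden per year with incidence held fixed; percent increases vs baseline."""
    all_years = [baseline_year] + [y for y in years if y != baseline_year]
    base = expected_counts(incidence, population, baseline_year)
    records = []
    for year in all_years:
        c = expected_counts(incidence, population, year)
        exact, rounded = percent_increase(base.total, c.total)
        records.append(
            {
                "year": year,
                "men": c.male,
                "women": c.female,
                "total": c.total,
                "men_rounded": round(c.male),
                "women_rounded": round(c.female),
                "total_rounded": round(c.total),
                "pct_increase": exact,
                "pct_increase_rounded": rounded,
            }
        )
    return BurdenTable(baseline_year=baseline_year, data=pd.DataFrame.from_records(records))
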