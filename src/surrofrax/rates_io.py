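"""Typed age/sex rate tables and their CSV I/O.

Everything downstream runs on three kinds of table:

* :class:`HazardTable` -- annual event rates (hip-fracture incidence,
  major-osteoporotic-fracture incidence, or all-cause mortality) by
  5-year age band for one sex.  Rates live on disk as events per
  100,000 person-years (the way epidemiological sources report them)
  and in memory as events per person-year (the way the math wants
  them).
* :class:`RatioTable` -- dimensionless MOF:hip incidence multipliers by
  age band and sex, used to impute major-osteoporotic-fracture
  incidence where only hip rates exist.
* :class:`PopulationTable` -- person counts by age band, sex and
  calendar year, the exposure side of burden projections.

Age bands are half-open ``[lo, hi+1)`` in integer years; the shipped
default banding is 50-54, 55-59, ..., 85-89, 90+ and a banding must be
a sorted, gapless, non-overlapping partition of ``[floor, inf)``.
Within a band the hazard is step-constant (life-table convention); no
interpolation is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Generic, Iterable, Iterator, Sequence, TypeVar

import numpy as np
import pandas as pd

__all__ = [
    "AgeBand",
    "BandingError",
    "FormatError",
    "HazardTable",
    "PopulationTable",
    "RatioTable",
    "SexPair",
    "TableKind",
    "ValidationError",
    "default_banding",
    "rate_at_age",
    "read_hazard_table",
    "read_population_table",
    "read_ratio_table",
    "write_hazard_table",
    "write_population_table",
    "write_ratio_table",
]

SEXES = ("male", "female")

DEFAULT_FLOOR = 50

#: Hazard-table kinds understood by the engine.
TableKind = str
HIP_INCIDENCE: TableKind = "hip_incidence"
MOF_INCIDENCE: TableKind = "mof_incidence"
MORTALITY: TableKind = "mortality"
KINDS = (HIP_INCIDENCE, MOF_INCIDENCE, MORTALITY)

#: Scale factor between on-disk and in-memory rates.
PER_100K = 100_000.0


class BandingError(ValueError):
    """Age bands do not form a sorted, gapless, non-overlapping partition."""


class ValidationError(ValueError):
    """Table contents violate an invariant (negative rate, duplicate row, ...)."""


class FormatError(ValueError):
    """File does not conform to the expected CSV dialect."""


# ---------------------------------------------------------------------------
# Age bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class AgeBand:
    """Half-open age interval ``[lower, upper + 1)`` in integer years.

    ``upper is None`` marks the open-ended terminal band (e.g. 90+).
    """

    lower: int
    upper: int | None = None

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValidationError(f"band lower bound must be >= 0, got {self.lower}")
        if self.upper is not None and self.upper < self.lower:
            raise ValidationError(
                f"band upper bound {self.upper} below lower bound {self.lower}"
            )

    @property
    def open_ended(self) -> bool:
        return self.upper is None

    @property
    def hi_exclusive(self) -> float:
        """Exclusive right edge; +inf for the open band."""
        return math.inf if self.upper is None else self.upper + 1

    @property
    def midpoint(self) -> float:
        """Band midpoint; the open band uses lower + 2.5 (5-year-band convention)."""
        if self.upper is None:
            return self.lower + 2.5
        return (self.lower + self.upper + 1) / 2

    def contains(self, age: float) -> bool:
        return self.lower <= age < self.hi_exclusive

    def __str__(self) -> str:
        return f"{self.lower}+" if self.open_ended else f"{self.lower}-{self.upper}"


def default_banding(floor: int = DEFAULT_FLOOR, top: int = 90, width: int = 5) -> tuple[AgeBand, ...]:
    """The shipped banding: ``width``-year bands from ``floor`` up to an open ``top+`` band."""
    closed = [AgeBand(lo, lo + width - 1) for lo in range(floor, top, width)]
    return tuple(closed) + (AgeBand(top, None),)


def validate_banding(bands: Sequence[AgeBand], floor: int | None = None) -> None:
    """Check that *bands* partition ``[bands[0].lower, inf)`` without gap or overlap."""
    if not bands:
        raise BandingError("empty banding")
    if floor is not None and bands[0].lower != floor:
        raise BandingError(f"banding starts at {bands[0].lower}, expected floor {floor}")
    for prev, cur in zip(bands, bands[1:]):
        if prev.open_ended:
            raise BandingError(f"open-ended band {prev} is not last")
        if cur.lower != prev.upper + 1:
            kind = "overlap" if cur.lower <= prev.upper else "gap"
            raise BandingError(f"{kind} between bands {prev} and {cur}")
    if not bands[-1].open_ended:
        raise BandingError(f"last band {bands[-1]} must be open-ended")


def _band_index(bands: Sequence[AgeBand], age: float) -> int:
    if age < bands[0].lower:
        raise ValueError(f"age {age} below table floor {bands[0].lower}")
    edges = np.array([b.lower for b in bands], dtype=float)
    return int(np.searchsorted(edges, age, side="right")) - 1


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def _check_sex(sex: str) -> str:
    if sex not in SEXES:
        raise ValidationError(f"sex must be one of {SEXES}, got {sex!r}")
    return sex


@dataclass(frozen=True)
class HazardTable:
    """Annual event rates per person-year by age band, one sex, one kind."""

    sex: str
    bands: tuple[AgeBand, ...]
    rate: np.ndarray  # per person-year
    kind: TableKind

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        if self.kind not in KINDS:
            raise ValidationError(f"kind must be one of {KINDS}, got {self.kind!r}")
        object.__setattr__(self, "bands", tuple(self.bands))
        rate = np.asarray(self.rate, dtype=float)
        object.__setattr__(self, "rate", rate)
        validate_banding(self.bands)
        if rate.shape != (len(self.bands),):
            raise ValidationError(
                f"{len(self.bands)} bands but {rate.shape} rates"
            )
        if not np.all(np.isfinite(rate)):
            raise ValidationError("rates must be finite")
        if np.any(rate < 0):
            raise ValidationError("rates must be >= 0")

    @property
    def floor(self) -> int:
        return self.bands[0].lower

    def scaled(self, factor: float | np.ndarray) -> "HazardTable":
        """New table with band rates multiplied by *factor* (scalar or per-band)."""
        return replace(self, rate=self.rate * factor)

    def with_kind(self, kind: TableKind) -> "HazardTable":
        return replace(self, kind=kind)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HazardTable):
            return NotImplemented
        return (
            self.sex == other.sex
            and self.kind == other.kind
            and self.bands == other.bands
            and np.array_equal(self.rate, other.rate)
        )


def rate_at_age(table: HazardTable, age: float) -> float:
    """Band-constant annual rate at exact *age* (right-continuous step function).

    Ages beyond the last closed band fall in the open band and use its
    rate; ages below the table floor raise ``ValueError``.
    """
    return float(table.rate[_band_index(table.bands, age)])


@dataclass(frozen=True)
class RatioTable:
    """Dimensionless MOF-incidence / hip-incidence multiplier by age band and sex."""

    sex: str
    bands: tuple[AgeBand, ...]
    multiplier: np.ndarray

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        object.__setattr__(self, "bands", tuple(self.bands))
        mult = np.asarray(self.multiplier, dtype=float)
        object.__setattr__(self, "multiplier", mult)
        validate_banding(self.bands)
        if mult.shape != (len(self.bands),):
            raise ValidationError(f"{len(self.bands)} bands but {mult.shape} multipliers")
        if not np.all(np.isfinite(mult)) or np.any(mult < 1):
            raise ValidationError(
                "MOF:hip multipliers must be finite and >= 1 (MOF includes hip)"
            )


T = TypeVar("T")


@dataclass(frozen=True)
class SexPair(Generic[T]):
    """A male/female pair of tables, the unit most operations consume."""

    male: T
    female: T

    def __getitem__(self, sex: str) -> T:
        return getattr(self, _check_sex(sex))

    def __iter__(self) -> Iterator[tuple[str, T]]:
        yield "male", self.male
        yield "female", self.female

    def map(self, fn) -> "SexPair":
        return SexPair(male=fn(self.male), female=fn(self.female))


@dataclass(frozen=True)
class PopulationTable:
    """Person counts indexed by (calendar year, sex, age band).

    Each (year, sex) slice must cover the full banding exactly once.
    """

    bands: tuple[AgeBand, ...]
    counts: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        validate_banding(self.bands)
        for (year, sex), arr in self.counts.items():
            _check_sex(sex)
            arr = np.asarray(arr, dtype=float)
            self.counts[(year, sex)] = arr
            if arr.shape != (len(self.bands),):
                raise ValidationError(
                    f"({year},{sex}): {len(self.bands)} bands but {arr.shape} counts"
                )
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(f"({year},{sex}): counts must be finite and >= 0")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({y for y, _ in self.counts}))

    def slice(self, year: int, sex: str) -> np.ndarray:
        key = (int(year), _check_sex(sex))
        if key not in self.counts:
            raise ValueError(f"no population slice for year={year}, sex={sex}")
        return self.counts[key]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------
# Dialect: UTF-8, comma separated, '#' comment lines ignored.  Hazard and
# ratio files carry columns  sex, age_lo, age_hi, <value>;  age_hi is empty
# or the literal "plus" for the open terminal band.  Population files carry
# year, sex, age_lo, age_hi, count.

def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def _parse_band(lo, hi) -> AgeBand:
    try:
        lower = int(lo)
    except (TypeError, ValueError):
        raise FormatError(f"bad age_lo value {lo!r}") from None
    if hi is None or (isinstance(hi, float) and math.isnan(hi)) or str(hi).strip() in ("", "plus"):
        return AgeBand(lower, None)
    return AgeBand(lower, int(float(hi)))


def _bands_and_values(group: pd.DataFrame, value_col: str) -> tuple[tuple[AgeBand, ...], np.ndarray]:
    rows = [( _parse_band(r.age_lo, r.age_hi), float(getattr(r, value_col)) ) for r in group.itertuples()]
    rows.sort(key=lambda bv: bv[0].lower)
    bands = tuple(b for b, _ in rows)
    if len({b.lower for b in bands}) != len(bands):
        raise ValidationError("duplicate age band rows")
    return bands, np.array([v for _, v in rows])


def read_hazard_table(path: str | Path, kind: TableKind) -> SexPair[HazardTable]:
    """Read a two-sex hazard CSV; rates converted per-100,000 -> per person-year."""
    df = _read_csv(path, ["sex", "age_lo", "age_hi", "rate_per_100k"])
    tables = {}
    for sex, group in df.groupby("sex"):
        bands, vals = _bands_and_values(group, "rate_per_100k")
        tables[str(sex)] = HazardTable(sex=str(sex), bands=bands, rate=vals / PER_100K, kind=kind)
    for sex in SEXES:
        if sex not in tables:
            raise ValidationError(f"{path}: missing sex {sex!r}")
    return SexPair(male=tables["male"], female=tables["female"])


def write_hazard_table(pair: SexPair[HazardTable] | HazardTable, path: str | Path) -> None:
    """Write hazard table(s) as CSV, rates rescaled to per-100,000, 6 significant digits."""
    tables: Iterable[HazardTable]
    tables = [pair] if isinstance(pair, HazardTable) else [pair.male, pair.female]
    rows = []
    for t in tables:
        for band, r in zip(t.bands, t.rate):
            rows.append(
                {
                    "sex": t.sex,
                    "age_lo": band.lower,
                    "age_hi": "" if band.open_ended else band.upper,
                    "rate_per_100k": float(f"{r * PER_100K:.6g}"),
                }
            )
    pd.DataFrame(rows, columns=["sex", "age_lo", "age_hi", "rate_per_100k"]).to_csv(
        path, index=False
    )


def read_ratio_table(path: str | Path) -> SexPair[RatioTable]:
    """Read a two-sex MOF:hip multiplier CSV (column ``multiplier``)."""
    df = _read_csv(path, ["sex", "age_lo", "age_hi", "multiplier"])
    tables = {}
    for sex, group in df.groupby("sex"):
        bands, vals = _bands_and_values(group, "multiplier")
        tables[str(sex)] = RatioTable(sex=str(sex), bands=bands, multiplier=vals)
    for sex in SEXES:
        if sex not in tables:
            raise ValidationError(f"{path}: missing sex {sex!r}")
    return SexPair(male=tables["male"], female=tables["female"])


def write_ratio_table(pair: SexPair[RatioTable], path: str | Path) -> None:
    rows = []
    for _, t in pair:
        for band, m in zip(t.bands, t.multiplier):
            rows.append(
                {
                    "sex": t.sex,
                    "age_lo": band.lower,
                    "age_hi": "" if band.open_ended else band.upper,
                    "multiplier": float(f"{m:.6g}"),
                }
            )
    pd.DataFrame(rows, columns=["sex", "age_lo", "age_hi", "multiplier"]).to_csv(path, index=False)


def read_population_table(path: str | Path) -> PopulationTable:
    """Read person counts by (year, sex, band); every slice must cover the banding."""
    df = _read_csv(path, ["year", "sex", "age_lo", "age_hi", "count"])
    if df.duplicated(subset=["year", "sex", "age_lo"]).any():
        raise ValidationError(f"{path}: duplicate (year, sex, band) rows")
    slices: dict[tuple[int, str], tuple[tuple[AgeBand, ...], np.ndarray]] = {}
    for (year, sex), group in df.groupby(["year", "sex"]):
        bands, vals = _bands_and_values(group, "count")
        slices[(int(year), str(sex))] = (bands, vals)
    if not slices:
        raise ValidationError(f"{path}: no data rows")
    bandings = {bands for bands, _ in slices.values()}
    if len(bandings) != 1:
        raise ValidationError(f"{path}: (year, sex) slices use inconsistent bandings")
    (bands,) = bandings
    return PopulationTable(
        bands=bands, counts={key: vals for key, (_, vals) in slices.items()}
    )


def write_population_table(table: PopulationTable, path: str | Path) -> None:
    rows = []
    for (year, sex) in sorted(table.counts):
        for band, c in zip(table.bands, table.counts[(year, sex)]):
            rows.append(
                {
                    "year": year,
                    "sex": sex,
                    "age_lo": band.lower,
                    "age_hi": "" if band.open_ended else band.upper,
                    "count": float(f"{c:.10g}"),
                }
            )
    pd.DataFrame(rows, columns=["year", "sex", "age_lo", "age_hi", "count"]).to_csv(
        path, index=False
    )
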