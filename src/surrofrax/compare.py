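"""Model-comparison protocol: factorial profile grid, paired probabilities,
correlation, fixed-knot piecewise regression, medians and tolerance intervals.

Two models are compared on an exhaustive array of risk profiles -- every
on/off combination of the six clinical risk factors crossed with
femoral-neck T-scores from 0 to -3.5 SD in 0.5 SD steps at BMI 26
kg/m^2, i.e. 2^6 x 8 = 512 combinations per (age, sex).  This is an
array of all possible combinations, not a population simulation.  For
each (age, sex, outcome) cell the protocol reports:

* the Pearson correlation between the two models' probabilities,
* a piecewise linear regression of model-B probability on model-A
  probability with one fixed knot (default at 35%) on the A axis,
* the median A probability, the B probability at that median, and a
  95% nonparametric tolerance interval: the reference median plus the
  empirical 2.5th/97.5th percentiles of the paired B-minus-A
  differences among the profiles whose A ranks sit nearest the median
  (rank window, default 101 profiles).  A tolerance interval covers
  individual cases, unlike a confidence interval for a mean.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .prob_engine import CRF_NAMES, REFERENCE_BMI, RiskProfile, compute_probabilities
from .surrogate import FractureModel

__all__ = [
    "ComparisonResult",
    "DEFAULT_TSCORES",
    "ProfileGrid",
    "SplineFit",
    "correlation",
    "generate_profile_grid",
    "median_and_ti",
    "paired_probabilities",
    "piecewise_fit",
    "run_comparison",
]

#: Default BMD protocol: T-scores 0 to -3.5 SD in 0.5 SD steps.
DEFAULT_TSCORES: tuple[float, ...] = tuple(-0.5 * i for i in range(8))

DEFAULT_AGES: tuple[float, ...] = (50.0, 60.0, 70.0, 80.0)
DEFAULT_KNOT_PERCENT = 35.0
DEFAULT_TI_WINDOW = 101


@dataclass(frozen=True)
class ProfileGrid:
    """Deterministic factorial grid of risk profiles at one (age, sex)."""

    age: float
    sex: str
    rows: tuple[RiskProfile, ...]
    coords: pd.DataFrame  # one row per profile: tscore + one 0/1 column per CRF

    def __len__(self) -> int:
        return len(self.rows)


def generate_profile_grid(
    age: float,
    sex: str,
    tscores: tuple[float, ...] = DEFAULT_TSCORES,
    crf_names: tuple[str, ...] = CRF_NAMES,
) -> ProfileGrid:
    """Cartesian product of CRF on/off states and T-scores, BMI fixed at 26.

    Row order is deterministic: T-score outermost (in the given order),
    then CRF states as a binary counter with the first named factor as
    the most significant bit.
    """
    if not tscores:
        raise ValueError("tscores must be non-empty")
    if len(set(tscores)) != len(tscores):
        raise ValueError("duplicate T-scores in protocol")
    unknown = set(crf_names) - set(CRF_NAMES)
    if unknown:
        raise ValueError(f"unknown clinical risk factor(s): {sorted(unknown)}")
    rows: list[RiskProfile] = []
    coords: list[dict] = []
    for tscore in tscores:
        for states in itertools.product((0, 1), repeat=len(crf_names)):
            active = frozenset(c for c, on in zip(crf_names, states) if on)
            rows.append(
                RiskProfile(age=age, sex=sex, bmi=REFERENCE_BMI, crf=active, tscore=tscore)
            )
            coords.append({"tscore": tscore, **dict(zip(crf_names, states))})
    return ProfileGrid(age=age, sex=sex, rows=tuple(rows), coords=pd.DataFrame(coords))


def paired_probabilities(
    model_a: FractureModel, model_b: FractureModel, grid: ProfileGrid
) -> pd.DataFrame:
    """Both models' MOF and hip probabilities (in %) for every grid profile."""
    records = []
    for i, profile in enumerate(grid.rows):
        ra = compute_probabilities(model_a, profile)
        rb = compute_probabilities(model_b, profile)
        records.append(
            {
                "profile_id": i,
                "p_a_mof": 100.0 * ra.p_mof,
                "p_b_mof": 100.0 * rb.p_mof,
                "p_a_hip": 100.0 * ra.p_hip,
                "p_b_hip": 100.0 * rb.p_hip,
            }
        )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class SplineFit:
    """Continuous broken-stick fit of y on x with one fixed knot.

    ``slope_change`` is the increment to the slope above the knot; it
    is exactly 0 with ``knot_active=False`` when no observation lies
    above the knot (the above-knot basis column is then all zero).
    """

    intercept: float
    slope_below: float
    slope_change: float
    knot: float
    knot_active: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (
            self.intercept
            + self.slope_below * x
            + self.slope_change * np.clip(x - self.knot, 0.0, None)
        )


def piecewise_fit(
    x: np.ndarray, y: np.ndarray, knot_percent: float = DEFAULT_KNOT_PERCENT
) -> SplineFit:
    """Least-squares linear spline of y on x with one fixed knot (continuous)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a piecewise fit")
    if not 0 < knot_percent < 100:
        raise ValueError("knot must lie in (0, 100)")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("degenerate design: all x values equal")
    above = np.clip(x - knot_percent, 0.0, None)
    knot_active = bool(np.any(above > 0))
    if knot_active:
        design = np.column_stack([np.ones_like(x), x, above])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept, slope_below, slope_change = coef
    else:
        design = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept, slope_below = coef
        slope_change = 0.0
    return SplineFit(
        intercept=float(intercept),
        slope_below=float(slope_below),
        slope_change=float(slope_change),
        knot=knot_percent,
        knot_active=knot_active,
    )


def correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of the paired probabilities."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant column")
    if np.array_equal(x, y):
        return 1.0  # identical columns correlate exactly; skip rounding noise
    return float(stats.pearsonr(x, y).statistic)


def median_and_ti(
    p_ref: np.ndarray,
    p_other: np.ndarray,
    coverage: float = 0.95,
    window: int = DEFAULT_TI_WINDOW,
) -> tuple[float, float, float, float]:
    """Median comparison with a nonparametric tolerance interval.

    Pairs are ranked by the reference probability.  ``median_ref`` is
    the standard sample median of ``p_ref`` (mean of the two central
    order statistics for even n); ``median_other`` is the mean of
    ``p_other`` over those same central profile(s).  The tolerance
    interval describes where individual model-B values fall for
    profiles at the reference median: it is ``median_ref`` plus the
    empirical ``(1-coverage)/2`` and ``(1+coverage)/2`` percentiles of
    the paired differences ``p_other - p_ref`` among the ``window``
    profiles whose reference ranks are nearest the median.  Identical
    models (or any constant offset between them) therefore give a
    zero-width interval.

    Returns ``(median_ref, median_other, ti_low, ti_high)``.
    """
    p_ref = np.asarray(p_ref, dtype=float)
    p_other = np.asarray(p_other, dtype=float)
    n = p_ref.size
    if n == 0 or p_other.size != n:
        raise ValueError("p_ref and p_other must be equal-length and non-empty")
    window = min(int(window), n)
    if window < 20:
        warnings.warn(
            f"tolerance-interval window {window} < 20: percentile estimates are unstable",
            stacklevel=2,
        )
    order = np.argsort(p_ref, kind="stable")
    ref_sorted = p_ref[order]
    other_sorted = p_other[order]
    if n % 2:
        central = [n // 2]
    else:
        central = [n // 2 - 1, n // 2]
    median_ref = float(np.mean(ref_sorted[central]))
    median_other = float(np.mean(other_sorted[central]))
    start = (n - window) // 2
    diffs = other_sorted[start : start + window] - ref_sorted[start : start + window]
    lo_q = 100.0 * (1.0 - coverage) / 2.0
    ti_low = median_ref + float(np.percentile(diffs, lo_q))
    ti_high = median_ref + float(np.percentile(diffs, 100.0 - lo_q))
    return median_ref, median_other, ti_low, ti_high


@dataclass(frozen=True)
class ComparisonResult:
    """Per-(age, sex, outcome) summary plus the raw paired tables.

    ``summary`` columns: age, sex, outcome, n, r, median_a, median_b,
    ti_low, ti_high, intercept, slope_below, slope_change, knot,
    knot_active -- probabilities and interval bounds in percent.
    ``pairs`` maps (age, sex) to the per-profile probability table.
    """

    summary: pd.DataFrame
    pairs: dict[tuple[float, str], pd.DataFrame] = field(default_factory=dict)


def run_comparison(
    model_a: FractureModel,
    model_b: FractureModel,
    ages: tuple[float, ...] = DEFAULT_AGES,
    tscores: tuple[float, ...] = DEFAULT_TSCORES,
    knot_percent: float = DEFAULT_KNOT_PERCENT,
    ti_window: int = DEFAULT_TI_WINDOW,
) -> ComparisonResult:
    """Full comparison over ages x sexes x outcomes (default 4 x 2 x 2 cells)."""
    records = []
    pair_tables: dict[tuple[float, str], pd.DataFrame] = {}
    for age in ages:
        for sex in ("male", "female"):
            grid = generate_profile_grid(age, sex, tscores=tscores)
            pairs = paired_probabilities(model_a, model_b, grid)
            pair_tables[(age, sex)] = pairs
            for outcome in ("mof", "hip"):
                xa = pairs[f"p_a_{outcome}"].to_numpy()
                xb = pairs[f"p_b_{outcome}"].to_numpy()
                fit = piecewise_fit(xa, xb, knot_percent=knot_percent)
                med_a, med_b, ti_low, ti_high = median_and_ti(xa, xb, window=ti_window)
                records.append(
                    {
                        "age": age,
                        "sex": sex,
                        "outcome": outcome,
                        "n": len(pairs),
                        "r": correlation(xa, xb),
                        "median_a": med_a,
                        "median_b": med_b,
                        "ti_low": ti_low,
                        "ti_high": ti_high,
                        "intercept": fit.intercept,
                        "slope_below": fit.slope_below,
                        "slope_change": fit.slope_change,
                        "knot": fit.knot,
                        "knot_active": fit.knot_active,
                    }
                )
    return ComparisonResult(summary=pd.DataFrame.from_records(records), pairs=pair_tables)
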