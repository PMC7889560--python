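"""Synthetic fixtures with the statistical structure the method assumes.

The source numbers behind a real surrogate-model build -- the reference
country's hip-fracture incidence, the index country's life table, the
registry MOF:hip ratios and the UN population projections -- are not
shipped here.  This module generates stand-ins with the right shape so
the whole pipeline is exercisable offline:

* Gompertz hazards (``rate = alpha * exp(beta * years-past-floor)``)
  for both mortality and hip incidence -- the simplest form matching
  the near-universal log-linear age pattern of both;
* male mortality above female at every age, female hip incidence above
  male past age 60 (the usual sex crossover);
* MOF:hip multipliers declining with age from ~6 toward ~1.5, female
  >= male (younger people break wrists and humeri far more often than
  hips; the ratio compresses with age);
* a young, growing population pyramid with geometric total growth and
  a configurable ageing drift shifting mass into older bands;
* SYNTHETIC relative-risk coefficients (see
  :meth:`~surrofrax.prob_engine.RelativeRiskSpec.synthetic_default`).

Everything is closed-form and deterministic for a fixed spec, so
generated fixture files are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .prob_engine import RelativeRiskSpec
from .rates_io import (
    HIP_INCIDENCE,
    MORTALITY,
    AgeBand,
    HazardTable,
    PopulationTable,
    RatioTable,
    SexPair,
    ValidationError,
    default_banding,
)
from .surrogate import FractureModel, impute_mof_incidence

__all__ = [
    "SyntheticSpec",
    "make_demo_pair",
    "synth_incidence",
    "synth_mortality",
    "synth_population",
    "synth_ratios",
]


@dataclass(frozen=True)
class GompertzParams:
    """``rate(midpoint) = alpha * exp(beta * (midpoint - floor))``."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValidationError("Gompertz alpha must be > 0")
        if self.beta < 0:
            raise ValidationError("Gompertz beta must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults emulate a high-mortality, young, fast-growing index
    country paired with a lower-mortality reference population:
    mortality ~0.8%/yr (men) at the early 50s rising toward ~20%/yr at
    90+; hip incidence ~20/100,000/yr at the early 50s rising toward
    ~1,300/100,000/yr at 90+ with a 1.5x female excess past 60.  The
    population covers ages 50+ (~20 million people), grows 2%/yr and
    slowly shifts mass into older bands.
    """

    seed: int = 0
    mortality_male: GompertzParams = GompertzParams(alpha=0.008, beta=0.075)
    mortality_female: GompertzParams = GompertzParams(alpha=0.006, beta=0.075)
    hip_male: GompertzParams = GompertzParams(alpha=0.00015, beta=0.105)
    hip_female: GompertzParams = GompertzParams(alpha=0.00015, beta=0.105)
    female_excess: float = 1.5  # female:male hip-incidence ratio above crossover age
    female_excess_from_age: float = 60.0
    ratio_start: float = 6.0  # MOF:hip multiplier at the floor band
    ratio_floor: float = 1.5  # asymptote at old age
    ratio_decay: float = 0.05  # per year past the floor
    ratio_female_bump: float = 0.2  # additive female excess on the multiplier
    population_total: float = 20e6
    population_growth: float = 0.02  # per year
    ageing_drift: float = 0.003  # per-year decrease of the pyramid decay rate
    pyramid_decay: float = 0.28  # per band; larger = younger pyramid
    bands: tuple[AgeBand, ...] = field(default_factory=default_banding)

    def __post_init__(self) -> None:
        if self.population_growth <= -1:
            raise ValidationError("population growth below -100%/yr")
        if self.female_excess <= 0 or self.ratio_floor < 1 or self.ratio_start < self.ratio_floor:
            raise ValidationError("invalid synthetic shape parameters")


def _gompertz_rates(spec: SyntheticSpec, params: GompertzParams) -> np.ndarray:
    offsets = np.array([b.midpoint - spec.bands[0].lower for b in spec.bands])
    rates = params.alpha * np.exp(params.beta * offsets)
    if np.any(rates > 1):
        raise ValidationError("Gompertz parameters produce an annual rate > 1")
    return rates


def synth_mortality(spec: SyntheticSpec, sex: str) -> HazardTable:
    """Gompertz mortality table; strictly age-increasing when beta > 0."""
    params = spec.mortality_male if sex == "male" else spec.mortality_female
    return HazardTable(sex=sex, bands=spec.bands, rate=_gompertz_rates(spec, params), kind=MORTALITY)


def synth_incidence(spec: SyntheticSpec, sex: str) -> HazardTable:
    """Gompertz hip incidence with the female-excess multiplier above the crossover age."""
    params = spec.hip_male if sex == "male" else spec.hip_female
    rates = _gompertz_rates(spec, params)
    if sex == "female":
        above = np.array([b.midpoint >= spec.female_excess_from_age for b in spec.bands])
        rates = np.where(above, rates * spec.female_excess, rates)
    return HazardTable(sex=sex, bands=spec.bands, rate=rates, kind=HIP_INCIDENCE)


def synth_ratios(spec: SyntheticSpec, sex: str) -> RatioTable:
    """Age-declining MOF:hip multipliers, female >= male.

    SYNTHETIC stand-ins for registry-derived ratios, which are not
    shipped with the package.
    """
    offsets = np.array([b.midpoint - spec.bands[0].lower for b in spec.bands])
    mult = spec.ratio_floor + (spec.ratio_start - spec.ratio_floor) * np.exp(
        -spec.ratio_decay * offsets
    )
    if sex == "female":
        mult = mult + spec.ratio_female_bump
    return RatioTable(sex=sex, bands=spec.bands, multiplier=mult)


def synth_population(spec: SyntheticSpec, years: list[int] | tuple[int, ...]) -> PopulationTable:
    """Per-year pyramids with geometric growth and old-age share drift.

    Band counts decay geometrically with band index (a young pyramid);
    the decay rate shrinks by ``ageing_drift`` per calendar year so
    mass shifts into older bands over time, emulating demographic
    ageing.  Deterministic.
    """
    if not years:
        raise ValueError("years must be non-empty")
    base_year = min(years)
    counts: dict[tuple[int, str], np.ndarray] = {}
    idx = np.arange(len(spec.bands), dtype=float)
    for year in years:
        elapsed = year - base_year
        decay = max(spec.pyramid_decay - spec.ageing_drift * elapsed, 0.01)
        shape = np.exp(-decay * idx)
        shape /= shape.sum()
        total = spec.population_total * (1 + spec.population_growth) ** elapsed
        for sex in ("male", "female"):
            counts[(int(year), sex)] = 0.5 * total * shape
    return PopulationTable(bands=spec.bands, counts=counts)


def make_demo_pair(
    spec: SyntheticSpec | None = None,
) -> tuple[FractureModel, SexPair[HazardTable]]:
    """A reference model plus a distinct, higher index mortality.

    The reference model carries the synthetic hip incidence, imputed
    MOF incidence, reference mortality and the synthetic risk
    coefficients.  The index mortality equals the reference mortality
    scaled by a band-wise factor rising from ~1.05 at the floor to 2.0
    at the oldest ages, emulating a markedly higher-mortality index
    country; a surrogate model is buildable from the pair immediately.
    """
    spec = spec or SyntheticSpec()
    hip = SexPair(male=synth_incidence(spec, "male"), female=synth_incidence(spec, "female"))
    ratios = SexPair(male=synth_ratios(spec, "male"), female=synth_ratios(spec, "female"))
    mof = impute_mof_incidence(hip, ratios)
    mortality = SexPair(male=synth_mortality(spec, "male"), female=synth_mortality(spec, "female"))
    reference = FractureModel(
        name="reference",
        hip_incidence=hip,
        mof_incidence=mof,
        mortality=mortality,
        risk_coefficients=RelativeRiskSpec.synthetic_default(),
    )
    offsets = np.array([b.midpoint - spec.bands[0].lower for b in spec.bands])
    factor = np.minimum(1.05 + 0.0235 * offsets, 2.0)
    index_mortality = mortality.map(lambda t: t.scaled(factor))
    return reference, index_mortality
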