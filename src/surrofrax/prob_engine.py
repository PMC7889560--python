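"""Competing-risk 10-year fracture probability engine.

An individual's 10-year probability of hip fracture (or of major
osteoporotic fracture, MOF) is the cause-specific cumulative incidence
of a *first* fracture with death as a competing exit: someone who dies
fracture-free within the horizon never fractures.  With both hazards
piecewise constant over the age-band partition this integral has an
exact closed form.  Per segment of length ``d`` with constant fracture
hazard ``hf``, death hazard ``hd`` and fracture-free survival ``S`` on
entry::

    contribution = S * hf / (hf + hd) * (1 - exp(-(hf + hd) * d))
    S            -> S * exp(-(hf + hd) * d)

summed over segments split at every band boundary and at the horizon
end.  As ``hd -> 0`` this reduces to ``1 - exp(-integral hf)``, the
familiar no-competing-risk limit.

The individual's fracture hazard is the population baseline incidence
multiplied by a log-linear clinical-risk-factor (CRF) layer: one hazard
ratio per active binary risk factor, plus a gradient-of-risk per SD
decrease of the femoral-neck BMD T-score.  The shipped hazard ratios
are SYNTHETIC placeholders in a plausible range (the authentic FRAX
coefficients are proprietary and unpublished); the layer is fully
configurable through :class:`RelativeRiskSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .rates_io import HazardTable

if TYPE_CHECKING:  # pragma: no cover
    from .surrogate import FractureModel

__all__ = [
    "CRF_NAMES",
    "ProbabilityResult",
    "RelativeRiskSpec",
    "RiskProfile",
    "StepHazard",
    "compute_probabilities",
    "intervention_thresholds",
    "profile_hazard",
    "read_risk_spec",
    "ten_year_probability",
    "write_risk_spec",
]

#: The six binary clinical risk factors of the standard assessment protocol.
CRF_NAMES = (
    "prior_fracture",
    "parent_hip_fracture",
    "current_smoking",
    "glucocorticoids",
    "rheumatoid_arthritis",
    "alcohol_3plus_units",
)

#: BMI (kg/m^2) used throughout the comparison protocol.
REFERENCE_BMI = 26.0


class ConfigError(ValueError):
    """Risk-coefficient configuration names an unknown CRF or is malformed."""


@dataclass(frozen=True)
class RiskProfile:
    """One individual: exact age, sex, BMI, CRF flags and optional T-score."""

    age: float
    sex: str
    bmi: float = REFERENCE_BMI
    crf: frozenset[str] = frozenset()
    tscore: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male or female, got {self.sex!r}")
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")
        object.__setattr__(self, "crf", frozenset(self.crf))
        unknown = self.crf - set(CRF_NAMES)
        if unknown:
            raise ValueError(f"unknown clinical risk factor(s): {sorted(unknown)}")
        if self.tscore is not None and not math.isfinite(self.tscore):
            raise ValueError("tscore must be finite when present")


@dataclass(frozen=True)
class RelativeRiskSpec:
    """Multiplicative risk layer on top of the baseline rate tables.

    Attributes
    ----------
    fracture_hr, death_hr
        Per-CRF hazard ratios applied to the fracture and death hazard
        respectively when the factor is active.  Death HRs default to 1
        (off); authentic calculators modify death risk for some factors
        but the magnitudes are not public.
    bmd_gradient
        Gradient of risk: fracture hazard ratio per SD *decrease* of
        the femoral-neck T-score relative to ``tscore_ref``.
    tscore_ref
        T-score at which the BMD multiplier is 1.
    calibration_divisor
        Divides the reference-profile fracture hazard.  Baseline tables
        describe population-average incidence, which already includes
        CRF-positive people; a divisor > 1 deflates the all-reference
        profile accordingly.  Default 1 (no re-calibration) since the
        authentic calibration constants are unavailable.
    """

    fracture_hr: Mapping[str, float] = field(default_factory=dict)
    death_hr: Mapping[str, float] = field(default_factory=dict)
    bmd_gradient: float = 1.6
    tscore_ref: float = 0.0
    calibration_divisor: float = 1.0

    def __post_init__(self) -> None:
        for mapping, label in ((self.fracture_hr, "fracture"), (self.death_hr, "death")):
            unknown = set(mapping) - set(CRF_NAMES)
            if unknown:
                raise ConfigError(f"unknown CRF in {label} hazard ratios: {sorted(unknown)}")
            if any(v <= 0 for v in mapping.values()):
                raise ConfigError(f"{label} hazard ratios must be > 0")
        if self.bmd_gradient < 1:
            raise ConfigError("bmd gradient must be >= 1")
        if self.calibration_divisor <= 0:
            raise ConfigError("calibration divisor must be > 0")
        object.__setattr__(self, "fracture_hr", dict(self.fracture_hr))
        object.__setattr__(self, "death_hr", dict(self.death_hr))

    def fracture_multiplier(self, profile: RiskProfile) -> float:
        m = 1.0
        for crf in profile.crf:
            m *= self.fracture_hr.get(crf, 1.0)
        if profile.tscore is not None:
            m *= self.bmd_gradient ** (self.tscore_ref - profile.tscore)
        return m / self.calibration_divisor

    def death_multiplier(self, profile: RiskProfile) -> float:
        m = 1.0
        for crf in profile.crf:
            m *= self.death_hr.get(crf, 1.0)
        return m

    @staticmethod
    def synthetic_default() -> "RelativeRiskSpec":
        """SYNTHETIC demonstration coefficients -- NOT the authentic (proprietary)
        FRAX betas.  Values sit in the range meta-analyses report for these
        factors (hazard ratios ~1.3-2.0, gradient ~1.6/SD)."""
        return RelativeRiskSpec(
            fracture_hr={
                "prior_fracture": 1.85,
                "parent_hip_fracture": 1.9,
                "current_smoking": 1.3,
                "glucocorticoids": 1.65,
                "rheumatoid_arthritis": 1.45,
                "alcohol_3plus_units": 1.4,
            },
            bmd_gradient=1.6,
        )


# -- flat key-value config: <crf>.fracture_hr, <crf>.death_hr,
#    bmd.gradient_per_sd, bmd.tscore_ref, calibration.divisor ---------------

def read_risk_spec(path: str | Path) -> RelativeRiskSpec:
    frac: dict[str, float] = {}
    death: dict[str, float] = {}
    scalars = {"bmd.gradient_per_sd": 1.6, "bmd.tscore_ref": 0.0, "calibration.divisor": 1.0}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = (s.strip() for s in line.partition("="))
        try:
            value = float(val)
        except ValueError:
            raise ConfigError(f"{path}:{lineno}: non-numeric value {val!r}") from None
        if key in scalars:
            scalars[key] = value
        elif key.endswith(".fracture_hr"):
            frac[key[: -len(".fracture_hr")]] = value
        elif key.endswith(".death_hr"):
            death[key[: -len(".death_hr")]] = value
        else:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
    return RelativeRiskSpec(
        fracture_hr=frac,
        death_hr=death,
        bmd_gradient=scalars["bmd.gradient_per_sd"],
        tscore_ref=scalars["bmd.tscore_ref"],
        calibration_divisor=scalars["calibration.divisor"],
    )


def write_risk_spec(spec: RelativeRiskSpec, path: str | Path) -> None:
    lines = ["# relative-risk coefficients (synthetic demonstration values unless edited)"]
    for crf, v in sorted(spec.fracture_hr.items()):
        lines.append(f"{crf}.fracture_hr = {v:g}")
    for crf, v in sorted(spec.death_hr.items()):
        lines.append(f"{crf}.death_hr = {v:g}")
    lines.append(f"bmd.gradient_per_sd = {spec.bmd_gradient:g}")
    lines.append(f"bmd.tscore_ref = {spec.tscore_ref:g}")
    lines.append(f"calibration.divisor = {spec.calibration_divisor:g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Piecewise-constant hazards and the competing-risk integral
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepHazard:
    """Right-continuous step hazard: rate ``rates[i]`` on ``[edges[i], edges[i+1])``.

    The last segment is open-ended.  Ages below ``edges[0]`` are outside
    the domain.
    """

    edges: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "rates", rates)
        if edges.ndim != 1 or edges.shape != rates.shape or edges.size == 0:
            raise ValueError("edges and rates must be equal-length 1-d arrays")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise ValueError("hazard rates must be finite and >= 0")

    @classmethod
    def constant(cls, rate: float, start: float = 0.0) -> "StepHazard":
        return cls(edges=np.array([start]), rates=np.array([float(rate)]))

    @classmethod
    def from_table(cls, table: HazardTable) -> "StepHazard":
        return cls(
            edges=np.array([b.lower for b in table.bands], dtype=float),
            rates=table.rate.copy(),
        )

    def rate(self, age: float) -> float:
        if age < self.edges[0]:
            raise ValueError(f"age {age} below hazard domain start {self.edges[0]}")
        idx = int(np.searchsorted(self.edges, age, side="right")) - 1
        return float(self.rates[idx])

    def scaled(self, factor: float) -> "StepHazard":
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return replace(self, rates=self.rates * factor)


def profile_hazard(
    model: "FractureModel", profile: RiskProfile, outcome: str
) -> StepHazard:
    """Individualized annual fracture hazard for *outcome* ('hip' or 'mof').

    The baseline age-band incidence for the profile's sex is scaled by
    the product of active CRF hazard ratios, the BMD gradient term, and
    the inverse calibration divisor.
    """
    if outcome == "hip":
        table = model.hip_incidence[profile.sex]
    elif outcome == "mof":
        table = model.mof_incidence[profile.sex]
    else:
        raise ValueError(f"outcome must be 'hip' or 'mof', got {outcome!r}")
    mult = model.risk_coefficients.fracture_multiplier(profile)
    return StepHazard.from_table(table).scaled(mult)


def death_hazard(model: "FractureModel", profile: RiskProfile) -> StepHazard:
    """Individualized annual death hazard (CRF death HRs default to 1)."""
    mult = model.risk_coefficients.death_multiplier(profile)
    return StepHazard.from_table(model.mortality[profile.sex]).scaled(mult)


def ten_year_probability(
    frac_hazard: StepHazard,
    death_hazard: StepHazard,
    start_age: float,
    horizon: float = 10.0,
) -> float:
    """Probability of a first fracture before death within *horizon* years.

    Exact integration over the piecewise-constant partition; segments
    split at every band boundary of either hazard and at the horizon
    end.  Splitting any segment further leaves the result unchanged to
    machine precision.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    end_age = start_age + horizon
    cuts = np.concatenate([frac_hazard.edges, death_hazard.edges])
    cuts = cuts[(cuts > start_age) & (cuts < end_age)]
    bounds = np.concatenate([[start_age], np.unique(cuts), [end_age]])
    prob = 0.0
    survival = 1.0
    for left, right in zip(bounds[:-1], bounds[1:]):
        hf = frac_hazard.rate(left)
        hd = death_hazard.rate(left)
        total = hf + hd
        delta = right - left
        if total > 0:
            # expm1 keeps precision when total * delta is tiny
            cum = -math.expm1(-total * delta)
            prob += survival * (hf / total) * cum
            survival *= 1.0 - cum
    return prob


@dataclass(frozen=True)
class ProbabilityResult:
    """10-year probabilities (fractions in [0, 1]) for one profile."""

    p_mof: float
    p_hip: float
    horizon: float = 10.0


def compute_probabilities(
    model: "FractureModel", profile: RiskProfile, horizon: float = 10.0
) -> ProbabilityResult:
    """MOF and hip fracture probabilities for *profile* under *model*."""
    hd = death_hazard(model, profile)
    p_mof = ten_year_probability(profile_hazard(model, profile, "mof"), hd, profile.age, horizon)
    p_hip = ten_year_probability(profile_hazard(model, profile, "hip"), hd, profile.age, horizon)
    return ProbabilityResult(p_mof=p_mof, p_hip=p_hip, horizon=horizon)


def intervention_thresholds(
    model: "FractureModel", ages: list[float] | tuple[float, ...]
) -> dict[float, float]:
    """Age-dependent MOF intervention thresholds.

    The threshold at each age is the 10-year MOF probability of a woman
    of that age with a prior fragility fracture, no other clinical risk
    factors, no BMD measurement, and BMI at the protocol reference --
    the "woman with a prior fracture" convention many national
    guidelines use to anchor treatment decisions.
    """
    out: dict[float, float] = {}
    for age in ages:
        profile = RiskProfile(
            age=float(age), sex="female", bmi=REFERENCE_BMI, crf=frozenset({"prior_fracture"})
        )
        out[float(age)] = compute_probabilities(model, profile).p_mof
    return out
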