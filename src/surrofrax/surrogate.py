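"""Surrogate fracture-model construction.

Countries without usable hip-fracture epidemiology can still run a
probability calculator by borrowing fracture incidence from a
reference country whose rates are judged representative, while keeping
the index country's own mortality.  That pairing -- reference
incidence + index mortality -- is the surrogate model built here.
Because the competing risk of death differs between the countries, the
surrogate's absolute probabilities differ from the reference's (higher
index mortality pushes every probability down) while the rank order of
risk across profiles is essentially preserved.

Where only hip incidence is known, the incidence of the remaining
major osteoporotic fractures (clinical spine, distal forearm, proximal
humerus) is imputed by age/sex MOF:hip ratios assumed transportable
from well-documented registries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .prob_engine import RelativeRiskSpec
from .rates_io import (
    HIP_INCIDENCE,
    MOF_INCIDENCE,
    MORTALITY,
    HazardTable,
    RatioTable,
    SexPair,
    ValidationError,
)

__all__ = ["AlignmentError", "FractureModel", "build_surrogate", "impute_mof_incidence"]


class AlignmentError(ValueError):
    """Tables that must share a banding (and sexes) do not."""


def _check_same_banding(*tables) -> None:
    bandings = {t.bands for t in tables}
    if len(bandings) != 1:
        raise AlignmentError("tables do not share one age banding")


@dataclass(frozen=True)
class FractureModel:
    """A named country model: incidence, mortality and the risk layer.

    All four hazard tables (hip and MOF incidence, both sexes;
    mortality, both sexes) must share one banding, and MOF incidence
    must dominate hip incidence band-wise since hip fractures are a
    subset of major osteoporotic fractures.
    """

    name: str
    hip_incidence: SexPair[HazardTable]
    mof_incidence: SexPair[HazardTable]
    mortality: SexPair[HazardTable]
    risk_coefficients: RelativeRiskSpec

    def __post_init__(self) -> None:
        _check_same_banding(
            self.hip_incidence.male,
            self.hip_incidence.female,
            self.mof_incidence.male,
            self.mof_incidence.female,
            self.mortality.male,
            self.mortality.female,
        )
        for sex in ("male", "female"):
            if (self.mof_incidence[sex].rate < self.hip_incidence[sex].rate).any():
                raise ValidationError(
                    f"MOF incidence below hip incidence for {sex}; "
                    "hip fractures are a subset of MOF"
                )

    @property
    def bands(self):
        return self.hip_incidence.male.bands


def impute_mof_incidence(
    hip: SexPair[HazardTable], ratios: SexPair[RatioTable]
) -> SexPair[HazardTable]:
    """MOF incidence = hip incidence x age/sex MOF:hip multiplier, band-wise.

    Assumes the ratio of hip to other major osteoporotic fracture
    incidence is the same in the target population as in the registry
    the ratios came from.
    """

    def one(sex: str) -> HazardTable:
        h, r = hip[sex], ratios[sex]
        if h.bands != r.bands:
            raise AlignmentError(f"hip and ratio tables disagree on banding for {sex}")
        if h.kind != HIP_INCIDENCE:
            raise ValidationError(f"expected hip_incidence table, got {h.kind}")
        return h.scaled(r.multiplier).with_kind(MOF_INCIDENCE)

    return SexPair(male=one("male"), female=one("female"))


def build_surrogate(
    reference: FractureModel,
    index_mortality: SexPair[HazardTable],
    name: str,
) -> FractureModel:
    """Pair the reference model's fracture incidence with the index country's mortality.

    The surrogate keeps the reference's hip and MOF incidence and its
    risk-coefficient layer unchanged; only the mortality tables are
    replaced.
    """
    for sex in ("male", "female"):
        t = index_mortality[sex]
        if t.bands != reference.bands:
            raise AlignmentError("index mortality banding differs from reference model")
        if t.kind != MORTALITY:
            raise ValidationError(f"expected mortality table, got {t.kind}")
    return replace(reference, name=name, mortality=index_mortality)
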