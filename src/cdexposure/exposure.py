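"""Construction of lifetime exposure profiles for diet and smoking scenarios.

Dietary intake is specified as the adult level (ug/day) and scaled down
through childhood by the catalogue's caloric-intake curve.  Smoking is a step
exposure: a constant inhaled dose, packs/day times a locality-specific
cadmium yield per pack, from the smoking start age onward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .kinetics import DAYS_PER_YEAR, ExposureProfile
from .params import TKParameters

__all__ = [
    "DietaryScenario",
    "SmokingScenario",
    "cd_per_pack",
    "smoking_cd_dose",
    "build_profile",
    "normalize_locality",
    "normalize_sex",
    "CD_PER_PACK",
    "DEFAULT_SMOKING_START_AGE",
]

#: Inhaled cadmium dose per pack of cigarettes (ug/pack).  The high-exposure
#: locality is assigned a higher effective dose, reflecting both tobacco
#: cadmium content and anemia-enhanced pulmonary uptake in that population.
CD_PER_PACK = {"bangkok": 5.5, "mae_sot": 6.5}

#: Default age (years) at which smokers start; adult initiation.
DEFAULT_SMOKING_START_AGE = 18.0

_LOCALITY_ALIASES = {
    "bangkok": "bangkok",
    "maesot": "mae_sot",
    "mae_sot": "mae_sot",
    "mae sot": "mae_sot",
}


def normalize_locality(locality: str) -> str:
    key = str(locality).strip().lower().replace("-", "_")
    if key not in _LOCALITY_ALIASES:
        raise ValueError(f"unknown locality {locality!r}; expected Bangkok or Mae Sot")
    return _LOCALITY_ALIASES[key]


def normalize_sex(sex: str) -> str:
    key = str(sex).strip().lower()
    if key in ("m", "male"):
        return "male"
    if key in ("f", "female"):
        return "female"
    raise ValueError(f"unknown sex {sex!r}")


@dataclass
class DietaryScenario:
    """Constant adult dietary cadmium intake for one population group."""

    adult_intake: float           # ug/day at adult ages
    locality: str
    sex: str
    evaluation_age: float         # years

    def __post_init__(self) -> None:
        self.locality = normalize_locality(self.locality)
        self.sex = normalize_sex(self.sex)
        if self.adult_intake < 0:
            raise ValueError("adult_intake must be non-negative")
        if self.evaluation_age <= 0:
            raise ValueError("evaluation_age must be positive")


@dataclass
class SmokingScenario:
    """Constant smoking habit from ``start_age`` onward."""

    packs_per_day: float
    cd_per_pack: float            # ug inhaled per pack
    start_age: float = DEFAULT_SMOKING_START_AGE
    locality: str = "bangkok"
    sex: str = "male"

    def __post_init__(self) -> None:
        self.locality = normalize_locality(self.locality)
        self.sex = normalize_sex(self.sex)
        if self.packs_per_day < 0:
            raise ValueError("packs_per_day must be non-negative")
        if self.cd_per_pack <= 0:
            raise ValueError("cd_per_pack must be positive")


def cd_per_pack(locality: str) -> float:
    """Inhaled cadmium per pack (ug) for a locality."""
    return CD_PER_PACK[normalize_locality(locality)]


def smoking_cd_dose(packs_per_day: float, cd_per_pack: float) -> float:
    """Daily inhaled cadmium dose (ug/day) from smoking: packs x ug/pack."""
    if packs_per_day < 0 or cd_per_pack < 0:
        raise ValueError("packs_per_day and cd_per_pack must be non-negative")
    return packs_per_day * cd_per_pack


def build_profile(
    diet: DietaryScenario,
    smoke: Optional[SmokingScenario],
    params: TKParameters,
) -> ExposureProfile:
    """Assemble the lifetime exposure profile for a scenario pair.

    Ingested series: adult intake times the age-scaling curve.  Inhaled
    series: the smoking dose for every day at or past the start age, zero
    before (and zero throughout for never smokers).
    """
    n = int(round(diet.evaluation_age * DAYS_PER_YEAR))
    ages_years = np.arange(n) / DAYS_PER_YEAR
    ingested = diet.adult_intake * params.diet_scaling_for_age(ages_years)
    inhaled = np.zeros(n)
    if smoke is not None and smoke.packs_per_day > 0:
        start = int(round(smoke.start_age * DAYS_PER_YEAR))
        if start >= n:
            warnings.warn(
                "smoking start age is past the evaluation age; inhalation series is empty",
                stacklevel=2,
            )
        else:
            inhaled[start:] = smoking_cd_dose(smoke.packs_per_day, smoke.cd_per_pack)
    return ExposureProfile(ingested, inhaled, diet.evaluation_age)
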