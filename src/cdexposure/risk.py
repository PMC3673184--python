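"""Comparison of estimated exposures against tolerable-intake references.

Two reference systems are carried: the WHO tolerable intake of
25 ug/kg body weight/month (62 ug/day for a 70-kg adult) with a urinary
threshold of 5.24 ug/g creatinine, and the EFSA tolerable intake of
2.5 ug/kg body weight/week (25 ug/day at 70 kg) with a urinary threshold of
1 ug/g creatinine.  The historic provisional tolerable weekly intake
(400-500 ug/week, later 7 ug/kg/week) is retained for documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ReferenceCatalogue",
    "REFERENCES",
    "intake_ratio",
    "kg_based_conversion",
    "exceedance_report",
]


@dataclass(frozen=True)
class ReferenceCatalogue:
    """Tolerable-intake and urinary-threshold reference values."""

    who_tolerable_intake: float = 62.0       # ug/day, 70-kg adult (25 ug/kg bw/month)
    efsa_tolerable_intake: float = 25.0      # ug/day, 70-kg adult (2.5 ug/kg bw/week)
    who_urinary_threshold: float = 5.24      # ug/g creatinine
    efsa_urinary_threshold: float = 1.0      # ug/g creatinine
    historic_ptwi_ug_week: tuple[float, float] = (400.0, 500.0)   # ug/person/week
    historic_ptwi_per_kg_week: float = 7.0   # ug/kg bw/week
    citations: dict = field(
        default_factory=lambda: {
            "who_tolerable_intake": "WHO/JECFA tolerable intake, 25 ug/kg bw/month",
            "efsa_tolerable_intake": "EFSA tolerable weekly intake, 2.5 ug/kg bw/week",
            "who_urinary_threshold": "WHO urinary cadmium threshold, kidney protection",
            "efsa_urinary_threshold": "EFSA urinary cadmium threshold, kidney protection",
            "historic_ptwi": "original and revised provisional tolerable weekly intakes",
        }
    )

    def __post_init__(self) -> None:
        for name in (
            "who_tolerable_intake",
            "efsa_tolerable_intake",
            "who_urinary_threshold",
            "efsa_urinary_threshold",
            "historic_ptwi_per_kg_week",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


REFERENCES = ReferenceCatalogue()


def intake_ratio(intake: float, reference: float, decimals: int = 1) -> float:
    """intake / reference, rounded to one decimal (ratio-to-guideline)."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return round(intake / reference, decimals)


def kg_based_conversion(
    per_kg_dose: float, period_days: float, body_weight_kg: float = 70.0
) -> float:
    """Convert a per-kg tolerable dose over a period to ug/day for an adult.

    A month is conventionally taken as 28 days here, which reproduces the
    stored WHO constant (25 x 70 / 28 = 62.5, printed as 62); a 30.44-day
    calendar month would give 57.5.
    """
    if per_kg_dose < 0:
        raise ValueError("per_kg_dose must be non-negative")
    if period_days <= 0 or body_weight_kg <= 0:
        raise ValueError("period and body weight must be positive")
    return per_kg_dose * body_weight_kg / period_days


def exceedance_report(
    summary: pd.DataFrame,
    catalogue: ReferenceCatalogue = REFERENCES,
    intake_col: str = "diet_cd_ug_day",
    ucd_col: str = "measured_gm",
) -> dict:
    """Flag each group against both tolerable intakes and urinary thresholds.

    ``summary`` carries one row per group with an intake estimate and a GM
    U-Cd.  Returns the flag table plus, per reference intake, the list of
    exceeding groups and the range of their U-Cd values — the quantity that
    shows what urinary levels accompany above-guideline intakes.
    """
    if summary.empty:
        return {"flags": summary.copy(), "exceedances": {}}
    flags = summary.copy()
    flags["exceeds_who_intake"] = flags[intake_col] >= catalogue.who_tolerable_intake
    flags["exceeds_efsa_intake"] = flags[intake_col] >= catalogue.efsa_tolerable_intake
    flags["who_intake_ratio"] = [
        intake_ratio(v, catalogue.who_tolerable_intake) for v in flags[intake_col]
    ]
    flags["exceeds_who_ucd"] = flags[ucd_col] >= catalogue.who_urinary_threshold
    flags["exceeds_efsa_ucd"] = flags[ucd_col] >= catalogue.efsa_urinary_threshold

    exceedances = {}
    for label, flag_col in (
        ("who_intake", "exceeds_who_intake"),
        ("efsa_intake", "exceeds_efsa_intake"),
    ):
        over = flags[flags[flag_col]]
        exceedances[label] = {
            "n_groups": int(len(over)),
            "ucd_range": (
                (float(over[ucd_col].min()), float(over[ucd_col].max()))
                if len(over)
                else None
            ),
        }
    return {"flags": flags, "exceedances": exceedances}
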