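"""Synthetic individual-level cohorts with the structure of the survey tables.

The raw survey records are not public, so downstream code is exercised on
synthetic cohorts: within every (locality x sex x age band x smoking
category) cell, U-Cd values are drawn from the lognormal whose geometric
mean and arithmetic SD match the published cell, ages are drawn uniformly
within the band, and cigarettes/day uniformly within the category's range
(light-to-moderate 10-25, heavy 26-80).  Generation is fully deterministic
given the spec's seed.

``survey_spec()`` transcribes the published tables into a complete cell
roster.  Where a category's per-band sizes are printed they are used
directly; remaining categories (former smokers, and current-smoker
categories without printed sizes) get their prevalence-implied totals
allocated across age bands proportionally to the never-smoker age
distribution, so each locality/sex cohort sums exactly to its published
size (Bangkok 199 + 200, Mae Sot 3,021 + 3,726).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import survey

__all__ = ["CellSpec", "CohortSpec", "generate", "survey_spec", "CIGARETTE_RANGE"]

#: cigarettes/day range (inclusive) per current-smoker category; a pack is 20.
CIGARETTE_RANGE = {"light_moderate": (10, 25), "heavy": (26, 80)}

CIGARETTES_PER_PACK = 20


@dataclass
class CellSpec:
    locality: str
    sex: str
    age_band: str
    smoking_category: str
    n: int
    gm: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cell n must be non-negative")
        if self.n > 0 and self.gm <= 0:
            raise ValueError("cell gm must be positive")
        if self.sd < 0:
            raise ValueError("cell sd must be non-negative")
        if self.age_band not in survey.BAND_RANGE:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.smoking_category not in survey.SMOKING_CATEGORIES:
            raise ValueError(f"unknown smoking category {self.smoking_category!r}")


@dataclass
class CohortSpec:
    cells: list[CellSpec]
    seed: int = 0
    age_range: tuple[float, float] = survey.AGE_RANGE

    def total(self, locality: str | None = None) -> int:
        return sum(
            c.n for c in self.cells if locality is None or c.locality == locality
        )

    def cell_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.cells])


def generate(spec: CohortSpec) -> pd.DataFrame:
    """Draw one synthetic cohort from a :class:`CohortSpec`.

    Returns a DataFrame with columns id, locality, sex, age, smoking_category,
    cigarettes_per_day, packs_per_day, ucd_ug_per_g.  Deterministic given
    ``spec.seed``; cells are generated in roster order from independent
    substreams of one seeded generator.
    """
    from .biostats import lognormal_from_gm_sd

    rng = np.random.default_rng(spec.seed)
    frames = []
    next_id = 0
    for cell in spec.cells:
        if cell.n == 0:
            continue
        pars = lognormal_from_gm_sd(cell.gm, cell.sd)
        ucd = rng.lognormal(pars["mu"], pars["sigma"], size=cell.n)
        lo, hi = survey.BAND_RANGE[cell.age_band]
        hi = min(hi, spec.age_range[1] + 1)
        ages = rng.uniform(max(lo, spec.age_range[0]), hi, size=cell.n)
        if cell.smoking_category in CIGARETTE_RANGE:
            c_lo, c_hi = CIGARETTE_RANGE[cell.smoking_category]
            cigarettes = rng.integers(c_lo, c_hi + 1, size=cell.n)
        else:
            cigarettes = np.zeros(cell.n, dtype=int)
        frames.append(
            pd.DataFrame(
                {
                    "id": np.arange(next_id, next_id + cell.n),
                    "locality": cell.locality,
                    "sex": cell.sex,
                    "age_band": cell.age_band,
                    "age": np.round(ages, 2),
                    "smoking_category": cell.smoking_category,
                    "cigarettes_per_day": cigarettes,
                    "packs_per_day": cigarettes / CIGARETTES_PER_PACK,
                    "ucd_ug_per_g": ucd,
                }
            )
        )
        next_id += cell.n
    if not frames:
        return pd.DataFrame(
            columns=[
                "id", "locality", "sex", "age_band", "age", "smoking_category",
                "cigarettes_per_day", "packs_per_day", "ucd_ug_per_g",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    if total == 0 or weights.sum() == 0:
        return np.zeros(len(weights), dtype=int)
    raw = total * weights / weights.sum()
    alloc = np.floor(raw).astype(int)
    remainder = total - alloc.sum()
    order = np.argsort(-(raw - alloc))
    alloc[order[:remainder]] += 1
    return alloc


def survey_spec(seed: int = 0) -> CohortSpec:
    """The published survey structure as a complete generation spec.

    Every reported (GM, SD) cell appears with a size: printed sizes where
    the tables give them, prevalence-derived band allocations elsewhere.
    Cells the tables suppressed (<= 5 subjects, e.g. Bangkok female smokers)
    are absent.
    """
    cells: list[CellSpec] = []
    for (loc, sex), total in survey.GROUP_SIZES.items():
        prev = survey.PREVALENCE_PCT[(loc, sex)]
        never_n = {
            band: survey.NEVER_SMOKER_N.get((loc, sex, band), 0)
            for band in survey.AGE_BANDS
        }
        never_weights = np.array(
            [max(never_n[b], 1) if (loc, sex, b, "never") in survey.UCD_BY_CELL else 0
             for b in survey.AGE_BANDS],
            dtype=float,
        )

        def category_total(cat: str, band_sizes: dict[str, int]) -> int:
            # printed band sizes win when they cover every reported GM cell;
            # otherwise the prevalence-implied total fills the unprinted bands
            gm_bands = [
                b for b in survey.AGE_BANDS if (loc, sex, b, cat) in survey.UCD_BY_CELL
            ]
            printed_sum = sum(band_sizes.values())
            if printed_sum > 0 and all(band_sizes.get(b, 0) > 0 for b in gm_bands):
                return printed_sum
            return max(printed_sum, round(prev[cat] * total / 100))

        category_totals: dict[str, int] = {}
        printed: dict[str, dict[str, int]] = {"never": never_n}
        category_totals["never"] = category_total("never", never_n)

        cal_cat = survey.CALIBRATED_SMOKER_CATEGORY[loc]
        cal_n = {
            band: survey.CURRENT_SMOKER_CALIBRATED.get((loc, sex, band), (0,))[0]
            for band in survey.AGE_BANDS
        }
        printed[cal_cat] = cal_n
        category_totals[cal_cat] = category_total(cal_cat, cal_n)
        other_current = [
            c for c in ("light_moderate", "heavy") if c != cal_cat and prev[c] > 0
        ]
        for cat in other_current:
            category_totals[cat] = round(prev[cat] * total / 100)
        if prev["former"] > 0:
            category_totals["former"] = total - sum(category_totals.values())
        else:
            # absorb rounding slack into the largest category
            slack = total - sum(category_totals.values())
            largest = max(category_totals, key=category_totals.get)
            category_totals[largest] += slack

        for cat, cat_total in category_totals.items():
            if cat_total <= 0:
                continue
            has_gm = np.array(
                [(loc, sex, b, cat) in survey.UCD_BY_CELL for b in survey.AGE_BANDS]
            )
            band_n = np.array(
                [printed.get(cat, {}).get(b, 0) for b in survey.AGE_BANDS], dtype=int
            )
            leftover = cat_total - band_n.sum()
            if leftover > 0:
                weights = never_weights * has_gm * (band_n == 0)
                if weights.sum() == 0:
                    weights = never_weights * has_gm
                band_n = band_n + _largest_remainder(leftover, weights)
            for band, n in zip(survey.AGE_BANDS, band_n):
                if n <= 0 or (loc, sex, band, cat) not in survey.UCD_BY_CELL:
                    continue
                gm, sd = survey.UCD_BY_CELL[(loc, sex, band, cat)]
                cells.append(CellSpec(loc, sex, band, cat, int(n), gm, sd))

    return CohortSpec(cells=cells, seed=seed)
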