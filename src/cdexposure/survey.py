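"""Published group-level summaries of the two Thai study populations.

The underlying individual records are not public; what is available are
group summary tables for a low-exposure urban population (Bangkok, n = 399)
and a high-exposure rice-farming population (Mae Sot district, n = 6,747):
group sizes, smoking-category prevalences, and geometric mean (GM) with
arithmetic SD of creatinine-adjusted urinary cadmium (U-Cd, ug/g creatinine)
within locality x sex x age-band x smoking-category cells, plus the
model-calibrated dietary intakes and smoking rates reported for those cells.

This module transcribes those summaries as plain data and serves them as
DataFrames; the synthetic-cohort generator and the reverse-dosimetry layer
both draw on it.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "AGE_BANDS",
    "BAND_MIDPOINT",
    "BAND_RANGE",
    "SMOKING_CATEGORIES",
    "GROUP_SIZES",
    "OVERALL_UCD",
    "PREVALENCE_PCT",
    "UCD_BY_CELL",
    "NEVER_SMOKER_N",
    "DIET_INTAKE",
    "CURRENT_SMOKER_CALIBRATED",
    "CALIBRATED_SMOKER_CATEGORY",
    "AGE_SUMMARY",
    "AGE_RANGE",
    "anchor_pair",
    "measured_ucd_table",
    "never_smoker_table",
]

AGE_BANDS = ("13-19", "20-39", "40-59", "60+")

#: Evaluation age used for a band: the band midpoint (60+ uses 70, roughly
#: central in the observed 60-92 range).
BAND_MIDPOINT = {"13-19": 16.0, "20-39": 30.0, "40-59": 50.0, "60+": 70.0}

#: Age interval [lo, hi) for sampling; the oldest participants were 92.
BAND_RANGE = {"13-19": (13.0, 20.0), "20-39": (20.0, 40.0), "40-59": (40.0, 60.0), "60+": (60.0, 93.0)}

SMOKING_CATEGORIES = ("never", "former", "light_moderate", "heavy")

GROUP_SIZES = {
    ("bangkok", "male"): 199,
    ("bangkok", "female"): 200,
    ("mae_sot", "male"): 3021,
    ("mae_sot", "female"): 3726,
}

#: Whole-group U-Cd, GM (arithmetic SD), ug/g creatinine.
OVERALL_UCD = {
    ("bangkok", "male"): (0.40, 0.46),
    ("bangkok", "female"): (0.50, 0.46),
    ("mae_sot", "male"): (1.65, 2.40),
    ("mae_sot", "female"): (2.10, 2.91),
}

#: Smoking-status prevalence (%) per locality and sex.
PREVALENCE_PCT = {
    ("bangkok", "male"): {"never": 59.3, "former": 0.0, "light_moderate": 40.7, "heavy": 0.0},
    ("bangkok", "female"): {"never": 100.0, "former": 0.0, "light_moderate": 0.0, "heavy": 0.0},
    ("mae_sot", "male"): {"never": 27.2, "former": 20.9, "light_moderate": 9.2, "heavy": 42.7},
    ("mae_sot", "female"): {"never": 77.2, "former": 7.4, "light_moderate": 4.4, "heavy": 11.0},
}

#: Group age (years), mean and SD, per locality and sex.
AGE_SUMMARY = {
    ("bangkok", "male"): (32.9, 8.8),
    ("bangkok", "female"): (36.9, 10.0),
    ("mae_sot", "male"): (47.7, 16.6),
    ("mae_sot", "female"): (46.4, 15.2),
}

AGE_RANGE = (13, 92)

#: Measured U-Cd GM (arithmetic SD) per cell; cells with <= 5 subjects were
#: not reported and are absent here.
UCD_BY_CELL = {
    # Bangkok males
    ("bangkok", "male", "13-19", "never"): (0.30, 0.10),
    ("bangkok", "male", "20-39", "never"): (0.33, 0.36),
    ("bangkok", "male", "40-59", "never"): (0.49, 0.38),
    ("bangkok", "male", "13-19", "light_moderate"): (0.28, 0.32),
    ("bangkok", "male", "20-39", "light_moderate"): (0.41, 0.41),
    ("bangkok", "male", "40-59", "light_moderate"): (0.92, 0.93),
    # Bangkok females (never smokers only)
    ("bangkok", "female", "13-19", "never"): (0.35, 0.22),
    ("bangkok", "female", "20-39", "never"): (0.48, 0.43),
    ("bangkok", "female", "40-59", "never"): (0.54, 0.51),
    # Mae Sot males
    ("mae_sot", "male", "13-19", "never"): (0.70, 0.84),
    ("mae_sot", "male", "20-39", "never"): (1.04, 1.61),
    ("mae_sot", "male", "40-59", "never"): (1.50, 1.98),
    ("mae_sot", "male", "60+", "never"): (1.85, 2.47),
    ("mae_sot", "male", "13-19", "former"): (0.45, 0.46),
    ("mae_sot", "male", "20-39", "former"): (0.99, 1.54),
    ("mae_sot", "male", "40-59", "former"): (1.78, 3.11),
    ("mae_sot", "male", "60+", "former"): (2.45, 3.04),
    ("mae_sot", "male", "13-19", "light_moderate"): (0.72, 0.54),
    ("mae_sot", "male", "20-39", "light_moderate"): (1.00, 1.15),
    ("mae_sot", "male", "40-59", "light_moderate"): (2.07, 1.78),
    ("mae_sot", "male", "60+", "light_moderate"): (2.55, 2.53),
    ("mae_sot", "male", "13-19", "heavy"): (0.79, 0.61),
    ("mae_sot", "male", "20-39", "heavy"): (1.17, 1.51),
    ("mae_sot", "male", "40-59", "heavy"): (2.12, 2.54),
    ("mae_sot", "male", "60+", "heavy"): (2.84, 4.46),
    # Mae Sot females
    ("mae_sot", "female", "13-19", "never"): (0.95, 1.36),
    ("mae_sot", "female", "20-39", "never"): (1.49, 2.26),
    ("mae_sot", "female", "40-59", "never"): (2.08, 2.82),
    ("mae_sot", "female", "60+", "never"): (3.07, 3.79),
    ("mae_sot", "female", "13-19", "former"): (1.93, 0.36),
    ("mae_sot", "female", "20-39", "former"): (1.74, 1.24),
    ("mae_sot", "female", "40-59", "former"): (2.89, 2.78),
    ("mae_sot", "female", "60+", "former"): (3.70, 3.09),
    ("mae_sot", "female", "20-39", "light_moderate"): (2.10, 1.48),
    ("mae_sot", "female", "40-59", "light_moderate"): (2.75, 2.26),
    ("mae_sot", "female", "60+", "light_moderate"): (3.13, 3.73),
    ("mae_sot", "female", "13-19", "heavy"): (0.73, 0.08),
    ("mae_sot", "female", "20-39", "heavy"): (1.91, 1.59),
    ("mae_sot", "female", "40-59", "heavy"): (3.41, 2.66),
    ("mae_sot", "female", "60+", "heavy"): (3.92, 3.46),
}

#: Never-smoker group sizes per cell (cells with n < 5 were not analysed).
NEVER_SMOKER_N = {
    ("bangkok", "male", "20-39"): 85,
    ("bangkok", "male", "40-59"): 31,
    ("bangkok", "female", "20-39"): 117,
    ("bangkok", "female", "40-59"): 81,
    ("mae_sot", "male", "13-19"): 152,
    ("mae_sot", "male", "20-39"): 191,
    ("mae_sot", "male", "40-59"): 327,
    ("mae_sot", "male", "60+"): 151,
    ("mae_sot", "female", "13-19"): 221,
    ("mae_sot", "female", "20-39"): 903,
    ("mae_sot", "female", "40-59"): 1394,
    ("mae_sot", "female", "60+"): 358,
}

#: Model-calibrated dietary cadmium intakes (ug/day) reported for never
#: smokers; the 20-39 entries double as the anchoring pairs.
DIET_INTAKE = {
    ("bangkok", "male", "20-39"): 56.0,
    ("bangkok", "male", "40-59"): 50.0,
    ("bangkok", "female", "20-39"): 27.0,
    ("bangkok", "female", "40-59"): 21.0,
    ("mae_sot", "male", "13-19"): 234.0,
    ("mae_sot", "male", "20-39"): 224.0,
    ("mae_sot", "male", "40-59"): 188.0,
    ("mae_sot", "male", "60+"): 167.0,
    ("mae_sot", "female", "13-19"): 132.0,
    ("mae_sot", "female", "20-39"): 113.0,
    ("mae_sot", "female", "40-59"): 99.0,
    ("mae_sot", "female", "60+"): 118.0,
}

#: Which current-smoker category was calibrated in each locality: Bangkok had
#: only light-to-moderate smokers; Mae Sot calibration covered heavy smokers.
CALIBRATED_SMOKER_CATEGORY = {"bangkok": "light_moderate", "mae_sot": "heavy"}

#: (n, packs/day) reported for the calibrated current-smoker cells.
CURRENT_SMOKER_CALIBRATED = {
    ("bangkok", "male", "20-39"): (65, 1.0),
    ("bangkok", "male", "40-59"): (12, 3.7),
    ("mae_sot", "male", "13-19"): (55, 1.5),
    ("mae_sot", "male", "20-39"): (296, 1.5),
    ("mae_sot", "male", "40-59"): (663, 3.0),
    ("mae_sot", "male", "60+"): (277, 4.0),
    ("mae_sot", "female", "20-39"): (38, 4.0),
    ("mae_sot", "female", "40-59"): (207, 4.0),
    ("mae_sot", "female", "60+"): (162, 4.0),
}


def anchor_pair(locality: str, sex: str) -> tuple[float, float]:
    """(dietary intake ug/day, measured GM U-Cd) for the 20-39 never-smoker cell."""
    intake = DIET_INTAKE[(locality, sex, "20-39")]
    gm, _ = UCD_BY_CELL[(locality, sex, "20-39", "never")]
    return intake, gm


def measured_ucd_table() -> pd.DataFrame:
    """All reported U-Cd cells as a tidy DataFrame.

    Columns: locality, sex, age_band, smoking_category, n (where known,
    else <NA>), gm, sd.
    """
    rows = []
    for (loc, sex, band, cat), (gm, sd) in UCD_BY_CELL.items():
        if cat == "never":
            n = NEVER_SMOKER_N.get((loc, sex, band))
        elif cat == CALIBRATED_SMOKER_CATEGORY[loc]:
            n = CURRENT_SMOKER_CALIBRATED.get((loc, sex, band), (None,))[0]
        else:
            n = None
        rows.append(
            {
                "locality": loc,
                "sex": sex,
                "age_band": band,
                "smoking_category": cat,
                "n": n,
                "gm": gm,
                "sd": sd,
            }
        )
    frame = pd.DataFrame(rows)
    frame["n"] = frame["n"].astype("Int64")
    return frame


def never_smoker_table() -> pd.DataFrame:
    """Never-smoker cells with reported n, GM, SD and calibrated intake."""
    frame = measured_ucd_table()
    frame = frame[frame["smoking_category"] == "never"].copy()
    frame["reported_intake"] = [
        DIET_INTAKE.get((r.locality, r.sex, r.age_band)) for r in frame.itertuples()
    ]
    return frame.reset_index(drop=True)
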