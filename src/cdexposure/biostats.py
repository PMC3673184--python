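"""Descriptive and inferential statistics for urinary-cadmium biomonitoring.

U-Cd in population samples is right-skewed and conventionally summarised as
a geometric mean (GM) with the arithmetic SD of the untransformed values.
This module provides that summary layer, the LOD substitution rule
(values below the detection limit are replaced by LOD/sqrt(2)), the exact
inversion of a (GM, SD) pair into lognormal parameters, threshold
exceedance fractions, ratio tables, and the group-comparison battery
(Kolmogorov-Smirnov normality screen, t-test / Mann-Whitney for two groups,
one-way ANOVA with Dunnett contrasts against the never-smoker reference for
three or more).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "DEFAULT_LOD",
    "SIGNIFICANCE_LEVEL",
    "lod_substitute",
    "geometric_mean",
    "lognormal_from_gm_sd",
    "pct_over_threshold",
    "summarize_cohort",
    "compare_groups",
    "ratio_report",
]

#: Detection limit of the urinary cadmium assay, ug/L.
DEFAULT_LOD = 0.05

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class GroupSummary:
    """One (locality, sex, age band, smoking category) summary cell."""

    locality: str
    sex: str
    age_band: str
    smoking_category: str
    n: int
    gm: float
    sd: float
    pct_ge_1: float
    pct_ge_5: float


def lod_substitute(ucd_ug_per_l, lod: float = DEFAULT_LOD):
    """Replace concentrations strictly below the LOD by LOD/sqrt(2).

    Standard imputation for left-censored biomonitoring values; a value
    exactly at the LOD is considered detected and kept.
    """
    values = np.asarray(ucd_ug_per_l, dtype=float)
    if np.any(values < 0):
        raise ValueError("concentrations must be non-negative")
    out = np.where(values < lod, lod / np.sqrt(2.0), values)
    return float(out) if np.isscalar(ucd_ug_per_l) else out


def geometric_mean(values) -> float:
    """exp(mean(log x)); requires strictly positive values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("geometric mean of an empty sample")
    if np.any(values <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(values))))


def lognormal_from_gm_sd(gm: float, sd: float) -> dict[str, float]:
    """Log-scale (mu, sigma) of the lognormal with geometric mean ``gm`` and
    arithmetic SD ``sd``.

    For X ~ Lognormal(mu, sigma): GM = e^mu and
    Var = e^(2 mu + sigma^2) (e^(sigma^2) - 1) = gm^2 * w (w - 1) with
    w = e^(sigma^2).  Solving w^2 - w - (sd/gm)^2 = 0 gives
    w = (1 + sqrt(1 + 4 (sd/gm)^2)) / 2, hence sigma^2 = ln w.
    """
    if gm <= 0:
        raise ValueError("gm must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    cv2 = (sd / gm) ** 2
    w = (1.0 + np.sqrt(1.0 + 4.0 * cv2)) / 2.0
    return {"mu": float(np.log(gm)), "sigma": float(np.sqrt(np.log(w)))}


def pct_over_threshold(values, tau: float) -> float:
    """Percentage of values >= tau (inclusive)."""
    if tau <= 0:
        raise ValueError("threshold must be positive")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return 0.0
    return float(100.0 * np.mean(values >= tau))


def summarize_cohort(
    records: pd.DataFrame,
    value_col: str = "ucd_ug_per_g",
    group_cols: tuple[str, ...] = ("locality", "sex", "age_band", "smoking_category"),
) -> pd.DataFrame:
    """Per-cell n, GM, arithmetic SD and threshold exceedance percentages."""
    rows = []
    for key, cell in records.groupby(list(group_cols), sort=True):
        values = cell[value_col].to_numpy(dtype=float)
        rows.append(
            dict(
                zip(group_cols, key),
                n=len(values),
                gm=geometric_mean(values),
                sd=float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
                pct_ge_1=pct_over_threshold(values, 1.0),
                pct_ge_5=pct_over_threshold(values, 5.0),
            )
        )
    return pd.DataFrame(rows)


def _ks_normality(values: np.ndarray) -> tuple[float, float]:
    """KS goodness-of-fit statistic and p against a fitted normal."""
    mean, sd = np.mean(values), np.std(values, ddof=1)
    if sd == 0:
        return np.inf, 0.0
    stat, p = stats.kstest(values, "norm", args=(mean, sd))
    return float(stat), float(p)


def compare_groups(
    records: pd.DataFrame,
    grouping: str,
    value_col: str = "ucd_ug_per_g",
    reference: str | None = None,
    alpha: float = SIGNIFICANCE_LEVEL,
) -> dict:
    """Group-difference testing battery.

    Normality of raw and log10-transformed values is screened per group with
    the Kolmogorov-Smirnov goodness-of-fit test.  Two groups: Student's
    t-test when both pass the raw-scale normality screen, otherwise the
    Mann-Whitney U test.  Three or more groups: one-way ANOVA on log10
    values followed by Dunnett contrasts against ``reference`` (default:
    ``"never"`` if present, else the first group).  Degenerate
    (zero-variance) groups are reported rather than raised.
    """
    groups = {
        name: cell[value_col].to_numpy(dtype=float)
        for name, cell in records.groupby(grouping, sort=True)
    }
    if len(groups) < 2:
        raise ValueError("compare_groups needs at least two groups")
    for name, values in groups.items():
        if len(values) < 2:
            raise ValueError(f"group {name!r} has fewer than two observations")

    report: dict = {"grouping": grouping, "alpha": alpha, "normality": {}, "degenerate": []}
    for name, values in groups.items():
        if np.std(values, ddof=1) == 0:
            report["degenerate"].append(name)
            report["normality"][name] = {"raw_p": np.nan, "log10_p": np.nan}
            continue
        _, p_raw = _ks_normality(values)
        _, p_log = _ks_normality(np.log10(values))
        report["normality"][name] = {"raw_p": p_raw, "log10_p": p_log}

    names = sorted(groups)
    if len(groups) == 2:
        a, b = (groups[n] for n in names)
        both_normal = all(
            not np.isnan(report["normality"][n]["raw_p"])
            and report["normality"][n]["raw_p"] > alpha
            for n in names
        )
        if both_normal:
            stat, p = stats.ttest_ind(a, b, equal_var=True)
            test = "t-test"
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann-whitney"
        report["test"] = test
        report["statistic"] = float(stat)
        report["p_value"] = float(p)
        report["significant"] = bool(p <= alpha)
        return report

    if reference is None:
        reference = "never" if "never" in groups else names[0]
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    log_groups = {n: np.log10(v) for n, v in groups.items()}
    f_stat, f_p = stats.f_oneway(*log_groups.values())
    others = [n for n in names if n != reference]
    dunnett = stats.dunnett(
        *(log_groups[n] for n in others), control=log_groups[reference]
    )
    report["test"] = "anova+dunnett(log10)"
    report["reference"] = reference
    report["anova_F"] = float(f_stat)
    report["anova_p"] = float(f_p)
    report["comparisons"] = {
        name: {"p_value": float(p), "significant": bool(p <= alpha)}
        for name, p in zip(others, np.atleast_1d(dunnett.pvalue))
    }
    report["significant"] = bool(f_p <= alpha) or any(
        c["significant"] for c in report["comparisons"].values()
    )
    return report


def ratio_report(
    summary: pd.DataFrame,
    reference_category: str = "never",
    group_cols: tuple[str, ...] = ("locality", "sex", "age_band"),
    decimals: int = 1,
) -> pd.DataFrame:
    """GM ratios of each smoking category to the never-smoker reference.

    One row per (locality, sex, age band, category); missing references
    raise.  Ratios are computed from the table's GM cells as given and
    rounded to one decimal.
    """
    rows = []
    for key, cell in summary.groupby(list(group_cols), sort=True):
        cats = cell.set_index("smoking_category")["gm"]
        if reference_category not in cats.index:
            raise ValueError(f"missing {reference_category!r} reference for {key}")
        ref = cats[reference_category]
        for cat, gm in cats.items():
            if cat == reference_category:
                continue
            rows.append(
                dict(
                    zip(group_cols, key),
                    smoking_category=cat,
                    gm=gm,
                    reference_gm=ref,
                    ratio=round(gm / ref, decimals),
                )
            )
    return pd.DataFrame(rows)
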