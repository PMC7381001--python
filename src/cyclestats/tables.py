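"""Cohort-level stratified tables and distributions.

All operations consume a tidy per-woman *cohort frame* (one row per
included woman: age group, BMI category, per-woman flow category, survey
answers, length category, rounded median, variation bin) or per-cycle
phase estimates, and emit tidy DataFrames with explicit counts,
denominators and percentages.

Missing data are never imputed: every variable's percentages are taken
over the women reporting that variable (the "n = ..." convention), so
each table row carries its own denominator.  Percentages are printed to
two decimals, rounded half up.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigError
from .events import SURVEY_FIELDS, SURVEY_VOCABULARY, EventLog, UserProfile
from .flow import FLOW_CATEGORIES
from .phases import PhaseEstimate
from .stats import (
    AGE_GROUPS,
    BMI_CATEGORIES,
    LENGTH_CATEGORIES,
    NORMAL_MAX_DAYS,
    SHORT_MAX_DAYS,
    VARIATION_BINS,
    Anthropometrics,
    CycleSummary,
    round_half_up,
)

#: printed spans of the per-cycle distributions; anything outside lands
#: in an explicit "other" bucket rather than being dropped
OVULATION_DAY_SPAN = range(11, 30)
LUTEAL_LENGTH_SPAN = range(5, 21)
OTHER = "other"

#: demographic variables tabulated per woman, with their category order
DEMOGRAPHIC_VARIABLES: dict[str, tuple[str, ...]] = {
    "age_group": AGE_GROUPS,
    "bmi_category": BMI_CATEGORIES,
    "flow_category": FLOW_CATEGORIES,
    **{field: SURVEY_VOCABULARY[field] for field in SURVEY_FIELDS},
}


def pct(numerator: int, denominator: int, decimals: int = 2) -> float | None:
    """Percentage rounded half up; ``None`` (blank) when the denominator
    is zero."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, decimals)


def build_cohort_frame(
    profiles: Mapping[str, UserProfile],
    summaries: Mapping[str, CycleSummary],
    anthro: Mapping[str, Anthropometrics],
    flow_by_user: Mapping[str, str | None],
) -> pd.DataFrame:
    """Assemble the per-woman frame all table operations consume.

    One row per summarized woman; BMI, flow and survey columns hold
    ``None`` where the woman did not report the variable.
    """
    rows = []
    for uid, summary in summaries.items():
        profile = profiles[uid]
        a = anthro.get(uid)
        row: dict[str, object] = {
            "user_id": uid,
            "age_group": a.age_group if a is not None else None,
            "bmi": a.bmi if a is not None else None,
            "bmi_category": a.bmi_category if a is not None else None,
            "flow_category": flow_by_user.get(uid),
            "n_completed": summary.n_completed,
            "mean_length": summary.mean,
            "median_length": summary.median_length,
            "median_rounded": int(round_half_up(summary.median_length)),
            "variance": summary.variance,
            "variation_days": summary.variation_days,
            "length_category": summary.length_category,
            "variation_bin": summary.variation_bin,
        }
        for field in SURVEY_FIELDS:
            row[field] = profile.survey.get(field)
        rows.append(row)
    columns = [
        "user_id", "age_group", "bmi", "bmi_category", "flow_category",
        "n_completed", "mean_length", "median_length", "median_rounded",
        "variance", "variation_days", "length_category", "variation_bin",
        *SURVEY_FIELDS,
    ]
    return pd.DataFrame(rows, columns=columns)


def demographics_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-variable category counts and percentages (cohort description).

    Denominators are per variable: the number of women with that variable
    present.  Percentage cells are blank when a variable has no
    reporters.
    """
    rows = []
    for variable, categories in DEMOGRAPHIC_VARIABLES.items():
        reported = cohort[variable].dropna() if variable in cohort else pd.Series(dtype=object)
        denominator = int(len(reported))
        counts = reported.value_counts()
        for category in categories:
            n = int(counts.get(category, 0))
            rows.append({
                "variable": variable,
                "category": category,
                "count": n,
                "denominator": denominator,
                "percent": pct(n, denominator),
            })
    return pd.DataFrame(rows, columns=["variable", "category", "count",
                                       "denominator", "percent"])


def crosstab_by_length_category(cohort: pd.DataFrame) -> pd.DataFrame:
    """Demographic variables cross-tabulated by length category.

    Within each (variable, length-category) column the denominator is the
    number of women in that column reporting the variable, so column
    percentages for one variable sum to 100.
    """
    rows = []
    for variable, categories in DEMOGRAPHIC_VARIABLES.items():
        per_column: dict[str, pd.Series] = {}
        denominators: dict[str, int] = {}
        for length_cat in LENGTH_CATEGORIES:
            if variable in cohort:
                column = cohort.loc[cohort["length_category"] == length_cat, variable]
                column = column.dropna()
            else:
                column = pd.Series(dtype=object)
            per_column[length_cat] = column.value_counts()
            denominators[length_cat] = int(len(column))
        for category in categories:
            row: dict[str, object] = {"variable": variable, "category": category}
            for length_cat in LENGTH_CATEGORIES:
                n = int(per_column[length_cat].get(category, 0))
                row[f"{length_cat}_count"] = n
                row[f"{length_cat}_denominator"] = denominators[length_cat]
                row[f"{length_cat}_percent"] = pct(n, denominators[length_cat])
            rows.append(row)
    columns = ["variable", "category"]
    for length_cat in LENGTH_CATEGORIES:
        columns += [f"{length_cat}_count", f"{length_cat}_denominator",
                    f"{length_cat}_percent"]
    return pd.DataFrame(rows, columns=columns)


def _per_cycle_distribution(
    values: list[int], span: range, label: str
) -> pd.DataFrame:
    """Count/percent table over a fixed integer span plus an ``other``
    bucket for values outside it; empty input yields an empty table."""
    if not values:
        return pd.DataFrame(columns=[label, "count", "denominator", "percent"])
    denominator = len(values)
    counts: dict[object, int] = {day: 0 for day in span}
    other = 0
    for v in values:
        if v in counts:
            counts[v] += 1
        else:
            other += 1
    rows = [
        {label: day, "count": n, "denominator": denominator,
         "percent": pct(n, denominator)}
        for day, n in counts.items()
    ]
    if other:
        rows.append({label: OTHER, "count": other, "denominator": denominator,
                     "percent": pct(other, denominator)})
    return pd.DataFrame(rows, columns=[label, "count", "denominator", "percent"])


def ovulation_day_distribution(estimates: Iterable[PhaseEstimate]) -> pd.DataFrame:
    """Distribution of estimated ovulation day over all estimated cycles
    (per cycle, not per woman)."""
    days = [e.ovulation_day for e in estimates]
    return _per_cycle_distribution(days, OVULATION_DAY_SPAN, "ovulation_day")


def luteal_length_distribution(estimates: Iterable[PhaseEstimate]) -> pd.DataFrame:
    """Distribution of luteal phase length over estimated *completed*
    cycles (the current cycle has no luteal length)."""
    lengths = [e.luteal_days for e in estimates if e.luteal_days is not None]
    return _per_cycle_distribution(lengths, LUTEAL_LENGTH_SPAN, "luteal_days")


_GROUPINGS = {"age_group": AGE_GROUPS, "bmi_category": BMI_CATEGORIES}

#: integer median-day bins with collapsed edges
MEDIAN_EDGE_LOW = f"<={SHORT_MAX_DAYS}"
MEDIAN_EDGE_HIGH = f">={NORMAL_MAX_DAYS + 1}"
MEDIAN_BINS = (MEDIAN_EDGE_LOW,
               *[str(d) for d in range(SHORT_MAX_DAYS + 1, NORMAL_MAX_DAYS + 1)],
               MEDIAN_EDGE_HIGH)


def _median_bin(median_rounded: int) -> str:
    if median_rounded <= SHORT_MAX_DAYS:
        return MEDIAN_EDGE_LOW
    if median_rounded > NORMAL_MAX_DAYS:
        return MEDIAN_EDGE_HIGH
    return str(median_rounded)


def median_hist_by_group(cohort: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Per group, the share of women at each integer median cycle length
    (medians at or below 20 and at or above 36 collapsed into edge bins).
    Percentages use one decimal, figure style."""
    if grouping not in _GROUPINGS:
        raise ConfigError(f"unknown grouping {grouping!r}; "
                          f"expected one of {sorted(_GROUPINGS)}")
    rows = []
    for group in _GROUPINGS[grouping]:
        members = cohort[cohort[grouping] == group]
        denominator = int(len(members))
        binned = members["median_rounded"].map(_median_bin).value_counts()
        for b in MEDIAN_BINS:
            n = int(binned.get(b, 0))
            rows.append({grouping: group, "median_length": b, "count": n,
                         "denominator": denominator,
                         "percent": pct(n, denominator, decimals=1)})
    return pd.DataFrame(rows, columns=[grouping, "median_length", "count",
                                       "denominator", "percent"])


def variation_hist_by_group(cohort: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Per group, the share of women in each cycle-length variation bin."""
    if grouping not in _GROUPINGS:
        raise ConfigError(f"unknown grouping {grouping!r}; "
                          f"expected one of {sorted(_GROUPINGS)}")
    rows = []
    for group in _GROUPINGS[grouping]:
        members = cohort[cohort[grouping] == group]
        denominator = int(len(members))
        counts = members["variation_bin"].value_counts()
        for b in VARIATION_BINS:
            n = int(counts.get(b, 0))
            rows.append({grouping: group, "variation_bin": b, "count": n,
                         "denominator": denominator,
                         "percent": pct(n, denominator, decimals=1)})
    return pd.DataFrame(rows, columns=[grouping, "variation_bin", "count",
                                       "denominator", "percent"])


@dataclass
class CohortTables:
    """Bundle of every stratified output for one analyzed cohort."""

    demographics: pd.DataFrame
    by_length_category: pd.DataFrame
    ovulation_day_dist: pd.DataFrame
    luteal_dist: pd.DataFrame
    median_hist_age: pd.DataFrame
    median_hist_bmi: pd.DataFrame
    variation_hist_age: pd.DataFrame
    variation_hist_bmi: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mapping = {
            "table1_demographics.csv": self.demographics,
            "table2_by_length.csv": self.by_length_category,
            "table3_ovulation.csv": self.ovulation_day_dist,
            "table4_luteal.csv": self.luteal_dist,
            "fig_median_by_age_group.csv": self.median_hist_age,
            "fig_median_by_bmi_category.csv": self.median_hist_bmi,
            "fig_variation_by_age_group.csv": self.variation_hist_age,
            "fig_variation_by_bmi_category.csv": self.variation_hist_bmi,
        }
        paths = {}
        for name, frame in mapping.items():
            path = out / name
            frame.to_csv(path, index=False, encoding="utf-8")
            paths[name] = path
        return paths


def build_tables(
    cohort: pd.DataFrame, estimates: Iterable[PhaseEstimate]
) -> CohortTables:
    estimates = list(estimates)
    return CohortTables(
        demographics=demographics_table(cohort),
        by_length_category=crosstab_by_length_category(cohort),
        ovulation_day_dist=ovulation_day_distribution(estimates),
        luteal_dist=luteal_length_distribution(estimates),
        median_hist_age=median_hist_by_group(cohort, "age_group"),
        median_hist_bmi=median_hist_by_group(cohort, "bmi_category"),
        variation_hist_age=variation_hist_by_group(cohort, "age_group"),
        variation_hist_bmi=variation_hist_by_group(cohort, "bmi_category"),
    )
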