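"""Stratified tables: hand counts, denominators, percentage consistency."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from cyclestats import ConfigError, pct
from cyclestats.phases import PhaseEstimate
from cyclestats.tables import (
    demographics_table,
    crosstab_by_length_category,
    luteal_length_distribution,
    median_hist_by_group,
    ovulation_day_distribution,
    variation_hist_by_group,
)


def estimate(day: int, luteal: int | None, uid: str = "u") -> PhaseEstimate:
    return PhaseEstimate(user_id=uid, cycle_start=dt.date(2018, 1, 1),
                         lh_positive_day=day - 1, ovulation_day=day,
                         follicular_days=day - 1, luteal_days=luteal)


def cohort_frame(rows: list[dict]) -> pd.DataFrame:
    defaults = {"user_id": "u", "age_group": None, "bmi": None,
                "bmi_category": None, "flow_category": None,
                "length_category": "normal", "median_rounded": 28,
                "variation_bin": "0-1.5", "smoking": None, "stress": None}
    return pd.DataFrame([{**defaults, **r} for r in rows])


def test_percent_formatting_rounds_half_up_to_two_decimals():
    assert pct(1, 3) == 33.33
    assert pct(2, 3) == 66.67
    assert pct(1, 8) == 12.5
    assert pct(0, 0) is None


def test_demographics_hand_count_four_ages():
    cohort = cohort_frame([{"age_group": g} for g in
                           ("18-24", "18-24", "30-34", "40-55")])
    table = demographics_table(cohort)
    ages = table[table.variable == "age_group"].set_index("category")
    assert ages.loc["18-24", "count"] == 2
    assert ages.loc["18-24", "percent"] == 50.00
    assert ages.loc["30-34", "percent"] == 25.00
    assert (ages["denominator"] == 4).all()


def test_unreported_variable_has_zero_denominator_blank_percent():
    cohort = cohort_frame([{"age_group": "18-24"}])  # nobody reports smoking
    table = demographics_table(cohort)
    smoking = table[table.variable == "smoking"]
    assert (smoking["denominator"] == 0).all()
    assert smoking["percent"].isna().all()


def test_demographics_counts_match_generator_tally(tiny_run):
    _, log, truth, results = tiny_run
    table = demographics_table(results.cohort)
    ages = table[table.variable == "age_group"].set_index("category")["count"]
    included_truth = truth.users[truth.users.user_id.isin(results.included)]
    expected = included_truth["age_group"].value_counts()
    for group, n in expected.items():
        assert ages[group] == n


def test_crosstab_uses_per_column_per_variable_denominators():
    cohort = cohort_frame([
        {"length_category": "short", "flow_category": "light"},
        {"length_category": "short", "flow_category": "light"},
        {"length_category": "normal", "flow_category": "medium"},
        {"length_category": "normal", "flow_category": None},
    ])
    table = crosstab_by_length_category(cohort)
    flow = table[table.variable == "flow_category"].set_index("category")
    assert flow.loc["light", "short_percent"] == 100.00
    assert flow.loc["light", "short_denominator"] == 2
    # the None reporter drops out of the normal column's denominator
    assert flow.loc["medium", "normal_denominator"] == 1
    assert flow.loc["medium", "normal_percent"] == 100.00


def test_crosstab_empty_column_is_blank_with_zero_denominator():
    cohort = cohort_frame([{"length_category": "normal", "flow_category": "medium"}])
    table = crosstab_by_length_category(cohort)
    flow = table[table.variable == "flow_category"]
    assert (flow["short_denominator"] == 0).all()
    assert flow["short_percent"].isna().all()


def test_ovulation_day_distribution_hand_counts():
    table = ovulation_day_distribution(
        [estimate(14, 15), estimate(14, 15), estimate(15, 14)])
    idx = table.set_index("ovulation_day")
    assert idx.loc[14, "count"] == 2 and idx.loc[14, "percent"] == 66.67
    assert idx.loc[15, "count"] == 1 and idx.loc[15, "percent"] == 33.33


def test_ovulation_day_outside_span_goes_to_other():
    table = ovulation_day_distribution([estimate(14, 15), estimate(33, 5)])
    assert table.set_index("ovulation_day").loc["other", "count"] == 1


def test_empty_estimates_give_empty_tables():
    assert ovulation_day_distribution([]).empty
    assert luteal_length_distribution([]).empty


def test_luteal_distribution_ignores_current_cycles():
    table = luteal_length_distribution(
        [estimate(14, 15), estimate(14, 15), estimate(15, 14), estimate(14, None)])
    idx = table.set_index("luteal_days")
    assert idx.loc[15, "count"] == 2 and idx.loc[15, "percent"] == 66.67
    assert (idx["denominator"] == 3).all()


def test_median_hist_single_group_hand_percentages():
    cohort = cohort_frame([{"age_group": "18-24", "median_rounded": m}
                           for m in (27, 28, 28, 29)])
    table = median_hist_by_group(cohort, "age_group")
    young = table[table.age_group == "18-24"].set_index("median_length")
    assert young.loc["27", "percent"] == 25.0
    assert young.loc["28", "percent"] == 50.0
    assert young.loc["29", "percent"] == 25.0


def test_median_edge_bins_collapse():
    cohort = cohort_frame([{"age_group": "18-24", "median_rounded": 19},
                           {"age_group": "18-24", "median_rounded": 40}])
    table = median_hist_by_group(cohort, "age_group")
    young = table[table.age_group == "18-24"].set_index("median_length")
    assert young.loc["<=20", "count"] == 1
    assert young.loc[">=36", "count"] == 1


def test_unknown_grouping_is_config_error():
    with pytest.raises(ConfigError):
        median_hist_by_group(cohort_frame([{}]), "zodiac_sign")
    with pytest.raises(ConfigError):
        variation_hist_by_group(cohort_frame([{}]), "zodiac_sign")


def test_variation_hist_hand_cases():
    cohort = cohort_frame([
        {"age_group": "18-24", "variation_bin": "1.5-3"},
        {"age_group": "18-24", "variation_bin": ">=6"},
    ])
    table = variation_hist_by_group(cohort, "age_group")
    young = table[table.age_group == "18-24"].set_index("variation_bin")
    assert young.loc["1.5-3", "percent"] == 50.0
    assert young.loc[">=6", "percent"] == 50.0


def test_percentages_sum_to_100_within_rounding(paper_like_run):
    """Every nonempty distribution's percentages sum to 100 +- 0.5."""
    _, _, _, results = paper_like_run
    t = results.tables

    demo = t.demographics[t.demographics["denominator"] > 0]
    for _, grp in demo.groupby("variable"):
        assert grp["percent"].sum() == pytest.approx(100, abs=0.5)

    for dist in (t.ovulation_day_dist, t.luteal_dist):
        if not dist.empty:
            assert dist["percent"].sum() == pytest.approx(100, abs=0.5)

    for hist, key in ((t.median_hist_age, "age_group"),
                      (t.variation_hist_age, "age_group")):
        nonempty = hist[hist["denominator"] > 0]
        for _, grp in nonempty.groupby(key):
            assert grp["percent"].sum() == pytest.approx(100, abs=1.0)


def test_grand_totals_consistent_across_tables(paper_like_run):
    """short + normal + long = cohort N, in frame and crosstab."""
    _, _, _, results = paper_like_run
    counts = results.cohort["length_category"].value_counts()
    assert counts.sum() == results.n_included
    table = results.tables.by_length_category
    ages = table[table.variable == "age_group"]
    reported = results.cohort["age_group"].notna().sum()
    assert (ages["short_count"].sum() + ages["normal_count"].sum()
            + ages["long_count"].sum()) == reported


def test_rerun_is_bit_identical(tiny_run):
    from cyclestats import analyze_event_log

    _, log, _, results = tiny_run
    again = analyze_event_log(log)
    assert again.tables.demographics.equals(results.tables.demographics)
    assert again.tables.luteal_dist.equals(results.tables.luteal_dist)
    assert again.cohort.equals(results.cohort)
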