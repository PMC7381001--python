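"""Event-log model: CSV round trips, parsing, and validation."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclestats import (
    FormatError,
    ReferentialError,
    UserProfile,
    read_event_log,
    validate_log,
    write_event_log,
)
from cyclestats.events import (
    INTENSITIES,
    LHTest,
    MenstruationDay,
    SURVEY_VOCABULARY,
    UNREPORTED,
    parse_intensity,
)
from cyclestats.simulate import default_params, generate_cohort

from conftest import EXTRACTION, make_log


def write_read(log, tmp_path):
    paths = write_event_log(log, tmp_path)
    return read_event_log(paths["profiles"], paths["menses"], paths["lh_tests"],
                          log.extraction_date)


def test_three_user_fixture_counts_preserved(tmp_path):
    profiles = [UserProfile(user_id=f"u{i}", age_years=20 + i) for i in range(3)]
    menses = [
        MenstruationDay(p.user_id, dt.date(2018, 1, 1 + d), "medium")
        for p in profiles for d in range(2)
    ]
    log = make_log(profiles, menses)
    back = write_read(log, tmp_path)
    assert len(back.profiles) == 3
    assert len(back.menses) == 6


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Heavy", "heavy"), ("HEAVY", "heavy"), ("h", "heavy"),
        ("light", "light"), ("L", "light"), ("M", "medium"),
        ("", UNREPORTED), ("none", UNREPORTED),
    ],
)
def test_intensity_case_folding(raw, expected):
    assert parse_intensity(raw) == expected


def test_unknown_intensity_becomes_unreported_with_warning():
    with pytest.warns(UserWarning, match="unknown intensity"):
        assert parse_intensity("torrential") == UNREPORTED


def test_event_after_extraction_is_referential_error(tmp_path):
    log = make_log(
        [UserProfile(user_id="u1", age_years=30)],
        [MenstruationDay("u1", EXTRACTION + dt.timedelta(days=1), "light")],
    )
    paths = write_event_log(log, tmp_path)
    with pytest.raises(ReferentialError, match="after extraction_date"):
        read_event_log(paths["profiles"], paths["menses"], paths["lh_tests"],
                       EXTRACTION)


def test_event_for_unknown_user_lists_offending_ids(tmp_path):
    log = make_log([UserProfile(user_id="u1", age_years=30)],
                   [MenstruationDay("u1", dt.date(2018, 1, 1), "light")])
    paths = write_event_log(log, tmp_path)
    (tmp_path / "menses.csv").write_text(
        "user_id,date,intensity\nghost,2018-01-01,light\n", encoding="utf-8"
    )
    with pytest.raises(ReferentialError, match="ghost"):
        read_event_log(paths["profiles"], paths["menses"], paths["lh_tests"],
                       EXTRACTION)


def test_missing_required_column_names_it(tmp_path):
    log = make_log([UserProfile(user_id="u1", age_years=30)])
    paths = write_event_log(log, tmp_path)
    (tmp_path / "menses.csv").write_text("user_id,intensity\n", encoding="utf-8")
    with pytest.raises(FormatError, match="'date'"):
        read_event_log(paths["profiles"], paths["menses"], paths["lh_tests"],
                       EXTRACTION)


def test_empty_log_round_trips_with_headers(tmp_path):
    log = make_log([])
    back = write_read(log, tmp_path)
    assert back == log
    assert list(back.menses.columns) == ["user_id", "date", "intensity"]


def test_unicode_user_ids_round_trip(tmp_path):
    profiles = [UserProfile(user_id="üser-Ω", age_years=28,
                            survey={"children": "≥3"})]
    menses = [MenstruationDay("üser-Ω", dt.date(2018, 3, 1), "heavy")]
    log = make_log(profiles, menses)
    assert write_read(log, tmp_path) == log


def test_synthetic_cohort_round_trip(tmp_path):
    log, _ = generate_cohort(default_params("tiny", seed=5))
    assert write_read(log, tmp_path) == log


# -- validate_log ----------------------------------------------------------

def test_valid_log_yields_no_issues(tiny_run):
    _, log, _, _ = tiny_run
    assert validate_log(log) == []


def test_duplicate_menses_day_is_one_issue():
    day = MenstruationDay("u1", dt.date(2018, 1, 1), "light")
    log = make_log([UserProfile(user_id="u1", age_years=30)], [day, day])
    issues = validate_log(log)
    assert [i.rule for i in issues] == ["duplicate_menses_day"]


def test_weight_log_out_of_order_is_flagged():
    p = UserProfile(user_id="u1", age_years=30, height_cm=165,
                    weight_log=[(dt.date(2018, 6, 1), 60.0),
                                (dt.date(2018, 1, 1), 62.0)])
    issues = validate_log(make_log([p]))
    assert [i.rule for i in issues] == ["weight_log_order"]


@pytest.mark.parametrize(
    "mutate,rule",
    [
        (lambda log: log.profiles["u1"].__setattr__("age_years", -1), "negative_age"),
        (lambda log: log.profiles["u1"].__setattr__("height_cm", 0.0), "nonpositive_height"),
        (lambda log: log.profiles["u1"].survey.__setitem__("smoking", "vape"),
         "invalid_survey_answer"),
        (lambda log: log.menses.__setitem__("intensity", ["purple"]),
         "invalid_intensity"),
        (lambda log: log.lh_tests.__setitem__("result", ["maybe"]),
         "invalid_lh_result"),
    ],
)
def test_each_broken_invariant_yields_an_issue(mutate, rule):
    log = make_log(
        [UserProfile(user_id="u1", age_years=30, height_cm=160.0)],
        [MenstruationDay("u1", dt.date(2018, 1, 1), "light")],
        [LHTest("u1", dt.date(2018, 1, 10), "positive")],
    )
    assert validate_log(log) == []
    mutate(log)
    assert rule in {i.rule for i in validate_log(log)}


# -- property: round-trip identity on generated logs -----------------------

profile_strategy = st.builds(
    UserProfile,
    user_id=st.text(st.characters(min_codepoint=33, max_codepoint=1000,
                                  exclude_characters=",;:\"\n\r"),
                    min_size=1, max_size=8),
    age_years=st.integers(18, 55),
    height_cm=st.one_of(st.none(), st.floats(140, 195)),
    weight_log=st.lists(
        st.tuples(st.dates(dt.date(2017, 1, 1), dt.date(2018, 11, 1)),
                  st.floats(40, 150).map(lambda w: round(w, 1))),
        max_size=3,
    ).map(lambda entries: sorted(entries)),
    pregnancy_logged=st.booleans(),
    oc_reminder=st.booleans(),
    survey=st.dictionaries(
        st.sampled_from(sorted(SURVEY_VOCABULARY)), st.none(), max_size=3
    ).map(lambda d: {k: SURVEY_VOCABULARY[k][0] for k in d}),
)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(profiles=st.lists(profile_strategy, max_size=5,
                         unique_by=lambda p: p.user_id),
       data=st.data())
def test_round_trip_identity_on_arbitrary_valid_logs(profiles, data, tmp_path_factory):
    menses, lh = [], []
    for p in profiles:
        dates = data.draw(st.lists(
            st.dates(dt.date(2018, 1, 1), dt.date(2018, 11, 30)),
            unique=True, max_size=6))
        for d in dates:
            menses.append(MenstruationDay(
                p.user_id, d,
                data.draw(st.sampled_from(INTENSITIES + (UNREPORTED,)))))
        lh_dates = data.draw(st.lists(
            st.dates(dt.date(2018, 1, 1), dt.date(2018, 11, 30)),
            unique=True, max_size=3))
        for d in lh_dates:
            lh.append(LHTest(p.user_id, d,
                             data.draw(st.sampled_from(["positive", "negative"]))))
    log = make_log(profiles, menses, lh)
    assert validate_log(log) == []
    out = tmp_path_factory.mktemp("roundtrip")
    assert write_read(log, out) == log
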