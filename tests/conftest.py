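"""Shared fixtures: hand-built event logs and a session-scoped large cohort."""

from __future__ import annotations

import datetime as dt

import pytest

from cyclestats import EventLog, UserProfile, analyze_event_log, default_params, generate_cohort
from cyclestats.events import (
    LHTest,
    MenstruationDay,
    UNREPORTED,
    lh_frame,
    menses_frame,
)

EXTRACTION = dt.date(2018, 12, 1)


def make_log(
    profiles: list[UserProfile],
    menses: list[MenstruationDay] = (),
    lh: list[LHTest] = (),
    extraction_date: dt.date = EXTRACTION,
) -> EventLog:
    return EventLog(
        profiles={p.user_id: p for p in profiles},
        menses=menses_frame(menses),
        lh_tests=lh_frame(lh),
        extraction_date=extraction_date,
    )


def period_starts(uid: str, starts: list[dt.date], period_len: int = 1,
                  intensity: str = UNREPORTED) -> list[MenstruationDay]:
    """Single- or multi-day periods at the given start dates."""
    days = []
    for s in starts:
        for d in range(period_len):
            days.append(MenstruationDay(uid, s + dt.timedelta(days=d), intensity))
    return days


def regular_starts(first: dt.date, cycle_len: int, n_periods: int) -> list[dt.date]:
    return [first + dt.timedelta(days=cycle_len * k) for k in range(n_periods)]


@pytest.fixture
def filter_fixture_log() -> tuple[EventLog, set[str], dict[str, int]]:
    """Ten hand-written users covering every exclusion rule.

    Returns (log, expected included set, expected first-failing tally).
    """
    first = dt.date(2018, 1, 5)

    def profile(uid, age, preg=False, oc=False):
        return UserProfile(user_id=uid, age_years=age,
                           pregnancy_logged=preg, oc_reminder=oc)

    profiles = [
        profile("u01", 17),                     # under age despite 10 cycles
        profile("u02", 25, preg=True),          # pregnancy
        profile("u03", 30, oc=True),            # OC reminder
        profile("u04", 30, preg=True, oc=True), # pregnancy wins (order)
        profile("u05", 17, preg=True),          # age wins (order)
        profile("u06", 30),                     # 1 completed + current only
        profile("u07", 30),                     # no menses logged at all
        profile("u08", 18),                     # boundary age, included
        profile("u09", 45),                     # included
        profile("u10", 30),                     # included
    ]
    menses: list[MenstruationDay] = []
    menses += period_starts("u01", regular_starts(first, 28, 11))
    menses += period_starts("u02", regular_starts(first, 28, 4))
    menses += period_starts("u03", regular_starts(first, 28, 4))
    menses += period_starts("u04", regular_starts(first, 28, 4))
    menses += period_starts("u05", regular_starts(first, 28, 4))
    menses += period_starts("u06", regular_starts(first, 28, 2))
    menses += period_starts("u08", regular_starts(first, 28, 3))
    menses += period_starts("u09", regular_starts(first, 30, 6))
    menses += period_starts("u10", regular_starts(first, 26, 3))

    expected_included = {"u08", "u09", "u10"}
    expected_tally = {"under_age": 2, "pregnancy": 2, "oc_reminder": 1,
                      "too_few_cycles": 2, "n_included": 3}
    return make_log(profiles, menses), expected_included, expected_tally


@pytest.fixture(scope="session")
def paper_like_run():
    """One 5,000-user cohort generated and analyzed once per session.

    Seed 1 is the suite's canonical simulation seed.
    """
    params = default_params("paper_like", seed=1)
    log, truth = generate_cohort(params)
    results = analyze_event_log(log)
    return params, log, truth, results


@pytest.fixture(scope="session")
def tiny_run():
    params = default_params("tiny", seed=7)
    log, truth = generate_cohort(params)
    results = analyze_event_log(log)
    return params, log, truth, results
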