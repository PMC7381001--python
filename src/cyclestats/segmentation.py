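"""Segment per-user menstruation days into periods and cycles.

A *period* is a run of bleeding days; a *cycle* runs from the first day of
one menstruation to the day before the first day of the next.  Cycle starts
are defined by the logged first day of menstruation, so cycle length is the
date difference between consecutive period starts.  The last period opens
the *current* (ongoing) cycle, whose length is undefined at extraction.

Day-level logging lapses are common, so a small unlogged gap inside a run
of bleeding days is bridged (``merge_gap_days``, default one day): a 1-day
bridge cannot merge two true periods at plausible cycle lengths.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping

from .events import EventLog

#: Completed-cycle lengths outside this window are flagged, never dropped.
MIN_PLAUSIBLE_DAYS = 10
MAX_PLAUSIBLE_DAYS = 90
DEFAULT_MERGE_GAP_DAYS = 1


@dataclass(frozen=True)
class Period:
    """One run of bleeding days (dates with their logged intensity)."""

    bleeding_days: tuple[tuple[dt.date, str], ...]

    @property
    def start_date(self) -> dt.date:
        return self.bleeding_days[0][0]

    @property
    def end_date(self) -> dt.date:
        return self.bleeding_days[-1][0]

    @property
    def length_days(self) -> int:
        # span including both endpoints; >= number of logged days
        return (self.end_date - self.start_date).days + 1

    @property
    def n_logged_intensity(self) -> int:
        from .events import UNREPORTED

        return sum(1 for _, i in self.bleeding_days if i != UNREPORTED)


@dataclass(frozen=True)
class Cycle:
    """One menstrual cycle of one user.

    Completed cycles have ``length_days = next_start_date - start_date``;
    the current cycle has neither.  ``flagged`` marks completed lengths
    outside the plausibility window.
    """

    user_id: str
    start_date: dt.date
    period: Period
    next_start_date: dt.date | None = None
    length_days: int | None = None
    is_current: bool = False
    flagged: bool = False


def group_bleeding_days(
    days: Iterable[tuple[dt.date, str]],
    merge_gap_days: int = DEFAULT_MERGE_GAP_DAYS,
) -> list[Period]:
    """Group bleeding days into periods, bridging short unlogged gaps.

    Two consecutive logged days belong to the same period when the number
    of unlogged days between them is at most ``merge_gap_days``.  Input is
    sorted and de-duplicated defensively, so the result is independent of
    input order and idempotent.
    """
    ordered = sorted(dict(days).items())
    periods: list[Period] = []
    run: list[tuple[dt.date, str]] = []
    for date, intensity in ordered:
        if run and (date - run[-1][0]).days - 1 > merge_gap_days:
            periods.append(Period(tuple(run)))
            run = []
        run.append((date, intensity))
    if run:
        periods.append(Period(tuple(run)))
    return periods


def build_cycles(
    user_id: str,
    periods: list[Period],
    extraction_date: dt.date,
    min_plausible: int = MIN_PLAUSIBLE_DAYS,
    max_plausible: int = MAX_PLAUSIBLE_DAYS,
) -> list[Cycle]:
    """Turn chronologically ordered periods into cycles.

    Period *i* starts cycle *i*; with a successor the cycle is completed,
    otherwise it is the single current cycle.  An empty period list yields
    an empty cycle list.
    """
    cycles: list[Cycle] = []
    for i, period in enumerate(periods):
        if i + 1 < len(periods):
            nxt = periods[i + 1].start_date
            length = (nxt - period.start_date).days
            cycles.append(
                Cycle(
                    user_id=user_id,
                    start_date=period.start_date,
                    period=period,
                    next_start_date=nxt,
                    length_days=length,
                    flagged=not (min_plausible <= length <= max_plausible),
                )
            )
        else:
            cycles.append(
                Cycle(
                    user_id=user_id,
                    start_date=period.start_date,
                    period=period,
                    is_current=True,
                )
            )
    return cycles


def segment_user(
    user_id: str,
    days: Iterable[tuple[dt.date, str]],
    extraction_date: dt.date,
    merge_gap_days: int = DEFAULT_MERGE_GAP_DAYS,
    min_plausible: int = MIN_PLAUSIBLE_DAYS,
    max_plausible: int = MAX_PLAUSIBLE_DAYS,
) -> list[Cycle]:
    periods = group_bleeding_days(days, merge_gap_days)
    return build_cycles(user_id, periods, extraction_date, min_plausible, max_plausible)


def segment_log(
    log: EventLog,
    merge_gap_days: int = DEFAULT_MERGE_GAP_DAYS,
    min_plausible: int = MIN_PLAUSIBLE_DAYS,
    max_plausible: int = MAX_PLAUSIBLE_DAYS,
) -> dict[str, list[Cycle]]:
    """Segment every user's menstruation days; users without bleeding
    events map to an empty cycle list."""
    by_user: dict[str, list[tuple[dt.date, str]]] = {
        uid: [] for uid in log.profiles
    }
    for uid, date, intensity in zip(
        log.menses["user_id"], log.menses["date"], log.menses["intensity"]
    ):
        by_user[uid].append((date, intensity))
    return {
        uid: segment_user(uid, days, log.extraction_date,
                          merge_gap_days, min_plausible, max_plausible)
        for uid, days in by_user.items()
    }


def completed_lengths(cycles: list[Cycle]) -> list[int]:
    """Lengths of the completed cycles, in chronological order."""
    return [c.length_days for c in cycles if not c.is_current]


def cycles_to_frame(cycles_by_user: Mapping[str, list[Cycle]]):
    """Flatten segmented cycles to a tidy DataFrame (one row per cycle)."""
    import pandas as pd

    rows = []
    for uid, cycles in cycles_by_user.items():
        for c in cycles:
            rows.append(
                {
                    "user_id": uid,
                    "start_date": c.start_date.isoformat(),
                    "length_days": c.length_days,
                    "is_current": c.is_current,
                    "period_length": c.period.length_days,
                    "flagged": c.flagged,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["user_id", "start_date", "length_days", "is_current",
                 "period_length", "flagged"],
    )
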