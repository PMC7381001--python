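"""Ovulation-day estimation from LH tests and phase lengths.

A positive urinary LH test marks the pre-ovulatory LH surge — the end of
the follicular phase — and ovulation is estimated as the *next* day.  When
a cycle holds several positive tests, the last one is used.  Cycle days
are 1-based (day 1 = first day of menstruation), so a positive test on
cycle day 13 puts ovulation at day 14 and a 13-day follicular phase.

Phase lengths partition the cycle exactly: the follicular phase runs from
day 1 up to and excluding the ovulation day (ovulation_day - 1 days); the
luteal phase runs from the ovulation day up to and excluding the next
menstruation (cycle_length - ovulation_day + 1 days, the ovulation day
counting as luteal day 1).  A day-14 ovulation in a 28-day cycle thus has
a 15-day luteal phase.  Cycles without a positive LH test have no
estimate (treated as anovulatory for these tables).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable

from .events import POSITIVE
from .segmentation import Cycle


@dataclass(frozen=True)
class PhaseEstimate:
    """Ovulation estimate for one cycle, with derived phase lengths."""

    user_id: str
    cycle_start: dt.date
    lh_positive_day: int   # 1-based cycle day of the last positive test
    ovulation_day: int     # lh_positive_day + 1
    follicular_days: int   # ovulation_day - 1
    luteal_days: int | None  # completed cycles only


def estimate_ovulation(
    cycle: Cycle,
    lh_tests: Iterable[tuple[dt.date, str]],
    extraction_date: dt.date | None = None,
) -> PhaseEstimate | None:
    """Estimate ovulation for one cycle from that user's LH tests.

    Positive tests are considered within [start, next start) for completed
    cycles and [start, extraction] for the current cycle.  Returns ``None``
    with no positive test, or when the estimated ovulation day would fall
    beyond the cycle's end (the estimate belongs to this cycle or not at
    all).
    """
    if cycle.is_current:
        if extraction_date is None:
            raise ValueError("extraction_date required for the current cycle")
        in_window = lambda d: cycle.start_date <= d <= extraction_date
    else:
        in_window = lambda d: cycle.start_date <= d < cycle.next_start_date

    positives = sorted(
        d for d, result in lh_tests if result == POSITIVE and in_window(d)
    )
    if not positives:
        return None
    last = positives[-1]  # multiple results logged: the last one is used
    lh_day = (last - cycle.start_date).days + 1
    ovulation_day = lh_day + 1
    if cycle.length_days is not None and ovulation_day > cycle.length_days:
        return None
    return PhaseEstimate(
        user_id=cycle.user_id,
        cycle_start=cycle.start_date,
        lh_positive_day=lh_day,
        ovulation_day=ovulation_day,
        follicular_days=follicular_length(ovulation_day),
        luteal_days=luteal_length(cycle, ovulation_day),
    )


def follicular_length(ovulation_day: int) -> int:
    """Days from cycle day 1 up to and excluding the ovulation day."""
    return ovulation_day - 1


def luteal_length(cycle: Cycle, ovulation_day: int) -> int | None:
    """Days from the ovulation day up to and excluding the next
    menstruation; undefined for the current cycle."""
    if cycle.is_current or cycle.length_days is None:
        return None
    return cycle.length_days - ovulation_day + 1


def estimate_phases_for_user(
    cycles: list[Cycle],
    lh_tests: list[tuple[dt.date, str]],
    extraction_date: dt.date,
) -> list[PhaseEstimate]:
    """At most one estimate per cycle, in chronological order."""
    out = []
    for cycle in cycles:
        est = estimate_ovulation(cycle, lh_tests, extraction_date)
        if est is not None:
            out.append(est)
    return out
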