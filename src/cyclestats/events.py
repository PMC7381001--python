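"""Domain model and tidy-CSV I/O for period-tracker event logs.

An :class:`EventLog` is the package's in-memory representation of a cohort
snapshot from a cycle-tracking app: one profile per user (sign-up age,
anthropometrics, survey answers, pregnancy / oral-contraceptive-reminder
flags) plus two day-resolution event streams, menstruation days with an
optional flow intensity and urinary LH (luteinizing hormone) test results.
All dates are calendar dates; the analysis operates at day resolution
throughout.

The on-disk dialect is three headered UTF-8 CSV files with ISO-8601 dates:
``profiles.csv``, ``menses.csv`` and ``lh_tests.csv``.  The weight history
is serialized inside profiles.csv as semicolon-joined ``date:kg`` pairs.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from .errors import FormatError, ReferentialError

# Flow intensity vocabulary.  "unreported" marks a bleeding day logged
# without an intensity; it is distinct from the day not being logged at all.
LIGHT = "light"
MEDIUM = "medium"
HEAVY = "heavy"
UNREPORTED = "unreported"
INTENSITIES = (LIGHT, MEDIUM, HEAVY)

# Case-insensitive synonyms accepted on input (single letters are the
# app-style shorthand).  Anything else maps to UNREPORTED with a warning:
# real tracker logs are messy and an odd string should not abort a read.
_INTENSITY_SYNONYMS = {
    "l": LIGHT,
    "light": LIGHT,
    "m": MEDIUM,
    "medium": MEDIUM,
    "h": HEAVY,
    "heavy": HEAVY,
}

POSITIVE = "positive"
NEGATIVE = "negative"
LH_RESULTS = (POSITIVE, NEGATIVE)

# Closed survey vocabularies, labels exactly as the app's questionnaire
# categories used in the cohort description.
SURVEY_VOCABULARY: dict[str, tuple[str, ...]] = {
    "smoking": ("Regularly", "Sometimes", "Do not smoke"),
    "alcohol": (
        "≥3 times a week",
        "1-2 times a week",
        "<2-3 times a month",
        "None",
    ),
    "stress": (
        "≥3 times a week",
        "1-2 times a week",
        "<3 times a month",
        "None",
    ),
    "physical_activity": (
        "≥3 times a week",
        "1-2 times a week",
        "<3 times a month",
        "None",
    ),
    "relationship": ("Married or stable partner", "Single", "No partner"),
    "trying_to_conceive": (
        "<1 month",
        "1-3 months",
        "3-6 months",
        ">6 months to 1 year",
        ">1 year",
    ),
    "children": ("0", "1 or 2", "≥3"),
    "reproductive_disorders": ("Yes", "No", "I don't know"),
}
SURVEY_FIELDS = tuple(SURVEY_VOCABULARY)


class MenstruationDay(NamedTuple):
    user_id: str
    date: dt.date
    intensity: str  # one of INTENSITIES or UNREPORTED


class LHTest(NamedTuple):
    user_id: str
    date: dt.date
    result: str  # one of LH_RESULTS


@dataclass
class UserProfile:
    """Static per-user record from the sign-up questionnaire and surveys.

    ``age_years`` is the sign-up age (age at data collection); it is never
    recomputed from a birth date.  ``weight_log`` is the manual weight
    history, ordered by date; BMI computations use its latest entry.
    """

    user_id: str
    age_years: int
    height_cm: float | None = None
    weight_log: list[tuple[dt.date, float]] = field(default_factory=list)
    pregnancy_logged: bool = False
    oc_reminder: bool = False
    survey: dict[str, str] = field(default_factory=dict)


@dataclass
class EventLog:
    """A cohort snapshot: profiles plus the two event streams.

    ``menses`` has columns (user_id, date, intensity); ``lh_tests`` has
    (user_id, date, result).  ``extraction_date`` is the snapshot date —
    no event may post-date it.
    """

    profiles: dict[str, UserProfile]
    menses: pd.DataFrame
    lh_tests: pd.DataFrame
    extraction_date: dt.date

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        return (
            self.profiles == other.profiles
            and self.extraction_date == other.extraction_date
            and _frames_equal(self.menses, other.menses, ["user_id", "date"])
            and _frames_equal(self.lh_tests, other.lh_tests, ["user_id", "date"])
        )

    @property
    def n_users(self) -> int:
        return len(self.profiles)


@dataclass(frozen=True)
class Issue:
    """One validation finding: which user, which rule, what value."""

    user_id: str
    rule: str
    value: str


def empty_menses_frame() -> pd.DataFrame:
    return pd.DataFrame({"user_id": pd.Series(dtype=object),
                         "date": pd.Series(dtype=object),
                         "intensity": pd.Series(dtype=object)})


def empty_lh_frame() -> pd.DataFrame:
    return pd.DataFrame({"user_id": pd.Series(dtype=object),
                         "date": pd.Series(dtype=object),
                         "result": pd.Series(dtype=object)})


def menses_frame(days: Iterable[MenstruationDay]) -> pd.DataFrame:
    rows = list(days)
    if not rows:
        return empty_menses_frame()
    return pd.DataFrame(rows, columns=["user_id", "date", "intensity"])


def lh_frame(tests: Iterable[LHTest]) -> pd.DataFrame:
    rows = list(tests)
    if not rows:
        return empty_lh_frame()
    return pd.DataFrame(rows, columns=["user_id", "date", "result"])


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame, keys: list[str]) -> bool:
    if len(a) != len(b):
        return False
    if len(a) == 0:
        return list(a.columns) == list(b.columns)
    a = a.sort_values(keys, kind="mergesort").reset_index(drop=True)
    b = b.sort_values(keys, kind="mergesort").reset_index(drop=True)
    return a.equals(b)


def parse_intensity(raw: object) -> str:
    """Map a raw intensity string to the canonical vocabulary.

    Case-insensitive; unknown or missing values become ``unreported`` with
    a warning rather than an error.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return UNREPORTED
    text = str(raw).strip().lower()
    if text in ("", "unreported", "none", "nan"):
        return UNREPORTED
    canonical = _INTENSITY_SYNONYMS.get(text)
    if canonical is None:
        warnings.warn(
            f"unknown intensity {raw!r} stored as 'unreported'", stacklevel=3
        )
        return UNREPORTED
    return canonical


def _parse_date(raw: object, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(raw).strip())
    except ValueError as exc:
        raise FormatError(f"bad ISO-8601 date {raw!r} in {where}") from exc


def _parse_bool(raw: object) -> bool:
    text = str(raw).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no", "", "nan"):
        return False
    raise FormatError(f"bad boolean value {raw!r}")


def _serialize_weight_log(weight_log: list[tuple[dt.date, float]]) -> str:
    return ";".join(f"{d.isoformat()}:{w!r}" for d, w in weight_log)


def _parse_weight_log(raw: object) -> list[tuple[dt.date, float]]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return []
    text = str(raw).strip()
    if not text:
        return []
    out = []
    for pair in text.split(";"):
        datepart, _, kgpart = pair.partition(":")
        out.append((_parse_date(datepart, "weight_log"), float(kgpart)))
    return out


_PROFILE_REQUIRED = ("user_id", "age_years")
_MENSES_REQUIRED = ("user_id", "date", "intensity")
_LH_REQUIRED = ("user_id", "date", "result")


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path: object) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")


def read_event_log(
    profile_path: str | Path,
    menses_path: str | Path,
    lh_path: str | Path,
    extraction_date: dt.date | str,
) -> EventLog:
    """Read the three-CSV dialect and return a validated :class:`EventLog`.

    Raises :class:`FormatError` for a missing required column or malformed
    field, and :class:`ReferentialError` when an event references an
    unknown user or post-dates ``extraction_date``.
    """
    if isinstance(extraction_date, str):
        extraction_date = dt.date.fromisoformat(extraction_date)

    pdf = pd.read_csv(profile_path, dtype=str, keep_default_na=False)
    _require_columns(pdf, _PROFILE_REQUIRED, profile_path)
    profiles: dict[str, UserProfile] = {}
    for row in pdf.to_dict("records"):
        uid = row["user_id"]
        height_raw = row.get("height_cm", "")
        survey = {}
        for fld in SURVEY_FIELDS:
            answer = row.get(f"survey_{fld}", "")
            if answer != "":
                survey[fld] = answer
        profiles[uid] = UserProfile(
            user_id=uid,
            age_years=int(row["age_years"]),
            height_cm=float(height_raw) if height_raw != "" else None,
            weight_log=_parse_weight_log(row.get("weight_log", "")),
            pregnancy_logged=_parse_bool(row.get("pregnancy_logged", "false")),
            oc_reminder=_parse_bool(row.get("oc_reminder", "false")),
            survey=survey,
        )

    mdf = pd.read_csv(menses_path, dtype=str, keep_default_na=False)
    _require_columns(mdf, _MENSES_REQUIRED, menses_path)
    menses = menses_frame(
        MenstruationDay(r["user_id"], _parse_date(r["date"], str(menses_path)),
                        parse_intensity(r["intensity"]))
        for r in mdf.to_dict("records")
    )

    ldf = pd.read_csv(lh_path, dtype=str, keep_default_na=False)
    _require_columns(ldf, _LH_REQUIRED, lh_path)
    lh_records = []
    for r in ldf.to_dict("records"):
        result = r["result"].strip().lower()
        if result not in LH_RESULTS:
            raise FormatError(f"{lh_path}: bad LH result {r['result']!r}")
        lh_records.append(
            LHTest(r["user_id"], _parse_date(r["date"], str(lh_path)), result)
        )
    lh_tests = lh_frame(lh_records)

    log = EventLog(profiles, menses, lh_tests, extraction_date)
    _check_referential(log)
    return log


def _check_referential(log: EventLog) -> None:
    unknown: list[str] = []
    late: list[str] = []
    for frame in (log.menses, log.lh_tests):
        for uid, date in zip(frame["user_id"], frame["date"]):
            if uid not in log.profiles:
                unknown.append(uid)
            if date > log.extraction_date:
                late.append(f"{uid}@{date.isoformat()}")
    if unknown:
        raise ReferentialError(
            f"events reference unknown users: {sorted(set(unknown))}"
        )
    if late:
        raise ReferentialError(
            f"events dated after extraction_date: {sorted(set(late))}"
        )


def write_event_log(log: EventLog, out_dir: str | Path) -> dict[str, Path]:
    """Write ``log`` as the three-CSV dialect; returns the file paths.

    Round-trip guarantee: ``read_event_log(**write_event_log(log), ...)``
    with the same extraction date reproduces ``log`` field for field.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": out / "profiles.csv",
        "menses": out / "menses.csv",
        "lh_tests": out / "lh_tests.csv",
    }

    prof_rows = []
    for uid, p in log.profiles.items():
        row: dict[str, object] = {
            "user_id": uid,
            "age_years": p.age_years,
            "height_cm": "" if p.height_cm is None else repr(float(p.height_cm)),
            "weight_log": _serialize_weight_log(p.weight_log),
            "pregnancy_logged": str(p.pregnancy_logged).lower(),
            "oc_reminder": str(p.oc_reminder).lower(),
        }
        for fld in SURVEY_FIELDS:
            row[f"survey_{fld}"] = p.survey.get(fld, "")
        prof_rows.append(row)
    cols = ["user_id", "age_years", "height_cm", "weight_log",
            "pregnancy_logged", "oc_reminder"] + [f"survey_{f}" for f in SURVEY_FIELDS]
    pd.DataFrame(prof_rows, columns=cols).to_csv(
        paths["profiles"], index=False, encoding="utf-8"
    )

    m = log.menses.copy()
    if len(m):
        m["date"] = [d.isoformat() for d in m["date"]]
    m.to_csv(paths["menses"], index=False, encoding="utf-8")

    t = log.lh_tests.copy()
    if len(t):
        t["date"] = [d.isoformat() for d in t["date"]]
    t.to_csv(paths["lh_tests"], index=False, encoding="utf-8")
    return paths


def validate_log(log: EventLog) -> list[Issue]:
    """Check every type invariant; returns one :class:`Issue` per violation.

    Validation never raises: an empty return value means the log is valid.
    """
    issues: list[Issue] = []

    for uid, p in log.profiles.items():
        if p.age_years < 0:
            issues.append(Issue(uid, "negative_age", str(p.age_years)))
        if p.height_cm is not None and p.height_cm <= 0:
            issues.append(Issue(uid, "nonpositive_height", str(p.height_cm)))
        dates = [d for d, _ in p.weight_log]
        if any(b < a for a, b in zip(dates, dates[1:])):
            issues.append(Issue(uid, "weight_log_order",
                                ";".join(d.isoformat() for d in dates)))
        for fld, answer in p.survey.items():
            vocab = SURVEY_VOCABULARY.get(fld)
            if vocab is None:
                issues.append(Issue(uid, "unknown_survey_field", fld))
            elif answer not in vocab:
                issues.append(Issue(uid, "invalid_survey_answer", f"{fld}={answer}"))

    def check_events(frame: pd.DataFrame, value_col: str, vocab: tuple[str, ...],
                     dup_rule: str, value_rule: str) -> None:
        seen: set[tuple[str, dt.date]] = set()
        for uid, date, value in zip(frame["user_id"], frame["date"], frame[value_col]):
            key = (uid, date)
            if key in seen:
                issues.append(Issue(uid, dup_rule, date.isoformat()))
            seen.add(key)
            if uid not in log.profiles:
                issues.append(Issue(uid, "unknown_user", uid))
            if date > log.extraction_date:
                issues.append(Issue(uid, "event_after_extraction", date.isoformat()))
            if value not in vocab:
                issues.append(Issue(uid, value_rule, str(value)))

    check_events(log.menses, "intensity", INTENSITIES + (UNREPORTED,),
                 "duplicate_menses_day", "invalid_intensity")
    check_events(log.lh_tests, "result", LH_RESULTS,
                 "duplicate_lh_day", "invalid_lh_result")
    return issues
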