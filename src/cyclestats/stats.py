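"""Per-woman cycle-length statistics and categorical classifiers.

Each woman is summarized over her *completed* cycle lengths x: mean
mu = E[x], the midpoint median, and the population variance
var(x) = E[(x - mu)^2] (divide by n, exactly the expectation form — not
the n-1 sample estimator).  Because the variance formula yields days² but
cycle-length *variation* is reported in days, variation_days is defined as
sqrt(var(x)); both are retained in output.

Classifiers: per-woman length category from the rounded median (short
<=20 d, normal 21–35 d, long >=36 d), variation bins of width 1.5 days,
BMI (latest logged weight over squared height) and the cohort age groups.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError

LENGTH_SHORT = "short"
LENGTH_NORMAL = "normal"
LENGTH_LONG = "long"
LENGTH_CATEGORIES = (LENGTH_SHORT, LENGTH_NORMAL, LENGTH_LONG)

SHORT_MAX_DAYS = 20   # short cycle: rounded median <= 20 days
NORMAL_MAX_DAYS = 35  # normal: 21-35; long: >= 36

VARIATION_BIN_WIDTH = 1.5
VARIATION_BINS = ("0-1.5", "1.5-3", "3-4.5", "4.5-6", ">=6")

BMI_CATEGORIES = ("<=18.4", "18.5-24.9", "25.0-29.9", "30.0-34.9",
                  "35.0-50.0", ">=50")
#: half-open upper edges matching BMI_CATEGORIES[:-1]
_BMI_EDGES = (18.5, 25.0, 30.0, 35.0, 50.0)

AGE_GROUPS = ("18-24", "25-29", "30-34", "35-39", "40-55")
#: closed integer upper bounds matching AGE_GROUPS
_AGE_UPPER = (24, 29, 34, 39, 55)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero-free half-up (0.5 -> 1), deterministic
    alternative to banker's rounding for integer-day bins."""
    factor = 10 ** decimals
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class CycleSummary:
    """One woman's completed-cycle length statistics and categories."""

    user_id: str | None
    n_completed: int
    lengths: tuple[int, ...]
    mean: float
    median_length: float
    variance: float        # days^2, population formula
    variation_days: float  # sqrt(variance), days
    length_category: str
    variation_bin: str


def summarize_woman(lengths, user_id: str | None = None) -> CycleSummary:
    """Summarize one woman's completed cycle lengths (requires n >= 2;
    variation is undefined on a single cycle)."""
    x = [int(v) for v in lengths]
    if len(x) < 2:
        raise InsufficientDataError(
            f"need >= 2 completed cycles, got {len(x)}"
        )
    arr = np.asarray(x, dtype=float)
    mu = float(arr.mean())
    median = float(np.median(arr))
    variance = float(np.mean((arr - mu) ** 2))
    variation = math.sqrt(variance)
    return CycleSummary(
        user_id=user_id,
        n_completed=len(x),
        lengths=tuple(x),
        mean=mu,
        median_length=median,
        variance=variance,
        variation_days=variation,
        length_category=length_category(median),
        variation_bin=variation_bin(variation),
    )


def length_category(median_length: float) -> str:
    """Short / normal / long from the median rounded to an integer day."""
    day = int(round_half_up(median_length))
    if day <= SHORT_MAX_DAYS:
        return LENGTH_SHORT
    if day <= NORMAL_MAX_DAYS:
        return LENGTH_NORMAL
    return LENGTH_LONG


def variation_bin(variation_days: float, width: float = VARIATION_BIN_WIDTH) -> str:
    """Half-open bins [0,1.5), [1.5,3), [3,4.5), [4.5,6), [6, inf)."""
    if variation_days < 0:
        raise ValueError("variation_days must be >= 0")
    idx = int(variation_days // width)
    if idx >= len(VARIATION_BINS) - 1:
        return VARIATION_BINS[-1]
    return VARIATION_BINS[idx]


@dataclass(frozen=True)
class Anthropometrics:
    user_id: str | None
    bmi: float | None
    bmi_category: str | None
    age_group: str


def compute_bmi(
    height_cm: float | None,
    weight_log: list[tuple[dt.date, float]],
) -> tuple[float, str] | None:
    """BMI (kg/m²) from height and the *latest* logged weight.

    Returns ``None`` when height or weight is missing — the woman is then
    simply absent from BMI stratifications, not from the cohort.
    """
    if height_cm is None or height_cm <= 0 or not weight_log:
        return None
    latest_weight = max(weight_log, key=lambda e: e[0])[1]
    bmi = latest_weight / (height_cm / 100.0) ** 2
    return bmi, bmi_category(bmi)


def bmi_category(bmi: float) -> str:
    # epsilon absorbs binary float error (e.g. 64/1.6**2 = 24.999...96)
    # so values landing on a boundary classify as the boundary intends
    for label, upper in zip(BMI_CATEGORIES, _BMI_EDGES):
        if bmi < upper - 1e-9:
            return label
    return BMI_CATEGORIES[-1]


def age_group(age_years: int) -> str:
    """Cohort age group; ages above 55 clamp into 40-55 with a warning."""
    if age_years < 18:
        raise ValueError("age groups are defined for ages >= 18")
    if age_years > _AGE_UPPER[-1]:
        warnings.warn(
            f"age {age_years} above the top group; clamped into "
            f"{AGE_GROUPS[-1]}", stacklevel=2
        )
        return AGE_GROUPS[-1]
    for label, upper in zip(AGE_GROUPS, _AGE_UPPER):
        if age_years <= upper:
            return label
    raise AssertionError("unreachable")


def anthropometrics(profile) -> Anthropometrics:
    """Convenience: BMI fields plus age group for one profile."""
    result = compute_bmi(profile.height_cm, profile.weight_log)
    if result is None:
        bmi, cat = None, None
    else:
        bmi, cat = result
    return Anthropometrics(
        user_id=profile.user_id,
        bmi=bmi,
        bmi_category=cat,
        age_group=age_group(profile.age_years),
    )
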