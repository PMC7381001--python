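"""Synthetic tracker-cohort generator with ground truth.

Emulates the statistical structure the analysis assumes: each woman has a
latent mean cycle length m_i drawn around a population mean with
between-woman spread, and a within-woman day-to-day SD s_i drawn from a
Gamma law; observed cycle lengths are rounded Gaussians around (m_i, s_i).
Periods of 3-7 days carry an intensity ramp (medium, heavy, heavy, medium,
light) with each day's intensity logged only with some probability; a
fraction of women use LH tests, for whom each completed cycle draws a
luteal length ~ Normal(14.5, 1.5) rounded and logs one positive test the
day before the implied ovulation day.  Pregnancy / OC-reminder flags,
heights, weights and survey answers are drawn per configured category
probabilities patterned on the cohort's published composition.

Every draw descends from a single integer seed via per-user substreams
keyed on (seed, user index), so a cohort is reproducible and extensible
without reshuffling existing users.  The generator emits a ground-truth
table (latent means, SDs, luteal lengths, true ovulation days) so every
pipeline stage can be tested for recovery without any external data.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .events import (
    HEAVY,
    LIGHT,
    MEDIUM,
    POSITIVE,
    UNREPORTED,
    EventLog,
    LHTest,
    MenstruationDay,
    UserProfile,
    lh_frame,
    menses_frame,
)
from .stats import AGE_GROUPS

#: integer age bounds per group label
_AGE_BOUNDS = {"18-24": (18, 24), "25-29": (25, 29), "30-34": (30, 34),
               "35-39": (35, 39), "40-55": (40, 55)}

#: cohort-composition age-group weights (young users dominate)
_DEFAULT_AGE_PROBS = {"18-24": 0.404, "25-29": 0.243, "30-34": 0.174,
                      "35-39": 0.103, "40-55": 0.076}

#: survey answer weights patterned on the published cohort description
_DEFAULT_SURVEY_PROBS: dict[str, dict[str, float]] = {
    "smoking": {"Regularly": 0.14, "Sometimes": 0.12, "Do not smoke": 0.74},
    "alcohol": {"≥3 times a week": 0.06, "1-2 times a week": 0.19,
                "<2-3 times a month": 0.42, "None": 0.33},
    "stress": {"≥3 times a week": 0.33, "1-2 times a week": 0.32,
               "<3 times a month": 0.28, "None": 0.07},
    "physical_activity": {"≥3 times a week": 0.18, "1-2 times a week": 0.22,
                          "<3 times a month": 0.15, "None": 0.45},
    "relationship": {"Married or stable partner": 0.71, "Single": 0.10,
                     "No partner": 0.19},
    "trying_to_conceive": {"<1 month": 0.26, "1-3 months": 0.20,
                           "3-6 months": 0.12, ">6 months to 1 year": 0.11,
                           ">1 year": 0.31},
    "children": {"0": 0.71, "1 or 2": 0.25, "≥3": 0.04},
    "reproductive_disorders": {"Yes": 0.11, "No": 0.65, "I don't know": 0.24},
}

LATENT_MEAN_BOUNDS = (15.0, 60.0)  # truncation for m_i
LENGTH_CLIP = (15, 90)             # observed lengths stay segmentable


@dataclass
class SimulationParams:
    """Everything the generator draws from, under one seed.

    Defaults describe a plausible app cohort: population mean cycle
    28.5 d, between-woman SD 2.5 d, within-woman SD ~ Gamma(4, 0.5)
    (mean 2 d), periods of 3-7 days, 80% of bleeding days with a logged
    intensity, luteal length ~ N(14.5, 1.5) for the ~10% of women using
    LH tests, and roughly half of women answering any given survey
    question.
    """

    n_users: int = 50
    seed: int = 0
    age_group_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AGE_PROBS))
    bmi_lognormal: tuple[float, float] = (3.13, 0.16)  # ln-scale mu, sigma
    p_report_bmi: float = 0.23
    height_normal: tuple[float, float] = (165.0, 7.0)
    cycle_mean_population: float = 28.5
    between_woman_sd: float = 2.5
    within_woman_sd_gamma: tuple[float, float] = (4.0, 0.5)  # shape, scale
    n_completed_range: tuple[int, int] = (3, 11)
    period_length_range: tuple[int, int] = (3, 7)
    intensity_ramp: tuple[str, ...] = (MEDIUM, HEAVY, HEAVY, MEDIUM, LIGHT)
    p_intensity_logged: float = 0.8
    luteal_mean: float = 14.5
    luteal_sd: float = 1.5
    p_lh_user: float = 0.1
    p_negative_lh: float = 0.0
    p_pregnancy_flag: float = 0.05
    p_oc_flag: float = 0.05
    p_survey_response: float = 0.5
    survey_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_SURVEY_PROBS.items()})
    extraction_date: dt.date = dt.date(2018, 12, 1)
    #: optional planted effects, keyed by age group label
    mean_shift_by_age_group: dict[str, float] = field(default_factory=dict)
    within_sd_shift_by_age_group: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        probs = [self.p_report_bmi, self.p_intensity_logged, self.p_lh_user,
                 self.p_negative_lh, self.p_pregnancy_flag, self.p_oc_flag,
                 self.p_survey_response]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if self.n_users < 0:
            raise ConfigError("n_users must be >= 0")
        if self.between_woman_sd <= 0 or self.luteal_sd <= 0:
            raise ConfigError("sds must be > 0")
        if any(v <= 0 for v in self.within_woman_sd_gamma):
            raise ConfigError("gamma shape and scale must be > 0")
        for name, (lo, hi) in (("n_completed_range", self.n_completed_range),
                               ("period_length_range", self.period_length_range)):
            if lo > hi or lo < 1:
                raise ConfigError(f"{name} must be a nonempty positive range")
        for probs_map in (self.age_group_probs, *self.survey_probs.values()):
            if any(p < 0 for p in probs_map.values()) or sum(probs_map.values()) <= 0:
                raise ConfigError("category probabilities must be >= 0, sum > 0")
        if not self.intensity_ramp:
            raise ConfigError("intensity_ramp must be nonempty")

    @property
    def within_sd_mean(self) -> float:
        shape, scale = self.within_woman_sd_gamma
        return shape * scale


@dataclass
class GroundTruth:
    """Latent truths per generated user and cycle."""

    users: pd.DataFrame   # user_id, age..., latent_mean, within_sd, ...
    cycles: pd.DataFrame  # user_id, cycle_index, start, length, luteal...


def default_params(profile: str, seed: int = 0, **overrides) -> SimulationParams:
    """Named parameter sets: ``tiny`` (50 users, unit-test scale) and
    ``paper_like`` (5,000 users, published-cohort-like composition)."""
    if profile == "tiny":
        params = SimulationParams(n_users=50, seed=seed)
    elif profile == "paper_like":
        params = SimulationParams(n_users=5000, seed=seed)
    else:
        raise ConfigError(f"unknown simulation profile {profile!r}")
    params = replace(params, **overrides)
    params.validate()
    return params


def _choice(rng: np.random.Generator, probs: dict[str, float]) -> str:
    labels = list(probs)
    weights = np.array([probs[k] for k in labels], dtype=float)
    return labels[rng.choice(len(labels), p=weights / weights.sum())]


def _ramp_intensity(ramp: tuple[str, ...], day_index: int) -> str:
    # truncated to short periods, extended with the last element for long
    if day_index < len(ramp):
        return ramp[day_index]
    return ramp[-1]


def generate_cohort(params: SimulationParams) -> tuple[EventLog, GroundTruth]:
    """Generate one cohort snapshot plus its ground truth.

    Each user's stream: her completed cycle lengths are drawn first, then
    period starts are laid backwards from the extraction date so the last
    period opens a current (incomplete) cycle.
    """
    params.validate()
    profiles: dict[str, UserProfile] = {}
    menses: list[MenstruationDay] = []
    lh_tests: list[LHTest] = []
    user_rows = []
    cycle_rows = []

    for i in range(params.n_users):
        rng = np.random.default_rng([params.seed, i])
        uid = f"u{i:06d}"

        group = _choice(rng, params.age_group_probs)
        lo, hi = _AGE_BOUNDS[group]
        age = int(rng.integers(lo, hi + 1))
        pregnancy = bool(rng.random() < params.p_pregnancy_flag)
        oc = bool(rng.random() < params.p_oc_flag)

        # latent cycle-length law for this woman
        mean_target = (params.cycle_mean_population
                       + params.mean_shift_by_age_group.get(group, 0.0))
        m_i = float(rng.normal(mean_target, params.between_woman_sd))
        while not LATENT_MEAN_BOUNDS[0] <= m_i <= LATENT_MEAN_BOUNDS[1]:
            m_i = float(rng.normal(mean_target, params.between_woman_sd))
        shape, scale = params.within_woman_sd_gamma
        s_i = float(rng.gamma(shape, scale)
                    + params.within_sd_shift_by_age_group.get(group, 0.0))
        s_i = max(s_i, 1e-9)

        n_completed = int(rng.integers(params.n_completed_range[0],
                                       params.n_completed_range[1] + 1))
        lengths = np.clip(
            np.rint(rng.normal(m_i, s_i, size=n_completed)),
            LENGTH_CLIP[0], LENGTH_CLIP[1],
        ).astype(int)

        plo, phi = params.period_length_range
        period_lengths = rng.integers(plo, phi + 1, size=n_completed + 1)
        # current-cycle progress: far enough in for its period to be logged
        offset = int(rng.integers(5, 21))
        offset = max(offset, int(period_lengths[-1]))
        first_start = params.extraction_date - dt.timedelta(
            days=int(lengths.sum()) + offset)

        is_lh_user = bool(rng.random() < params.p_lh_user)
        report_bmi = bool(rng.random() < params.p_report_bmi)

        start = first_start
        starts = []
        for k in range(n_completed + 1):
            starts.append(start)
            completed = k < n_completed
            p_len = int(period_lengths[k])
            for d in range(p_len):
                date = start + dt.timedelta(days=d)
                if date > params.extraction_date:
                    break
                logged = rng.random() < params.p_intensity_logged
                intensity = _ramp_intensity(params.intensity_ramp, d) if logged else UNREPORTED
                menses.append(MenstruationDay(uid, date, intensity))

            luteal = None
            ovulation_day = None
            if completed:
                length = int(lengths[k])
                if is_lh_user:
                    luteal = int(round(float(rng.normal(params.luteal_mean,
                                                        params.luteal_sd))))
                    luteal = int(np.clip(luteal, 5, length - 2))
                    ovulation_day = length - luteal + 1  # >= 3
                    test_date = start + dt.timedelta(days=ovulation_day - 2)
                    lh_tests.append(LHTest(uid, test_date, POSITIVE))
                    if params.p_negative_lh and rng.random() < params.p_negative_lh:
                        neg_date = start + dt.timedelta(days=max(ovulation_day - 5, 1))
                        if neg_date != test_date:
                            lh_tests.append(LHTest(uid, neg_date, "negative"))
                cycle_rows.append({
                    "user_id": uid, "cycle_index": k,
                    "start_date": start.isoformat(), "length_days": length,
                    "is_current": False, "luteal_days": luteal,
                    "ovulation_day": ovulation_day,
                })
                start = start + dt.timedelta(days=length)
            else:
                cycle_rows.append({
                    "user_id": uid, "cycle_index": k,
                    "start_date": start.isoformat(), "length_days": None,
                    "is_current": True, "luteal_days": None,
                    "ovulation_day": None,
                })

        height = None
        weight_log: list[tuple[dt.date, float]] = []
        bmi_true = None
        if report_bmi:
            height = float(np.clip(rng.normal(*params.height_normal), 140.0, 195.0))
            bmi_true = float(rng.lognormal(*params.bmi_lognormal))
            weight = bmi_true * (height / 100.0) ** 2
            latest_date = params.extraction_date - dt.timedelta(
                days=int(rng.integers(0, 30)))
            if rng.random() < 0.3:  # an earlier, superseded weight entry
                earlier = latest_date - dt.timedelta(days=int(rng.integers(30, 200)))
                weight_log.append((earlier, round(weight * float(rng.normal(1.0, 0.05)), 1)))
            weight_log.append((latest_date, round(weight, 1)))
            bmi_true = weight_log[-1][1] / (height / 100.0) ** 2

        survey: dict[str, str] = {}
        for fld, cat_probs in params.survey_probs.items():
            if rng.random() < params.p_survey_response:
                survey[fld] = _choice(rng, cat_probs)

        profiles[uid] = UserProfile(
            user_id=uid, age_years=age, height_cm=height,
            weight_log=weight_log, pregnancy_logged=pregnancy,
            oc_reminder=oc, survey=survey,
        )
        user_rows.append({
            "user_id": uid, "age_years": age, "age_group": group,
            "latent_mean": m_i, "within_sd": s_i,
            "n_completed": n_completed, "is_lh_user": is_lh_user,
            "pregnancy_logged": pregnancy, "oc_reminder": oc,
            "bmi": bmi_true,
        })

    log = EventLog(
        profiles=profiles,
        menses=menses_frame(menses),
        lh_tests=lh_frame(lh_tests),
        extraction_date=params.extraction_date,
    )
    truth = GroundTruth(
        users=pd.DataFrame(user_rows),
        cycles=pd.DataFrame(
            cycle_rows,
            columns=["user_id", "cycle_index", "start_date", "length_days",
                     "is_current", "luteal_days", "ovulation_day"],
        ),
    )
    return log, truth
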