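"""Cohort inclusion/exclusion rules.

A user enters the analysis cohort when she is of age, has logged neither a
pregnancy nor oral-contraceptive reminders, and has recorded at least three
menstrual cycles — two completed plus one current — the minimum needed for
a per-woman median.  Excluded users are tallied under the *first* failing
rule in the fixed order age → pregnancy → OC reminder → cycles, so the
tally is a deterministic partition of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError, ReferentialError
from .events import EventLog
from .segmentation import Cycle


@dataclass
class InclusionConfig:
    min_age: int = 18
    min_completed_cycles: int = 2
    require_current_cycle: bool = True
    exclude_pregnancy: bool = True
    exclude_oc: bool = True

    def validate(self) -> None:
        if self.min_age < 0 or self.min_completed_cycles < 0:
            raise ConfigError("min_age and min_completed_cycles must be >= 0")


@dataclass
class ExclusionTally:
    """Counts of excluded users by first-failing rule, plus the included N."""

    under_age: int = 0
    pregnancy: int = 0
    oc_reminder: int = 0
    too_few_cycles: int = 0
    n_included: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "under_age": self.under_age,
            "pregnancy": self.pregnancy,
            "oc_reminder": self.oc_reminder,
            "too_few_cycles": self.too_few_cycles,
            "n_included": self.n_included,
        }

    @property
    def n_excluded(self) -> int:
        return self.under_age + self.pregnancy + self.oc_reminder + self.too_few_cycles


def apply_inclusion_criteria(
    log: EventLog,
    cycles_by_user: dict[str, list[Cycle]],
    config: InclusionConfig | None = None,
) -> tuple[set[str], ExclusionTally]:
    """Partition the log's users into included set and exclusion tally.

    ``cycles_by_user`` must come from segmenting the same log; a user with
    cycles but no profile is a referential error.  Users absent from
    ``cycles_by_user`` count as having zero cycles.
    """
    config = config or InclusionConfig()
    config.validate()

    orphans = set(cycles_by_user) - set(log.profiles)
    if orphans:
        raise ReferentialError(
            f"cycles for users missing from the log: {sorted(orphans)}"
        )

    included: set[str] = set()
    tally = ExclusionTally()
    for uid, profile in log.profiles.items():
        if profile.age_years < config.min_age:
            tally.under_age += 1
            continue
        if config.exclude_pregnancy and profile.pregnancy_logged:
            tally.pregnancy += 1
            continue
        if config.exclude_oc and profile.oc_reminder:
            tally.oc_reminder += 1
            continue
        cycles = cycles_by_user.get(uid, [])
        n_completed = sum(1 for c in cycles if not c.is_current)
        has_current = any(c.is_current for c in cycles)
        if n_completed < config.min_completed_cycles or (
            config.require_current_cycle and not has_current
        ):
            tally.too_few_cycles += 1
            continue
        included.add(uid)
    tally.n_included = len(included)
    return included, tally
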