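"""Ordinal menstrual-flow scoring and per-cycle / per-woman categories.

Each logged bleeding day scores light=1, medium=2, heavy=3; days without a
reported intensity carry no score.  A period of 1–2 days is classified
light outright.  For periods of three days or more, the mean score over
the logged days is taken when at least half of the period's days have a
reported intensity, and the cycle is classed light (mean < 1.5), medium
(1.5 ≤ mean < 2.4) or heavy (mean ≥ 2.4); otherwise the cycle's flow is
``not_tracked``.  Example: a fully logged L,M,H,H,M,L period averages
(1+2+3+3+2+1)/6 = 2 → medium.

The scores are ordinal conveniences, not volumes of blood loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType

from .errors import ContractError
from .events import HEAVY, LIGHT, MEDIUM, UNREPORTED
from .segmentation import Period

NOT_TRACKED = "not_tracked"
FLOW_CATEGORIES = (LIGHT, MEDIUM, HEAVY)

_DEFAULT_SCORES = MappingProxyType({LIGHT: 1, MEDIUM: 2, HEAVY: 3})


@dataclass(frozen=True)
class FlowConfig:
    scores: MappingProxyType = field(default_factory=lambda: _DEFAULT_SCORES)
    light_upper: float = 1.5   # mean below this -> light
    heavy_lower: float = 2.4   # mean at or above this -> heavy
    min_logged_fraction: float = 0.5
    short_period_max: int = 2  # periods this short are light by rule

    def validate(self) -> None:
        from .errors import ConfigError

        if not self.light_upper < self.heavy_lower:
            raise ConfigError("light_upper must be < heavy_lower")
        if not 0 < self.min_logged_fraction <= 1:
            raise ConfigError("min_logged_fraction must be in (0, 1]")


DEFAULT_FLOW_CONFIG = FlowConfig()


@dataclass(frozen=True)
class FlowResult:
    """Flow classification of one cycle's period."""

    period: Period
    mean_score: float | None
    category: str  # light / medium / heavy / not_tracked


def intensity_score(intensity: str, config: FlowConfig = DEFAULT_FLOW_CONFIG) -> int | None:
    """Score one day's intensity; ``None`` (no score) for unreported."""
    if intensity == UNREPORTED:
        return None
    try:
        return config.scores[intensity]
    except KeyError:
        raise ContractError(f"unknown intensity {intensity!r}") from None


def cycle_flow_category(period: Period, config: FlowConfig = DEFAULT_FLOW_CONFIG) -> FlowResult:
    """Classify one period per the short-period, coverage and mean rules.

    The logged fraction is taken over the period's day span, so unlogged
    days bridged inside the period count against tracking coverage.
    """
    if not period.bleeding_days:
        raise ContractError("cannot classify an empty period")

    if period.length_days <= config.short_period_max:
        return FlowResult(period, None, LIGHT)

    scores = [
        s for _, intensity in period.bleeding_days
        if (s := intensity_score(intensity, config)) is not None
    ]
    if len(scores) / period.length_days < config.min_logged_fraction:
        return FlowResult(period, None, NOT_TRACKED)

    mean = sum(scores) / len(scores)
    if mean < config.light_upper:
        category = LIGHT
    elif mean < config.heavy_lower:
        category = MEDIUM
    else:
        category = HEAVY
    return FlowResult(period, mean, category)


#: heavier-wins order for per-woman tie-breaking
_HEAVINESS = {LIGHT: 0, MEDIUM: 1, HEAVY: 2}


def woman_flow_category(results: list[FlowResult]) -> str | None:
    """Modal flow category over a woman's classified cycles.

    Cycles classed ``not_tracked`` are ignored; ties break toward the
    heavier category; with no classifiable cycle the result is absent.
    """
    if not results:
        raise ContractError("need at least one FlowResult")
    counts: dict[str, int] = {}
    for r in results:
        if r.category != NOT_TRACKED:
            counts[r.category] = counts.get(r.category, 0) + 1
    if not counts:
        return None
    return max(counts, key=lambda c: (counts[c], _HEAVINESS[c]))
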