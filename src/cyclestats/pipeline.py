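"""End-to-end orchestration: events → cycles → cohort → tables.

:func:`analyze_event_log` is the library entry point; it returns a
:class:`CohortResults` carrying every intermediate product (segmented
cycles, inclusion tally, per-woman summaries, phase estimates, the tidy
cohort frame and the stratified tables).  :func:`run_pipeline` wraps it
with file I/O and a run manifest for the command line.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .events import EventLog, read_event_log, write_event_log
from .filters import ExclusionTally, InclusionConfig, apply_inclusion_criteria
from .flow import DEFAULT_FLOW_CONFIG, FlowConfig, FlowResult, cycle_flow_category, woman_flow_category
from .phases import PhaseEstimate, estimate_phases_for_user
from .segmentation import (
    DEFAULT_MERGE_GAP_DAYS,
    MAX_PLAUSIBLE_DAYS,
    MIN_PLAUSIBLE_DAYS,
    Cycle,
    cycles_to_frame,
    segment_log,
)
from .simulate import GroundTruth, default_params, generate_cohort
from .stats import Anthropometrics, CycleSummary, anthropometrics, summarize_woman
from .tables import CohortTables, build_cohort_frame, build_tables

logger = logging.getLogger("cyclestats")


@dataclass
class SegmentationConfig:
    merge_gap_days: int = DEFAULT_MERGE_GAP_DAYS
    min_plausible: int = MIN_PLAUSIBLE_DAYS
    max_plausible: int = MAX_PLAUSIBLE_DAYS
    exclude_flagged: bool = False  # drop flagged cycles from length stats


@dataclass
class CohortResults:
    """Everything computed for one analyzed cohort snapshot."""

    log: EventLog
    cycles_by_user: dict[str, list[Cycle]]
    included: set[str]
    tally: ExclusionTally
    summaries: dict[str, CycleSummary]
    anthro: dict[str, Anthropometrics]
    flow_results: dict[str, list[FlowResult]]
    flow_by_user: dict[str, str | None]
    phase_estimates: list[PhaseEstimate]
    cohort: pd.DataFrame
    tables: CohortTables

    @property
    def n_included(self) -> int:
        return len(self.included)


def analyze_event_log(
    log: EventLog,
    inclusion: InclusionConfig | None = None,
    segmentation: SegmentationConfig | None = None,
    flow: FlowConfig | None = None,
) -> CohortResults:
    """Run the full analysis on an event log.

    Stages: segment every user's bleeding days into cycles; apply the
    inclusion rules; per included woman classify each cycle's flow and
    summarize completed cycle lengths; estimate ovulation and phase
    lengths from LH tests; assemble the per-woman cohort frame and the
    stratified tables.
    """
    inclusion = inclusion or InclusionConfig()
    segmentation = segmentation or SegmentationConfig()
    flow = flow or DEFAULT_FLOW_CONFIG

    cycles_by_user = segment_log(
        log,
        merge_gap_days=segmentation.merge_gap_days,
        min_plausible=segmentation.min_plausible,
        max_plausible=segmentation.max_plausible,
    )
    logger.info("segmented %d users", len(cycles_by_user))

    included, tally = apply_inclusion_criteria(log, cycles_by_user, inclusion)
    logger.info("included %d of %d users", len(included), log.n_users)

    lh_by_user: dict[str, list[tuple[dt.date, str]]] = {uid: [] for uid in log.profiles}
    for uid, date, result in zip(
        log.lh_tests["user_id"], log.lh_tests["date"], log.lh_tests["result"]
    ):
        lh_by_user[uid].append((date, result))

    summaries: dict[str, CycleSummary] = {}
    anthro: dict[str, Anthropometrics] = {}
    flow_results: dict[str, list[FlowResult]] = {}
    flow_by_user: dict[str, str | None] = {}
    phase_estimates: list[PhaseEstimate] = []

    for uid in sorted(included):
        cycles = cycles_by_user[uid]
        lengths = [
            c.length_days for c in cycles
            if not c.is_current and not (segmentation.exclude_flagged and c.flagged)
        ]
        summaries[uid] = summarize_woman(lengths, user_id=uid)
        anthro[uid] = anthropometrics(log.profiles[uid])
        results = [cycle_flow_category(c.period, flow) for c in cycles]
        flow_results[uid] = results
        flow_by_user[uid] = woman_flow_category(results)
        phase_estimates.extend(
            estimate_phases_for_user(cycles, lh_by_user[uid], log.extraction_date)
        )

    cohort = build_cohort_frame(log.profiles, summaries, anthro, flow_by_user)
    tables = build_tables(cohort, phase_estimates)
    return CohortResults(
        log=log,
        cycles_by_user=cycles_by_user,
        included=included,
        tally=tally,
        summaries=summaries,
        anthro=anthro,
        flow_results=flow_results,
        flow_by_user=flow_by_user,
        phase_estimates=phase_estimates,
        cohort=cohort,
        tables=tables,
    )


@dataclass
class PipelineConfig:
    """Pipeline run configuration (YAML-loadable).

    Exactly one input source: either the three event-CSV paths together
    with ``extraction_date``, or a named simulation profile.
    """

    profiles_path: str | None = None
    menses_path: str | None = None
    lh_path: str | None = None
    extraction_date: dt.date | None = None
    simulate_profile: str | None = None
    simulate_n_users: int | None = None
    seed: int = 0
    inclusion: InclusionConfig = field(default_factory=InclusionConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    output_dir: str = "cyclestats_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        has_paths = any([self.profiles_path, self.menses_path, self.lh_path])
        has_profile = self.simulate_profile is not None
        if has_paths == has_profile:
            raise ConfigError(
                "specify exactly one of input paths or simulate_profile"
            )
        if has_paths:
            if not all([self.profiles_path, self.menses_path, self.lh_path]):
                raise ConfigError("all three event-CSV paths are required")
            if self.extraction_date is None:
                raise ConfigError("extraction_date is required with input paths")
        self.inclusion.validate()
        self.flow.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "inclusion" in raw:
            raw["inclusion"] = InclusionConfig(**raw["inclusion"])
        if "segmentation" in raw:
            raw["segmentation"] = SegmentationConfig(**raw["segmentation"])
        if "flow" in raw:
            raw["flow"] = FlowConfig(**raw["flow"])
        if isinstance(raw.get("extraction_date"), str):
            raw["extraction_date"] = dt.date.fromisoformat(raw["extraction_date"])
        return cls(**raw)


def _config_echo(config: PipelineConfig) -> dict[str, Any]:
    def convert(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, dt.date):
            return obj.isoformat()
        if isinstance(obj, Mapping):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return convert(config)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured run end to end; returns the manifest."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth: GroundTruth | None = None
    if config.simulate_profile is not None:
        overrides = {"seed": config.seed}
        if config.simulate_n_users is not None:
            overrides["n_users"] = config.simulate_n_users
        params = default_params(config.simulate_profile, **overrides)
        log, truth = generate_cohort(params)
        write_event_log(log, out / "events")
        truth.users.to_csv(out / "ground_truth_users.csv", index=False)
        truth.cycles.to_csv(out / "ground_truth_cycles.csv", index=False)
    else:
        log = read_event_log(
            config.profiles_path, config.menses_path, config.lh_path,
            config.extraction_date,
        )

    results = analyze_event_log(
        log, inclusion=config.inclusion,
        segmentation=config.segmentation, flow=config.flow,
    )

    cycles_to_frame(results.cycles_by_user).to_csv(out / "cycles.csv", index=False)
    pd.DataFrame(
        [{"rule": k, "n": v} for k, v in results.tally.as_dict().items()]
    ).to_csv(out / "exclusions.csv", index=False)

    flow_rows = [
        {"user_id": uid, "cycle_start": r.period.start_date.isoformat(),
         "mean_score": r.mean_score, "category": r.category}
        for uid, rs in results.flow_results.items() for r in rs
    ]
    pd.DataFrame(
        flow_rows, columns=["user_id", "cycle_start", "mean_score", "category"]
    ).to_csv(out / "flows.csv", index=False)

    results.cohort.to_csv(out / "summaries.csv", index=False)

    phase_rows = [
        {"user_id": e.user_id, "cycle_start": e.cycle_start.isoformat(),
         "lh_positive_day": e.lh_positive_day, "ovulation_day": e.ovulation_day,
         "follicular_days": e.follicular_days, "luteal_days": e.luteal_days}
        for e in results.phase_estimates
    ]
    pd.DataFrame(
        phase_rows,
        columns=["user_id", "cycle_start", "lh_positive_day", "ovulation_day",
                 "follicular_days", "luteal_days"],
    ).to_csv(out / "phases.csv", index=False)

    results.tables.write(out)

    n_cycles = sum(len(c) for c in results.cycles_by_user.values())
    n_completed = sum(
        1 for cs in results.cycles_by_user.values() for c in cs if not c.is_current
    )
    manifest = {
        "version": __version__,
        "config": _config_echo(config),
        "seed": config.seed,
        "counts": {
            "n_users": log.n_users,
            "n_cycles": n_cycles,
            "n_completed_cycles": n_completed,
            "n_included": results.n_included,
            "exclusions": results.tally.as_dict(),
            "n_phase_estimates": len(results.phase_estimates),
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %d included users", results.n_included)
    return manifest
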