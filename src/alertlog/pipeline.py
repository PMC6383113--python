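"""End-to-end orchestration: events + rosters -> analysis table."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
from zoneinfo import ZoneInfo

import pandas as pd

from .analysis import build_analysis_table
from .config import DEFAULT_TZ
from .immediate import ImmediateActionResult, evaluate_immediate_actions
from .openings import OpeningRecord, find_first_openings
from .schema import Alert, LogEvent
from .subsequent import SubsequentActionResult, evaluate_subsequent_actions


@dataclass(frozen=True)
class PipelineResult:
    openings: list[OpeningRecord]
    immediate: list[ImmediateActionResult]
    subsequent: list[SubsequentActionResult]
    table: pd.DataFrame


def run_pipeline(
    events: Sequence[LogEvent],
    alerts: Sequence[Alert],
    tz: ZoneInfo = DEFAULT_TZ,
    context: Optional[Sequence[dict]] = None,
) -> PipelineResult:
    """Opening detection -> immediate classification -> two-day detection -> join."""
    events = sorted(events, key=LogEvent.sort_key)
    openings = find_first_openings(events, alerts, tz)
    immediate = evaluate_immediate_actions(events, alerts, openings)
    subsequent = evaluate_subsequent_actions(events, alerts, openings, tz)
    table = build_analysis_table(alerts, openings, immediate, subsequent, context)
    return PipelineResult(
        openings=openings, immediate=immediate, subsequent=subsequent, table=table
    )


__all__ = ["PipelineResult", "run_pipeline"]
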