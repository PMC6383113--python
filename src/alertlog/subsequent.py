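"""Two-day subsequent-action detection.

Physicians often open alerts between visits and come back to the chart
later, so this stage widens the lens: from the instant of the alert's first
opening (by anyone) through the end of the *next* local calendar day, did the
addressed PCP touch the alert's patient in the EHR?  Actions are classified
as general (any section view, alert-link summary, or order for that patient),
medication-specific (medication-list view or medication order), and
laboratory-specific (laboratory view, lab-flagged results view, or lab
order).  The module reports temporal co-occurrence only — it makes no causal
claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Sequence
from zoneinfo import ZoneInfo

from .config import DEFAULT_TZ
from .openings import OpeningRecord
from .schema import Action, Alert, LogEvent, OrderKind, SectionCode


@dataclass(frozen=True)
class SubsequentActionResult:
    alert_id: str
    window_start: datetime
    window_end: datetime
    general: bool
    medication_specific: bool
    laboratory_specific: bool


def action_window(
    first_open_ts: datetime, tz: ZoneInfo = DEFAULT_TZ
) -> tuple[datetime, datetime]:
    """[opening instant, end of the following local calendar day).

    "Day of opening and the following day" is calendar-day, not 48-hour,
    semantics: the window always ends at the second local midnight after the
    opening day, regardless of the opening's time of day.
    """
    if first_open_ts.tzinfo is None or first_open_ts.tzinfo.utcoffset(
        first_open_ts
    ) is None:
        raise ValueError("first_open_ts must be timezone-aware")
    local = first_open_ts.astimezone(tz)
    end_local = datetime(
        local.year, local.month, local.day, tzinfo=tz
    ) + timedelta(days=2)
    return (first_open_ts, end_local)


def _classify(e: LogEvent) -> tuple[bool, bool]:
    """(medication_specific, laboratory_specific) for one qualifying event."""
    med = lab = False
    if e.action is Action.section_view:
        if e.section is SectionCode.medications:
            med = True
        elif e.section is SectionCode.laboratory:
            lab = True
        elif e.section is SectionCode.results and e.lab_result:
            lab = True
    elif e.action is Action.order_placed:
        if e.order.order_kind is OrderKind.medication:
            med = True
        else:
            lab = True
    return med, lab


def detect_actions(
    events: Sequence[LogEvent],
    pcp_id: str,
    target_patient_id: str,
    window: tuple[datetime, datetime],
) -> SubsequentActionResult:
    """Scan sorted events for qualifying PCP actions inside the window.

    Flags are monotone in the event set, and the specific flags imply the
    general one by construction.
    """
    start, end = window
    general = med = lab = False
    for e in events:
        if (
            e.actor_id == pcp_id
            and e.patient_id == target_patient_id
            and start <= e.ts < end
            and e.action in (Action.section_view, Action.order_placed)
        ):
            general = True
            m, l = _classify(e)
            med = med or m
            lab = lab or l
    return SubsequentActionResult(
        alert_id="",
        window_start=start,
        window_end=end,
        general=general,
        medication_specific=med,
        laboratory_specific=lab,
    )


def evaluate_subsequent_actions(
    events: Sequence[LogEvent],
    alerts: Sequence[Alert],
    openings: Sequence[OpeningRecord],
    tz: ZoneInfo = DEFAULT_TZ,
) -> list[SubsequentActionResult]:
    """Run the two-day stage for every *opened* alert.

    The window anchors at the first opening irrespective of who opened it;
    the tracked actor is always the addressed PCP (a staff member may triage
    the InBasket, but the outcome of interest is physician follow-up).
    Never-opened alerts are skipped.
    """
    open_map = {o.alert_id: o for o in openings}
    by_pcp_patient: dict[tuple[str, str], list[LogEvent]] = {}
    for e in events:
        if e.patient_id is not None and e.action in (
            Action.section_view,
            Action.order_placed,
        ):
            by_pcp_patient.setdefault((e.actor_id, e.patient_id), []).append(e)

    results = []
    for alert in alerts:
        rec = open_map.get(alert.alert_id)
        if rec is None or rec.never_opened:
            continue
        window = action_window(rec.first_open_ts, tz)
        cand = by_pcp_patient.get((alert.pcp_id, alert.patient_id), [])
        res = detect_actions(cand, alert.pcp_id, alert.patient_id, window)
        results.append(
            SubsequentActionResult(
                alert_id=alert.alert_id,
                window_start=res.window_start,
                window_end=res.window_end,
                general=res.general,
                medication_specific=res.medication_specific,
                laboratory_specific=res.laboratory_specific,
            )
        )
    return results


__all__ = [
    "SubsequentActionResult",
    "action_window",
    "detect_actions",
    "evaluate_subsequent_actions",
]
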