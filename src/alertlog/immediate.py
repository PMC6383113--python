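"""Five-minute immediate-action classification and viewing-time attribution.

Only alerts whose *first* opener is the addressed PCP anchor this analysis:
the 5-minute window starts at that opening.  The first navigation event in
the half-open window [t_open, t_open + 300 s) decides whether the PCP
immediately engaged with the alert's patient: a chart-section view, an
alert-link summary, or an order for that patient counts as relevant; opening
a different patient's notification, viewing a different patient's chart, or
doing nothing for 5 minutes does not.

Access logs record openings, not closings, so "time with the alert on
display" is estimated as the gap from opening to the actor's next navigation
event (of any kind, any patient), capped at 300 s.  Time on the relevant
patient is the sum of dwell spans whose current event is a relevant-patient
view, each span ending at the actor's next event or the window end.  Passive
deliveries and InBasket message lifecycle events are not navigation and never
terminate a span.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional, Sequence

from .openings import OpeningRecord
from .schema import NAVIGATION_ACTIONS, Action, Alert, LogEvent, SectionCode

WINDOW_SECONDS = 300


@dataclass(frozen=True)
class ImmediateActionResult:
    alert_id: str
    evaluable: bool
    #: why an alert is not evaluable: "not_pcp_first" (someone else opened it
    #: first, or it was never opened) or "no_window_data" (empty window with
    #: no later navigation by the actor — nothing to estimate from).
    exclusion_reason: Optional[str] = None
    relevant: Optional[bool] = None
    #: the relevant section/"order" when relevant; otherwise one of
    #: "other_patient_notification", "other_patient_chart", "no_action".
    first_action: Optional[str] = None
    alert_display_seconds: Optional[int] = None
    relevant_patient_seconds: Optional[int] = None
    total_seconds: Optional[int] = None


def _is_navigation(e: LogEvent) -> bool:
    return e.action in NAVIGATION_ACTIONS


def extract_window(
    events: Sequence[LogEvent],
    actor_id: str,
    t_open: datetime,
    exclude_event_ids: frozenset[str] = frozenset(),
) -> list[LogEvent]:
    """Navigation events by ``actor_id`` in [t_open, t_open + 300 s).

    The triggering alert_opened event itself is excluded via
    ``exclude_event_ids``.  ``events`` must be sorted.
    """
    end = t_open + timedelta(seconds=WINDOW_SECONDS)
    return [
        e
        for e in events
        if e.actor_id == actor_id
        and t_open <= e.ts < end
        and _is_navigation(e)
        and e.event_id not in exclude_event_ids
    ]


def _is_relevant_patient_view(e: LogEvent, target_patient_id: str) -> bool:
    if e.patient_id != target_patient_id:
        return False
    return e.action in (Action.section_view, Action.order_placed)


def classify_first_action(
    window: Sequence[LogEvent], target_patient_id: str
) -> tuple[bool, str]:
    """Classify the window's first event.  Empty window -> (False, "no_action")."""
    if not window:
        return (False, "no_action")
    first = window[0]
    if _is_relevant_patient_view(first, target_patient_id):
        if first.action is Action.order_placed:
            return (True, "order")
        return (True, first.section.value)
    if first.action is Action.alert_opened:
        return (False, "other_patient_notification")
    return (False, "other_patient_chart")


def attribute_time(
    window: Sequence[LogEvent],
    t_open: datetime,
    target_patient_id: str,
    next_event_ts: Optional[datetime] = None,
) -> tuple[int, int, int]:
    """Return (alert_display_seconds, relevant_patient_seconds, total_seconds).

    ``next_event_ts`` is the actor's first navigation event at/after the
    window end, if any; it only matters for confirming that an empty window
    means "did nothing for 5 minutes" rather than missing data — the display
    estimate itself is capped at the window length either way.
    """
    window_end = t_open + timedelta(seconds=WINDOW_SECONDS)
    if not window:
        display = WINDOW_SECONDS
        return (display, 0, display)
    display = int((window[0].ts - t_open).total_seconds())
    display = min(display, WINDOW_SECONDS)
    relevant = 0
    for i, e in enumerate(window):
        if _is_relevant_patient_view(e, target_patient_id):
            span_end = window[i + 1].ts if i + 1 < len(window) else window_end
            relevant += int((span_end - e.ts).total_seconds())
    return (display, relevant, display + relevant)


class _ActorIndex:
    """Per-actor sorted navigation timestamps for O(log n) lookahead."""

    def __init__(self, events: Sequence[LogEvent]):
        self._by_actor: dict[str, list[LogEvent]] = {}
        for e in events:
            if _is_navigation(e):
                self._by_actor.setdefault(e.actor_id, []).append(e)
        self._keys: dict[str, list[tuple[datetime, str]]] = {
            actor: [ev.sort_key() for ev in evs]
            for actor, evs in self._by_actor.items()
        }

    def window(
        self, actor_id: str, t_open: datetime, exclude: frozenset[str]
    ) -> list[LogEvent]:
        evs = self._by_actor.get(actor_id, [])
        keys = self._keys.get(actor_id, [])
        end = t_open + timedelta(seconds=WINDOW_SECONDS)
        lo = bisect.bisect_left(keys, (t_open, ""))
        hi = bisect.bisect_left(keys, (end, ""))
        return [e for e in evs[lo:hi] if e.event_id not in exclude]

    def has_event_at_or_after(self, actor_id: str, ts: datetime) -> bool:
        keys = self._keys.get(actor_id, [])
        return bisect.bisect_left(keys, (ts, "")) < len(keys)


def evaluate_immediate_actions(
    events: Sequence[LogEvent],
    alerts: Sequence[Alert],
    openings: Sequence[OpeningRecord],
) -> list[ImmediateActionResult]:
    """Run the immediate-action stage for every alert.

    Alerts not first-opened by the addressed PCP are not evaluable here.  An
    alert whose window is empty *and* whose actor shows no navigation at all
    after the opening is flagged ``no_window_data`` (there is no terminating
    evidence from which to estimate anything); an empty window followed by
    later activity is the genuine "did nothing for 5 minutes" case.
    """
    index = _ActorIndex(events)
    open_map = {o.alert_id: o for o in openings}
    trigger_ids: dict[str, frozenset[str]] = {}
    for e in events:
        if e.action is Action.alert_opened and e.alert_id is not None:
            trigger_ids.setdefault(e.alert_id, frozenset())
            trigger_ids[e.alert_id] = trigger_ids[e.alert_id] | {e.event_id}

    results = []
    for alert in alerts:
        rec = open_map.get(alert.alert_id)
        if rec is None or rec.never_opened or not rec.opened_by_pcp:
            results.append(
                ImmediateActionResult(
                    alert_id=alert.alert_id,
                    evaluable=False,
                    exclusion_reason="not_pcp_first",
                )
            )
            continue
        t_open = rec.first_pcp_open_ts
        window = index.window(
            alert.pcp_id, t_open, trigger_ids.get(alert.alert_id, frozenset())
        )
        if not window:
            window_end = t_open + timedelta(seconds=WINDOW_SECONDS)
            if not index.has_event_at_or_after(alert.pcp_id, window_end):
                results.append(
                    ImmediateActionResult(
                        alert_id=alert.alert_id,
                        evaluable=False,
                        exclusion_reason="no_window_data",
                    )
                )
                continue
        relevant, category = classify_first_action(window, alert.patient_id)
        display, rel_secs, total = attribute_time(window, t_open, alert.patient_id)
        results.append(
            ImmediateActionResult(
                alert_id=alert.alert_id,
                evaluable=True,
                relevant=relevant,
                first_action=category,
                alert_display_seconds=display,
                relevant_patient_seconds=rel_secs,
                total_seconds=total,
            )
        )
    return results


__all__ = [
    "WINDOW_SECONDS",
    "ImmediateActionResult",
    "extract_window",
    "classify_first_action",
    "attribute_time",
    "evaluate_immediate_actions",
]
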