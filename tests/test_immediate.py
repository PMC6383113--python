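"""5-minute window extraction, first-action classification, time attribution."""

from __future__ import annotations

from datetime import timedelta

import numpy as np
import pytest

from alertlog.immediate import (
    WINDOW_SECONDS,
    attribute_time,
    classify_first_action,
    evaluate_immediate_actions,
    extract_window,
)
from alertlog.openings import find_first_openings
from alertlog.schema import (
    Action,
    ActorRole,
    Alert,
    AlertType,
    LogEvent,
    OrderDetail,
    OrderKind,
    SectionCode,
)
from conftest import dt

T0 = dt(2011, 3, 1, 10, 0, 0)
PCP = "PCP0"
PT = "PT0"


def view(eid, offset_s, patient=PT, section=SectionCode.encounters, actor=PCP):
    return LogEvent(
        event_id=eid, ts=T0 + timedelta(seconds=offset_s), actor_id=actor,
        actor_role=ActorRole.pcp, action=Action.section_view,
        patient_id=patient, section=section,
    )


def opened(eid, offset_s, alert_id="A9", actor=PCP):
    return LogEvent(
        event_id=eid, ts=T0 + timedelta(seconds=offset_s), actor_id=actor,
        actor_role=ActorRole.pcp, action=Action.alert_opened, alert_id=alert_id,
    )


class TestExtractWindow:
    def test_halfopen_window_boundaries(self):
        events = [view("E1", 299), view("E2", 300)]
        w = extract_window(events, PCP, T0)
        assert [e.event_id for e in w] == ["E1"]

    def test_other_actor_excluded(self):
        events = [view("E1", 10, actor="PCP1")]
        assert extract_window(events, PCP, T0) == []

    def test_trigger_event_excluded(self):
        trig = opened("E0", 0, alert_id="A1")
        events = [trig, view("E1", 10)]
        w = extract_window(events, PCP, T0, exclude_event_ids=frozenset({"E0"}))
        assert [e.event_id for e in w] == ["E1"]

    def test_passive_delivery_not_a_window_action(self):
        delivered = LogEvent(
            event_id="E1", ts=T0 + timedelta(seconds=5), actor_id=PCP,
            actor_role=ActorRole.pcp, action=Action.alert_delivered,
            alert_id="A2",
        )
        assert extract_window([delivered], PCP, T0) == []


class TestClassifyFirstAction:
    def test_relevant_section_view(self):
        rel, cat = classify_first_action(
            [view("E1", 10, section=SectionCode.medications)], PT
        )
        assert rel and cat == "medications"

    def test_order_counts_as_relevant(self):
        e = LogEvent(
            event_id="E1", ts=T0 + timedelta(seconds=10), actor_id=PCP,
            actor_role=ActorRole.pcp, action=Action.order_placed, patient_id=PT,
            order=OrderDetail(order_kind=OrderKind.laboratory),
        )
        assert classify_first_action([e], PT) == (True, "order")

    def test_other_patient_notification(self):
        rel, cat = classify_first_action([opened("E1", 10)], PT)
        assert not rel and cat == "other_patient_notification"

    def test_other_patient_chart(self):
        rel, cat = classify_first_action([view("E1", 10, patient="PTX")], PT)
        assert not rel and cat == "other_patient_chart"

    def test_empty_window_is_no_action(self):
        assert classify_first_action([], PT) == (False, "no_action")


class TestAttributeTime:
    def test_display_then_relevant_then_other(self):
        # open at 0, relevant view at 20 s, other-patient event at 50 s
        w = [view("E1", 20), view("E2", 50, patient="PTX")]
        assert attribute_time(w, T0, PT) == (20, 30, 50)

    def test_empty_window_caps_display(self):
        assert attribute_time([], T0, PT) == (300, 0, 300)

    def test_short_display_no_action(self):
        w = [view("E1", 15, patient="PTX")]
        assert attribute_time(w, T0, PT) == (15, 0, 15)

    def test_relevant_span_runs_to_window_end(self):
        w = [view("E1", 250)]
        assert attribute_time(w, T0, PT) == (250, 50, 300)

    def test_matches_bruteforce_interval_oracle_on_random_windows(self):
        """Independent oracle: materialize each event's [start, next) interval,
        filter relevant-patient views, sum — exact agreement on 1,000 windows."""
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = int(rng.integers(0, 8))
            offsets = sorted(int(o) for o in rng.integers(1, 300, size=n))
            w = []
            for i, off in enumerate(offsets):
                patient = PT if rng.random() < 0.5 else "PTX"
                if rng.random() < 0.15:
                    w.append(opened(f"E{i}", off))
                else:
                    w.append(view(f"E{i}", off, patient=patient))
            display, relevant, total = attribute_time(w, T0, PT)

            # oracle
            if not w:
                exp_display, exp_relevant = WINDOW_SECONDS, 0
            else:
                bounds = [e.ts for e in w] + [T0 + timedelta(seconds=300)]
                exp_display = min(
                    int((w[0].ts - T0).total_seconds()), WINDOW_SECONDS
                )
                exp_relevant = sum(
                    int((bounds[i + 1] - e.ts).total_seconds())
                    for i, e in enumerate(w)
                    if e.action in (Action.section_view, Action.order_placed)
                    and e.patient_id == PT
                )
            assert (display, relevant) == (exp_display, exp_relevant)
            assert total == display + relevant
            assert 0 <= display <= 300 and 0 <= relevant <= 300
            assert total <= 300


def _mini_cohort(window_events, opener="pcp", trailing=True):
    """One alert plus supplied in-window events; returns (events, alerts)."""
    alert = Alert(
        alert_id="A1", alert_type=AlertType.information_only, pcp_id=PCP,
        patient_id=PT, delivery_ts=T0 - timedelta(hours=2),
    )
    actor = PCP if opener == "pcp" else f"{PCP}-staff"
    events = [
        LogEvent(
            event_id="D1", ts=alert.delivery_ts, actor_id=PCP,
            actor_role=ActorRole.pcp, action=Action.alert_delivered,
            alert_id="A1",
        ),
        LogEvent(
            event_id="O1", ts=T0, actor_id=actor,
            actor_role=ActorRole.pcp if opener == "pcp" else ActorRole.staff,
            action=Action.alert_opened, alert_id="A1",
        ),
        *window_events,
    ]
    if trailing:
        events.append(view("Z9", 90_000, patient=None,
                           section=SectionCode.nonclinical))
    return sorted(events, key=LogEvent.sort_key), [alert]


class TestEvaluability:
    def _run(self, events, alerts):
        openings = find_first_openings(events, alerts)
        return evaluate_immediate_actions(events, alerts, openings)[0]

    def test_staff_first_opening_not_evaluable(self):
        events, alerts = _mini_cohort([], opener="staff")
        res = self._run(events, alerts)
        assert not res.evaluable
        assert res.exclusion_reason == "not_pcp_first"

    def test_empty_window_without_later_activity_is_missing_data(self):
        events, alerts = _mini_cohort([], trailing=False)
        res = self._run(events, alerts)
        assert not res.evaluable
        assert res.exclusion_reason == "no_window_data"

    def test_empty_window_with_later_activity_is_no_action(self):
        events, alerts = _mini_cohort([], trailing=True)
        res = self._run(events, alerts)
        assert res.evaluable
        assert res.relevant is False
        assert res.first_action == "no_action"
        assert res.total_seconds == 300

    def test_relevant_window_classified_and_timed(self):
        events, alerts = _mini_cohort(
            [view("E1", 20), view("E2", 50, patient="PTX")]
        )
        res = self._run(events, alerts)
        assert res.evaluable and res.relevant
        assert (res.alert_display_seconds, res.relevant_patient_seconds,
                res.total_seconds) == (20, 30, 50)
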