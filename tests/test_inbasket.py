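"""InBasket replay reconstruction, quartile binning, covariate assembly."""

from __future__ import annotations

from datetime import timedelta

import numpy as np
import pytest

from alertlog.inbasket import (
    InBasketSnapshot,
    ReplayConsistencyError,
    build_context_covariates,
    quartile_bin,
    reconstruct_inbasket,
)
from alertlog.schema import Action, ActorRole, LogEvent
from alertlog.simulate import Cohort, TrafficModel, generate_cohort, generate_inbasket_traffic
from conftest import dt

P = "PCP0"
T = dt(2011, 6, 1, 9, 0)


def msg_event(eid, ts, action, mid, actor=P):
    return LogEvent(event_id=eid, ts=ts, actor_id=actor,
                    actor_role=ActorRole.pcp, action=action, message_id=mid)


def days_ago(n):
    return T - timedelta(days=n)


class TestReconstruct:
    def test_replay_example(self):
        # m1: delivered 100 d ago, completed 10 d ago -> removed
        # m2: delivered 30 d ago, opened 5 d ago -> present, opened
        # m3: delivered 2 d ago, untouched -> present, unopened, within 7 d
        events = [
            msg_event("E1", days_ago(100), Action.message_delivered, "m1"),
            msg_event("E2", days_ago(10), Action.message_completed, "m1"),
            msg_event("E3", days_ago(30), Action.message_delivered, "m2"),
            msg_event("E4", days_ago(5), Action.message_opened, "m2"),
            msg_event("E5", days_ago(2), Action.message_delivered, "m3"),
        ]
        snap = reconstruct_inbasket(events, P, T)
        assert (snap.total_messages, snap.unopened_messages,
                snap.prior_week_arrivals) == (2, 1, 1)

    def test_empty_stream(self):
        snap = reconstruct_inbasket([], P, T)
        assert (snap.total_messages, snap.unopened_messages,
                snap.prior_week_arrivals) == (0, 0, 0)

    def test_lookback_excludes_year_old_messages(self):
        events = [msg_event("E1", days_ago(400), Action.message_delivered, "m1")]
        assert reconstruct_inbasket(events, P, T).total_messages == 0

    def test_postponed_removed_like_completed(self):
        events = [
            msg_event("E1", days_ago(20), Action.message_delivered, "m1"),
            msg_event("E2", days_ago(3), Action.message_postponed, "m1"),
        ]
        assert reconstruct_inbasket(events, P, T).total_messages == 0

    def test_lifecycle_before_delivery_is_error(self):
        events = [
            msg_event("E1", days_ago(10), Action.message_delivered, "m1"),
            msg_event("E2", days_ago(20), Action.message_opened, "m1"),
        ]
        with pytest.raises(ReplayConsistencyError):
            reconstruct_inbasket(events, P, T)

    def test_unopened_never_exceeds_total(self):
        with pytest.raises(ValueError):
            InBasketSnapshot(provider_id=P, at=T, total_messages=1,
                             unopened_messages=2, prior_week_arrivals=0)

    def test_completion_before_t_never_increases_total(self):
        events = [
            msg_event("E1", days_ago(20), Action.message_delivered, "m1"),
            msg_event("E2", days_ago(15), Action.message_delivered, "m2"),
        ]
        before = reconstruct_inbasket(events, P, T).total_messages
        events.append(msg_event("E3", days_ago(1), Action.message_completed, "m1"))
        after = reconstruct_inbasket(events, P, T).total_messages
        assert after <= before


def _forward_oracle(events, provider_id, t, lookback_days=365):
    """Naive mailbox simulation: walk events chronologically, mutate state,
    read it off at t."""
    mailbox: dict[str, dict] = {}
    for e in sorted(events, key=LogEvent.sort_key):
        if e.actor_id != provider_id or e.message_id is None or e.ts >= t:
            # opening/removal at or after t must not affect state at t,
            # except completion exactly at t which the replay treats as
            # still-present (strict <) and opening at t as opened (<=)
            if not (e.action is Action.message_opened and e.ts <= t):
                continue
        slot = mailbox.setdefault(
            e.message_id, {"delivered": None, "opened": False, "removed": False}
        )
        if e.action is Action.message_delivered:
            slot["delivered"] = e.ts if slot["delivered"] is None else min(
                slot["delivered"], e.ts)
        elif e.action is Action.message_opened:
            slot["opened"] = True
        elif e.action in (Action.message_completed, Action.message_postponed):
            if e.ts < t:
                slot["removed"] = True
    total = unopened = week = 0
    for slot in mailbox.values():
        d = slot["delivered"]
        if d is None or d >= t:
            continue
        if t - timedelta(days=7) <= d:
            week += 1
        if d < t - timedelta(days=lookback_days) or slot["removed"]:
            continue
        total += 1
        if not slot["opened"]:
            unopened += 1
    return total, unopened, week


def test_replay_matches_forward_oracle_on_random_streams():
    rng = np.random.default_rng(23)
    cohort = generate_cohort(1, 1, (1, 0, 0), seed=3)
    for i in range(100):
        traffic = TrafficModel(
            weekly_arrival_rate=float(rng.integers(1, 30)),
            open_prob=float(rng.uniform(0.2, 1.0)),
            complete_prob=float(rng.uniform(0.2, 1.0)),
            postpone_prob=float(rng.uniform(0, 0.3)),
        )
        events = generate_inbasket_traffic(
            cohort, traffic, horizon_days=30, seed=100 + i
        )
        t = cohort.alerts[0].delivery_ts - timedelta(
            days=int(rng.integers(0, 25)), seconds=int(rng.integers(0, 86400))
        )
        pid = cohort.providers[0].provider_id
        snap = reconstruct_inbasket(events, pid, t, lookback_days=40)
        assert (
            snap.total_messages, snap.unopened_messages, snap.prior_week_arrivals
        ) == _forward_oracle(events, pid, t, lookback_days=40)


class TestQuartileBin:
    def test_one_to_eight_splits_evenly(self):
        labels, cuts = quartile_bin(list(range(1, 9)))
        assert [labels.count(b) for b in range(4)] == [2, 2, 2, 2]

    def test_degenerate_values_warn_and_collapse(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels, _ = quartile_bin([5, 5, 5, 5, 5])
        assert set(labels) == {0}

    def test_fewer_than_four_values_rejected(self):
        with pytest.raises(ValueError):
            quartile_bin([1, 2, 3])

    def test_fixture_encounters_reproduce_published_edges(self, canonical):
        values = [p.encounters_prior_year for p in canonical.providers]
        _, cuts = quartile_bin(values)
        assert cuts == (2326.0, 2783.0, 3173.0)


class TestContextCovariates:
    def _one_alert_setup(self, canonical, total, unopened, week):
        alert = canonical.alerts[0]
        snap = InBasketSnapshot(
            provider_id=alert.pcp_id, at=alert.delivery_ts,
            total_messages=total, unopened_messages=unopened,
            prior_week_arrivals=week,
        )
        return build_context_covariates(
            [alert], [snap], canonical.providers, canonical.patients
        )[0]

    def test_published_edge_binning(self, canonical):
        row = self._one_alert_setup(canonical, 40, 3, 300)
        assert row["inbasket_total_cat"] == "<=42"
        assert row["inbasket_unopened_cat"] == "1-4"
        assert row["prior_week_cat"] == "<=344"

    def test_zero_unopened_in_lowest_bin(self, canonical):
        assert self._one_alert_setup(canonical, 40, 0, 0)[
            "inbasket_unopened_cat"] == "0"

    def test_value_on_cut_point_goes_to_lower_bin(self, canonical):
        assert self._one_alert_setup(canonical, 42, 0, 0)[
            "inbasket_total_cat"] == "<=42"

    def test_missing_snapshot_error_names_alert(self, canonical):
        with pytest.raises(ValueError, match=canonical.alerts[0].alert_id):
            build_context_covariates(
                [canonical.alerts[0]], [], canonical.providers,
                canonical.patients,
            )
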