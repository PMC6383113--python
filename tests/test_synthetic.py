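"""Generator determinism, degenerate parameters, and generative fidelity."""

from __future__ import annotations

import math

import numpy as np
import pytest

from alertlog.fixture import make_canonical_fixture
from alertlog.pipeline import run_pipeline
from alertlog.schema import Action, AlertType
from alertlog.simulate import (
    BehaviorModel,
    LogitSpec,
    ParameterError,
    TrafficModel,
    generate_cohort,
    generate_event_streams,
    generate_inbasket_traffic,
)


class TestGenerateCohort:
    def test_study_scale_type_counts(self):
        cohort = generate_cohort(75, 799, (593 / 799, 37 / 799, 169 / 799), seed=2)
        counts = {t: 0 for t in AlertType}
        for a in cohort.alerts:
            counts[a.alert_type] += 1
        # multinomial draws around the expected 593/37/169 (±4 SD)
        for t, expected in zip(AlertType, (593, 37, 169)):
            p = expected / 799
            sd = math.sqrt(799 * p * (1 - p))
            assert abs(counts[t] - expected) < 4 * sd
        assert len({a.patient_id for a in cohort.alerts}) == 799

    def test_single_alert_degenerate_weights(self):
        cohort = generate_cohort(1, 1, (1, 0, 0), seed=9)
        assert len(cohort.alerts) == 1
        assert cohort.alerts[0].alert_type is AlertType.information_only

    def test_invalid_weights_rejected(self):
        with pytest.raises(ParameterError):
            generate_cohort(5, 10, (0, 0, 0), seed=1)
        with pytest.raises(ParameterError):
            generate_cohort(5, 10, (-1, 1, 1), seed=1)
        with pytest.raises(ParameterError):
            generate_cohort(0, 10, (1, 1, 1), seed=1)

    def test_same_seed_is_byte_identical(self):
        a = generate_cohort(10, 50, seed=4)
        b = generate_cohort(10, 50, seed=4)
        assert [x.model_dump() for x in a.alerts] == [
            x.model_dump() for x in b.alerts
        ]
        assert [x.model_dump() for x in a.providers] == [
            x.model_dump() for x in b.providers
        ]


def _forced_behavior(p_immediate: float) -> BehaviorModel:
    big = 30.0 if p_immediate >= 0.5 else -30.0
    return BehaviorModel(
        opener_mix=1.0,
        never_open_prob=0.0,
        missing_window_prob=0.0,
        provider_random_effect_sd=0.0,
        immediate_logit=LogitSpec(intercept=big),
        general_logit=LogitSpec(intercept=big),
        medication_logit=LogitSpec(intercept=big),
        laboratory_logit=LogitSpec(intercept=big),
    )


class TestGenerateEventStreams:
    def test_forced_action_puts_relevant_event_in_every_window(self):
        cohort = generate_cohort(10, 60, seed=5)
        events = generate_event_streams(cohort, _forced_behavior(1.0), seed=6)
        result = run_pipeline(events, cohort.alerts)
        assert result.table.immediate_evaluable.all()
        assert result.table.immediate_relevant.astype(bool).all()
        assert result.table.general.all()

    def test_zero_probabilities_give_no_own_patient_actions(self):
        cohort = generate_cohort(10, 60, seed=5)
        events = generate_event_streams(cohort, _forced_behavior(0.0), seed=6)
        own = {(a.pcp_id, a.patient_id) for a in cohort.alerts}
        assert not any(
            e.action in (Action.section_view, Action.order_placed)
            and (e.actor_id, e.patient_id) in own
            for e in events
        )

    def test_chronological_soundness(self):
        cohort = generate_cohort(10, 80, seed=7)
        events = generate_event_streams(cohort, BehaviorModel(), seed=8)
        delivered = {
            e.alert_id: e.ts for e in events if e.action is Action.alert_delivered
        }
        for e in events:
            if e.action is Action.alert_opened:
                assert e.ts >= delivered[e.alert_id]

    def test_same_seed_identical_streams(self):
        cohort = generate_cohort(10, 40, seed=3)
        a = generate_event_streams(cohort, BehaviorModel(), seed=1)
        b = generate_event_streams(cohort, BehaviorModel(), seed=1)
        assert [e.model_dump() for e in a] == [e.model_dump() for e in b]

    def test_rates_converge_to_logistic_probabilities(self):
        """Law of large numbers: with the random effect off and one alert per
        provider, pipeline-observed action rates match the generating
        logistic probabilities within 3 Monte-Carlo SEs (n = 20,000)."""
        n = 20_000
        behavior = BehaviorModel(
            opener_mix=1.0,
            never_open_prob=0.0,
            missing_window_prob=0.0,
            provider_random_effect_sd=0.0,
        )
        cohort = generate_cohort(n, n, seed=12)
        # one alert per provider
        alerts = [
            a.model_copy(update={"pcp_id": cohort.providers[i].provider_id})
            for i, a in enumerate(cohort.alerts)
        ]
        cohort = type(cohort)(
            providers=cohort.providers, patients=cohort.patients, alerts=alerts
        )
        events = generate_event_streams(cohort, behavior, seed=13)
        table = run_pipeline(events, cohort.alerts).table

        for outcome, spec in [
            ("immediate_relevant", behavior.immediate_logit),
            ("medication_specific", behavior.medication_logit),
            ("laboratory_specific", behavior.laboratory_logit),
        ]:
            for atype in AlertType:
                sub = table[table.alert_type == atype.value]
                obs = sub[outcome].astype(bool).mean()
                exp = spec.probability(atype)
                se = math.sqrt(exp * (1 - exp) / len(sub))
                assert abs(obs - exp) < 3 * se, (outcome, atype, obs, exp)


class TestInBasketTraffic:
    def test_zero_rate_no_events(self):
        cohort = generate_cohort(3, 5, seed=1)
        events = generate_inbasket_traffic(
            cohort, TrafficModel(weekly_arrival_rate=0.0), horizon_days=30, seed=2
        )
        assert events == []

    def test_immediate_completion_empties_basket(self):
        from datetime import timedelta
        from alertlog.inbasket import reconstruct_inbasket

        cohort = generate_cohort(1, 1, (1, 0, 0), seed=1)
        traffic = TrafficModel(
            weekly_arrival_rate=70.0, open_prob=1.0, complete_prob=1.0,
            postpone_prob=0.0,
        )
        events = generate_inbasket_traffic(cohort, traffic, horizon_days=20, seed=2)
        assert events
        t = max(e.ts for e in events) + timedelta(days=2)
        snap = reconstruct_inbasket(
            events, cohort.providers[0].provider_id, t, lookback_days=30
        )
        assert snap.total_messages == 0

    def test_prior_week_arrivals_match_rate(self):
        from alertlog.inbasket import reconstruct_inbasket

        cohort = generate_cohort(1, 1, (1, 0, 0), seed=1)
        events = generate_inbasket_traffic(
            cohort, TrafficModel(weekly_arrival_rate=450.0),
            horizon_days=30, seed=4,
        )
        t = cohort.alerts[0].delivery_ts
        snap = reconstruct_inbasket(
            events, cohort.providers[0].provider_id, t, lookback_days=30
        )
        assert abs(snap.prior_week_arrivals - 450) < 4 * math.sqrt(450)

    def test_lifecycle_never_precedes_delivery(self):
        cohort = generate_cohort(2, 4, seed=6)
        events = generate_inbasket_traffic(
            cohort, TrafficModel(weekly_arrival_rate=20.0),
            horizon_days=40, seed=7,
        )
        delivered = {}
        for e in sorted(events, key=lambda e: e.sort_key()):
            if e.action is Action.message_delivered:
                delivered[e.message_id] = e.ts
            elif e.message_id is not None:
                assert e.ts >= delivered[e.message_id]


class TestCanonicalFixtureDeterminism:
    def test_rebuild_is_identical(self, canonical):
        again = make_canonical_fixture()
        assert [e.model_dump() for e in again.events] == [
            e.model_dump() for e in canonical.events
        ]
        assert [p.model_dump() for p in again.providers] == [
            p.model_dump() for p in canonical.providers
        ]
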