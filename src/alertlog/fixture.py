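"""Deterministic canonical fixture: 799 alerts over 75 PCPs, by construction.

The fixture hard-constructs (quota assignment, not sampling) an event log
whose stage-by-stage accounting is known exactly:

* 799 alerts: 593 information-only, 37 medication-recommendation, 169
  test-recommendation, all opened by someone;
* 627 first-opened by the addressed PCP (78.5%), 172 by staff;
* 11 of the PCP-opened alerts have no usable 5-minute window data (their
  opening is the provider's final navigation event), leaving 616 evaluable;
* 208 immediate relevant first actions, split 125/17/66 by type over
  445/31/140 evaluable;
* two-day outcomes by type — general 382/29/127 (538 total, 261 with none),
  medication-specific 95/18/41, laboratory-specific 100/20/60;
* delivery→opening delay margins: over all 799, 472 <=24 h / 137 24-48 h /
  190 >48 h; over the 616, the coarse split 119 <=1 h / 252 1-24 h /
  245 >24 h; 304 of 616 openings inside office hours; 166 Saturday
  deliveries.

Every non-missing alert's window contains either a relevant-patient view or
a brief other-patient view (display ~15 s), so evaluability never depends on
lookahead.  Rebuilding with the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional
from zoneinfo import ZoneInfo

import numpy as np

from .config import DEFAULT_TZ
from .schema import (
    Action,
    Alert,
    AlertType,
    ActorRole,
    CharlsonCategory,
    Gender,
    LengthOfStayCategory,
    LogEvent,
    MedAction,
    OrderDetail,
    OrderKind,
    Patient,
    PatientAgeGroup,
    Provider,
    ProviderAgeGroup,
    SectionCode,
    Specialty,
)
from .simulate import Cohort, TrafficModel, generate_inbasket_traffic

FIXTURE_SEED = 20110825
N_PROVIDERS = 75

_INFO = AlertType.information_only
_MED = AlertType.medication_recommendation
_TEST = AlertType.test_recommendation

TYPE_TOTALS = {_INFO: 593, _MED: 37, _TEST: 169}
EVALUABLE = {_INFO: 445, _MED: 31, _TEST: 140}
MISSING = {_INFO: 8, _MED: 1, _TEST: 2}
IMMEDIATE = {_INFO: 125, _MED: 17, _TEST: 66}
GENERAL = {_INFO: 382, _MED: 29, _TEST: 127}
MED_SPECIFIC = {_INFO: 95, _MED: 18, _TEST: 41}
LAB_SPECIFIC = {_INFO: 100, _MED: 20, _TEST: 60}

# (delay bin, opened within office hours, Saturday delivery, count)
# Fine delay bins: A <=1h, B (1,24]h, C (24,48]h, D >48h.
_COMBOS_EVALUABLE = [
    ("A", False, True, 30),
    ("B", False, True, 40),
    ("C", True, True, 20),
    ("C", False, True, 10),
    ("D", True, True, 20),
    ("D", False, True, 8),
    ("A", True, False, 45),
    ("A", False, False, 44),
    ("B", True, False, 110),
    ("B", False, False, 102),
    ("C", True, False, 40),
    ("C", False, False, 30),
    ("D", True, False, 69),
    ("D", False, False, 48),
]
_COMBOS_OTHER = [
    ("A", False, True, 10),
    ("B", False, True, 10),
    ("C", False, True, 10),
    ("D", False, True, 8),
    ("A", False, False, 40),
    ("B", False, False, 41),
    ("C", False, False, 27),
    ("D", False, False, 37),
]

# (delivery local hour:minute, opening delta seconds) per (bin, office, saturday)
_TIMING = {
    ("A", True, False): ((9, 0), 1_800),
    ("A", False, False): ((16, 45), 1_800),
    ("B", True, False): ((9, 0), 18_000),
    ("B", False, False): ((9, 0), 36_000),
    ("C", True, False): ((9, 0), 90_000),
    ("C", False, False): ((9, 0), 129_600),
    ("D", True, False): ((9, 0), 176_400),
    ("D", False, False): ((9, 0), 216_000),
    ("A", False, True): ((10, 0), 1_800),
    ("B", False, True): ((10, 0), 18_000),
    ("C", True, True): ((10, 0), 169_200),
    ("C", False, True): ((10, 0), 129_600),
    ("D", True, True): ((10, 0), 259_200),
    ("D", False, True): ((10, 0), 216_000),
}

_BASE_MONDAY = datetime(2010, 9, 6)  # local Monday anchoring the study weeks


@dataclass
class _AlertSpec:
    alert_type: AlertType
    opener: str  # "pcp" or "staff"
    missing_window: bool
    immediate: bool
    general: bool
    med: bool
    lab: bool
    combo: Optional[tuple] = None
    provider_idx: int = 0
    slot: int = 0


@dataclass(frozen=True)
class CanonicalFixture:
    providers: list[Provider]
    patients: list[Patient]
    alerts: list[Alert]
    events: list[LogEvent]

    @property
    def cohort(self) -> Cohort:
        return Cohort(
            providers=self.providers, patients=self.patients, alerts=self.alerts
        )


def _provider_encounters() -> list[int]:
    """75 encounter counts whose empirical quartiles are exactly the
    published category edges (2326, 2783, 3173)."""
    vals = [0] * N_PROVIDERS
    for i in range(18):
        vals[i] = 1500 + 40 * i
    vals[18] = vals[19] = 2326
    for i in range(20, 37):
        vals[i] = 2350 + 25 * (i - 20)
    vals[37] = 2783
    for i in range(38, 55):
        vals[i] = 2800 + 20 * (i - 38)
    vals[55] = vals[56] = 3173
    for i in range(57, 75):
        vals[i] = 3200 + 60 * (i - 57)
    return vals


def _build_specs(rng: np.random.Generator) -> list[_AlertSpec]:
    evaluable: list[_AlertSpec] = []
    others: list[_AlertSpec] = []
    for atype in (_INFO, _MED, _TEST):
        n_eval = EVALUABLE[atype]
        n_imm = IMMEDIATE[atype]
        n_staff = TYPE_TOTALS[atype] - n_eval - MISSING[atype]
        type_eval = [
            _AlertSpec(atype, "pcp", False, i < n_imm, False, False, False)
            for i in range(n_eval)
        ]
        type_staff = [
            _AlertSpec(atype, "staff", False, False, False, False, False)
            for _ in range(n_staff)
        ]
        type_missing = [
            _AlertSpec(atype, "pcp", True, False, False, False, False)
            for _ in range(MISSING[atype])
        ]
        # two-day outcomes: candidates are the non-missing alerts, immediate
        # ones first so that immediate action implies a general action.
        candidates = type_eval + type_staff
        g, m, l = GENERAL[atype], MED_SPECIFIC[atype], LAB_SPECIFIC[atype]
        for spec in candidates[:g]:
            spec.general = True
        for spec in candidates[:m]:
            spec.med = True
        for spec in candidates[g - l : g]:
            spec.lab = True
        evaluable.extend(type_eval)
        others.extend(type_staff + type_missing)

    combos_eval = [c[:3] for c in _COMBOS_EVALUABLE for _ in range(c[3])]
    combos_other = [c[:3] for c in _COMBOS_OTHER for _ in range(c[3])]
    assert len(combos_eval) == len(evaluable) == 616
    assert len(combos_other) == len(others) == 183
    for spec, combo in zip(evaluable, combos_eval):
        spec.combo = combo
    for spec, combo in zip(others, combos_other):
        spec.combo = combo

    # Shuffle before provider assignment: a plain round-robin would hand
    # every provider an almost identical outcome mix, inducing a strong
    # negative intra-cluster correlation that sits on the exchangeable
    # boundary and destabilizes the GEE.  The shuffle keeps every margin
    # (they are set-level quotas) while making clusters exchangeable-like.
    # The 11 missing-window alerts go last to providers 0..10 so each such
    # opening is its provider's final navigation event.
    specs = evaluable + [s for s in others if not s.missing_window]
    missing_specs = [s for s in others if s.missing_window]
    rng.shuffle(specs)  # type: ignore[arg-type]
    counters = [0] * N_PROVIDERS
    for k, spec in enumerate(specs):
        p = k % N_PROVIDERS
        spec.provider_idx = p
        spec.slot = counters[p]
        counters[p] += 1
    for i, spec in enumerate(missing_specs):
        spec.provider_idx = i
        spec.slot = counters[i]
        counters[i] += 1
    return specs + missing_specs


def make_canonical_fixture(
    seed: int = FIXTURE_SEED,
    tz: ZoneInfo = DEFAULT_TZ,
    include_traffic: bool = False,
    traffic: Optional[TrafficModel] = None,
) -> CanonicalFixture:
    """Build the canonical dataset; same seed -> byte-identical output.

    ``include_traffic`` adds a modest InBasket message stream (the accounting
    margins above involve no InBasket quantities, so it is off by default).
    """
    rng = np.random.default_rng(seed)
    specs = _build_specs(rng)

    encounters = _provider_encounters()
    order = rng.permutation(N_PROVIDERS)
    providers = [
        Provider(
            provider_id=f"PCP{i:03d}",
            age_group=(
                ProviderAgeGroup.under_50
                if rng.random() < 0.37
                else ProviderAgeGroup.ge_50
            ),
            gender=Gender.female if rng.random() < 0.33 else Gender.male,
            specialty=list(Specialty)[
                int(rng.choice(4, p=np.array([118, 661, 11, 9]) / 799))
            ],
            encounters_prior_year=encounters[int(order[i])],
        )
        for i in range(N_PROVIDERS)
    ]
    patients = [
        Patient(
            patient_id=f"PT{i:04d}",
            age_group=list(PatientAgeGroup)[
                int(rng.choice(3, p=[0.319, 0.437, 0.244]))
            ],
            gender=Gender.female if rng.random() < 0.523 else Gender.male,
            charlson_category=list(CharlsonCategory)[
                int(rng.choice(4, p=[0.098, 0.115, 0.148, 0.639]))
            ],
            length_of_stay_cat=list(LengthOfStayCategory)[
                int(rng.choice(3, p=[0.451, 0.352, 0.197]))
            ],
            office_visits_prior_year=int(rng.negative_binomial(3, 0.2)),
        )
        for i in range(len(specs))
    ]

    alerts: list[Alert] = []
    events: list[LogEvent] = []
    n_ev = 0

    def add_event(**kwargs) -> None:
        nonlocal n_ev
        n_ev += 1
        events.append(LogEvent(event_id=f"EV{n_ev:06d}", **kwargs))

    # decoy patient for provider p: first patient of provider p+1 (mod 75);
    # slot-0 alerts are assigned round-robin, so alert index (p+1) % 75 is
    # provider (p+1)'s first alert and its patient the decoy.
    def decoy_patient(p: int) -> str:
        return patients[(p + 1) % N_PROVIDERS].patient_id

    for idx, spec in enumerate(specs):
        bin_, office, saturday = spec.combo
        (hour, minute), delta = _TIMING[(bin_, office, saturday)]
        week = spec.slot * 4 + (spec.provider_idx % 4)
        day = _BASE_MONDAY + timedelta(weeks=week, days=5 if saturday else 1)
        delivery = datetime(day.year, day.month, day.day, hour, minute, tzinfo=tz)
        t_open = delivery + timedelta(seconds=delta)

        pcp_id = providers[spec.provider_idx].provider_id
        patient_id = patients[idx].patient_id
        alert_id = f"A{idx:04d}"
        alerts.append(
            Alert(
                alert_id=alert_id,
                alert_type=spec.alert_type,
                pcp_id=pcp_id,
                patient_id=patient_id,
                delivery_ts=delivery,
            )
        )
        add_event(
            ts=delivery,
            actor_id=pcp_id,
            actor_role=ActorRole.pcp,
            action=Action.alert_delivered,
            alert_id=alert_id,
        )
        opener = pcp_id if spec.opener == "pcp" else f"{pcp_id}-staff"
        add_event(
            ts=t_open,
            actor_id=opener,
            actor_role=ActorRole.pcp if spec.opener == "pcp" else ActorRole.staff,
            action=Action.alert_opened,
            alert_id=alert_id,
        )
        if spec.missing_window:
            continue  # no further trace: immediate stage flags no_window_data

        if spec.opener == "pcp":
            if spec.immediate:
                # display 15 s, relevant dwell to a varying session end
                session_end = 50 + 30 * (idx % 7)
                for offset, section in (
                    (15, SectionCode.alert_link_summary),
                    (35, SectionCode.encounters),
                ):
                    add_event(
                        ts=t_open + timedelta(seconds=offset),
                        actor_id=pcp_id,
                        actor_role=ActorRole.pcp,
                        action=Action.section_view,
                        patient_id=patient_id,
                        section=section,
                    )
                add_event(
                    ts=t_open + timedelta(seconds=session_end),
                    actor_id=pcp_id,
                    actor_role=ActorRole.pcp,
                    action=Action.section_view,
                    patient_id=decoy_patient(spec.provider_idx),
                    section=SectionCode.nonclinical,
                )
            else:
                add_event(
                    ts=t_open + timedelta(seconds=15),
                    actor_id=pcp_id,
                    actor_role=ActorRole.pcp,
                    action=Action.section_view,
                    patient_id=decoy_patient(spec.provider_idx),
                    section=SectionCode.nonclinical,
                )

        if spec.general and not spec.immediate:
            add_event(
                ts=t_open + timedelta(hours=4),
                actor_id=pcp_id,
                actor_role=ActorRole.pcp,
                action=Action.section_view,
                patient_id=patient_id,
                section=SectionCode.encounters,
            )
        if spec.med:
            if idx % 2 == 0:
                add_event(
                    ts=t_open + timedelta(hours=5),
                    actor_id=pcp_id,
                    actor_role=ActorRole.pcp,
                    action=Action.section_view,
                    patient_id=patient_id,
                    section=SectionCode.medications,
                )
            else:
                add_event(
                    ts=t_open + timedelta(hours=5),
                    actor_id=pcp_id,
                    actor_role=ActorRole.pcp,
                    action=Action.order_placed,
                    patient_id=patient_id,
                    order=OrderDetail(
                        order_kind=OrderKind.medication,
                        med_action=[MedAction.new, MedAction.change, MedAction.discontinue][
                            idx % 3
                        ],
                    ),
                )
        if spec.lab:
            if idx % 3 == 0:
                add_event(
                    ts=t_open + timedelta(hours=6),
                    actor_id=pcp_id,
                    actor_role=ActorRole.pcp,
                    action=Action.section_view,
                    patient_id=patient_id,
                    section=SectionCode.laboratory,
                )
            elif idx % 3 == 1:
                add_event(
                    ts=t_open + timedelta(hours=6),
                    actor_id=pcp_id,
                    actor_role=ActorRole.pcp,
                    action=Action.section_view,
                    patient_id=patient_id,
                    section=SectionCode.results,
                    lab_result=True,
                )
            else:
                add_event(
                    ts=t_open + timedelta(hours=6),
                    actor_id=pcp_id,
                    actor_role=ActorRole.pcp,
                    action=Action.order_placed,
                    patient_id=patient_id,
                    order=OrderDetail(order_kind=OrderKind.laboratory),
                )

    if include_traffic:
        cohort = Cohort(providers=providers, patients=patients, alerts=alerts)
        events.extend(
            generate_inbasket_traffic(
                cohort,
                traffic or TrafficModel(weekly_arrival_rate=2.0),
                horizon_days=730,
                seed=seed,
            )
        )

    events.sort(key=LogEvent.sort_key)
    return CanonicalFixture(
        providers=providers, patients=patients, alerts=alerts, events=events
    )


__all__ = [
    "FIXTURE_SEED",
    "CanonicalFixture",
    "make_canonical_fixture",
    "TYPE_TOTALS",
    "EVALUABLE",
    "MISSING",
    "IMMEDIATE",
    "GENERAL",
    "MED_SPECIFIC",
    "LAB_SPECIFIC",
]
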