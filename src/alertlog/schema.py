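"""Shared data model for EHR access/audit-log events and study rosters.

The atomic record is :class:`LogEvent`: one time-stamped action by one actor,
optionally tied to a patient, an alert, or an InBasket message.  Access-log
content (alert openings, chart-section views, orders) and audit/InBasket
content (message lifecycle) are unified into a single event stream with an
``action`` discriminator; loaders may still ingest them from separate files.

All timestamps are timezone-aware (ISO-8601 with explicit UTC offset on disk).
Window arithmetic elsewhere in the package is done in a single configured
clinic timezone, because office hours and "the following day" are local-time
concepts.
"""

from __future__ import annotations

import enum
from datetime import datetime
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class ActorRole(str, enum.Enum):
    pcp = "pcp"
    staff = "staff"
    other_provider = "other_provider"


class Action(str, enum.Enum):
    alert_delivered = "alert_delivered"
    alert_opened = "alert_opened"
    section_view = "section_view"
    order_placed = "order_placed"
    message_delivered = "message_delivered"
    message_opened = "message_opened"
    message_completed = "message_completed"
    message_postponed = "message_postponed"


#: Actor-initiated chart-navigation actions recorded in the access log.
#: Deliveries are passive and message lifecycle belongs to the InBasket
#: subsystem; neither counts as evidence of chart navigation.
NAVIGATION_ACTIONS = frozenset(
    {Action.alert_opened, Action.section_view, Action.order_placed}
)

MESSAGE_ACTIONS = frozenset(
    {
        Action.message_delivered,
        Action.message_opened,
        Action.message_completed,
        Action.message_postponed,
    }
)


class SectionCode(str, enum.Enum):
    """Closed vocabulary of chart sections a view event can target.

    ``alert_link_summary`` covers the clickable options on the alert itself
    that link directly to summaries of the patient's chart.
    """

    medications = "medications"
    laboratory = "laboratory"
    orders = "orders"
    results = "results"
    encounters = "encounters"
    demographics = "demographics"
    other_clinical = "other_clinical"
    nonclinical = "nonclinical"
    info_entry = "info_entry"
    alert_link_summary = "alert_link_summary"


class OrderKind(str, enum.Enum):
    medication = "medication"
    laboratory = "laboratory"


class MedAction(str, enum.Enum):
    new = "new"
    change = "change"
    discontinue = "discontinue"


class AlertType(str, enum.Enum):
    information_only = "information_only"
    medication_recommendation = "medication_recommendation"
    test_recommendation = "test_recommendation"


class OrderDetail(BaseModel):
    model_config = ConfigDict(frozen=True)

    order_kind: OrderKind
    med_action: Optional[MedAction] = None

    @model_validator(mode="after")
    def _med_action_iff_medication(self) -> "OrderDetail":
        if self.order_kind is OrderKind.medication and self.med_action is None:
            raise ValueError("med_action required for medication orders")
        if self.order_kind is OrderKind.laboratory and self.med_action is not None:
            raise ValueError("med_action only valid for medication orders")
        return self


def _require_aware(ts: datetime, name: str) -> datetime:
    if ts.tzinfo is None or ts.tzinfo.utcoffset(ts) is None:
        raise ValueError(f"{name} must be timezone-aware")
    return ts


class LogEvent(BaseModel):
    model_config = ConfigDict(frozen=True)

    event_id: str
    ts: datetime
    actor_id: str
    actor_role: ActorRole
    action: Action
    patient_id: Optional[str] = None
    section: Optional[SectionCode] = None
    order: Optional[OrderDetail] = None
    alert_id: Optional[str] = None
    message_id: Optional[str] = None
    #: Only meaningful on ``section_view`` of the results section: whether the
    #: viewed result is a laboratory result (logs distinguish only sections).
    lab_result: Optional[bool] = None

    @field_validator("ts")
    @classmethod
    def _aware(cls, v: datetime) -> datetime:
        return _require_aware(v, "ts")

    @model_validator(mode="after")
    def _field_presence(self) -> "LogEvent":
        if (self.section is not None) != (self.action is Action.section_view):
            raise ValueError("section present iff action=section_view")
        if (self.order is not None) != (self.action is Action.order_placed):
            raise ValueError("order present iff action=order_placed")
        alert_actions = {Action.alert_delivered, Action.alert_opened}
        if (self.alert_id is not None) != (self.action in alert_actions):
            raise ValueError(
                "alert_id present iff action is alert_delivered/alert_opened"
            )
        if (self.message_id is not None) != (self.action in MESSAGE_ACTIONS):
            raise ValueError("message_id present iff action is a message event")
        if self.lab_result is not None and self.section is not SectionCode.results:
            raise ValueError("lab_result only valid on results section views")
        return self

    def sort_key(self) -> tuple[datetime, str]:
        """Total, deterministic ordering: timestamp then event_id.

        Logs have 1-second resolution, so same-second ties are common; the
        lexicographic event_id tiebreak makes replay deterministic.
        """
        return (self.ts, self.event_id)


class Alert(BaseModel):
    model_config = ConfigDict(frozen=True)

    alert_id: str
    alert_type: AlertType
    pcp_id: str
    patient_id: str
    delivery_ts: datetime

    @field_validator("delivery_ts")
    @classmethod
    def _aware(cls, v: datetime) -> datetime:
        return _require_aware(v, "delivery_ts")


class ProviderAgeGroup(str, enum.Enum):
    under_50 = "<50"
    ge_50 = ">=50"


class Gender(str, enum.Enum):
    female = "female"
    male = "male"


class Specialty(str, enum.Enum):
    internal_medicine = "internal_medicine"
    family_medicine = "family_medicine"
    non_md_pcp = "non_md_pcp"
    subspecialty = "subspecialty"


class Provider(BaseModel):
    model_config = ConfigDict(frozen=True)

    provider_id: str
    age_group: ProviderAgeGroup
    gender: Gender
    specialty: Specialty
    encounters_prior_year: int

    @field_validator("encounters_prior_year")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("encounters_prior_year must be >= 0")
        return v


class PatientAgeGroup(str, enum.Enum):
    age_65_74 = "65-74"
    age_75_84 = "75-84"
    age_85_plus = ">=85"


class CharlsonCategory(str, enum.Enum):
    c0 = "0"
    c1 = "1"
    c2 = "2"
    c3_plus = ">=3"


class LengthOfStayCategory(str, enum.Enum):
    le_2d = "<=2d"
    d3 = "3d"
    ge_4d = ">=4d"


class Patient(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    age_group: PatientAgeGroup
    gender: Gender
    charlson_category: CharlsonCategory
    length_of_stay_cat: LengthOfStayCategory
    office_visits_prior_year: int

    @field_validator("office_visits_prior_year")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("office_visits_prior_year must be >= 0")
        return v
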