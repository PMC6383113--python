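"""First-opening detection and delivery/opening context categories.

For each delivered alert we find the earliest ``alert_opened`` event (any
actor) and the earliest one by the addressed PCP, attribute the opener, and
derive the categories the downstream analyses stratify on: delay from
delivery to first opening (two categorizations are emitted: a fine
<=24h / 24-48h / >48h split and a coarse <=1h / 1-24h / >24h split),
office-hours context of the opening, and Saturday delivery.  Saturday matters
because a Saturday delivery is the only case where the first 24 hours contain
no weekday time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence
from zoneinfo import ZoneInfo

from .config import DEFAULT_TZ
from .schema import Action, Alert, LogEvent

_DAY = 86_400
_HOUR = 3_600


class DelayCategory(str, enum.Enum):
    le_24h = "<=24h"
    h24_48 = "24-48h"
    gt_48h = ">48h"


class DelayCategoryCoarse(str, enum.Enum):
    le_1h = "<=1h"
    h1_24 = "1-24h"
    gt_24h = ">24h"


class DataConsistencyError(ValueError):
    """The log contradicts itself (e.g. opening precedes delivery)."""


@dataclass(frozen=True)
class OpeningRecord:
    alert_id: str
    first_open_ts: Optional[datetime]
    first_opener_id: Optional[str]
    opened_by_pcp: bool
    first_pcp_open_ts: Optional[datetime]
    delay_category: Optional[DelayCategory]
    delay_category_coarse: Optional[DelayCategoryCoarse]
    within_office_hours: Optional[bool]
    saturday_delivery: bool

    @property
    def never_opened(self) -> bool:
        return self.first_open_ts is None


def classify_delay(delivery_ts: datetime, open_ts: datetime) -> DelayCategory:
    """Bin the delivery-to-opening delay; boundaries are inclusive on the
    upper end of each bin (<=24 h, (24, 48] h, >48 h), in exact seconds."""
    delta = (open_ts - delivery_ts).total_seconds()
    if delta < 0:
        raise DataConsistencyError("opening precedes delivery")
    if delta <= 24 * _HOUR:
        return DelayCategory.le_24h
    if delta <= 48 * _HOUR:
        return DelayCategory.h24_48
    return DelayCategory.gt_48h


def classify_delay_coarse(
    delivery_ts: datetime, open_ts: datetime
) -> DelayCategoryCoarse:
    delta = (open_ts - delivery_ts).total_seconds()
    if delta < 0:
        raise DataConsistencyError("opening precedes delivery")
    if delta <= _HOUR:
        return DelayCategoryCoarse.le_1h
    if delta <= 24 * _HOUR:
        return DelayCategoryCoarse.h1_24
    return DelayCategoryCoarse.gt_24h


def _local(ts: datetime, tz: ZoneInfo) -> datetime:
    if ts.tzinfo is None or ts.tzinfo.utcoffset(ts) is None:
        raise ValueError("timestamp must be timezone-aware")
    return ts.astimezone(tz)


def is_office_hours(ts: datetime, tz: ZoneInfo = DEFAULT_TZ) -> bool:
    """True iff local time falls in [08:00, 17:00) Monday through Friday.

    Half-open interval: 08:00:00 counts, 17:00:00 does not.
    """
    local = _local(ts, tz)
    if local.weekday() >= 5:
        return False
    seconds = local.hour * _HOUR + local.minute * 60 + local.second
    return 8 * _HOUR <= seconds < 17 * _HOUR


def is_saturday_delivery(delivery_ts: datetime, tz: ZoneInfo = DEFAULT_TZ) -> bool:
    return _local(delivery_ts, tz).weekday() == 5


def find_first_opening(
    events: Sequence[LogEvent], alert: Alert, tz: ZoneInfo = DEFAULT_TZ
) -> OpeningRecord:
    """Build the :class:`OpeningRecord` for one alert.

    ``events`` must be sorted; only ``alert_opened`` events referencing the
    alert are considered.  An opening earlier than the delivery timestamp is
    a data-consistency error.
    """
    opens = [
        e
        for e in events
        if e.action is Action.alert_opened and e.alert_id == alert.alert_id
    ]
    return _record_from_opens(opens, alert, tz)


def _record_from_opens(
    opens: Sequence[LogEvent], alert: Alert, tz: ZoneInfo
) -> OpeningRecord:
    saturday = is_saturday_delivery(alert.delivery_ts, tz)
    if not opens:
        return OpeningRecord(
            alert_id=alert.alert_id,
            first_open_ts=None,
            first_opener_id=None,
            opened_by_pcp=False,
            first_pcp_open_ts=None,
            delay_category=None,
            delay_category_coarse=None,
            within_office_hours=None,
            saturday_delivery=saturday,
        )
    first = opens[0]
    if first.ts < alert.delivery_ts:
        raise DataConsistencyError(
            f"alert {alert.alert_id}: opened at {first.ts.isoformat()} before "
            f"delivery at {alert.delivery_ts.isoformat()}"
        )
    pcp_opens = [e for e in opens if e.actor_id == alert.pcp_id]
    return OpeningRecord(
        alert_id=alert.alert_id,
        first_open_ts=first.ts,
        first_opener_id=first.actor_id,
        opened_by_pcp=first.actor_id == alert.pcp_id,
        first_pcp_open_ts=pcp_opens[0].ts if pcp_opens else None,
        delay_category=classify_delay(alert.delivery_ts, first.ts),
        delay_category_coarse=classify_delay_coarse(alert.delivery_ts, first.ts),
        within_office_hours=is_office_hours(first.ts, tz),
        saturday_delivery=saturday,
    )


def find_first_openings(
    events: Sequence[LogEvent], alerts: Sequence[Alert], tz: ZoneInfo = DEFAULT_TZ
) -> list[OpeningRecord]:
    """One pass over the sorted log, grouping openings by alert_id."""
    opens_by_alert: dict[str, list[LogEvent]] = {}
    for e in events:
        if e.action is Action.alert_opened and e.alert_id is not None:
            opens_by_alert.setdefault(e.alert_id, []).append(e)
    return [
        _record_from_opens(opens_by_alert.get(a.alert_id, []), a, tz) for a in alerts
    ]


__all__ = [
    "DelayCategory",
    "DelayCategoryCoarse",
    "DataConsistencyError",
    "OpeningRecord",
    "classify_delay",
    "classify_delay_coarse",
    "is_office_hours",
    "is_saturday_delivery",
    "find_first_opening",
    "find_first_openings",
]
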