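"""Readers/writers for event logs (JSONL, CSV) and roster tables (CSV).

Round-trip contract: ``read_log(write_log(x)) == x`` field-for-field, in both
formats and across them.  CSV is RFC-4180, UTF-8, mandatory header; optional
fields serialize as empty cells (JSONL uses explicit nulls).  Events are
always returned sorted by ``(ts, event_id)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from pydantic import ValidationError

from .schema import (
    Action,
    Alert,
    LogEvent,
    OrderDetail,
    Patient,
    Provider,
)


class LogValidationError(ValueError):
    """A record failed schema validation; message names the line and field."""


_EVENT_COLUMNS = [
    "event_id",
    "ts",
    "actor_id",
    "actor_role",
    "action",
    "patient_id",
    "section",
    "order_kind",
    "med_action",
    "alert_id",
    "message_id",
    "lab_result",
]


def _format_error(lineno: int, exc: ValidationError) -> LogValidationError:
    err = exc.errors()[0]
    loc = ".".join(str(p) for p in err["loc"]) or "<record>"
    return LogValidationError(f"line {lineno}: field '{loc}': {err['msg']}")


def _event_to_row(e: LogEvent) -> dict[str, str]:
    row = {c: "" for c in _EVENT_COLUMNS}
    row["event_id"] = e.event_id
    row["ts"] = e.ts.isoformat()
    row["actor_id"] = e.actor_id
    row["actor_role"] = e.actor_role.value
    row["action"] = e.action.value
    if e.patient_id is not None:
        row["patient_id"] = e.patient_id
    if e.section is not None:
        row["section"] = e.section.value
    if e.order is not None:
        row["order_kind"] = e.order.order_kind.value
        if e.order.med_action is not None:
            row["med_action"] = e.order.med_action.value
    if e.alert_id is not None:
        row["alert_id"] = e.alert_id
    if e.message_id is not None:
        row["message_id"] = e.message_id
    if e.lab_result is not None:
        row["lab_result"] = "true" if e.lab_result else "false"
    return row


def _row_to_event_dict(row: dict[str, str]) -> dict:
    d: dict = {
        "event_id": row.get("event_id") or None,
        "ts": row.get("ts") or None,
        "actor_id": row.get("actor_id") or None,
        "actor_role": row.get("actor_role") or None,
        "action": row.get("action") or None,
        "patient_id": row.get("patient_id") or None,
        "section": row.get("section") or None,
        "alert_id": row.get("alert_id") or None,
        "message_id": row.get("message_id") or None,
    }
    lab = row.get("lab_result") or None
    if lab is not None:
        d["lab_result"] = lab == "true"
    kind = row.get("order_kind") or None
    if kind is not None:
        d["order"] = {
            "order_kind": kind,
            "med_action": row.get("med_action") or None,
        }
    return d


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        return format
    return "csv" if path.suffix.lower() == ".csv" else "jsonl"


def read_log(path: str | Path, format: Optional[str] = None) -> list[LogEvent]:
    """Read an event log and return events sorted by ``(ts, event_id)``.

    Raises :class:`LogValidationError` naming the offending line and field on
    malformed records, unknown enum values, or duplicate event ids.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    events: list[LogEvent] = []
    seen: set[str] = set()

    def _add(lineno: int, event: LogEvent) -> None:
        if event.event_id in seen:
            raise LogValidationError(
                f"line {lineno}: field 'event_id': duplicate event_id"
                f" {event.event_id!r}"
            )
        seen.add(event.event_id)
        events.append(event)

    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    payload = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise LogValidationError(
                        f"line {lineno}: field '<record>': invalid JSON ({exc.msg})"
                    ) from exc
                try:
                    _add(lineno, LogEvent.model_validate(payload))
                except ValidationError as exc:
                    raise _format_error(lineno, exc) from exc
    elif fmt == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                try:
                    _add(lineno, LogEvent.model_validate(_row_to_event_dict(row)))
                except ValidationError as exc:
                    raise _format_error(lineno, exc) from exc
    else:
        raise ValueError(f"unknown log format: {fmt!r}")

    events.sort(key=LogEvent.sort_key)
    return events


def write_log(
    events: Iterable[LogEvent], path: str | Path, format: Optional[str] = None
) -> Path:
    """Write events to JSONL (one object per line) or CSV (flat columns)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    events = list(events)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for e in events:
                payload = e.model_dump(mode="json")
                fh.write(json.dumps(payload, separators=(",", ":")) + "\n")
    elif fmt == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_EVENT_COLUMNS)
            writer.writeheader()
            for e in events:
                writer.writerow(_event_to_row(e))
    else:
        raise ValueError(f"unknown log format: {fmt!r}")
    return path


def _write_models(models: Sequence, path: Path, columns: list[str]) -> Path:
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        for m in models:
            row = m.model_dump(mode="json")
            writer.writerow({c: "" if row[c] is None else row[c] for c in columns})
    return path


def _read_models(path: Path, model, lineno_offset: int = 2):
    out = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=lineno_offset):
            try:
                out.append(model.model_validate({k: v or None for k, v in row.items()}))
            except ValidationError as exc:
                raise _format_error(lineno, exc) from exc
    return out


def write_alerts(alerts: Sequence[Alert], path: str | Path) -> Path:
    cols = ["alert_id", "alert_type", "pcp_id", "patient_id", "delivery_ts"]
    return _write_models(alerts, Path(path), cols)


def read_alerts(path: str | Path) -> list[Alert]:
    return _read_models(path, Alert)


def write_providers(providers: Sequence[Provider], path: str | Path) -> Path:
    cols = ["provider_id", "age_group", "gender", "specialty", "encounters_prior_year"]
    return _write_models(providers, Path(path), cols)


def read_providers(path: str | Path) -> list[Provider]:
    return _read_models(path, Provider)


def write_patients(patients: Sequence[Patient], path: str | Path) -> Path:
    cols = [
        "patient_id",
        "age_group",
        "gender",
        "charlson_category",
        "length_of_stay_cat",
        "office_visits_prior_year",
    ]
    return _write_models(patients, Path(path), cols)


def read_patients(path: str | Path) -> list[Patient]:
    return _read_models(path, Patient)


@dataclass
class ValidationReport:
    """Referential-integrity report over a cohort; never mutates its inputs.

    An alert that was delivered but never opened is a legitimate study outcome
    (it is tallied, not flagged), whereas a dangling reference is a failure.
    """

    failures: list[str] = field(default_factory=list)
    never_opened: int = 0
    n_alerts: int = 0
    n_events: int = 0

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_cohort(
    alerts: Sequence[Alert],
    providers: Sequence[Provider],
    patients: Sequence[Patient],
    events: Sequence[LogEvent],
) -> ValidationReport:
    report = ValidationReport(n_alerts=len(alerts), n_events=len(events))
    provider_ids = {p.provider_id for p in providers}
    patient_ids = {p.patient_id for p in patients}
    alert_ids = {a.alert_id for a in alerts}

    for a in alerts:
        if a.pcp_id not in provider_ids:
            report.failures.append(
                f"alert {a.alert_id}: unknown provider {a.pcp_id}"
            )
        if a.patient_id not in patient_ids:
            report.failures.append(
                f"alert {a.alert_id}: unknown patient {a.patient_id}"
            )

    opened: set[str] = set()
    for e in events:
        if e.alert_id is not None and e.alert_id not in alert_ids:
            report.failures.append(
                f"event {e.event_id}: unknown alert {e.alert_id}"
            )
        if e.action is Action.alert_opened and e.alert_id in alert_ids:
            opened.add(e.alert_id)
    report.never_opened = len(alert_ids - opened)
    return report


__all__ = [
    "LogValidationError",
    "ValidationReport",
    "read_log",
    "write_log",
    "read_alerts",
    "write_alerts",
    "read_providers",
    "write_providers",
    "read_patients",
    "write_patients",
    "validate_cohort",
]
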