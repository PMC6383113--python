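"""Point-in-time InBasket reconstruction and contextual covariates.

EHR logs do not store successive snapshots of a provider's inbox, so the
state at a past instant ``t`` must be rebuilt by replay: assemble every
message delivered to the provider over the lookback year, drop the ones the
record shows as completed (e.g. deleted) or postponed before ``t``, and what
remains is the InBasket at ``t``.  A remaining message with no opening event
at or before ``t`` is unopened.  The 7-day arrival count captures recent
message flow.

The one-year lookback mirrors the reconstruction horizon of the source logs:
a message older than the lookback is invisible even if still open — a known
truncation.  Open/complete comparisons are done at timestamp resolution for
determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np

from .schema import Action, Alert, LogEvent, Patient, Provider


class ReplayConsistencyError(ValueError):
    """A message lifecycle event precedes its own delivery."""


@dataclass(frozen=True)
class InBasketSnapshot:
    provider_id: str
    at: datetime
    total_messages: int
    unopened_messages: int
    prior_week_arrivals: int

    def __post_init__(self):
        if not 0 <= self.unopened_messages <= self.total_messages:
            raise ValueError("unopened_messages must be within [0, total_messages]")


def reconstruct_inbasket(
    message_events: Sequence[LogEvent],
    provider_id: str,
    t: datetime,
    lookback_days: int = 365,
) -> InBasketSnapshot:
    """Replay message lifecycle events to the provider's InBasket state at ``t``.

    Candidate messages are those delivered in [t − lookback, t); messages
    completed or postponed strictly before ``t`` are removed; a remaining
    message is unopened if no opening is logged at or before ``t``.
    """
    if t.tzinfo is None or t.tzinfo.utcoffset(t) is None:
        raise ValueError("t must be timezone-aware")
    lookback_start = t - timedelta(days=lookback_days)
    week_start = t - timedelta(days=7)

    delivered: dict[str, datetime] = {}
    opened: dict[str, datetime] = {}
    removed: dict[str, datetime] = {}
    for e in message_events:
        if e.actor_id != provider_id or e.message_id is None:
            continue
        mid = e.message_id
        if e.action is Action.message_delivered:
            delivered[mid] = min(e.ts, delivered.get(mid, e.ts))
        elif e.action is Action.message_opened:
            opened[mid] = min(e.ts, opened.get(mid, e.ts))
        elif e.action in (Action.message_completed, Action.message_postponed):
            removed[mid] = min(e.ts, removed.get(mid, e.ts))

    for mid, ts in list(opened.items()) + list(removed.items()):
        if mid in delivered and ts < delivered[mid]:
            raise ReplayConsistencyError(
                f"message {mid}: lifecycle event at {ts.isoformat()} precedes "
                f"delivery at {delivered[mid].isoformat()}"
            )

    total = unopened = week = 0
    for mid, dts in delivered.items():
        if week_start <= dts < t:
            week += 1
        if not (lookback_start <= dts < t):
            continue
        if mid in removed and removed[mid] < t:
            continue
        total += 1
        if not (mid in opened and opened[mid] <= t):
            unopened += 1
    return InBasketSnapshot(
        provider_id=provider_id,
        at=t,
        total_messages=total,
        unopened_messages=unopened,
        prior_week_arrivals=week,
    )


def quartile_bin(values: Sequence[float]) -> tuple[list[int], tuple[float, float, float]]:
    """Empirical quartile binning with ties going to the lower bin.

    Returns (per-value bin indices 0..3, (q1, q2, q3) cut points).  Bins are
    <=q1, (q1,q2], (q2,q3], >q3.  With degenerate (all-equal) values every
    observation lands in the lowest bin and a warning is emitted.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("quartile binning requires at least 4 values")
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    if q1 == q3:
        warnings.warn("degenerate quartile cuts: all values in lowest bin")
    labels = [int(np.searchsorted([q1, q2, q3], v, side="left")) for v in arr]
    return labels, (float(q1), float(q2), float(q3))


#: Published category edges (upper-inclusive) from the source study's scale.
PUBLISHED_EDGES = {
    "inbasket_total": (42, 69, 157),
    "inbasket_unopened": (0, 4, 9),
    "prior_week_arrivals": (344, 453, 546),
    "encounters_prior_year": (2326, 2783, 3173),
    "office_visits_prior_year": (6, 11, 18),
}

_BIN_LABELS = {
    "inbasket_total": ("<=42", "43-69", "70-157", ">157"),
    "inbasket_unopened": ("0", "1-4", "5-9", ">9"),
    "prior_week_arrivals": ("<=344", "345-453", "454-546", ">546"),
    "encounters_prior_year": ("<=2326", "2327-2783", "2784-3173", ">3173"),
    "office_visits_prior_year": ("<=6", "7-11", "12-18", ">18"),
}


def _bin_with_edges(value: float, edges: tuple[float, float, float]) -> int:
    # upper-inclusive: a value equal to a cut point falls in the lower bin
    return int(np.searchsorted(np.asarray(edges, dtype=float), value, side="left"))


def build_context_covariates(
    alerts: Sequence[Alert],
    snapshots: Sequence[InBasketSnapshot],
    providers: Sequence[Provider],
    patients: Sequence[Patient],
    edges: Optional[dict[str, tuple[float, float, float]]] = None,
    saturday_flags: Optional[dict[str, bool]] = None,
) -> list[dict]:
    """Per-alert categorical covariates exactly as the analyses consume them.

    ``edges`` defaults to the published category edges; pass recomputed
    quartile cuts (from :func:`quartile_bin`) for new data.  One snapshot per
    alert, taken at its delivery timestamp, is required; a missing snapshot is
    an error naming the alert.
    """
    edges = {**PUBLISHED_EDGES, **(edges or {})}
    snap_by_provider_at = {(s.provider_id, s.at): s for s in snapshots}
    prov = {p.provider_id: p for p in providers}
    pat = {p.patient_id: p for p in patients}

    rows = []
    for a in alerts:
        snap = snap_by_provider_at.get((a.pcp_id, a.delivery_ts))
        if snap is None:
            raise ValueError(f"missing InBasket snapshot for alert {a.alert_id}")
        p = prov[a.pcp_id]
        q = pat[a.patient_id]
        row = {
            "alert_id": a.alert_id,
            "inbasket_total_cat": _BIN_LABELS["inbasket_total"][
                _bin_with_edges(snap.total_messages, edges["inbasket_total"])
            ],
            "inbasket_unopened_cat": _BIN_LABELS["inbasket_unopened"][
                _bin_with_edges(snap.unopened_messages, edges["inbasket_unopened"])
            ],
            "prior_week_cat": _BIN_LABELS["prior_week_arrivals"][
                _bin_with_edges(snap.prior_week_arrivals, edges["prior_week_arrivals"])
            ],
            "encounters_cat": _BIN_LABELS["encounters_prior_year"][
                _bin_with_edges(
                    p.encounters_prior_year, edges["encounters_prior_year"]
                )
            ],
            "office_visits_cat": _BIN_LABELS["office_visits_prior_year"][
                _bin_with_edges(
                    q.office_visits_prior_year, edges["office_visits_prior_year"]
                )
            ],
            "provider_age_group": p.age_group.value,
            "provider_gender": p.gender.value,
            "provider_specialty": p.specialty.value,
            "patient_age_group": q.age_group.value,
            "patient_gender": q.gender.value,
            "charlson_category": q.charlson_category.value,
            "length_of_stay_cat": q.length_of_stay_cat.value,
        }
        if saturday_flags is not None:
            row["saturday_delivery"] = saturday_flags[a.alert_id]
        rows.append(row)
    return rows


__all__ = [
    "InBasketSnapshot",
    "ReplayConsistencyError",
    "PUBLISHED_EDGES",
    "reconstruct_inbasket",
    "quartile_bin",
    "build_context_covariates",
]
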