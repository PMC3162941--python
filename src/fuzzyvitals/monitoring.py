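"""Per-second stream processing: pre-diagnosis timeline and prioritized alerts.

Each 1 Hz monitor record is reduced to the two engine inputs (mean blood
pressure, oxygen saturation), inferred, and appended to a per-patient
timeline. An alert is emitted when the situation label changes to one whose
urgency is not ``none``; a per-label refractory window (``debounce_seconds``)
suppresses repeat alerts for a label recently alerted, since per-tick
re-alerts at 1 Hz would flood the receiving staff. Ticks with no usable
inputs carry the last label forward, flagged stale; a gap longer than
``stale_gap_seconds`` raises a sensor-fault notice.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import IO, Iterable

from .engine import FuzzyEngine, PreDiagnosis, Urgency

__all__ = [
    "VitalRecord",
    "TimelineEntry",
    "Alert",
    "extract_inputs",
    "process_stream",
    "write_alert_log",
    "SENSOR_FAULT_LABEL",
]

SENSOR_FAULT_LABEL = "sensor_fault"


@dataclass(frozen=True)
class VitalRecord:
    """One per-second observation: a timestamped channel map for one patient."""

    patient_id: str
    timestamp: datetime
    channels: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class TimelineEntry:
    """One timeline tick: the inference result, or a stale carry-forward."""

    patient_id: str
    timestamp: datetime
    mbp: float | None
    spo2: float | None
    score: float | None
    label: str | None
    urgency: Urgency | None
    stale: bool
    mbp_derived: bool = False  # MBP computed from systolic/diastolic fallback


@dataclass(frozen=True)
class Alert:
    patient_id: str
    timestamp: datetime
    label: str
    message: str
    urgency: Urgency
    previous_label: str | None

    def __post_init__(self) -> None:
        if self.urgency == Urgency.none:
            raise ValueError("alerts must carry a non-none urgency")


def _finite(x: object) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


def extract_inputs(record: VitalRecord) -> tuple[float, float, bool] | None:
    """Extract ``(MBP, SpO2, mbp_derived)`` from a record, or None if missing.

    MBP comes from the ``ABP_mean`` channel when present; otherwise it falls
    back to the standard mean-arterial-pressure estimate
    ``(SBP + 2 DBP) / 3`` from the systolic/diastolic channels
    (``mbp_derived`` is True in that case). SpO2 is read directly.
    """
    ch = record.channels
    spo2 = ch.get("SpO2")
    if not _finite(spo2):
        return None
    mean = ch.get("ABP_mean")
    if _finite(mean):
        return float(mean), float(spo2), False
    sbp, dbp = ch.get("ABP_sys"), ch.get("ABP_dia")
    if _finite(sbp) and _finite(dbp):
        return (float(sbp) + 2.0 * float(dbp)) / 3.0, float(spo2), True
    return None


def process_stream(
    records: Iterable[VitalRecord],
    engine: FuzzyEngine,
    *,
    debounce_seconds: float = 0.0,
    stale_gap_seconds: float = 30.0,
) -> tuple[list[TimelineEntry], list[Alert]]:
    """Run the engine over a time-ordered record stream for one or more patients.

    Returns the per-tick timeline and the alert list. Records must be
    non-decreasing in time within each patient; a backwards timestamp is an
    input error. Alerts fire on transitions into a label whose urgency is not
    ``none``, subject to the per-label refractory window.
    """
    timeline: list[TimelineEntry] = []
    alerts: list[Alert] = []
    # per-patient state
    last_ts: dict[str, datetime] = {}
    last_label: dict[str, str | None] = {}
    last_urgency: dict[str, Urgency | None] = {}
    last_alert_ts: dict[tuple[str, str], datetime] = {}
    stale_since: dict[str, datetime] = {}
    fault_raised: dict[str, bool] = {}

    for record in records:
        pid = record.patient_id
        if pid in last_ts and record.timestamp < last_ts[pid]:
            raise ValueError(
                f"patient {pid}: timestamps must be non-decreasing "
                f"({record.timestamp} after {last_ts[pid]})"
            )
        last_ts[pid] = record.timestamp

        extracted = extract_inputs(record)
        if extracted is None:
            stale_since.setdefault(pid, record.timestamp)
            gap = (record.timestamp - stale_since[pid]).total_seconds()
            timeline.append(TimelineEntry(
                patient_id=pid, timestamp=record.timestamp,
                mbp=None, spo2=None, score=None,
                label=last_label.get(pid), urgency=last_urgency.get(pid),
                stale=True,
            ))
            if gap >= stale_gap_seconds and not fault_raised.get(pid, False):
                alerts.append(Alert(
                    patient_id=pid, timestamp=record.timestamp,
                    label=SENSOR_FAULT_LABEL,
                    message=f"No usable pressure/saturation signal for {gap:.0f} s",
                    urgency=Urgency.medium,
                    previous_label=last_label.get(pid),
                ))
                fault_raised[pid] = True
            continue

        stale_since.pop(pid, None)
        fault_raised[pid] = False
        mbp, spo2, derived = extracted
        diag: PreDiagnosis = engine.infer(mbp, spo2)
        previous = last_label.get(pid)
        timeline.append(TimelineEntry(
            patient_id=pid, timestamp=record.timestamp,
            mbp=diag.mbp, spo2=diag.spo2, score=diag.score,
            label=diag.label, urgency=diag.urgency,
            stale=False, mbp_derived=derived,
        ))
        if diag.label != previous and diag.urgency != Urgency.none:
            key = (pid, diag.label)
            prior = last_alert_ts.get(key)
            elapsed = None if prior is None else (record.timestamp - prior).total_seconds()
            if prior is None or elapsed >= debounce_seconds:
                alerts.append(Alert(
                    patient_id=pid, timestamp=record.timestamp,
                    label=diag.label, message=diag.message,
                    urgency=diag.urgency, previous_label=previous,
                ))
                last_alert_ts[key] = record.timestamp
        last_label[pid] = diag.label
        last_urgency[pid] = diag.urgency

    return timeline, alerts


def write_alert_log(alerts: Iterable[Alert], sink: str | Path | IO[str]) -> None:
    """Append-only JSON Lines alert log: one structured object per alert."""
    own = isinstance(sink, (str, Path))
    fh = open(sink, "a") if own else sink
    try:
        for alert in alerts:
            fh.write(json.dumps({
                "patient_id": alert.patient_id,
                "timestamp": alert.timestamp.isoformat(),
                "label": alert.label,
                "urgency": str(alert.urgency),
                "message": alert.message,
                "previous_label": alert.previous_label,
            }, sort_keys=True) + "\n")
    finally:
        if own:
            fh.close()
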