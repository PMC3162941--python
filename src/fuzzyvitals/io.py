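"""Record file I/O: CSV dialects for vital-sign streams and timeline export.

Two CSV dialects are accepted:

* ``long``: header ``patient_id,timestamp,channel,value`` — one channel
  reading per row, grouped into per-second records.
* ``wide``: header ``patient_id,timestamp,<channel>,...`` — one record per
  row, one column per channel.

Malformed rows (non-numeric values, unparseable timestamps) are skipped with
a warning and counted; a file that is mostly malformed is rejected outright.
"""

from __future__ import annotations

import logging
import math
from datetime import datetime
from pathlib import Path

import pandas as pd

from .monitoring import TimelineEntry, VitalRecord

__all__ = ["read_records", "write_timeline_csv"]

logger = logging.getLogger(__name__)

_META_COLS = {"patient_id", "timestamp"}


def _parse_ts(value: object) -> datetime | None:
    try:
        ts = pd.Timestamp(str(value))
    except (ValueError, TypeError):
        return None
    if pd.isna(ts):
        return None
    return ts.to_pydatetime()


def read_records(path: str | Path, dialect: str = "wide") -> list[VitalRecord]:
    """Read a vital-sign CSV into time-ordered per-patient records.

    Rows failing validation are skipped and logged; more than 50% malformed
    rows aborts with an error. Records are returned sorted by
    (patient, timestamp).
    """
    if dialect not in {"long", "wide"}:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        return []
    missing = _META_COLS - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    skipped = 0
    records: list[VitalRecord] = []
    if dialect == "long":
        if not {"channel", "value"} <= set(df.columns):
            raise ValueError(f"{path}: long dialect needs 'channel' and 'value' columns")
        good_rows = []
        for row in df.itertuples(index=False):
            ts = _parse_ts(row.timestamp)
            try:
                value = float(row.value)
            except (TypeError, ValueError):
                value = math.nan
            if ts is None or not math.isfinite(value) or not isinstance(row.channel, str):
                skipped += 1
                logger.warning("%s: skipping malformed long row %r", path, row)
                continue
            good_rows.append((str(row.patient_id), ts, row.channel, value))
        _check_skip_ratio(path, skipped, len(df))
        grouped: dict[tuple[str, datetime], dict[str, float]] = {}
        for pid, ts, channel, value in good_rows:
            grouped.setdefault((pid, ts), {})[channel] = value
        for (pid, ts), channels in sorted(grouped.items()):
            records.append(VitalRecord(patient_id=pid, timestamp=ts, channels=channels))
    else:
        channel_cols = [c for c in df.columns if c not in _META_COLS]
        for row in df.itertuples(index=False):
            ts = _parse_ts(getattr(row, "timestamp"))
            if ts is None:
                skipped += 1
                logger.warning("%s: skipping row with bad timestamp %r", path, row)
                continue
            channels: dict[str, float] = {}
            bad = False
            for col in channel_cols:
                raw = getattr(row, col)
                if raw is None or (isinstance(raw, float) and math.isnan(raw)) or \
                        (isinstance(raw, str) and raw.strip() == "") or pd.isna(raw):
                    continue  # genuinely missing channel, not malformed
                try:
                    channels[col] = float(raw)
                except (TypeError, ValueError):
                    bad = True
                    break
            if bad:
                skipped += 1
                logger.warning("%s: skipping row with non-numeric channel %r", path, row)
                continue
            records.append(VitalRecord(patient_id=str(row.patient_id),
                                       timestamp=ts, channels=channels))
        _check_skip_ratio(path, skipped, len(df))
        records.sort(key=lambda r: (r.patient_id, r.timestamp))
    if skipped:
        logger.warning("%s: skipped %d malformed row(s)", path, skipped)
    return records


def _check_skip_ratio(path: Path, skipped: int, total: int) -> None:
    if total > 0 and skipped / total > 0.5:
        raise ValueError(f"{path}: {skipped}/{total} rows malformed; aborting")


def write_timeline_csv(timeline: list[TimelineEntry], path: str | Path) -> None:
    """Export the pre-diagnosis timeline (one row per tick) to CSV."""
    rows = []
    for e in timeline:
        rows.append({
            "patient_id": e.patient_id,
            "timestamp": e.timestamp.isoformat(),
            "MBP": e.mbp,
            "SpO2": e.spo2,
            "score": e.score,
            "label": e.label,
            "urgency": None if e.urgency is None else str(e.urgency),
            "stale": e.stale,
            "mbp_derived": e.mbp_derived,
        })
    pd.DataFrame(rows, columns=[
        "patient_id", "timestamp", "MBP", "SpO2", "score",
        "label", "urgency", "stale", "mbp_derived",
    ]).to_csv(path, index=False)
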