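"""Synthetic MIMIC-like vital-sign streams with scriptable clinical scenarios.

Real multiparameter ICU recordings are per-second multi-channel numeric
streams (pressures, saturation, heart and respiratory rate, temperature).
This module emulates that structure at desk scale: a scenario is a list of
segments, each holding the patient in one clinical situation (or at explicit
channel means) for a number of seconds, with Gaussian channel noise and
Bernoulli spike/dropout artifacts. Generation is fully seeded, so identical
inputs give byte-identical streams.

Characteristic channel means per situation sit at the cores (peaks/plateaus)
of the engine's membership functions, since the situations are defined only
through those fuzzy sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .engine import FuzzyEngine
from .monitoring import VitalRecord

__all__ = [
    "STATE_MEANS",
    "PASSIVE_CHANNELS",
    "ScenarioSegment",
    "generate_stream",
    "records_to_frame",
    "generate_labelled_dataset",
    "train_test_split_stratified",
]

# (MBP mmHg, SpO2 %) at membership-function cores for each clinical situation.
STATE_MEANS: dict[str, tuple[float, float]] = {
    "instability": (55.0, 85.0),
    "low_MBP": (60.0, 97.0),
    "hypoxemia": (105.0, 85.0),
    "stable": (105.0, 97.0),
    "high_MBP": (150.0, 97.0),
}

# Inert adult-normal channels carried along to exercise channel extraction.
PASSIVE_CHANNELS: dict[str, float] = {"HR": 80.0, "RR": 16.0, "Temp": 36.5}

_PULSE_PRESSURE = 40.0  # systolic minus diastolic, mmHg


@dataclass(frozen=True)
class ScenarioSegment:
    """A stretch of the scenario: one target state held for ``duration`` s."""

    duration: int
    state: str | None = None
    channel_means: dict[str, float] = field(default_factory=dict)
    noise: float = 0.0
    artifact_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("segment duration must be >= 1 s")
        if self.noise < 0:
            raise ValueError("noise standard deviation must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact rate must lie in [0, 1]")
        if self.state is None and not self.channel_means:
            raise ValueError("segment needs a target state or explicit channel means")
        if self.state is not None and self.state not in STATE_MEANS:
            raise ValueError(
                f"unknown state {self.state!r}; expected one of {sorted(STATE_MEANS)}"
            )

    def means(self) -> dict[str, float]:
        ch: dict[str, float] = {}
        if self.state is not None:
            mbp, spo2 = STATE_MEANS[self.state]
            ch.update({
                "ABP_mean": mbp,
                "ABP_sys": mbp + 2.0 * _PULSE_PRESSURE / 3.0,
                "ABP_dia": mbp - _PULSE_PRESSURE / 3.0,
                "SpO2": spo2,
            })
        ch.update(PASSIVE_CHANNELS)
        ch.update(self.channel_means)
        return ch


def generate_stream(
    segments: list[ScenarioSegment],
    patient_id: str = "synthetic-001",
    seed: int = 0,
    start_time: datetime | None = None,
) -> list[VitalRecord]:
    """Generate a 1 Hz stream of :class:`VitalRecord` for a scenario.

    Artifacts: with probability ``artifact_rate`` per tick, the tick either
    drops its pressure/saturation channels (dropout) or spikes them out of
    range. SpO2 is truncated to [0, 100]; pressures floored at 0.
    """
    if not segments:
        raise ValueError("scenario needs at least one segment")
    rng = np.random.default_rng(seed)
    t = start_time if start_time is not None else datetime(2020, 1, 1, 12, 0, 0)
    records: list[VitalRecord] = []
    for seg in segments:
        means = seg.means()
        for _ in range(seg.duration):
            channels = {
                name: float(mu + rng.normal(0.0, seg.noise)) if seg.noise > 0 else float(mu)
                for name, mu in means.items()
            }
            channels["SpO2"] = float(np.clip(channels.get("SpO2", np.nan), 0.0, 100.0))
            for key in ("ABP_mean", "ABP_sys", "ABP_dia"):
                if key in channels:
                    channels[key] = max(channels[key], 0.0)
            if seg.artifact_rate > 0 and rng.random() < seg.artifact_rate:
                if rng.random() < 0.5:  # dropout
                    for key in ("ABP_mean", "ABP_sys", "ABP_dia", "SpO2"):
                        channels.pop(key, None)
                else:  # out-of-range spike
                    channels["ABP_mean"] = float(rng.uniform(250.0, 400.0))
                    channels["SpO2"] = 100.0
            records.append(VitalRecord(patient_id=patient_id, timestamp=t, channels=channels))
            t += timedelta(seconds=1)
    return records


def records_to_frame(records: list[VitalRecord]) -> pd.DataFrame:
    """Wide-form DataFrame (one row per second) for CSV export."""
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "timestamp": r.timestamp.isoformat()}
        row.update(r.channels)
        rows.append(row)
    return pd.DataFrame(rows)


def generate_labelled_dataset(
    n: int,
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
    engine: FuzzyEngine | None = None,
    spread: tuple[float, float] = (5.0, 1.5),
) -> pd.DataFrame:
    """Sample ``(MBP, SpO2)`` pairs per class and label them with the engine.

    Each row's class is drawn from ``class_mix`` (default: uniform over the
    five situations); inputs are Gaussian around that class's characteristic
    means with standard deviations ``spread`` (mmHg, %). The stored ``label``
    column is always the fuzzy engine's own verdict on the sampled inputs, so
    the dataset is label-consistent by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if engine is None:
        from .config import build_engine
        engine = build_engine()
    if class_mix is None:
        class_mix = {s: 1.0 / len(STATE_MEANS) for s in STATE_MEANS}
    states = sorted(class_mix)
    probs = np.array([class_mix[s] for s in states], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("class mix proportions must be non-negative and sum > 0")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class mix proportions must sum to 1")
    unknown = set(states) - set(STATE_MEANS)
    if unknown:
        raise ValueError(f"unknown classes in mix: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(states), size=n, p=probs)
    sd_mbp, sd_spo2 = spread
    mbp_lo, mbp_hi = engine.variables["MBP"].domain
    spo2_lo, spo2_hi = engine.variables["SpO2"].domain
    rows = []
    for idx in drawn:
        state = states[idx]
        mu_mbp, mu_spo2 = STATE_MEANS[state]
        mbp = float(np.clip(rng.normal(mu_mbp, sd_mbp), mbp_lo, mbp_hi))
        spo2 = float(np.clip(rng.normal(mu_spo2, sd_spo2), spo2_lo, spo2_hi))
        diag = engine.infer(mbp, spo2)
        rows.append({"MBP": mbp, "SpO2": spo2, "drawn_class": state, "label": diag.label})
    return pd.DataFrame(rows)


def train_test_split_stratified(
    dataset: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-label train/test split of a labelled dataset."""
    from sklearn.model_selection import train_test_split

    train, test = train_test_split(
        dataset,
        test_size=test_fraction,
        random_state=seed,
        stratify=dataset["label"],
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)
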