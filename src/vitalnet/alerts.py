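"""Range-based anomaly detection over vitals records and push-event logging.

A caregiver configures a [min, max] band per measurement (optionally per
patient); any measurement outside its band raises an alert event, and a
detected fall always alerts regardless of bands.  Real push delivery is a
vendor service; here events append to a local JSON-lines log with
timestamps so the pipeline latency is testable end to end.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path

import yaml

from vitalnet.vitals import VitalsRecord

logger = logging.getLogger(__name__)

MEASUREMENTS = ("temperature_c", "hr_bpm", "spo2_pct", "respiration_bpm", "gsr_ohms")

#: Conventional adult resting bands; every one is overridable per patient.
DEFAULT_RANGES = {
    "temperature_c": (36.0, 38.0),
    "hr_bpm": (60.0, 100.0),
    "spo2_pct": (94.0, 100.0),
    "respiration_bpm": (12.0, 20.0),
}


@dataclass(frozen=True)
class ThresholdRange:
    measurement: str
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.min >= self.max:
            raise ValueError("min must be below max")


@dataclass
class AlertEvent:
    patient_id: int
    measurement: str
    value: float
    violated: str  # "min" | "max" | "fall"
    timestamp: float


def default_ranges() -> dict[str, ThresholdRange]:
    return {k: ThresholdRange(k, lo, hi) for k, (lo, hi) in DEFAULT_RANGES.items()}


def check_record(rec: VitalsRecord,
                 ranges: dict[str, ThresholdRange] | None = None) -> list[AlertEvent]:
    """One alert per out-of-range present measurement; a set fall flag
    always alerts.  Absent fields and fields without a configured range are
    skipped (the latter with a logged warning)."""
    ranges = default_ranges() if ranges is None else ranges
    events: list[AlertEvent] = []
    for name in MEASUREMENTS:
        value = getattr(rec, name)
        if value is None:
            continue
        band = ranges.get(name)
        if band is None:
            logger.warning("no range configured for %s; skipping", name)
            continue
        if value < band.min:
            events.append(AlertEvent(rec.patient_id, name, value, "min", rec.timestamp))
        elif value > band.max:
            events.append(AlertEvent(rec.patient_id, name, value, "max", rec.timestamp))
    if rec.fall:
        events.append(AlertEvent(rec.patient_id, "fall", 1.0, "fall", rec.timestamp))
    return events


def load_ranges(path: str | Path) -> dict[int, dict[str, ThresholdRange]]:
    """Per-patient ranges from a YAML/JSON config keyed by patient id."""
    doc = yaml.safe_load(Path(path).read_text())
    out: dict[int, dict[str, ThresholdRange]] = {}
    for pid, bands in doc.items():
        out[int(pid)] = {
            name: ThresholdRange(name, float(lo), float(hi))
            for name, (lo, hi) in bands.items()
        }
    return out


def append_event_log(events: list[AlertEvent], path: str | Path) -> None:
    """Append alert events to a JSON-lines log (the local stand-in for a
    push-notification relay)."""
    with open(path, "a") as fh:
        for ev in events:
            fh.write(json.dumps(asdict(ev)) + "\n")


# --------------------------------------------------------------------------
# JSON record serialization

_RECORD_KEYS = ("patient_id", "timestamp", "temperature_c", "hr_bpm", "spo2_pct",
                "respiration_bpm", "gsr_ohms", "fall", "location")


def record_to_json(rec: VitalsRecord) -> str:
    """Canonical JSON: fixed key order, ISO-8601 UTC timestamp, absent
    fields omitted rather than null-filled.  Non-finite values are a
    serialization error (JSON has no NaN)."""
    out: dict = {}
    for key in _RECORD_KEYS:
        value = getattr(rec, key)
        if value is None:
            continue
        if key == "timestamp":
            out["timestamp"] = datetime.fromtimestamp(value, tz=timezone.utc).isoformat()
        elif isinstance(value, float) and not math.isfinite(value):
            raise ValueError(f"non-finite value for {key}")
        else:
            out[key] = value
    return json.dumps(out, allow_nan=False)


def record_from_json(text: str) -> VitalsRecord:
    """Inverse of :func:`record_to_json`."""
    d = json.loads(text)
    ts = datetime.fromisoformat(d["timestamp"]).timestamp()
    return VitalsRecord(
        patient_id=d["patient_id"],
        timestamp=ts,
        temperature_c=d.get("temperature_c"),
        hr_bpm=d.get("hr_bpm"),
        spo2_pct=d.get("spo2_pct"),
        respiration_bpm=d.get("respiration_bpm"),
        gsr_ohms=d.get("gsr_ohms"),
        fall=d.get("fall"),
        location=d.get("location"),
    )
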