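"""Fixed wire formats for the three telemetry packet types.

The field lists mirror the platform's three messages: the fixed-station
report (blood oxygen, respiration rate, galvanic resistance), the wearable
node's continuous-sampling report (temperature, heart rate, fall flag,
location), and the 80-sample electrocardiogram chunk.  The wire dialect is
little-endian with int32/int16/float32 fields and a leading one-byte type
tag; temperature travels as centi-degrees in an int32 so the integer field
type loses no clinical precision.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field

import numpy as np

TAG_FIXED_STATION = 1
TAG_CONTINUOUS = 2
TAG_ECG = 3

_FIXED_FMT = "<iifhf"     # 18 bytes
_CONT_FMT = "<iiifii"     # 24 bytes
_ECG_FMT = "<ii80f"       # 328 bytes

ECG_SAMPLES_PER_PACKET = 80


@dataclass
class FixedStationPacket:
    package_id: int
    patient_id: int
    blood_oxygen: float        # %
    respiration_rate: int      # breaths/min, int16 on the wire
    galvanic_resistance: float # ohms

    def __post_init__(self) -> None:
        if self.respiration_rate < 0:
            raise ValueError("respiration_rate must be non-negative")
        if not (-(1 << 15) <= self.respiration_rate < (1 << 15)):
            raise ValueError("respiration_rate out of int16 range")


@dataclass
class ContinuousSamplingPacket:
    package_id: int
    patient_id: int
    temperature_centi_c: int   # degC x100
    heart_rate: float          # bpm
    fall: int                  # 0/1
    location: int              # region id

    def __post_init__(self) -> None:
        if self.fall not in (0, 1):
            raise ValueError("fall must be 0 or 1")

    @property
    def temperature_c(self) -> float:
        return self.temperature_centi_c / 100.0


@dataclass
class ECGPacket:
    package_id: int
    patient_id: int
    samples: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = [float(v) for v in self.samples]
        if len(self.samples) != ECG_SAMPLES_PER_PACKET:
            raise ValueError(
                f"ECG packet requires exactly {ECG_SAMPLES_PER_PACKET} samples, "
                f"got {len(self.samples)}"
            )


Packet = FixedStationPacket | ContinuousSamplingPacket | ECGPacket


def encode_packet(p: Packet) -> bytes:
    """Serialize a packet to its fixed little-endian layout with a type tag."""
    if isinstance(p, FixedStationPacket):
        body = struct.pack(
            _FIXED_FMT, p.package_id, p.patient_id, p.blood_oxygen,
            p.respiration_rate, p.galvanic_resistance,
        )
        return bytes([TAG_FIXED_STATION]) + body
    if isinstance(p, ContinuousSamplingPacket):
        body = struct.pack(
            _CONT_FMT, p.package_id, p.patient_id, p.temperature_centi_c,
            p.heart_rate, p.fall, p.location,
        )
        return bytes([TAG_CONTINUOUS]) + body
    if isinstance(p, ECGPacket):
        body = struct.pack(_ECG_FMT, p.package_id, p.patient_id, *p.samples)
        return bytes([TAG_ECG]) + body
    raise TypeError(f"not a packet: {type(p).__name__}")


def decode_packet(b: bytes) -> Packet:
    """Exact inverse of :func:`encode_packet`; rejects bad tags and framing."""
    if len(b) < 1:
        raise ValueError("empty buffer")
    tag, body = b[0], b[1:]
    if tag == TAG_FIXED_STATION:
        _check_len(body, struct.calcsize(_FIXED_FMT))
        pid, pat, spo2, rr, gsr = struct.unpack(_FIXED_FMT, body)
        return FixedStationPacket(pid, pat, spo2, rr, gsr)
    if tag == TAG_CONTINUOUS:
        _check_len(body, struct.calcsize(_CONT_FMT))
        pid, pat, temp, hr, fall, loc = struct.unpack(_CONT_FMT, body)
        return ContinuousSamplingPacket(pid, pat, temp, hr, fall, loc)
    if tag == TAG_ECG:
        _check_len(body, struct.calcsize(_ECG_FMT))
        vals = struct.unpack(_ECG_FMT, body)
        return ECGPacket(vals[0], vals[1], list(vals[2:]))
    raise ValueError(f"unknown packet tag {tag}")


def _check_len(body: bytes, expect: int) -> None:
    if len(body) < expect:
        raise ValueError(f"truncated packet: {len(body)} < {expect} bytes")
    if len(body) > expect:
        raise ValueError(f"trailing bytes: {len(body)} > {expect}")


def packet_to_json(p: Packet) -> str:
    """Human-readable JSON rendering of any packet."""
    d = {"type": type(p).__name__}
    d.update({k: v for k, v in vars(p).items()})
    return json.dumps(d, indent=1)


def hexdump(b: bytes, width: int = 16) -> str:
    lines = []
    for off in range(0, len(b), width):
        chunk = b[off : off + width]
        lines.append(f"{off:08x}  {' '.join(f'{c:02x}' for c in chunk)}")
    return "\n".join(lines)


def ecg_packets_from_waveform(samples: np.ndarray, patient_id: int,
                              first_package_id: int = 0) -> list[ECGPacket]:
    """Chunk a signal into consecutive 80-sample packets (remainder dropped)."""
    samples = np.asarray(samples, dtype=float)
    n_full = samples.size // ECG_SAMPLES_PER_PACKET
    out = []
    for k in range(n_full):
        chunk = samples[k * ECG_SAMPLES_PER_PACKET : (k + 1) * ECG_SAMPLES_PER_PACKET]
        out.append(ECGPacket(first_package_id + k, patient_id, chunk.tolist()))
    return out
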