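"""Vital-sign estimation algorithms for the wearable node and fixed station.

Implements the device-style pipelines: buffered derivative-threshold QRS
detection with a refractory skip and RR-interval-averaged heart rate,
threshold-crossing respiration rate, ratio-of-ratios pulse oximetry,
Wheatstone-bridge RTD body temperature, ADC voltage-divider galvanic skin
resistance, and three-stage accelerometer fall detection
(free fall -> impact -> sustained vertical-to-horizontal transition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from vitalnet.constants import (
    ECG_FS,
    FALL_WINDOW_S,
    FREEFALL_G,
    FREEFALL_MIN_S,
    HORIZONTAL_DWELL_S,
    IMPACT_G,
    QRS_BUFFER_N,
    QRS_REFRACTORY,
    SPO2_INTERCEPT,
    SPO2_SLOPE,
    BridgeConfig,
)
from vitalnet.signals import AccelTrace, DualChannelPPG, Waveform

__all__ = [
    "QRSAnnotation",
    "DetectorConfig",
    "HeartRateEstimate",
    "BridgeConfig",
    "FallConfig",
    "FallEvent",
    "VitalsRecord",
    "detect_qrs",
    "heart_rate",
    "respiration_rate",
    "estimate_spo2",
    "body_temperature",
    "gsr_resistance",
    "detect_fall",
]


@dataclass
class DetectorConfig:
    """QRS detector parameters.

    ``buffer_n`` is the acquisition buffer length (samples); the derivative
    threshold is recomputed within each buffer as ``derivative_threshold_frac``
    of that buffer's maximum absolute first difference.  After each detection
    the next ``refractory`` samples are skipped so one complex is never
    counted twice.
    """

    buffer_n: int = QRS_BUFFER_N
    refractory: int = QRS_REFRACTORY
    derivative_threshold_frac: float = 0.5
    fs: float = ECG_FS

    def __post_init__(self) -> None:
        if self.buffer_n <= 2 * self.refractory:
            raise ValueError("buffer_n must exceed 2 * refractory")
        if not (0 < self.derivative_threshold_frac < 1):
            raise ValueError("derivative_threshold_frac must be in (0, 1)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


@dataclass
class QRSAnnotation:
    """Detected R-ridge sample indices for a signal sampled at ``fs``."""

    r_indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.r_indices = np.asarray(self.r_indices, dtype=int)
        if self.r_indices.size > 1 and not np.all(np.diff(self.r_indices) > 0):
            raise ValueError("r_indices must be strictly increasing")


@dataclass
class HeartRateEstimate:
    hr_bpm: float
    rr_avg_interval: float  # samples


def detect_qrs(ecg: Waveform, cfg: DetectorConfig | None = None) -> QRSAnnotation:
    """Derivative-threshold QRS detection with a refractory skip.

    The absolute first difference ``d[i] = |s[i+1] - s[i]|`` concentrates at
    the steep R ridge, dwarfing P/T slopes and discarding sign.  Within each
    ``buffer_n``-sample buffer the threshold is a fraction of that buffer's
    maximum; the scan runs left to right and, on a detection, skips the next
    ``refractory`` samples.  The skip carries across buffer boundaries so a
    complex straddling two buffers is neither lost nor double-counted.

    An all-constant signal has zero derivative everywhere and yields an
    empty annotation.
    """
    cfg = cfg or DetectorConfig()
    s = ecg.samples
    if s.size < 2 * ecg.fs:
        raise ValueError("signal too short: need at least 2 s of data")

    d = np.abs(np.diff(s))
    # Per-buffer thresholds over the derivative sequence.
    n_windows = int(np.ceil(d.size / cfg.buffer_n))
    thresholds = np.empty(d.size)
    for w in range(n_windows):
        lo, hi = w * cfg.buffer_n, min((w + 1) * cfg.buffer_n, d.size)
        m = d[lo:hi].max()
        # zero max => nothing can cross; use inf so the scan skips the window
        thresholds[lo:hi] = cfg.derivative_threshold_frac * m if m > 0 else np.inf

    marks = []
    i = 0
    while i < d.size:
        if d[i] > thresholds[i]:
            marks.append(i)
            i += cfg.refractory + 1
        else:
            i += 1
    return QRSAnnotation(np.array(marks, dtype=int), fs=ecg.fs)


def heart_rate(ann: QRSAnnotation) -> HeartRateEstimate:
    """Heart rate from the average R-to-R interval.

    HR (bpm) = 60 * fs / mean(successive R-index differences); the printed
    device form uses fs = 250 Hz.
    """
    if ann.r_indices.size < 2:
        raise ValueError("need at least two R ridges to estimate heart rate")
    rr_avg = float(np.mean(np.diff(ann.r_indices)))
    return HeartRateEstimate(hr_bpm=60.0 * ann.fs / rr_avg, rr_avg_interval=rr_avg)


def respiration_rate(resp: Waveform, threshold_frac: float = 0.5) -> float:
    """Breaths per minute from inter-threshold-crossing times.

    The threshold sits ``threshold_frac`` of the peak-to-peak range above
    the signal minimum; each upward crossing marks a breath onset and the
    rate extrapolates 60 s over the mean onset-to-onset time.
    """
    if not (0 < threshold_frac < 1):
        raise ValueError("threshold_frac must be in (0, 1)")
    s = resp.samples
    rng = s.max() - s.min()
    if rng == 0:
        raise ValueError("constant signal: no breaths measurable")
    thr = s.min() + threshold_frac * rng
    above = s >= thr
    onsets = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if onsets.size < 2:
        raise ValueError("fewer than two breath onsets: rate unmeasurable")
    mean_period_s = float(np.mean(np.diff(onsets))) / resp.fs
    return 60.0 / mean_period_s


@dataclass
class SpO2Calibration:
    """Empirical calibration line SpO2 = intercept + slope * R, clamped."""

    intercept: float = SPO2_INTERCEPT
    slope: float = SPO2_SLOPE


def estimate_spo2(ppg: DualChannelPPG, cal: SpO2Calibration | None = None) -> float:
    """Pulse oximetry by the ratio of ratios.

    Per channel, DC is the mean and AC the peak-to-peak of the mean-removed
    signal; R = (AC_red/DC_red)/(AC_ir/DC_ir) maps to saturation through the
    calibration line, clamped to [0, 100] %.
    """
    cal = cal or SpO2Calibration()
    out = []
    for wf in (ppg.red, ppg.ir):
        dc = float(np.mean(wf.samples))
        ac = float(np.ptp(wf.samples - dc))
        if dc == 0:
            raise ValueError("zero DC level: no light reaching the detector")
        out.append((ac, dc))
    (ac_r, dc_r), (ac_i, dc_i) = out
    if ac_i == 0:
        raise ValueError("zero infrared perfusion: ratio undefined")
    ratio = (ac_r / dc_r) / (ac_i / dc_i)
    return float(np.clip(cal.intercept + cal.slope * ratio, 0.0, 100.0))


def body_temperature(bridge_v: float, bridge: BridgeConfig | None = None) -> float:
    """Body temperature from the RTD Wheatstone-bridge output voltage.

    Inverts the bridge equation to the RTD resistance, then the linear RTD
    model T = (R/r0 - 1)/alpha.
    """
    bridge = bridge or BridgeConfig()
    r = bridge.invert_v(bridge_v)
    return (r / bridge.r0 - 1.0) / bridge.alpha


def gsr_resistance(adc_counts: int, adc_bits: int = 10, vref: float = 3.3,
                   divider_r: float = 100_000.0) -> float:
    """Skin resistance from an ADC reading of a voltage divider.

    The reference voltage drives ``divider_r`` in series with the skin; the
    ADC measures the voltage across the skin, so
    R_skin = divider_r * v / (vref - v) with v = counts * vref / (2^bits - 1).
    """
    full = (1 << adc_bits) - 1
    if not (0 <= adc_counts <= full):
        raise ValueError("adc_counts out of range for adc_bits")
    if adc_counts == full:
        raise ValueError("ADC at full scale: open circuit (no current path)")
    v = adc_counts * vref / full
    return divider_r * v / (vref - v)


@dataclass
class FallConfig:
    """Three-stage fall detector thresholds."""

    freefall_g: float = FREEFALL_G
    freefall_min_s: float = FREEFALL_MIN_S
    impact_g: float = IMPACT_G
    horizontal_dwell_s: float = HORIZONTAL_DWELL_S
    window_s: float = FALL_WINDOW_S


@dataclass
class FallEvent:
    index: int  # impact sample index
    freefall_duration_s: float
    impact_g: float


def detect_fall(trace: AccelTrace, cfg: FallConfig | None = None) -> list[FallEvent]:
    """Detect uncontrolled vertical-to-horizontal transitions.

    A fall is flagged when, within ``window_s`` of a free-fall onset:
    the vector magnitude stays below ``freefall_g`` for at least
    ``freefall_min_s`` while the wearer had been vertical (|z| dominant),
    an impact above ``impact_g`` follows, and the orientation then remains
    horizontal (|x| or |y| dominant) for ``horizontal_dwell_s``.  A slow
    deliberate lie-down has neither free fall nor impact and raises nothing.
    """
    cfg = cfg or FallConfig()
    if trace.fs < 20:
        raise ValueError("need fs >= 20 Hz")
    n = trace.x.size
    if n < 2 * trace.fs:
        raise ValueError("trace too short: need at least 2 s")

    mag = trace.magnitude
    horiz = np.maximum(np.abs(trace.x), np.abs(trace.y)) > np.abs(trace.z)
    ff_min = max(int(cfg.freefall_min_s * trace.fs), 1)
    dwell = int(cfg.horizontal_dwell_s * trace.fs)
    window = int(cfg.window_s * trace.fs)

    events: list[FallEvent] = []
    i = 0
    while i < n:
        if mag[i] >= cfg.freefall_g:
            i += 1
            continue
        # free-fall run starting at i
        j = i
        while j < n and mag[j] < cfg.freefall_g:
            j += 1
        if j - i < ff_min or i == 0 or horiz[i - 1]:
            i = j
            continue  # too short, or not vertical beforehand
        # impact within the window after free-fall onset
        hi = min(i + window, n)
        impact_rel = np.flatnonzero(mag[j:hi] > cfg.impact_g)
        if impact_rel.size == 0:
            i = j
            continue
        k = j + int(impact_rel[0])
        # sustained horizontal orientation after the impact settles
        post = np.flatnonzero(~(mag[k:] > cfg.impact_g))
        if post.size == 0:
            i = j
            continue
        start = k + int(post[0])
        if start + dwell <= n and np.all(horiz[start : start + dwell]):
            events.append(
                FallEvent(index=k, freefall_duration_s=(j - i) / trace.fs,
                          impact_g=float(mag[k]))
            )
            i = start + dwell
        else:
            i = j
    return events


@dataclass
class VitalsRecord:
    """One patient's measurement snapshot.

    Fields other than ``patient_id`` and ``timestamp`` may be absent
    (``None``): the fixed station and the wearable node source different
    subsets.
    """

    patient_id: int
    timestamp: float
    temperature_c: Optional[float] = None
    hr_bpm: Optional[float] = None
    spo2_pct: Optional[float] = None
    respiration_bpm: Optional[float] = None
    gsr_ohms: Optional[float] = None
    fall: Optional[bool] = None
    location: Optional[int] = None

    def __post_init__(self) -> None:
        if self.spo2_pct is not None and not (0 <= self.spo2_pct <= 100):
            raise ValueError("spo2_pct must be in [0, 100]")
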