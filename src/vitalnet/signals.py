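"""Synthetic physiological signal and scenario generators with ground truth.

Every generator returns the exact parameters it used (event sample indices,
true rates, true saturation, true temperature) so the estimators in
:mod:`vitalnet.vitals` can be tested without hardware.  All randomness is
driven by an explicit integer seed; identical seeds give bit-identical
output.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from vitalnet.constants import (
    ECG_FS,
    FREEFALL_G,
    IMPACT_G,
    SPO2_INTERCEPT,
    SPO2_SLOPE,
    BridgeConfig,
)

ACCEL_SCENARIOS = ("stand", "walk", "lie", "fall")


@dataclass
class Waveform:
    """A uniformly sampled signal: sample i is at time t0 + i / fs."""

    samples: np.ndarray
    fs: float
    units: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size < 1:
            raise ValueError("waveform needs at least one sample")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class GroundTruth:
    """Known truth attached to a generated waveform (the test oracle)."""

    event_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    scalar_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.event_indices = np.asarray(self.event_indices, dtype=int)
        if self.event_indices.size > 1 and not np.all(np.diff(self.event_indices) > 0):
            raise ValueError("event indices must be strictly increasing")


@dataclass
class DualChannelPPG:
    """Red + infrared photoplethysmogram sharing one time base."""

    red: Waveform
    ir: Waveform

    def __post_init__(self) -> None:
        if self.red.fs != self.ir.fs or self.red.samples.size != self.ir.samples.size:
            raise ValueError("red and ir channels must share fs and length")


@dataclass
class AccelTrace:
    """Tri-axial accelerometer trace in g."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float
    scenario_label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.size == self.y.size == self.z.size):
            raise ValueError("axes must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.x**2 + self.y**2 + self.z**2)


# --------------------------------------------------------------------------
# ECG

# Piecewise beat template, times in seconds relative to the R ridge.
# The R upstroke/downstroke are deliberately steep (two samples at 250 Hz)
# so the absolute first derivative concentrates at the ridge; P and T are
# broad Gaussian humps with negligible slope by comparison.
_P_AMP, _P_T0, _P_SIGMA = 0.15, -0.16, 0.022
_T_AMP, _T_T0, _T_SIGMA = 0.30, 0.24, 0.045
_Q_AMP, _S_AMP = -0.15, -0.25
_R_RISE_S = 0.008   # R upstroke duration
_R_FALL_S = 0.008


def _qrs_template(t: np.ndarray) -> np.ndarray:
    """Beat morphology sampled at times t (s, R ridge at t = 0)."""
    v = _P_AMP * np.exp(-0.5 * ((t - _P_T0) / _P_SIGMA) ** 2)
    v += _T_AMP * np.exp(-0.5 * ((t - _T_T0) / _T_SIGMA) ** 2)
    # Q dip ramping into the upstroke
    q0, q1 = -_R_RISE_S - 0.012, -_R_RISE_S
    m = (t >= q0) & (t < q1)
    v[m] += _Q_AMP * (t[m] - q0) / (q1 - q0)
    # R upstroke: linear from Q level to +1
    m = (t >= q1) & (t < 0)
    v[m] += _Q_AMP + (1.0 - _Q_AMP) * (t[m] - q1) / _R_RISE_S
    # R downstroke: +1 to S level
    m = (t >= 0) & (t < _R_FALL_S)
    v[m] += 1.0 + (_S_AMP - 1.0) * t[m] / _R_FALL_S
    # S recovery
    s0, s1 = _R_FALL_S, _R_FALL_S + 0.016
    m = (t >= s0) & (t < s1)
    v[m] += _S_AMP * (1.0 - (t[m] - s0) / (s1 - s0))
    return v


def gen_ecg(
    hr_bpm: float,
    duration_s: float,
    fs: float = ECG_FS,
    noise_sd: float = 0.0,
    jitter_frac: float = 0.0,
    seed: int = 0,
) -> tuple[Waveform, GroundTruth]:
    """Synthesize a single-lead ECG with known R-ridge locations.

    Beats are a fixed template (P hump, sharp biphasic QRS with a dominant
    R ridge, T hump) repeated with mean beat-to-beat spacing
    ``60 * fs / hr_bpm`` samples, optionally jittered by a uniform
    ±``jitter_frac`` fraction, plus additive Gaussian noise.

    Returns the waveform and a :class:`GroundTruth` whose ``event_indices``
    are the exact R-ridge sample positions.
    """
    if not (20 <= hr_bpm <= 250):
        raise ValueError("hr_bpm must be in [20, 250]")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if duration_s <= 2 * 60.0 / hr_bpm:
        raise ValueError("duration must cover more than two beats")
    if not (0 <= jitter_frac < 0.5):
        raise ValueError("jitter_frac must be in [0, 0.5)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    rr = 60.0 * fs / hr_bpm  # mean spacing in samples

    # R-ridge positions: start half an interval in, walk with jittered steps.
    peaks = []
    pos = rr / 2.0
    while pos < n - 1:
        peaks.append(int(round(pos)))
        step = rr * (1.0 + rng.uniform(-jitter_frac, jitter_frac)) if jitter_frac > 0 else rr
        pos += step
    peaks_arr = np.array(peaks, dtype=int)

    t = np.arange(n) / fs
    sig = np.zeros(n)
    for p in peaks_arr:
        sig += _qrs_template(t - p / fs)
    if noise_sd > 0:
        sig += rng.normal(0.0, noise_sd, size=n)

    wf = Waveform(sig, fs=fs, units="mV")
    gt = GroundTruth(
        event_indices=peaks_arr,
        scalar_params={"hr_bpm": float(hr_bpm)},
    )
    return wf, gt


# --------------------------------------------------------------------------
# Photoplethysmogram

_PPG_DC_IR = 1.0
_PPG_DC_RED = 0.9
_PPG_PI_IR = 0.02  # infrared perfusion index AC/DC


def gen_ppg(
    spo2_pct: float,
    hr_bpm: float = 72.0,
    duration_s: float = 10.0,
    fs: float = 100.0,
    seed: int = 0,
) -> tuple[DualChannelPPG, GroundTruth]:
    """Dual-wavelength PPG whose ratio of ratios encodes ``spo2_pct``.

    Oxygenated and deoxygenated hemoglobin absorb red and infrared light
    differently, so the ratio R = (AC/DC red)/(AC/DC ir) maps to SpO2 via
    the calibration line SpO2 = 110 - 25 R.  The generator inverts that
    line: the emitted channels have exactly the AC/DC amplitudes that make
    the estimator return ``spo2_pct``.
    """
    if not (70 <= spo2_pct <= 100):
        raise ValueError("spo2_pct must be in [70, 100]")
    if hr_bpm <= 0 or duration_s <= 0 or fs <= 0:
        raise ValueError("hr_bpm, duration_s and fs must be positive")

    ratio = (spo2_pct - SPO2_INTERCEPT) / SPO2_SLOPE
    pi_red = ratio * _PPG_PI_IR

    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(int(round(duration_s * fs))) / fs
    cardiac = np.sin(2 * np.pi * (hr_bpm / 60.0) * t + phase)

    # AC is defined as peak-to-peak of the pulsatile component (= 2x the
    # sinusoid amplitude), matching the estimator's measurement.
    red = _PPG_DC_RED * (1.0 + 0.5 * pi_red * cardiac)
    ir = _PPG_DC_IR * (1.0 + 0.5 * _PPG_PI_IR * cardiac)

    ppg = DualChannelPPG(
        red=Waveform(red, fs=fs, units="adu"),
        ir=Waveform(ir, fs=fs, units="adu"),
    )
    gt = GroundTruth(scalar_params={"spo2_pct": float(spo2_pct), "hr_bpm": float(hr_bpm)})
    return ppg, gt


# --------------------------------------------------------------------------
# Respiration

def gen_respiration(
    rr_bpm: float,
    duration_s: float = 60.0,
    fs: float = 25.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Waveform, GroundTruth]:
    """Airflow-like sinusoid with breath period ``60 / rr_bpm`` seconds.

    Breath onsets (ground truth) are the upward mid-line crossings, i.e.
    samples at integer multiples of the breath period.
    """
    if not (4 <= rr_bpm <= 60):
        raise ValueError("rr_bpm must be in [4, 60]")
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    f = rr_bpm / 60.0
    t = np.arange(n) / fs
    sig = np.sin(2 * np.pi * f * t)
    if noise_sd > 0:
        sig += rng.normal(0.0, noise_sd, size=n)

    period_samples = fs / f
    onsets = np.array(
        [int(round(k * period_samples)) for k in range(int(np.floor((n - 1) / period_samples)) + 1)],
        dtype=int,
    )
    wf = Waveform(sig, fs=fs, units="a.u.")
    gt = GroundTruth(event_indices=onsets, scalar_params={"rr_bpm": float(rr_bpm)})
    return wf, gt


# --------------------------------------------------------------------------
# Accelerometer scenarios

def gen_accel(
    scenario: str,
    duration_s: float = 10.0,
    fs: float = 50.0,
    seed: int = 0,
) -> AccelTrace:
    """Tri-axial accelerometer trace for a labeled activity scenario.

    ``stand``: gravity on z with small noise.  ``lie``: gravity on x.
    ``walk``: standing plus periodic ±0.3 g step bursts on z.  ``fall``:
    standing, then ~0.3 s of near-0 g free fall, an impact spike above the
    impact threshold, and sustained lying orientation.
    """
    if scenario not in ACCEL_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {ACCEL_SCENARIOS}")
    if duration_s < 4 or fs < 20:
        raise ValueError("need duration_s >= 4 and fs >= 20")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    noise = 0.02
    x = rng.normal(0.0, noise, n)
    y = rng.normal(0.0, noise, n)
    z = rng.normal(0.0, noise, n)

    if scenario == "stand":
        z += 1.0
    elif scenario == "lie":
        x += 1.0
    elif scenario == "walk":
        z += 1.0
        step_hz = 2.0
        t = np.arange(n) / fs
        z += 0.3 * np.sin(2 * np.pi * step_hz * t) ** 3
    else:  # fall
        t_fall = duration_s / 2.0
        i_ff = int(t_fall * fs)
        ff_len = max(int(0.3 * fs), 2)
        i_impact = i_ff + ff_len
        impact_len = max(int(0.04 * fs), 1)
        i_lie = i_impact + impact_len
        z[:i_ff] += 1.0                      # standing
        # free fall: all axes near zero (noise only)
        z[i_impact:i_lie] += IMPACT_G + 1.0  # impact spike, comfortably above threshold
        x[i_lie:] += 1.0                     # lying afterwards

    return AccelTrace(x, y, z, fs=fs, scenario_label=scenario)


# --------------------------------------------------------------------------
# RTD bridge

def gen_rtd_voltage(temp_c: float, bridge: BridgeConfig | None = None) -> float:
    """Wheatstone-bridge output voltage for a body temperature.

    Exact forward model of :func:`vitalnet.vitals.body_temperature`:
    RTD resistance from R(T) = r0 (1 + alpha T), then the bridge equation.
    """
    if not (-10 <= temp_c <= 60):
        raise ValueError("temp_c must be in [-10, 60]")
    bridge = bridge or BridgeConfig()
    return bridge.output_v(bridge.rtd_resistance(temp_c))


# --------------------------------------------------------------------------
# CSV / JSON sidecar I/O

def write_waveform_csv(wf: Waveform, path: str | Path, gt: GroundTruth | None = None) -> None:
    """Write a 2-column (time_s, value) CSV plus a .json sidecar."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "value"])
        for t, v in zip(wf.times, wf.samples):
            w.writerow([f"{t:.6f}", f"{v:.6g}"])
    meta = {"fs": wf.fs, "units": wf.units, "t0": wf.t0}
    if gt is not None:
        meta["ground_truth"] = {
            "event_indices": gt.event_indices.tolist(),
            "scalar_params": gt.scalar_params,
        }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_waveform_csv(path: str | Path) -> tuple[Waveform, GroundTruth | None]:
    """Read back the format written by :func:`write_waveform_csv`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = []
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        next(r)  # header
        for row in r:
            values.append(float(row[1]))
    wf = Waveform(np.array(values), fs=meta["fs"], units=meta.get("units", ""), t0=meta.get("t0", 0.0))
    gt = None
    if "ground_truth" in meta:
        g = meta["ground_truth"]
        gt = GroundTruth(np.array(g["event_indices"], dtype=int), g.get("scalar_params", {}))
    return wf, gt


def write_accel_csv(trace: AccelTrace, path: str | Path) -> None:
    """Write a 4-column (time_s, x_g, y_g, z_g) CSV plus a .json sidecar."""
    path = Path(path)
    times = np.arange(trace.x.size) / trace.fs
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "x_g", "y_g", "z_g"])
        for t, a, b, c in zip(times, trace.x, trace.y, trace.z):
            w.writerow([f"{t:.6f}", f"{a:.6g}", f"{b:.6g}", f"{c:.6g}"])
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"fs": trace.fs, "scenario_label": trace.scenario_label})
    )


def read_accel_csv(path: str | Path) -> AccelTrace:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cols: list[list[float]] = [[], [], []]
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        next(r)
        for row in r:
            for i in range(3):
                cols[i].append(float(row[i + 1]))
    return AccelTrace(
        np.array(cols[0]), np.array(cols[1]), np.array(cols[2]),
        fs=meta["fs"], scenario_label=meta.get("scenario_label", ""),
    )
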