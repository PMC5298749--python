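"""Estimator correctness: QRS/heart rate, respiration, SpO2, temperature,
GSR and fall detection, each against its generator or an independent oracle."""

import numpy as np
import pytest

from conftest import qrs_oracle
from vitalnet import (
    DetectorConfig,
    QRSAnnotation,
    body_temperature,
    detect_fall,
    detect_qrs,
    estimate_spo2,
    gen_accel,
    gen_ecg,
    gen_ppg,
    gen_respiration,
    gen_rtd_voltage,
    gsr_resistance,
    heart_rate,
    respiration_rate,
)
from vitalnet.constants import BridgeConfig
from vitalnet.signals import AccelTrace, Waveform
from vitalnet.vitals import SpO2Calibration


class TestQRSDetection:
    def test_flat_line_yields_no_detections(self):
        wf = Waveform(np.zeros(2000), fs=250)
        assert detect_qrs(wf).r_indices.size == 0

    def test_matches_generator_ground_truth(self):
        wf, gt = gen_ecg(60, 20, fs=250, noise_sd=0, jitter_frac=0, seed=1)
        ann = detect_qrs(wf)
        assert ann.r_indices.size == gt.event_indices.size
        assert np.max(np.abs(ann.r_indices - gt.event_indices)) <= 2

    def test_refractory_suppresses_close_double(self):
        # two sharp spikes 40 samples apart with a 50-sample refractory
        s = np.zeros(1000)
        s[100] = 1.0
        s[140] = 1.0
        ann = detect_qrs(Waveform(s, fs=250), DetectorConfig(refractory=50))
        assert ann.r_indices.size == 1

    def test_too_short_signal_errors(self):
        with pytest.raises(ValueError):
            detect_qrs(Waveform(np.zeros(100), fs=250))

    def test_refractory_spacing_invariant(self, rng):
        for _ in range(20):
            hr = rng.uniform(40, 180)
            wf, _ = gen_ecg(hr, 10, noise_sd=0.05, jitter_frac=0.1,
                            seed=int(rng.integers(1 << 30)))
            ann = detect_qrs(wf)
            if ann.r_indices.size > 1:
                assert np.min(np.diff(ann.r_indices)) > 50

    def test_agrees_with_brute_force_oracle(self, rng):
        cfg = DetectorConfig(buffer_n=500, refractory=30,
                             derivative_threshold_frac=0.5, fs=100)
        for _ in range(50):
            n = int(rng.integers(200, 2000))
            s = rng.normal(0, 1, n)
            ann = detect_qrs(Waveform(s, fs=100), cfg)
            expected = qrs_oracle(s, 500, 30, 0.5)
            assert ann.r_indices.tolist() == expected


class TestHeartRate:
    def test_uniform_250_spacing_is_60bpm(self):
        ann = QRSAnnotation(np.arange(0, 2500, 250), fs=250)
        est = heart_rate(ann)
        assert est.hr_bpm == pytest.approx(60.0)
        assert est.rr_avg_interval == 250.0

    def test_200_spacing_is_75bpm(self):
        ann = QRSAnnotation(np.array([0, 200, 400, 600]), fs=250)
        assert heart_rate(ann).hr_bpm == pytest.approx(75.0)

    def test_single_ridge_errors(self):
        with pytest.raises(ValueError):
            heart_rate(QRSAnnotation(np.array([100]), fs=250))

    def test_rate_interval_product_identity(self, rng):
        # hr * mean RR interval == 60 * fs, by construction
        for _ in range(10):
            idx = np.cumsum(rng.integers(150, 400, size=8))
            ann = QRSAnnotation(idx, fs=250)
            est = heart_rate(ann)
            assert est.hr_bpm * est.rr_avg_interval == pytest.approx(60 * 250, rel=1e-12)

    def test_recovery_sweep_noise_free(self):
        for hr in np.linspace(40, 180, 8):
            wf, _ = gen_ecg(hr, 20, fs=250, noise_sd=0, jitter_frac=0, seed=5)
            est = heart_rate(detect_qrs(wf))
            assert est.hr_bpm == pytest.approx(hr, abs=2)

    def test_recovery_with_noise(self):
        # 5% of R amplitude additive noise
        for hr in (55, 90, 150):
            wf, _ = gen_ecg(hr, 20, fs=250, noise_sd=0.05, jitter_frac=0.05, seed=9)
            est = heart_rate(detect_qrs(wf))
            assert est.hr_bpm == pytest.approx(hr, abs=3)


class TestRespiration:
    def test_quarter_hz_sinusoid_is_15bpm(self):
        t = np.arange(0, 60, 1 / 25)
        wf = Waveform(np.sin(2 * np.pi * 0.25 * t), fs=25)
        assert respiration_rate(wf) == pytest.approx(15.0, abs=0.1)

    def test_generator_roundtrip(self):
        for rr in (6, 12, 25, 40):
            wf, _ = gen_respiration(rr, 60, 25, noise_sd=0, seed=2)
            assert respiration_rate(wf) == pytest.approx(rr, abs=1)

    def test_constant_signal_errors(self):
        with pytest.raises(ValueError):
            respiration_rate(Waveform(np.ones(500), fs=25))


class TestSpO2:
    def test_calibration_line_at_r04_saturates(self):
        # ratio 0.4 maps to 110 - 25*0.4 = 100 exactly at the clamp
        t = np.arange(0, 10, 0.01)
        ir = 1.0 + 0.01 * np.sin(2 * np.pi * 1.2 * t)
        red = 1.0 + 0.004 * np.sin(2 * np.pi * 1.2 * t)
        from vitalnet.signals import DualChannelPPG
        ppg = DualChannelPPG(Waveform(red, 100), Waveform(ir, 100))
        assert estimate_spo2(ppg) == pytest.approx(100.0, abs=0.01)

    @pytest.mark.parametrize("spo2", [70, 85, 92, 98, 100])
    def test_generator_roundtrip(self, spo2):
        ppg, _ = gen_ppg(spo2, seed=4)
        assert estimate_spo2(ppg) == pytest.approx(spo2, abs=0.5)

    def test_zero_red_dc_errors(self):
        from vitalnet.signals import DualChannelPPG
        ppg = DualChannelPPG(Waveform(np.zeros(100), 100),
                             Waveform(np.ones(100), 100))
        with pytest.raises(ValueError):
            estimate_spo2(ppg)

    def test_monotone_decreasing_in_ratio(self):
        # higher ratio of ratios => lower saturation (before clamping)
        sats = [estimate_spo2(gen_ppg(s, seed=1)[0]) for s in (98, 90, 80)]
        assert sats[0] > sats[1] > sats[2]


class TestTemperature:
    def test_balanced_bridge_is_zero_celsius(self):
        assert body_temperature(0.0, BridgeConfig()) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("t", [30.0, 36.5, 37.0, 41.3])
    def test_bridge_roundtrip(self, t):
        assert body_temperature(gen_rtd_voltage(t)) == pytest.approx(t, abs=0.01)

    def test_voltage_beyond_rail_errors(self):
        b = BridgeConfig()
        with pytest.raises(ValueError):
            body_temperature(b.excitation_v, b)  # implies infinite resistance
        with pytest.raises(ValueError):
            body_temperature(-b.excitation_v, b)


class TestGSR:
    def test_half_scale_equals_divider(self):
        full = (1 << 12) - 1
        r = gsr_resistance((full + 1) // 2, adc_bits=12, vref=3.3, divider_r=100_000)
        assert r == pytest.approx(100_000, rel=1e-3)

    def test_zero_counts_zero_resistance(self):
        assert gsr_resistance(0) == 0.0

    def test_full_scale_open_circuit(self):
        with pytest.raises(ValueError):
            gsr_resistance((1 << 10) - 1, adc_bits=10)


class TestFallDetection:
    @pytest.mark.parametrize("scenario,n_events", [
        ("stand", 0), ("walk", 0), ("lie", 0), ("fall", 1),
    ])
    def test_scenario_labels(self, scenario, n_events):
        tr = gen_accel(scenario, 10, 50, seed=6)
        assert len(detect_fall(tr)) == n_events

    def test_slow_lie_down_is_not_a_fall(self):
        # gradual rotation from vertical to horizontal: magnitude stays ~1 g
        fs, n = 50, 500
        theta = np.concatenate([np.zeros(200),
                                np.linspace(0, np.pi / 2, 100),
                                np.full(200, np.pi / 2)])
        tr = AccelTrace(np.sin(theta), np.zeros(n), np.cos(theta), fs=fs)
        assert detect_fall(tr) == []

    def test_fall_event_fields(self):
        tr = gen_accel("fall", 10, 50, seed=7)
        ev, = detect_fall(tr)
        assert ev.impact_g >= 2.5
        assert ev.freefall_duration_s >= 0.06
        assert 0 <= ev.index < tr.x.size

    def test_short_trace_errors(self):
        tr = gen_accel("stand", 4, 50, seed=0)
        short = AccelTrace(tr.x[:40], tr.y[:40], tr.z[:40], fs=50)
        with pytest.raises(ValueError):
            detect_fall(short)
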