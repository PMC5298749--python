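"""Shared physical constants and calibrations.

The generators and the estimators are exact inverses of one another through
the models defined here, which makes every generator→estimator round trip a
testable contract.  All values are configurable at the call sites; these are
the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

# Pulse-oximetry calibration line: SpO2 = intercept + slope * R, where R is
# the ratio of ratios (AC/DC red) / (AC/DC infrared).  The classic empirical
# two-wavelength calibration; device-internal calibrations are proprietary.
SPO2_INTERCEPT = 110.0
SPO2_SLOPE = -25.0

# Default ECG sampling rate (Hz) of the wearable node's front end.
ECG_FS = 250.0

# QRS detector defaults: buffer length and post-detection refractory skip,
# both in samples at ECG_FS.
QRS_BUFFER_N = 1000
QRS_REFRACTORY = 50

# Fall detection thresholds, co-designed with the accelerometer scenario
# generator so that labeled scenarios are separable.
FREEFALL_G = 0.4        # vector magnitude below this => free fall
FREEFALL_MIN_S = 0.06   # minimum free-fall duration
IMPACT_G = 2.5          # vector magnitude above this => impact
HORIZONTAL_DWELL_S = 1.0  # sustained horizontal orientation after impact
FALL_WINDOW_S = 2.0     # free fall, impact and orientation change must fit here


@dataclass(frozen=True)
class BridgeConfig:
    """Wheatstone quarter-bridge around an RTD.

    Topology: excitation across two dividers; the reference arm is
    ``r_top`` over ``r_bottom``, the sense arm is ``r_series`` over the
    RTD.  Output is sense-node minus reference-node voltage, so a bridge
    with all arms equal to ``r0`` balances at 0 °C.

    The RTD follows the linear model R(T) = r0 * (1 + alpha * T)
    (the first-order Callendar-Van Dusen approximation), with PT100
    defaults r0 = 100 ohm and alpha = 0.00385 / degC.
    """

    r0: float = 100.0
    alpha: float = 0.00385
    r_top: float = 100.0
    r_bottom: float = 100.0
    r_series: float = 100.0
    excitation_v: float = 3.3

    def __post_init__(self) -> None:
        for name in ("r0", "alpha", "r_top", "r_bottom", "r_series", "excitation_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"BridgeConfig.{name} must be positive")

    def rtd_resistance(self, temp_c: float) -> float:
        return self.r0 * (1.0 + self.alpha * temp_c)

    def output_v(self, r_rtd: float) -> float:
        """Bridge output voltage for a given RTD resistance."""
        sense = r_rtd / (self.r_series + r_rtd)
        ref = self.r_bottom / (self.r_top + self.r_bottom)
        return self.excitation_v * (sense - ref)

    def invert_v(self, bridge_v: float) -> float:
        """RTD resistance implied by a bridge output voltage."""
        ref = self.r_bottom / (self.r_top + self.r_bottom)
        a = bridge_v / self.excitation_v + ref
        if a < 0:
            raise ValueError("bridge voltage implies negative RTD resistance")
        if a >= 1:
            raise ValueError("bridge voltage beyond reachable range")
        return a * self.r_series / (1.0 - a)
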