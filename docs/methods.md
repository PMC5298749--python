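# Methods

## Scope and model

`vitalnet` re-creates, in testable software, the computational stack of a
wearable + fixed-station remote health monitor: device-style estimation
algorithms, wire packets with payload encryption, a hierarchical WSN routing
layer, and range-free indoor localization. All inputs come from the
synthetic generators in `vitalnet.signals`; there is no hardware path.

## Synthetic signals: what they emulate and what they do not

The generators emulate only the signal features the estimators consume.

- **ECG** (`gen_ecg`): a fixed sum-of-bumps beat template — broad Gaussian
  P and T humps plus a piecewise-linear QRS whose R upstroke/downstroke
  span ~8 ms — repeated with mean beat spacing 60·fs/HR samples, optional
  uniform RR jitter, and additive white Gaussian noise. Only R-ridge timing
  matters to the derivative-threshold detector, so morphology realism ends
  there: no arrhythmias, baseline wander, or motion artifacts. Default
  fs = 250 Hz, the front-end rate the detector is designed around.
- **PPG** (`gen_ppg`): per channel, DC offset plus a cardiac-frequency
  sinusoid whose amplitude encodes the AC/DC perfusion ratio. The infrared
  perfusion index is fixed at 2 %; the red amplitude is chosen so the
  ratio of ratios inverts the SpO2 calibration exactly. No motion or
  venous artifacts.
- **Respiration** (`gen_respiration`): a unit sinusoid at the breath
  frequency plus optional noise; no apnea or variable tidal volumes.
- **Accelerometer** (`gen_accel`): four canonical scenarios (stand, walk,
  lie, fall) at 50 Hz with 0.02 g sensor noise. The fall scenario is
  0.3 s of free fall, a 3.5 g impact, then lying; thresholds in
  `constants.py` are co-designed with the detector so labeled scenarios
  are separable by construction.
- **RTD bridge** (`gen_rtd_voltage`): the exact forward model of the
  temperature estimator (linear RTD law + quarter-bridge equation).

Passing round-trip tests therefore demonstrates algorithmic correctness and
internal consistency — that each estimator exactly inverts the declared
physical model — not clinical performance on real patients.

## Estimators

- **QRS detection**: absolute first difference, thresholded at a fraction
  (default 0.5) of the per-buffer maximum over 1000-sample buffers, with a
  50-sample refractory skip after each mark. The threshold fraction is a
  design choice (the device literature leaves it unstated); a per-buffer
  adaptive fraction is gain-free across amplifiers. The scan and the
  refractory skip run continuously across buffer boundaries; thresholds
  alone are per-buffer. A constant buffer has zero maximum derivative and
  is skipped rather than treated as an error.
- **Heart rate**: HR = 60·fs / mean(RR intervals). The estimate stores both
  the rate and the average interval, so the product identity
  HR·RR_avg = 60·fs holds by construction (to IEEE-754 rounding).
- **SpO2 calibration**: SpO2 = 110 − 25·R, clamped to [0,100]. Slope and
  intercept are exposed in `SpO2Calibration`; generator and estimator share
  the line, making the round trip the testable contract.
- **Temperature**: quarter-bridge inversion then T = (R/R0 − 1)/α.
  Voltages outside the reachable open interval of the bridge raise.
- **GSR**: divider inversion R = R_div·v/(vref − v); full-scale ADC counts
  mean no current path and raise an open-circuit error. Reported in ohms.
- **Fall detection**: free fall (< 0.4 g for ≥ 60 ms, entered from a
  vertical posture) → impact (> 2.5 g within a 2 s window) → horizontal
  dwell (|x| or |y| dominant for ≥ 1 s). All thresholds configurable in
  `FallConfig`. A slow deliberate lie-down fails the free-fall stage and
  raises nothing.

## Packets and encryption

Field lists follow the platform's three message types; the wire dialect
(int32/int16/float32, little-endian, 1-byte type tag) is this package's
choice, matching common microcontroller conventions. Temperature travels as
centi-degrees in an int32 so an integer field loses no clinical precision.
AES-128 is implemented in-package (FIPS-197 forward cipher, validated
against the FIPS-197 Appendix C and NIST SP 800-38A F.5.1 vectors in the
test suite) and used in CTR mode with an 8-byte prepended nonce: CTR needs
no padding, keeps frames short, and requires only the forward cipher. CBC
was considered and rejected — it would double the cipher code for no tested
behaviour. Keys are static pre-shared material; nonce uniqueness is the
caller's contract (reuse within a process logs a warning).

## Network simulator

- **Channel**: log-distance path loss RSSI(d) = P_tx − (L0 + 10·n·log10 d)
  with optional log-normal shadowing; a link exists when the deterministic
  RSSI reaches the sensitivity. Defaults n = 2.5, L0 = 40 dB, P_tx = 0 dBm,
  sensitivity −90 dBm.
- **Link metric**: weight = 0.5·norm(RSSI) − 0.3·hops/10 + 0.2·norm(TTL),
  monotone in each ingredient; the combination is a design choice (only the
  three ingredients are given by the routing scheme being modeled). TTL is
  a battery-proxy counter decremented per transmission.
- **Routing**: BFS hop counts from the sink; every in-range neighbor
  strictly closer to the sink is kept as a redundant entry, best weight
  first. Remote nodes originate traffic but never relay. Unreachable nodes
  are flagged, not fatal.
- **Medium access**: contention is modeled abstractly among packets
  originating in the same slot (default 10 ms): uniform backoff draws in a
  window of 8, equal draws collide and retry up to 3 times. Forwarding
  along an acquired route is atomic; relay-to-relay contention is not
  modeled. An independent per-packet Bernoulli loss floor represents
  residual channel loss, and specific packet ids can be force-dropped for
  fault-injection arithmetic.
- **Failure/rejoin**: scheduled events kill or revive nodes; routes are
  rebuilt on each event, a dead next hop falls back to the next routing
  entry, and a rejoining relay re-elects its role (cluster if a remote is
  in range, else gateway).

Determinism: one `numpy` generator seeded per run drives backoffs and loss
draws; fixed seeds give identical results.

## Localization

Plain centroid (default, the classic range-free form: the estimate is
independent of RSSI values) and an RSSI-weighted variant using linearized
received power 10^(RSSI/10). The Monte-Carlo evaluator samples positions
uniformly, collects the anchors in radio range under the noise-free
channel, and reports mean/max Euclidean error over covered positions plus
the coverage fraction. The pilot fixture is a 4×3 anchor grid spanning
27 m × 17 m (the floor dimensions of the deployment being emulated; the
published floor plan's exact coordinates are not machine-readable, so a
uniform grid is used). Packets carry an integer location field interpreted
as the nearest-anchor region id; continuous coordinates live only in
simulator output.

## Alerts

Per-measurement [min, max] bands; any present out-of-range measurement
raises one event and a set fall flag always raises one. Shipped defaults
(36–38 °C, 60–100 bpm, 94–100 %, 12–20 breaths/min) are conventional adult
resting bands and are overridable per patient. Push delivery through vendor
notification services is out of scope; events append to a local JSON-lines
log so pipeline latency is testable without vendor infrastructure.

## Pilot scenario

Twelve communication nodes (5 cluster, 6 gateway, 1 sink) on a 4×3 grid,
one wearable visiting the 16 room centers of a 4×4 grid for 3 minutes each,
continuous packets at 1 Hz and ECG chunks every 2 s (offset 0.5 s so a
single node never contends with itself), a fixed station at 1 packet/s
during the room-1 dwell (180 packets), per-room vitals runs of the actual
estimator pipelines on fresh synthetic signals, centroid localization per
packet, and alert checking with optional injected anomalies. The remote
node's radio range defaults to 12 m so every room reaches a relay. Reports
are byte-identical for a fixed seed.

## Numerical choices and problem sizes

- Generator/estimator tolerances asserted in tests: HR ±2 bpm (noise-free,
  40–180 bpm) and ±3 bpm at 5 % R-amplitude noise; respiration ±1 bpm;
  SpO2 ±0.5 %; temperature ±0.01 °C.
- The detector-vs-oracle equivalence uses 200 random signals of ≤ 2000
  samples; the localization evaluation uses 1000 sampled positions. These
  sizes give stable statistics while keeping the full suite under a few
  seconds.
- Ties in backoff draws collide (no capture effect); ties in link weight
  keep insertion order (stable sort).

## Limitations

No arrhythmia or artifact modeling, no radio-accurate PHY or interference,
no energy-accurate battery model, no real push-notification transport, and
the MAC abstraction ignores hidden terminals and relay-queue contention.
Accuracy numbers produced here characterize the algorithms under the
synthetic conditions above, not a hospital deployment.
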