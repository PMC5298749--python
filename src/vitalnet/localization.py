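"""Range-free centroid indoor localization.

A mobile node is placed at the (optionally RSSI-weighted) mean of the
positions of the fixed communication nodes that hear it.  Accuracy is
governed entirely by anchor density and radio range: more anchors in
earshot pull the centroid closer to the true position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from vitalnet.netsim import ChannelConfig, rssi_model


@dataclass
class AnchorObservation:
    anchor_id: int
    position: tuple[float, float]
    rssi_dbm: float


@dataclass
class LocalizationEstimate:
    position: tuple[float, float]
    n_anchors: int
    error_m: float | None = None  # filled in when ground truth is known


def estimate_position(obs: list[AnchorObservation],
                      mode: str = "plain") -> LocalizationEstimate:
    """Centroid of the anchors that hear the node.

    ``plain`` ignores signal strength (the classic range-free form);
    ``weighted`` weights each anchor by its linearized received power
    10^(rssi/10), pulling the estimate toward closer anchors.
    """
    if not obs:
        raise ValueError("need at least one anchor observation")
    pos = np.array([o.position for o in obs], dtype=float)
    if mode == "plain":
        c = pos.mean(axis=0)
    elif mode == "weighted":
        w = np.array([10 ** (o.rssi_dbm / 10.0) for o in obs])
        c = (pos * w[:, None]).sum(axis=0) / w.sum()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return LocalizationEstimate(position=(float(c[0]), float(c[1])), n_anchors=len(obs))


def grid_layout(n_x: int, n_y: int, width_m: float, height_m: float
                ) -> list[tuple[float, float]]:
    """Anchor positions on an n_x-by-n_y grid spanning a rectangle,
    edges included."""
    xs = np.linspace(0.0, width_m, n_x)
    ys = np.linspace(0.0, height_m, n_y)
    return [(float(x), float(y)) for y in ys for x in xs]


@dataclass
class LocalizationReport:
    mean_error_m: float
    max_error_m: float
    coverage: float  # fraction of sampled positions with >= 1 anchor in range
    n_positions: int
    mode: str


def observations_at(point: tuple[float, float],
                    anchors: list[tuple[float, float]],
                    cfg: ChannelConfig,
                    rng: np.random.Generator | None = None
                    ) -> list[AnchorObservation]:
    """Anchors that hear a node at ``point`` under the channel model."""
    obs = []
    for aid, a in enumerate(anchors):
        d = float(np.hypot(point[0] - a[0], point[1] - a[1]))
        if d == 0:
            d = 1e-6
        rssi = rssi_model(d, cfg, rng)
        if rssi >= cfg.sensitivity_dbm:
            obs.append(AnchorObservation(aid, a, rssi))
    return obs


def evaluate_localization(
    anchors: list[tuple[float, float]],
    area: tuple[float, float],
    n_positions: int,
    cfg: ChannelConfig,
    mode: str = "plain",
    seed: int = 0,
) -> LocalizationReport:
    """Monte-Carlo accuracy of centroid localization over an area.

    Samples node positions uniformly, determines the anchors in radio
    range, estimates each position, and reports mean and max Euclidean
    error over the covered positions plus the coverage fraction.
    """
    if len(anchors) < 3:
        raise ValueError("need at least 3 anchors")
    if n_positions < 100:
        raise ValueError("need at least 100 sampled positions")
    rng = np.random.default_rng(seed)
    w, h = area
    pts = rng.uniform([0, 0], [w, h], size=(n_positions, 2))
    errors = []
    for p in pts:
        obs = observations_at((p[0], p[1]), anchors, cfg, rng)
        if not obs:
            continue
        est = estimate_position(obs, mode)
        errors.append(float(np.hypot(est.position[0] - p[0], est.position[1] - p[1])))
    if not errors:
        raise ValueError("zero coverage: no sampled position hears any anchor")
    return LocalizationReport(
        mean_error_m=float(np.mean(errors)),
        max_error_m=float(np.max(errors)),
        coverage=len(errors) / n_positions,
        n_positions=n_positions,
        mode=mode,
    )


def range_limited_channel(range_m: float, cfg: ChannelConfig | None = None
                          ) -> ChannelConfig:
    """A noise-free channel whose sensitivity puts the radio range at
    exactly ``range_m`` under the log-distance model."""
    base = cfg or ChannelConfig()
    sens = base.tx_power_dbm - base.ref_loss_db \
        - 10 * base.path_loss_exp * np.log10(range_m)
    return ChannelConfig(
        path_loss_exp=base.path_loss_exp,
        ref_loss_db=base.ref_loss_db,
        tx_power_dbm=base.tx_power_dbm,
        sensitivity_dbm=float(sens),
        noise_sd_db=0.0,
        slot_s=base.slot_s,
        backoff_window=base.backoff_window,
        loss_floor=base.loss_floor,
        retry_limit=base.retry_limit,
    )


def nearest_anchor_region(point: tuple[float, float],
                          anchors: list[tuple[float, float]]) -> int:
    """Integer region id: index of the nearest anchor (the form carried in
    the continuous-sampling packet's location field)."""
    d = [np.hypot(point[0] - a[0], point[1] - a[1]) for a in anchors]
    return int(np.argmin(d))
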