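"""Discrete-event simulator of the hierarchical sensor-network routing layer.

Models a body-sensor network with four node roles (remote wearable,
cluster, gateway, sink), a log-distance radio channel, a link metric that
combines received signal strength (RSSI), hop count toward the sink, and a
node-lifetime proxy (TTL), routing tables that keep every useful neighbor
as a redundant entry, abstract listen-before-talk contention (slotted
random backoff with collision retries), node failure with fallback routing,
and scheduled rejoin with role re-election.

The medium-access model is deliberately abstract: contention applies among
packets originating in the same slot, forwarding along an acquired route is
atomic, and the radio physical layer is a deterministic path-loss curve
plus optional log-normal shadowing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

ROLES = ("remote", "cluster", "gateway", "sink")


@dataclass
class Node:
    id: int
    role: str
    position: tuple[float, float]
    ttl: float = 100.0
    alive: bool = True

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class ChannelConfig:
    """Radio and medium-access parameters.

    Log-distance path loss: RSSI(d) = tx_power - (ref_loss_db +
    10 * path_loss_exp * log10(d)) + N(0, noise_sd_db).  A link exists when
    the deterministic RSSI is at or above ``sensitivity_dbm``.
    """

    path_loss_exp: float = 2.5
    ref_loss_db: float = 40.0
    tx_power_dbm: float = 0.0
    sensitivity_dbm: float = -90.0
    noise_sd_db: float = 0.0
    slot_s: float = 0.01
    backoff_window: int = 8
    loss_floor: float = 0.0
    retry_limit: int = 3
    ttl_init: float = 100.0
    ttl_per_tx: float = 0.01

    def __post_init__(self) -> None:
        if self.sensitivity_dbm >= self.tx_power_dbm:
            raise ValueError("sensitivity must be below tx power")
        if not (0 <= self.loss_floor <= 1):
            raise ValueError("loss_floor must be a probability")

    @property
    def max_range_m(self) -> float:
        """Distance at which the noise-free RSSI hits sensitivity."""
        return 10 ** ((self.tx_power_dbm - self.ref_loss_db - self.sensitivity_dbm)
                      / (10 * self.path_loss_exp))


def rssi_model(distance_m: float, cfg: ChannelConfig,
               rng: np.random.Generator | None = None) -> float:
    """Received signal strength (dBm) at a distance; deterministic when
    the shadowing standard deviation is zero."""
    if distance_m <= 0:
        raise ValueError("distance must be positive")
    rssi = cfg.tx_power_dbm - (cfg.ref_loss_db
                               + 10 * cfg.path_loss_exp * np.log10(distance_m))
    if cfg.noise_sd_db > 0:
        if rng is None:
            rng = np.random.default_rng()
        rssi += rng.normal(0.0, cfg.noise_sd_db)
    return float(rssi)


def link_weight(rssi_dbm: float, hops: int, ttl: float,
                weights: tuple[float, float, float] = (0.5, 0.3, 0.2),
                cfg: ChannelConfig | None = None,
                max_hops: int = 10) -> float:
    """Link metric: higher is better.

    weight = w_r * norm(rssi) - w_h * hops/max_hops + w_t * norm(ttl),
    with RSSI normalized over [sensitivity, tx power] and TTL over
    [0, ttl_init].  Monotone increasing in RSSI and TTL, decreasing in
    hop count.
    """
    if hops < 1:
        raise ValueError("hops must be >= 1")
    if ttl < 0:
        raise ValueError("ttl must be non-negative")
    cfg = cfg or ChannelConfig()
    w_r, w_h, w_t = weights
    nr = np.clip((rssi_dbm - cfg.sensitivity_dbm)
                 / (cfg.tx_power_dbm - cfg.sensitivity_dbm), 0.0, 1.0)
    nt = np.clip(ttl / cfg.ttl_init, 0.0, 1.0)
    return float(w_r * nr - w_h * hops / max_hops + w_t * nt)


@dataclass
class RouteEntry:
    next_hop: int
    weight: float


class Network:
    """Node set plus the in-range link graph derived from positions."""

    def __init__(self, nodes: list[Node], cfg: ChannelConfig):
        sinks = [n for n in nodes if n.role == "sink"]
        if len(sinks) != 1:
            raise ValueError("network must contain exactly one sink")
        self.nodes: dict[int, Node] = {n.id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise ValueError("duplicate node ids")
        self.cfg = cfg
        self.sink_id = sinks[0].id
        for n in nodes:
            n.ttl = cfg.ttl_init
        self.routes: dict[int, list[RouteEntry]] = {}
        self.hops: dict[int, int] = {}
        self.unreachable: set[int] = set()

    def distance(self, a: int, b: int) -> float:
        pa, pb = self.nodes[a].position, self.nodes[b].position
        return float(np.hypot(pa[0] - pb[0], pa[1] - pb[1]))

    def neighbors(self, nid: int) -> list[int]:
        """Alive nodes within radio range (remote nodes never relay)."""
        r = self.cfg.max_range_m
        out = []
        for m in self.nodes.values():
            if m.id == nid or not m.alive:
                continue
            if self.distance(nid, m.id) <= r:
                out.append(m.id)
        return out


def build_routes(net: Network) -> dict[int, list[RouteEntry]]:
    """Breadth-first hop counts from the sink; each node keeps every
    in-range neighbor strictly closer to the sink, best weight first.

    Remote nodes originate but never relay, so they are excluded as next
    hops for other nodes.  Nodes without a path are flagged unreachable.
    """
    hops = {net.sink_id: 0}
    frontier = [net.sink_id]
    while frontier:
        nxt = []
        for nid in frontier:
            for m in net.neighbors(nid):
                if m not in hops and net.nodes[m].alive:
                    # remote nodes are leaves: they get a hop count but
                    # never extend the tree
                    hops[m] = hops[nid] + 1
                    if net.nodes[m].role != "remote":
                        nxt.append(m)
        frontier = nxt

    routes: dict[int, list[RouteEntry]] = {}
    unreachable: set[int] = set()
    for n in net.nodes.values():
        if not n.alive:
            continue
        if n.id == net.sink_id:
            routes[n.id] = []
            continue
        if n.id not in hops:
            unreachable.add(n.id)
            routes[n.id] = []
            continue
        entries = []
        for m in net.neighbors(n.id):
            if m in hops and hops[m] < hops[n.id] and net.nodes[m].role != "remote":
                rssi = rssi_model(net.distance(n.id, m), net.cfg)
                w = link_weight(rssi, hops[m] + 1, net.nodes[m].ttl, cfg=net.cfg)
                entries.append(RouteEntry(m, w))
        entries.sort(key=lambda e: -e.weight)
        routes[n.id] = entries
    net.routes, net.hops, net.unreachable = routes, hops, unreachable
    return routes


@dataclass
class PacketTrace:
    packet_id: int
    src: int
    time_s: float
    path: list[int]
    status: str  # delivered | lost_collision | lost_channel | lost_no_route | lost_injected


@dataclass
class SimResult:
    generated: int
    delivered: int
    lost: int
    traces: list[PacketTrace] = field(default_factory=list)

    @property
    def loss_pct(self) -> float:
        return 100.0 * self.lost / self.generated if self.generated else 0.0

    def to_dict(self) -> dict:
        return {
            "generated": self.generated,
            "delivered": self.delivered,
            "lost": self.lost,
            "loss_pct": self.loss_pct,
        }


@dataclass
class NetEvent:
    """Scheduled node failure or rejoin."""

    time_s: float
    kind: str  # "fail" | "rejoin"
    node_id: int


def _elect_role(net: Network, nid: int) -> str:
    """A rejoining relay becomes a cluster if any remote is in range,
    otherwise a gateway (the sink role is never re-elected)."""
    for m in net.neighbors(nid):
        if net.nodes[m].role == "remote":
            return "cluster"
    return "gateway"


def run_simulation(
    net: Network,
    traffic: list[tuple[float, int]],
    events: list[NetEvent] | None = None,
    seed: int = 0,
    drop_packet_ids: set[int] | None = None,
) -> SimResult:
    """Run the network over a traffic schedule of (time_s, source_id).

    Each packet follows the best routing entry hop by hop; a dead next hop
    falls back to the next redundant entry.  Packets originating in the same
    contention slot draw uniform backoffs; equal backoffs collide and retry
    in later slots up to the retry limit.  An independent per-packet
    Bernoulli loss floor models residual channel loss.  ``drop_packet_ids``
    force-drops specific packets (fault injection).  Fixed seeds give
    identical results.
    """
    if not traffic:
        raise ValueError("empty traffic schedule")
    cfg = net.cfg
    rng = np.random.default_rng(seed)
    drop_packet_ids = drop_packet_ids or set()
    events = sorted(events or [], key=lambda e: e.time_s)
    build_routes(net)

    # slot index -> list of (packet_id, src, t, retries)
    pending: dict[int, list[list]] = {}
    for pid, (t, src) in enumerate(sorted(traffic)):
        if src not in net.nodes:
            raise ValueError(f"unknown traffic source {src}")
        pending.setdefault(int(t / cfg.slot_s), []).append([pid, src, t, 0])

    traces: list[PacketTrace] = []
    delivered = lost = 0
    ev_i = 0
    slot = min(pending)
    max_slot = max(pending)

    def finish(pid, src, t, path, status):
        nonlocal delivered, lost
        traces.append(PacketTrace(pid, src, t, path, status))
        if status == "delivered":
            delivered += 1
        else:
            lost += 1

    while pending and slot <= max_slot + cfg.retry_limit + 1:
        now = slot * cfg.slot_s
        # apply scheduled failures / rejoins that are due
        dirty = False
        while ev_i < len(events) and events[ev_i].time_s <= now:
            ev = events[ev_i]
            node = net.nodes[ev.node_id]
            if ev.kind == "fail":
                node.alive = False
            elif ev.kind == "rejoin":
                node.alive = True
                node.ttl = cfg.ttl_init
                if node.role not in ("remote", "sink"):
                    node.role = _elect_role(net, node.id)
            else:
                raise ValueError(f"unknown event kind {ev.kind!r}")
            dirty = True
            ev_i += 1
        if dirty:
            build_routes(net)

        batch = pending.pop(slot, [])
        if not batch:
            slot += 1
            continue

        # contention: uniform backoff, equal draws collide
        if len(batch) > 1:
            backoffs = rng.integers(0, cfg.backoff_window, size=len(batch))
            winners, losers = [], []
            for k, pkt in enumerate(batch):
                if np.sum(backoffs == backoffs[k]) == 1:
                    winners.append(pkt)
                else:
                    losers.append(pkt)
            for pkt in losers:
                pkt[3] += 1
                if pkt[3] > cfg.retry_limit:
                    finish(pkt[0], pkt[1], pkt[2], [pkt[1]], "lost_collision")
                else:
                    pending.setdefault(slot + 1, []).append(pkt)
        else:
            winners = batch

        for pid, src, t, _retries in winners:
            if pid in drop_packet_ids:
                finish(pid, src, t, [src], "lost_injected")
                continue
            if cfg.loss_floor > 0 and rng.random() < cfg.loss_floor:
                finish(pid, src, t, [src], "lost_channel")
                continue
            # hop-by-hop with redundant fallback
            path = [src]
            cur = src
            ok = True
            while cur != net.sink_id:
                entries = net.routes.get(cur, [])
                nxt = next((e.next_hop for e in entries if net.nodes[e.next_hop].alive), None)
                if nxt is None:
                    ok = False
                    break
                net.nodes[cur].ttl = max(net.nodes[cur].ttl - cfg.ttl_per_tx, 0.0)
                path.append(nxt)
                cur = nxt
            finish(pid, src, t, path, "delivered" if ok else "lost_no_route")
        slot += 1

    # anything still pending past the horizon is lost to contention
    for batch in pending.values():
        for pid, src, t, _ in batch:
            finish(pid, src, t, [src], "lost_collision")

    generated = delivered + lost
    assert generated == len(traffic)
    return SimResult(generated=generated, delivered=delivered, lost=lost, traces=traces)


# --------------------------------------------------------------------------
# Scenario files

def load_scenario(path: str | Path) -> tuple[Network, list[tuple[float, int]], list[NetEvent]]:
    """Load a YAML/JSON scenario: nodes, channel, traffic, events.

    Structure::

        channel: {path_loss_exp: 2.5, tx_power_dbm: 0, ...}
        nodes: [{id: 1, role: remote, x: 0.0, y: 0.0}, ...]
        traffic: [{time: 0.0, src: 1}, ...]
        events: [{time: 5.0, kind: fail, node: 2}, ...]
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    cfg = ChannelConfig(**doc.get("channel", {}))
    nodes = [Node(d["id"], d["role"], (float(d["x"]), float(d["y"])))
             for d in doc["nodes"]]
    traffic = [(float(d["time"]), int(d["src"])) for d in doc.get("traffic", [])]
    events = [NetEvent(float(d["time"]), d["kind"], int(d["node"]))
              for d in doc.get("events", [])]
    return Network(nodes, cfg), traffic, events


def result_to_json(res: SimResult) -> str:
    return json.dumps(res.to_dict(), indent=1)


def traces_to_csv(res: SimResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("packet_id,src,time_s,status,path\n")
        for tr in res.traces:
            fh.write(f"{tr.packet_id},{tr.src},{tr.time_s},{tr.status},"
                     f"{'-'.join(map(str, tr.path))}\n")
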