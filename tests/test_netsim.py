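"""Routing simulator: channel model, link metric monotonicity, route
construction, packet conservation, determinism and fault tolerance."""

import numpy as np
import pytest

from vitalnet.netsim import (
    ChannelConfig,
    NetEvent,
    Network,
    Node,
    build_routes,
    link_weight,
    load_scenario,
    rssi_model,
    run_simulation,
)

# range exactly 100 m: 0 - 40 - 10*2*log10(100) = -80 dBm
CFG = ChannelConfig(path_loss_exp=2.0, ref_loss_db=40.0,
                    tx_power_dbm=0.0, sensitivity_dbm=-80.0)


def chain_network():
    nodes = [Node(0, "remote", (0, 0)), Node(1, "cluster", (80, 0)),
             Node(2, "sink", (160, 0))]
    return Network(nodes, CFG)


def diamond_network():
    nodes = [Node(0, "remote", (0, 0)), Node(1, "cluster", (60, 40)),
             Node(2, "cluster", (60, -40)), Node(3, "sink", (120, 0))]
    return Network(nodes, CFG)


class TestChannel:
    def test_reference_distance(self):
        assert rssi_model(1.0, CFG) == pytest.approx(0.0 - 40.0)

    def test_doubling_distance_drops_6db(self):
        drop = rssi_model(10.0, CFG) - rssi_model(20.0, CFG)
        assert drop == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            rssi_model(0.0, CFG)

    def test_max_range(self):
        assert CFG.max_range_m == pytest.approx(100.0)


class TestLinkWeight:
    def test_monotone_in_hops(self):
        assert link_weight(-60, 1, 50, cfg=CFG) > link_weight(-60, 3, 50, cfg=CFG)

    def test_monotone_in_rssi(self):
        assert link_weight(-60, 2, 50, cfg=CFG) > link_weight(-90, 2, 50, cfg=CFG)

    def test_monotone_in_ttl(self):
        assert link_weight(-60, 2, 100, cfg=CFG) > link_weight(-60, 2, 0, cfg=CFG)

    def test_negative_hops_rejected(self):
        with pytest.raises(ValueError):
            link_weight(-60, 0, 50, cfg=CFG)


class TestRoutes:
    def test_chain_topology(self):
        net = chain_network()
        routes = build_routes(net)
        assert [e.next_hop for e in routes[0]] == [1]
        assert [e.next_hop for e in routes[1]] == [2]
        assert net.unreachable == set()

    def test_diamond_stores_redundant_entries(self):
        net = diamond_network()
        routes = build_routes(net)
        assert len(routes[0]) == 2
        assert {e.next_hop for e in routes[0]} == {1, 2}

    def test_isolated_node_flagged_unreachable(self):
        nodes = [Node(0, "remote", (0, 0)), Node(1, "sink", (500, 0))]
        net = Network(nodes, CFG)
        build_routes(net)
        assert 0 in net.unreachable

    def test_exactly_one_sink_enforced(self):
        with pytest.raises(ValueError):
            Network([Node(0, "remote", (0, 0))], CFG)


class TestSimulation:
    def test_lossless_single_link(self):
        net = chain_network()
        res = run_simulation(net, [(float(i), 0) for i in range(50)], seed=0)
        assert res.loss_pct == 0.0
        assert res.delivered == 50

    def test_conservation_invariant(self, rng):
        cfg = ChannelConfig(path_loss_exp=2.0, ref_loss_db=40.0,
                            tx_power_dbm=0.0, sensitivity_dbm=-80.0,
                            loss_floor=0.2)
        for trial in range(5):
            net = diamond_network()
            net.cfg = cfg
            traffic = [(float(rng.uniform(0, 5)), 0) for _ in range(80)]
            res = run_simulation(net, traffic, seed=trial)
            assert res.generated == res.delivered + res.lost == 80

    def test_seed_determinism(self):
        traffic = [(float(i) * 0.005, 0) for i in range(100)]  # heavy contention
        cfg = ChannelConfig(path_loss_exp=2.0, ref_loss_db=40.0,
                            tx_power_dbm=0.0, sensitivity_dbm=-80.0,
                            loss_floor=0.1)
        results = []
        for _ in range(2):
            net = chain_network()
            net.cfg = cfg
            results.append(run_simulation(net, traffic, seed=99))
        assert results[0].to_dict() == results[1].to_dict()

    def test_fallback_on_dead_relay(self):
        # kill the primary relay mid-run; redundant entry keeps delivery at 100%
        traffic = [(float(i), 0) for i in range(100)]
        baseline = run_simulation(diamond_network(), traffic, seed=5)
        net = diamond_network()
        primary = build_routes(net)[0][0].next_hop
        res = run_simulation(diamond_network(), traffic,
                             events=[NetEvent(50.0, "fail", primary)], seed=5)
        assert res.delivered == baseline.delivered == 100

    def test_kill_any_single_relay_in_redundant_topology(self):
        traffic = [(float(i), 0) for i in range(60)]
        for victim in (1, 2):
            res = run_simulation(diamond_network(), traffic,
                                 events=[NetEvent(20.0, "fail", victim)], seed=3)
            assert res.delivered == res.generated

    def test_rejoin_restores_route(self):
        traffic = [(float(i), 0) for i in range(100)]
        events = [NetEvent(20.0, "fail", 1), NetEvent(60.0, "rejoin", 1)]
        net = chain_network()
        res = run_simulation(net, traffic, events=events, seed=7)
        # packets during the outage are lost, the rest delivered
        assert res.lost == 40
        assert res.delivered == 60
        assert net.nodes[1].alive

    def test_adding_relays_never_hurts(self):
        traffic = [(float(i), 0) for i in range(60)]
        sparse = run_simulation(chain_network(), traffic, seed=11)
        nodes = [Node(0, "remote", (0, 0)), Node(1, "cluster", (80, 0)),
                 Node(3, "cluster", (80, 30)), Node(4, "gateway", (120, 0)),
                 Node(2, "sink", (160, 0))]
        dense = run_simulation(Network(nodes, CFG), traffic, seed=11)
        assert dense.delivered >= sparse.delivered

    def test_empty_traffic_rejected(self):
        with pytest.raises(ValueError):
            run_simulation(chain_network(), [], seed=0)


def test_scenario_file_loading(tmp_path):
    text = """
channel: {path_loss_exp: 2.0, ref_loss_db: 40.0, tx_power_dbm: 0.0, sensitivity_dbm: -80.0}
nodes:
  - {id: 0, role: remote, x: 0, y: 0}
  - {id: 1, role: cluster, x: 80, y: 0}
  - {id: 2, role: sink, x: 160, y: 0}
traffic:
  - {time: 0.0, src: 0}
  - {time: 1.0, src: 0}
events:
  - {time: 0.5, kind: fail, node: 1}
"""
    p = tmp_path / "scn.yaml"
    p.write_text(text)
    net, traffic, events = load_scenario(p)
    assert len(net.nodes) == 3 and len(traffic) == 2 and len(events) == 1
    res = run_simulation(net, traffic, events, seed=0)
    assert res.delivered == 1 and res.lost == 1
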