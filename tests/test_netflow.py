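"""Network hydraulics: lattice construction, Kirchhoff/Hagen-Poiseuille
solves, blockage, solute routing, and dimensionless assumption checks."""

import math

import numpy as np
import pytest

from perfunet.netflow import (Edge, NetworkGraph, NetworkError, Node,
                              WellPosednessError, assumption_numbers,
                              block_edge, build_unit_network, route_solute,
                              solve_flow)
from perfunet.parameters import Medium

MEDIUM = Medium()


def lattice_with_dp(n=4, s=0.5, R_c=0.04, dp=100.0):
    g = build_unit_network(n, n, n, s, R_c)
    inlet = g.face_nodes(0, maximum=False)
    outlet = g.face_nodes(0, maximum=True)
    return g.with_bc(pressure={**{i: dp for i in inlet},
                               **{i: 0.0 for i in outlet}})


def test_lattice_counts():
    g = build_unit_network(4, 4, 4, 0.5, 0.04)
    assert len(g.nodes) == 125
    assert len(g.edges) == 300  # 3·n(n+1)² for n=4
    g1 = build_unit_network(1, 1, 1, 0.5, 0.04)
    assert (len(g1.nodes), len(g1.edges)) == (8, 12)


def test_lattice_degeneracy_error():
    with pytest.raises(NetworkError):
        build_unit_network(1, 1, 1, 0.05, 0.04)


def test_series_edges_conserve_inflow():
    nodes = [Node(0, 0, 0, 0, "inflow", 2.5), Node(1, 1, 0, 0),
             Node(2, 2, 0, 0, "pressure", 0.0)]
    edges = [Edge(0, 0, 1, 0.05, 1.0), Edge(1, 1, 2, 0.03, 1.0)]
    flow = solve_flow(NetworkGraph(nodes, edges), MEDIUM)
    assert flow.Q[0] == pytest.approx(2.5, rel=1e-12)
    assert flow.Q[1] == pytest.approx(2.5, rel=1e-12)


def test_parallel_edges_split_by_r4():
    """Equal-length parallel channels of radius R and 2R split 1:16."""
    nodes = [Node(0, 0, 0, 0, "pressure", 10.0), Node(1, 1, 0, 0, "pressure", 0.0)]
    edges = [Edge(0, 0, 1, 0.05, 1.0), Edge(1, 0, 1, 0.10, 1.0)]
    flow = solve_flow(NetworkGraph(nodes, edges), MEDIUM)
    assert flow.Q[1] / flow.Q[0] == pytest.approx(16.0, rel=1e-12)
    # direct two-unknown oracle: Q_i = G_i (p0 - p1)
    for e in edges:
        G = math.pi * e.R_c ** 4 / (8 * MEDIUM.mu * e.L)
        assert flow.Q[e.id] == pytest.approx(G * 10.0, rel=1e-12)


def test_dense_oracle_equivalence(rng):
    """On small random graphs, solve_flow matches a dense direct solve of
    the same linear system to 1e-12 relative."""
    for trial in range(10):
        n_nodes = int(rng.integers(3, 6))
        # random connected graph: a spine plus extra random edges (<= 6 total)
        nodes = [Node(i, *rng.uniform(0, 2, 3)) for i in range(n_nodes)]
        pairs = [(i, i + 1) for i in range(n_nodes - 1)]
        while len(pairs) < min(6, n_nodes * (n_nodes - 1) // 2):
            a, b = sorted(rng.integers(0, n_nodes, 2))
            if a != b and (a, b) not in pairs:
                pairs.append((a, b))
        edges = [Edge(k, a, b, float(rng.uniform(0.02, 0.08)),
                      float(rng.uniform(0.5, 2.0)))
                 for k, (a, b) in enumerate(pairs)]
        nodes[0] = Node(0, *rng.uniform(0, 2, 3), "pressure", 50.0)
        nodes[-1] = Node(n_nodes - 1, *rng.uniform(0, 2, 3), "pressure", 0.0)
        g = NetworkGraph(nodes, edges)
        flow = solve_flow(g, MEDIUM)

        # dense oracle
        G = {e.id: math.pi * e.R_c ** 4 / (8 * MEDIUM.mu * e.L) for e in edges}
        A = np.zeros((n_nodes, n_nodes))
        b = np.zeros(n_nodes)
        for e in edges:
            A[e.node_a, e.node_a] += G[e.id]
            A[e.node_b, e.node_b] += G[e.id]
            A[e.node_a, e.node_b] -= G[e.id]
            A[e.node_b, e.node_a] -= G[e.id]
        for i, p in ((0, 50.0), (n_nodes - 1, 0.0)):
            A[i, :] = 0.0
            A[i, i] = 1.0
            b[i] = p
        p_dense = np.linalg.solve(A, b)
        for node in g.nodes:
            assert flow.pressure[node.id] == pytest.approx(p_dense[node.id],
                                                           rel=1e-12, abs=1e-12)


def test_interior_node_balance_and_global_conservation():
    g = lattice_with_dp()
    flow = solve_flow(g, MEDIUM)
    bal = flow.node_imbalance()
    scale = max(abs(q) for q in flow.Q.values())
    for node in g.nodes:
        if node.bc_type == "interior":
            assert abs(bal[node.id]) < 1e-10 * scale
    inflow = sum(-b for b in bal.values() if b < 0)
    outflow = sum(b for b in bal.values() if b > 0)
    assert inflow == pytest.approx(outflow, rel=1e-10)


def test_gauge_invariance():
    g = lattice_with_dp(n=2)
    flow = solve_flow(g, MEDIUM)
    g2 = lattice_with_dp(n=2)
    g2 = g2.with_bc(pressure={n.id: n.bc_value + 777.0 for n in g2.nodes
                              if n.bc_type == "pressure"})
    flow2 = solve_flow(g2, MEDIUM)
    for e in g.edges:
        assert flow2.Q[e.id] == pytest.approx(flow.Q[e.id], rel=1e-9, abs=1e-15)


def test_blockage_redistributes_into_secondary_channels():
    """Blocking a central primary edge sends flow through secondary (y/z)
    channels that are stagnant in the unblocked symmetric lattice."""
    g = lattice_with_dp()
    flow = solve_flow(g, MEDIUM)
    coords = {n.id: np.array([n.x, n.y, n.z]) for n in g.nodes}

    def is_primary(e):
        return abs((coords[e.node_b] - coords[e.node_a])[0]) > 1e-12

    center = np.array([1.0, 1.0, 1.0])
    central = min((e for e in g.edges if is_primary(e)),
                  key=lambda e: np.linalg.norm(
                      (coords[e.node_a] + coords[e.node_b]) / 2 - center))
    # unblocked: all secondary edges stagnant
    qmax = max(abs(q) for q in flow.Q.values())
    for e in g.edges:
        if not is_primary(e):
            assert abs(flow.Q[e.id]) < 1e-10 * qmax
    gb = block_edge(g, central.id)
    flowb = solve_flow(gb, MEDIUM)
    assert flowb.Q[central.id] == 0.0
    adjacent_secondary = [e for e in gb.edges if not is_primary(e)
                          and {e.node_a, e.node_b} & {central.node_a, central.node_b}]
    assert adjacent_secondary
    for e in adjacent_secondary:
        assert abs(flowb.Q[e.id]) > 1e-8 * qmax


def test_blockage_monotonicity():
    """At fixed driving pressure, blocking an edge never increases total flow."""
    g = lattice_with_dp(n=2)
    total0 = sum(b for b in solve_flow(g, MEDIUM).node_imbalance().values() if b > 0)
    for eid in (0, 5, 17):
        gb = block_edge(g, eid)
        total = sum(b for b in solve_flow(gb, MEDIUM).node_imbalance().values()
                    if b > 0)
        assert total <= total0 * (1 + 1e-12)


def test_block_parallel_and_only_edge():
    nodes = [Node(0, 0, 0, 0, "pressure", 10.0), Node(1, 1, 0, 0, "pressure", 0.0)]
    g = NetworkGraph(nodes, [Edge(0, 0, 1, 0.05, 1.0), Edge(1, 0, 1, 0.05, 1.0)])
    gb = block_edge(g, 0)
    flow = solve_flow(gb, MEDIUM)
    assert flow.Q[0] == 0.0
    assert flow.Q[1] > 0
    g1 = NetworkGraph(nodes, [Edge(0, 0, 1, 0.05, 1.0)])
    with pytest.raises(WellPosednessError):
        block_edge(g1, 0)


def test_no_pressure_anchor_raises():
    nodes = [Node(0, 0, 0, 0, "inflow", 1.0), Node(1, 1, 0, 0)]
    with pytest.raises(WellPosednessError):
        solve_flow(NetworkGraph(nodes, [Edge(0, 0, 1, 0.05, 1.0)]), MEDIUM)


def test_route_solute_uniform():
    g = lattice_with_dp(n=2)
    flow = solve_flow(g, MEDIUM)
    sol = route_solute(g, flow, 0.2)
    for eid, c in sol.edge_c_out.items():
        if not math.isnan(c):
            assert c == pytest.approx(0.2, rel=1e-12)


def test_route_solute_y_junction_mixing():
    """(Q=1, c=1) merging with (Q=3, c=0) gives downstream c = 0.25."""
    nodes = [Node(0, 0, 0, 0, "inflow", 1.0), Node(1, 0, 2, 0, "inflow", 3.0),
             Node(2, 1, 1, 0), Node(3, 2, 1, 0, "pressure", 0.0)]
    edges = [Edge(0, 0, 2, 0.05, math.sqrt(2)), Edge(1, 1, 2, 0.05, math.sqrt(2)),
             Edge(2, 2, 3, 0.05, 1.0)]
    g = NetworkGraph(nodes, edges)
    flow = solve_flow(g, MEDIUM)
    sol = route_solute(g, flow, {0: 1.0, 1: 0.0})
    assert sol.node_c[2] == pytest.approx(0.25, rel=1e-12)
    assert sol.edge_c_in[2] == pytest.approx(0.25, rel=1e-12)


def test_route_solute_constant_sink_closed_form():
    """Single edge with constant per-length loss φ: outlet = inlet − φL/Q."""
    nodes = [Node(0, 0, 0, 0, "inflow", 0.5), Node(1, 2, 0, 0, "pressure", 0.0)]
    g = NetworkGraph(nodes, [Edge(0, 0, 1, 0.05, 2.0)])
    flow = solve_flow(g, MEDIUM)
    phi = 0.01
    sol = route_solute(g, flow, 1.0, per_edge_sink={0: phi})
    assert sol.edge_c_out[0] == pytest.approx(1.0 - phi * 2.0 / 0.5, rel=1e-12)


def test_solute_conservation_no_sink():
    """Flow-weighted concentration flux in equals out at every junction."""
    g = lattice_with_dp()
    # make the flow non-trivial by blocking a couple of edges
    g = block_edge(block_edge(g, 40), 140)
    flow = solve_flow(g, MEDIUM)
    sol = route_solute(g, flow, 0.37)
    for node in g.nodes:
        flux_in = flux_out = 0.0
        for e in g.edges:
            q = flow.Q[e.id]
            if abs(q) < 1e-14:
                continue
            upstream = e.node_a if q > 0 else e.node_b
            if upstream == node.id:
                flux_out += abs(q) * sol.edge_c_in[e.id]
            elif e.node_a == node.id or e.node_b == node.id:
                flux_in += abs(q) * sol.edge_c_out[e.id]
        if node.bc_type == "interior" and flux_in > 0:
            assert flux_out == pytest.approx(flux_in, rel=1e-8)


def test_assumption_numbers():
    Re, Pe, Gz = assumption_numbers(0.05, 5.0, 8.0, 0.696, 3e-3)
    assert Re == pytest.approx(1.149, rel=1e-3)  # Re ≈ 1 operating point
    assert Pe == pytest.approx(8.0 * 5.0 / 3e-3)
    assert Gz == pytest.approx(8.0 * 0.05 ** 2 / (3e-3 * 5.0))
    assert assumption_numbers(0.05, 5.0, 0.0, 0.696, 3e-3) == (0.0, 0.0, 0.0)


def test_assumption_warnings():
    with pytest.warns(UserWarning, match="Re"):
        assumption_numbers(0.05, 5.0, 200.0, 0.696, 3e-3)


def test_csv_json_roundtrip(tmp_path):
    g = lattice_with_dp(n=2)
    g.to_csv(tmp_path / "n.csv", tmp_path / "e.csv")
    g2 = NetworkGraph.from_csv(tmp_path / "n.csv", tmp_path / "e.csv")
    assert g2.to_frames()[0].equals(g.to_frames()[0])
    assert g2.to_frames()[1].equals(g.to_frames()[1])
    g.to_json(tmp_path / "net.json")
    g3 = NetworkGraph.from_json(tmp_path / "net.json")
    assert g3.to_frames()[1].equals(g.to_frames()[1])


def test_edge_length_consistency_check():
    nodes = [Node(0, 0, 0, 0, "pressure", 1.0), Node(1, 1, 0, 0, "pressure", 0.0)]
    g = NetworkGraph(nodes, [Edge(0, 0, 1, 0.05, 2.0)])  # wrong length
    with pytest.raises(NetworkError, match="length"):
        g.validate()
    g.validate(allow_length_mismatch=True)
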