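"""Hydraulics and solute routing on channel networks.

A supply network is a graph of rigid cylindrical channel segments.  Each
segment obeys Hagen–Poiseuille's law, Δp = 8μLQ/(πR_c⁴), and every junction
conserves both volumetric flow and solute flow (Kirchhoff's current law):

    Σ_i Q_i = 0   and   Σ_i Q_i·c_i = 0.

Pressures follow from a sparse symmetric positive-definite solve with edge
conductance G = πR_c⁴/(8μL); solute is then routed through the directed
acyclic flow graph in descending-pressure order (Stokes flow runs strictly
from high to low pressure).  Blocked edges keep their geometry but carry
zero conductance, matching the treatment of a clogged channel as an
impermeable surface.

Units: mm, s, Pa, mol m⁻³; flow rates in mm³ s⁻¹.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "Node",
    "Edge",
    "NetworkGraph",
    "FlowSolution",
    "SoluteSolution",
    "NetworkError",
    "WellPosednessError",
    "build_unit_network",
    "solve_flow",
    "route_solute",
    "block_edge",
    "assumption_numbers",
    "edge_assumption_numbers",
]

BC_INTERIOR = "interior"
BC_PRESSURE = "pressure"
BC_INFLOW = "inflow"

_LENGTH_TOL = 1e-9


class NetworkError(ValueError):
    """Invalid network description."""


class WellPosednessError(NetworkError):
    """Boundary conditions do not determine a unique flow solution."""


@dataclass(frozen=True)
class Node:
    id: int
    x: float
    y: float
    z: float
    bc_type: str = BC_INTERIOR
    bc_value: float = 0.0  # Pa for pressure BC, mm³ s⁻¹ for inflow BC

    @property
    def position(self):
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class Edge:
    id: int
    node_a: int
    node_b: int
    R_c: float  # inner radius, mm
    L: float    # segment length, mm
    blocked: bool = False

    def conductance(self, mu: float) -> float:
        """Hydraulic conductance G = πR_c⁴/(8μL), mm³ s⁻¹ Pa⁻¹."""
        if self.blocked:
            return 0.0
        return math.pi * self.R_c ** 4 / (8.0 * mu * self.L)


@dataclass
class NetworkGraph:
    """Channel network: nodes with boundary tags, edges with radii/lengths.

    Edge orientation is from lower to higher node id; signed flow rates
    follow that orientation.
    """

    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self):
        self._normalize()

    def _normalize(self):
        self.nodes = sorted(self.nodes, key=lambda n: n.id)
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate node ids")
        self.edges = [
            e if e.node_a < e.node_b else replace(e, node_a=e.node_b, node_b=e.node_a)
            for e in sorted(self.edges, key=lambda e: e.id)
        ]
        eids = [e.id for e in self.edges]
        if len(set(eids)) != len(eids):
            raise NetworkError("duplicate edge ids")
        self._node_index = {n.id: i for i, n in enumerate(self.nodes)}

    def node(self, node_id: int) -> Node:
        return self.nodes[self._node_index[node_id]]

    def edge(self, edge_id: int) -> Edge:
        for e in self.edges:
            if e.id == edge_id:
                return e
        raise NetworkError(f"no edge with id {edge_id}")

    def validate(self, allow_length_mismatch: bool = False) -> None:
        for e in self.edges:
            if e.R_c <= 0 or e.L <= 0:
                raise NetworkError(f"edge {e.id}: R_c and L must be positive")
            if e.node_a not in self._node_index or e.node_b not in self._node_index:
                raise NetworkError(f"edge {e.id} references unknown node")
            if not allow_length_mismatch:
                d = np.linalg.norm(self.node(e.node_a).position
                                   - self.node(e.node_b).position)
                if abs(d - e.L) > _LENGTH_TOL:
                    raise NetworkError(
                        f"edge {e.id}: length {e.L} differs from node distance {d}"
                    )
        if not any(n.bc_type == BC_PRESSURE for n in self.nodes):
            raise WellPosednessError(
                "no fixed-pressure node: the pressure gauge is undetermined"
            )
        g = self.to_networkx(unblocked_only=True)
        if self.nodes and not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise WellPosednessError(
                f"network not connected among unblocked edges; components: {comps}"
            )

    def to_networkx(self, unblocked_only: bool = False) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(n.id for n in self.nodes)
        for e in self.edges:
            if unblocked_only and e.blocked:
                continue
            g.add_edge(e.node_a, e.node_b, id=e.id)
        return g

    def with_bc(self, pressure: dict[int, float] | None = None,
                inflow: dict[int, float] | None = None) -> "NetworkGraph":
        """Return a copy with the given boundary tags applied."""
        pressure = pressure or {}
        inflow = inflow or {}
        overlap = set(pressure) & set(inflow)
        if overlap:
            raise NetworkError(f"nodes with both pressure and inflow BC: {sorted(overlap)}")
        nodes = []
        for n in self.nodes:
            if n.id in pressure:
                nodes.append(replace(n, bc_type=BC_PRESSURE, bc_value=pressure[n.id]))
            elif n.id in inflow:
                nodes.append(replace(n, bc_type=BC_INFLOW, bc_value=inflow[n.id]))
            else:
                nodes.append(replace(n, bc_type=BC_INTERIOR, bc_value=0.0))
        return NetworkGraph(nodes, list(self.edges))

    def face_nodes(self, axis: int, maximum: bool) -> list[int]:
        """Node ids on the min/max face of the lattice along an axis (0=x)."""
        coords = np.array([[n.x, n.y, n.z] for n in self.nodes])
        target = coords[:, axis].max() if maximum else coords[:, axis].min()
        sel = np.abs(coords[:, axis] - target) < _LENGTH_TOL
        return [n.id for n, s in zip(self.nodes, sel) if s]

    # ---- serialization ------------------------------------------------

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes = pd.DataFrame(
            [(n.id, n.x, n.y, n.z, n.bc_type, n.bc_value) for n in self.nodes],
            columns=["id", "x", "y", "z", "bc_type", "bc_value"],
        )
        edges = pd.DataFrame(
            [(e.id, e.node_a, e.node_b, e.R_c, e.L, e.blocked) for e in self.edges],
            columns=["id", "node_a", "node_b", "R_c", "L", "blocked"],
        )
        return nodes, edges

    def to_csv(self, nodes_path, edges_path) -> None:
        nodes, edges = self.to_frames()
        nodes.to_csv(nodes_path, index=False)
        edges.to_csv(edges_path, index=False)

    @classmethod
    def from_frames(cls, nodes: pd.DataFrame, edges: pd.DataFrame) -> "NetworkGraph":
        ns = [Node(int(r.id), float(r.x), float(r.y), float(r.z),
                   str(r.bc_type), float(r.bc_value))
              for r in nodes.itertuples()]
        es = [Edge(int(r.id), int(r.node_a), int(r.node_b), float(r.R_c),
                   float(r.L), bool(r.blocked))
              for r in edges.itertuples()]
        return cls(ns, es)

    @classmethod
    def from_csv(cls, nodes_path, edges_path) -> "NetworkGraph":
        return cls.from_frames(pd.read_csv(nodes_path), pd.read_csv(edges_path))

    def to_json(self, path=None):
        nodes, edges = self.to_frames()
        doc = {"nodes": nodes.to_dict("records"), "edges": edges.to_dict("records")}
        if path is None:
            return doc
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, source) -> "NetworkGraph":
        doc = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        return cls.from_frames(pd.DataFrame(doc["nodes"]), pd.DataFrame(doc["edges"]))


@dataclass
class FlowSolution:
    """Nodal pressures (Pa) and signed per-edge flow rates (mm³ s⁻¹)."""

    graph: NetworkGraph
    pressure: dict[int, float]
    Q: dict[int, float]

    def velocity(self, edge_id: int) -> float:
        """Signed mean velocity v̄ = Q/(πR_c²), mm s⁻¹."""
        e = self.graph.edge(edge_id)
        return self.Q[edge_id] / (math.pi * e.R_c ** 2)

    def pressure_drop(self, edge_id: int) -> float:
        e = self.graph.edge(edge_id)
        return self.pressure[e.node_a] - self.pressure[e.node_b]

    def node_imbalance(self) -> dict[int, float]:
        """Net flow into each node from edges (== −external exchange)."""
        bal = {n.id: 0.0 for n in self.graph.nodes}
        for e in self.graph.edges:
            q = self.Q[e.id]
            bal[e.node_a] -= q
            bal[e.node_b] += q
        return bal

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.graph.edges:
            rows.append((e.id, self.Q[e.id], self.velocity(e.id),
                         self.pressure_drop(e.id)))
        return pd.DataFrame(rows, columns=["edge_id", "Q", "v_bar", "dp"])


@dataclass
class SoluteSolution:
    """Per-edge inlet/outlet mean concentrations and nodal mixed values."""

    graph: NetworkGraph
    node_c: dict[int, float]
    edge_c_in: dict[int, float]
    edge_c_out: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [(e.id, self.edge_c_in[e.id], self.edge_c_out[e.id])
                for e in self.graph.edges]
        return pd.DataFrame(rows, columns=["edge_id", "c_in", "c_out"])


def build_unit_network(n_x: int, n_y: int, n_z: int, s: float,
                       R_c: float) -> NetworkGraph:
    """Cartesian lattice of cuboid base units with channels along the edges.

    Nodes sit at the (n_x+1)(n_y+1)(n_z+1) lattice points of spacing ``s``;
    primary channels run along x, secondary channels along y and z.  All
    nodes are created untagged; apply boundary conditions with
    :meth:`NetworkGraph.with_bc` / :meth:`NetworkGraph.face_nodes`.
    """
    if min(n_x, n_y, n_z) < 1:
        raise NetworkError("cell counts must be >= 1")
    if not s > 2.0 * R_c:
        raise NetworkError(
            f"edge length s={s} must exceed the channel diameter 2R_c={2 * R_c}"
        )
    shape = (n_x + 1, n_y + 1, n_z + 1)

    def nid(i, j, k):
        return (i * shape[1] + j) * shape[2] + k

    nodes = [Node(nid(i, j, k), i * s, j * s, k * s)
             for i in range(shape[0]) for j in range(shape[1]) for k in range(shape[2])]
    edges = []
    eid = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                for di, dj, dk in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if ii < shape[0] and jj < shape[1] and kk < shape[2]:
                        edges.append(Edge(eid, nid(i, j, k), nid(ii, jj, kk), R_c, s))
                        eid += 1
    return NetworkGraph(nodes, edges)


def solve_flow(g: NetworkGraph, medium) -> FlowSolution:
    """Solve Kirchhoff/Hagen–Poiseuille hydraulics for nodal pressures.

    Fixed-pressure nodes are eliminated (Dirichlet), fixed-inflow nodes add
    source terms; the reduced system is symmetric positive definite and
    solved directly.  Blocked edges carry Q = 0 exactly.
    """
    g.validate(allow_length_mismatch=True)
    n = len(g.nodes)
    idx = {node.id: i for i, node in enumerate(g.nodes)}
    fixed = np.array([node.bc_type == BC_PRESSURE for node in g.nodes])
    p = np.zeros(n)
    p[fixed] = [node.bc_value for node in g.nodes if node.bc_type == BC_PRESSURE]

    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    for node in g.nodes:
        if node.bc_type == BC_INFLOW:
            rhs[idx[node.id]] += node.bc_value
    for e in g.edges:
        cond = e.conductance(medium.mu)
        if cond == 0.0:
            continue
        a, b = idx[e.node_a], idx[e.node_b]
        rows += [a, a, b, b]
        cols += [a, b, b, a]
        vals += [cond, -cond, cond, -cond]
    lap = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    free = ~fixed
    if free.any():
        a_ff = lap[free][:, free]
        b_f = rhs[free] - lap[free][:, fixed] @ p[fixed]
        # SPD after gauge fixing; a singular factor here means a free
        # component without a pressure anchor (validate() should catch it).
        p[free] = spla.spsolve(a_ff.tocsc(), b_f)

    pressure = {node.id: float(p[idx[node.id]]) for node in g.nodes}
    Q = {}
    for e in g.edges:
        Q[e.id] = float(e.conductance(medium.mu)
                        * (pressure[e.node_a] - pressure[e.node_b]))
    return FlowSolution(g, pressure, Q)


def route_solute(g: NetworkGraph, flow: FlowSolution, c_inlet,
                 per_edge_sink: dict[int, float] | None = None,
                 q_tol: float = 1e-14) -> SoluteSolution:
    """Route solute through the flow field in descending-pressure order.

    ``c_inlet`` is the concentration (mol m⁻³) at every boundary node that
    injects flow into the network, either a scalar or a dict keyed by node
    id.  ``per_edge_sink`` maps edge id to a constant per-length solute loss
    φ (mol m⁻³ mm² s⁻¹); an edge's outlet concentration is then
    inlet − φ·L/|Q| (the closed-form integral of the axial transport
    balance with constant wall loss).  Stagnant edges carry NaN.
    """
    per_edge_sink = per_edge_sink or {}
    imbalance = flow.node_imbalance()

    def inlet_c(node_id):
        if isinstance(c_inlet, dict):
            if node_id not in c_inlet:
                raise NetworkError(
                    f"boundary node {node_id} injects flow but has no inlet concentration"
                )
            return c_inlet[node_id]
        return float(c_inlet)

    order = sorted(g.nodes, key=lambda node: (-flow.pressure[node.id], node.id))
    pressures = sorted(flow.pressure.values(), reverse=True)
    if any(abs(a - b) < 1e-15 for a, b in zip(pressures, pressures[1:])):
        has_flow = any(abs(q) > q_tol for q in flow.Q.values())
        if has_flow:
            warnings.warn("pressure ties among nodes; breaking by node id",
                          stacklevel=2)

    node_c: dict[int, float] = {}
    edge_c_in: dict[int, float] = {}
    edge_c_out: dict[int, float] = {}
    incoming: dict[int, list[tuple[float, float]]] = {node.id: [] for node in g.nodes}

    for node in order:
        flux_in = sum(q for q, _ in incoming[node.id])
        solute_in = sum(q * c for q, c in incoming[node.id])
        external = -imbalance[node.id]  # >0: network injects at this node
        if external > q_tol:
            flux_in += external
            solute_in += external * inlet_c(node.id)
        node_c[node.id] = solute_in / flux_in if flux_in > q_tol else float("nan")
        # push concentration down every edge leaving this node
        for e in g.edges:
            q = flow.Q[e.id]
            if e.node_a == node.id and q > q_tol:
                down = e.node_b
            elif e.node_b == node.id and -q > q_tol:
                down = e.node_a
            else:
                continue
            c_in = node_c[node.id]
            phi = per_edge_sink.get(e.id, 0.0)
            c_out = c_in - phi * e.L / abs(q)
            edge_c_in[e.id] = c_in
            edge_c_out[e.id] = c_out
            incoming[down].append((abs(q), c_out))

    for e in g.edges:
        edge_c_in.setdefault(e.id, float("nan"))
        edge_c_out.setdefault(e.id, float("nan"))
    return SoluteSolution(g, node_c, edge_c_in, edge_c_out)


def block_edge(g: NetworkGraph, edge_id: int) -> NetworkGraph:
    """Return a copy of the network with one edge blocked.

    The edge keeps its geometry (so volume and mask bookkeeping are
    unchanged) but its hydraulic conductance becomes zero and its tissue
    surface is treated as impermeable.  Raises if the blockage disconnects
    the network.
    """
    edges = [replace(e, blocked=True) if e.id == edge_id else e for e in g.edges]
    if not any(e.id == edge_id for e in g.edges):
        raise NetworkError(f"no edge with id {edge_id}")
    out = NetworkGraph(list(g.nodes), edges)
    gx = out.to_networkx(unblocked_only=True)
    if out.nodes and not nx.is_connected(gx):
        raise WellPosednessError(
            f"blocking edge {edge_id} disconnects the network"
        )
    return out


def assumption_numbers(R_c: float, L: float, v_bar: float, nu: float,
                       D_c: float) -> tuple[float, float, float]:
    """Dimensionless validity checks for the channel transport model.

    Re = 2R_c·v̄/ν (laminar fully developed flow wants Re small),
    Pe_z = v̄·L/D_c (axial diffusion negligible wants Pe_z large),
    Gz = v̄·R_c²/(D_c·L) (radially well-mixed channel wants Gz small).
    Emits warnings — never errors — when Re > 10, Pe_z < 10, or Gz > 1.
    """
    v = abs(v_bar)
    Re = 2.0 * R_c * v / nu
    Pe = v * L / D_c
    Gz = v * R_c ** 2 / (D_c * L)
    if Re > 10.0:
        warnings.warn(f"Re = {Re:.3g} > 10: fully developed laminar flow assumption "
                      "is questionable", stacklevel=2)
    if v > 0 and Pe < 10.0:
        warnings.warn(f"Pe_z = {Pe:.3g} < 10: axial diffusion may not be negligible",
                      stacklevel=2)
    if Gz > 1.0:
        warnings.warn(f"Gz = {Gz:.3g} > 1: channel may not be radially well mixed",
                      stacklevel=2)
    return Re, Pe, Gz


def edge_assumption_numbers(g: NetworkGraph, edge_id: int, flow: FlowSolution,
                            transport, medium) -> tuple[float, float, float]:
    """Convenience wrapper of :func:`assumption_numbers` for a solved edge."""
    e = g.edge(edge_id)
    return assumption_numbers(e.R_c, e.L, flow.velocity(edge_id),
                              medium.nu, transport.D_c)
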