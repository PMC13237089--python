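"""Run configuration schema and the scenario dispatcher.

A run is a single config document (TOML or JSON) naming one scenario:

    sphere_limit  — maximal viable sphere diameter
    unit_max      — constrained base-unit maximization
    sweep         — Cartesian volume-ratio parameter sweep
    march         — long-channel axial march
    unit_sim      — fixed-size unit-cell simulation (blockage, density field)
    net_flow      — network hydraulics + solute routing from CSV/JSON tables

Schemas are validated (unknown keys rejected) before any computation, and
every run emits a resolved-config echo plus its hash for provenance.
Outputs: a JSON report, CSV tables, and optional VTK fields.  With a fixed
seed and config, all numeric outputs are bit-reproducible.
"""

from __future__ import annotations

import json
import time
import tomllib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import design, geometry, io, netflow, rdsolver
from .parameters import Medium, SpeciesTransport, TissueParams, load_preset
from .wallmodel import ChannelSpec, effective_wall_diffusivity, wall_permeability

__all__ = ["RunConfig", "RunReport", "load_config", "run", "ValidationError"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TissueSection(_Section):
    rho_T: float
    k_ocr: float
    k_m: float
    c_H: float = 0.05


class TransportSection(_Section):
    D_t: float
    D_c: float = 3.0e-3
    D_ws: float = 1.0e-5
    K: float = 1.0


class MediumSection(_Section):
    mu: float = 6.9e-4
    nu: float = 0.696
    c_in: float = 0.2


class ChannelSection(_Section):
    R_c: float = 0.05
    t_w: float = 0.0
    f_p: float = 0.0
    no_wall: bool = True
    pi_w: Optional[float] = None  # mm/s; None with no_wall=True → Dirichlet


class GeometrySection(_Section):
    kind: Literal["cuboid", "rhombic_dodecahedron", "long_channel", "sphere"] = "cuboid"
    size: float = 0.5
    blocked_segments: list[int] = Field(default_factory=list)


class DensitySection(_Section):
    cv: float = 0.0
    correlation_length: float = 0.1


class SolverSection(_Section):
    tol: float = 1e-2
    resolution: Optional[float] = None
    s_cap: float = 8.0
    picard_tol: float = 1e-6
    max_iter: int = 200


class ConditionsSection(_Section):
    c_channel: float = 0.2
    v_bar: float = 8.0
    channel_length: float = 5.0
    n_elem: int = 10


class SweepSection(_Section):
    c_list: list[float] = Field(default_factory=lambda: [0.2, 0.6, 1.0])
    R_w_list: list[float] = Field(default_factory=lambda: [0.05])
    pi_list: list[Optional[float]] = Field(default_factory=lambda: [None])
    presets: list[str] = Field(default_factory=lambda: ["panelA"])


class NetworkSection(_Section):
    nodes_csv: Optional[str] = None
    edges_csv: Optional[str] = None
    json_path: Optional[str] = None
    n_cells: list[int] = Field(default_factory=lambda: [4, 4, 4])
    s: float = 0.5
    R_c: float = 0.04
    inlet_pressure: float = 100.0
    outlet_pressure: float = 0.0
    blocked_edges: list[int] = Field(default_factory=list)


class RunConfig(_Section):
    scenario: Literal["sphere_limit", "unit_max", "sweep", "march",
                      "unit_sim", "net_flow"]
    preset: str = "defaults"
    seed: int = 0
    tissue: Optional[TissueSection] = None
    transport: Optional[TransportSection] = None
    medium: Optional[MediumSection] = None
    channel: ChannelSection = ChannelSection()
    geometry: GeometrySection = GeometrySection()
    density: Optional[DensitySection] = None
    solver: SolverSection = SolverSection()
    conditions: ConditionsSection = ConditionsSection()
    sweep: Optional[SweepSection] = None
    network: Optional[NetworkSection] = None
    out_dir: str = "."
    write_vtk: bool = False

    def resolve_parameters(self):
        tissue, transport, medium = load_preset(self.preset)
        if self.tissue is not None:
            tissue = TissueParams(**self.tissue.model_dump())
        if self.transport is not None:
            transport = SpeciesTransport(**self.transport.model_dump())
        if self.medium is not None:
            medium = Medium(**self.medium.model_dump())
        return tissue, transport, medium

    def channel_spec(self) -> ChannelSpec:
        ch = self.channel
        mode = "no_wall" if ch.no_wall else "walled"
        return ChannelSpec(R_c=ch.R_c, t_w=0.0 if ch.no_wall else ch.t_w,
                           f_p=ch.f_p, wall_mode=mode)

    def wall_pi(self, transport) -> Optional[float]:
        ch = self.channel
        if ch.pi_w is not None:
            return ch.pi_w
        if ch.no_wall:
            return None
        spec = self.channel_spec()
        d_w = effective_wall_diffusivity(ch.f_p, transport.D_c, transport.D_ws)
        return wall_permeability(spec, d_w)


class RunReport(dict):
    """Machine-readable run outcome: inputs echo, headline scalars,
    convergence diagnostics, wall-clock, artifact paths."""


def load_config(path) -> RunConfig:
    path = Path(path)
    if path.suffix == ".toml":
        doc = tomllib.loads(path.read_text())
    else:
        doc = json.loads(path.read_text())
    return RunConfig.model_validate(doc)


def run(config: RunConfig) -> RunReport:
    """Dispatch a validated config to its scenario and write artifacts."""
    t0 = time.perf_counter()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_doc = config.model_dump()
    # the hash identifies the scientific inputs; where the artifacts land
    # is not part of them
    cfg_hash = io.config_hash({k: v for k, v in cfg_doc.items()
                               if k != "out_dir"})
    tissue, transport, medium = config.resolve_parameters()
    artifacts: list[str] = []
    scalars: dict = {}
    status = "ok"

    if config.scenario == "sphere_limit":
        d_max = design.max_sphere_diameter(config.conditions.c_channel,
                                           transport, tissue,
                                           tol=config.solver.tol)
        scalars["d_max"] = d_max

    elif config.scenario == "unit_max":
        res = design.max_unit_size(
            config.geometry.kind, config.channel_spec(),
            config.conditions.c_channel, tissue, transport,
            pi_w=config.wall_pi(transport), tol=config.solver.tol,
            s_cap=config.solver.s_cap, h_override=config.solver.resolution,
        )
        scalars.update(res.to_dict())
        if not res.feasible:
            status = "infeasible"

    elif config.scenario == "sweep":
        sw = config.sweep or SweepSection()
        presets = {name: load_preset(name)[0] for name in sw.presets}
        table = design.volume_ratio_sweep(sw.c_list, sw.R_w_list, sw.pi_list,
                                          presets, transport,
                                          kind=config.geometry.kind,
                                          tol=config.solver.tol,
                                          s_cap=config.solver.s_cap)
        path = out_dir / "sweep.csv"
        io.write_csv(table, path, cfg_hash)
        artifacts.append(str(path))
        scalars["n_cells"] = len(table)
        scalars["n_feasible"] = int(table["feasible"].sum())

    elif config.scenario == "march":
        res = design.long_channel_march(
            config.conditions.v_bar, config.conditions.c_channel,
            config.conditions.channel_length, config.conditions.n_elem,
            config.channel_spec(), transport, tissue,
            pi_w=config.wall_pi(transport), s_cap=config.solver.s_cap,
        )
        path = out_dir / "march.csv"
        io.write_csv(res.to_frame(), path, cfg_hash)
        artifacts.append(str(path))
        scalars.update({
            "c_out": float(res.c[-1]), "s_first": float(res.s[0]),
            "s_last": float(res.s[-1]),
            "balance_error": res.balance_error(),
            "n_feasible_elements": int(res.feasible.sum()),
        })
        if not res.feasible.all():
            status = "infeasible"

    elif config.scenario == "unit_sim":
        cell = geometry.make_unit_cell(config.geometry.kind,
                                       config.geometry.size,
                                       config.channel.R_c)
        if config.geometry.blocked_segments:
            cell = cell.with_blocked(config.geometry.blocked_segments)
        h = config.solver.resolution or design.unit_resolution(
            config.geometry.size, config.channel.R_c)
        octant = not config.geometry.blocked_segments
        grid = geometry.voxelize(cell, h, octant=octant)
        density = None
        if config.density is not None and config.density.cv > 0:
            density = geometry.correlated_density_field(
                grid, tissue.rho_T, config.density.cv,
                config.density.correlation_length, config.seed)
        pi_w = config.wall_pi(transport)
        if pi_w is None:
            bc = rdsolver.BoundarySpec.dirichlet_channel(config.conditions.c_channel)
        else:
            bc = rdsolver.BoundarySpec.robin_channel(pi_w, config.conditions.c_channel)
        fld = rdsolver.solve_steady_mm(grid, density, transport, tissue, bc)
        min_c, mean_c, frac = rdsolver.field_stats(fld.values, grid.tissue_mask,
                                                   tissue.c_H)
        omega_t, omega_net, ratio = geometry.measure_volumes(grid)
        scalars.update({
            "min_c": min_c, "mean_c": mean_c, "hypoxic_fraction": frac,
            "omega_t": omega_t, "omega_net": omega_net, "ratio": ratio,
            "picard_iterations": fld.iterations, "residual": fld.residual,
        })
        if config.write_vtk:
            path = out_dir / "concentration.vtk"
            fields = {"concentration": fld.values}
            if density is not None:
                fields["density"] = density.values
            io.write_vtk_image(path, grid, fields, cfg_hash)
            artifacts.append(str(path))
        if min_c < tissue.c_H:
            status = "infeasible"

    elif config.scenario == "net_flow":
        net_cfg = config.network or NetworkSection()
        if net_cfg.nodes_csv and net_cfg.edges_csv:
            g = netflow.NetworkGraph.from_csv(net_cfg.nodes_csv, net_cfg.edges_csv)
        elif net_cfg.json_path:
            g = netflow.NetworkGraph.from_json(net_cfg.json_path)
        else:
            nx_, ny_, nz_ = net_cfg.n_cells
            g = netflow.build_unit_network(nx_, ny_, nz_, net_cfg.s, net_cfg.R_c)
            inlet = g.face_nodes(0, maximum=False)
            outlet = g.face_nodes(0, maximum=True)
            g = g.with_bc(pressure={**{n: net_cfg.inlet_pressure for n in inlet},
                                    **{n: net_cfg.outlet_pressure for n in outlet}})
        for eid in net_cfg.blocked_edges:
            g = netflow.block_edge(g, eid)
        flow = netflow.solve_flow(g, medium)
        sol = netflow.route_solute(g, flow, medium.c_in)
        flow_path = out_dir / "flow.csv"
        sol_path = out_dir / "solute.csv"
        io.write_csv(flow.to_frame(), flow_path, cfg_hash)
        io.write_csv(sol.to_frame(), sol_path, cfg_hash)
        artifacts += [str(flow_path), str(sol_path)]
        speeds = np.array([abs(flow.velocity(e.id)) for e in g.edges])
        scalars.update({
            "max_velocity": float(speeds.max()),
            "total_inflow": float(sum(max(-v, 0.0) for v in
                                      flow.node_imbalance().values())),
        })

    report = RunReport(
        scenario=config.scenario, status=status, scalars=scalars,
        config_echo=cfg_doc, wallclock_s=time.perf_counter() - t0,
        artifacts=artifacts,
    )
    path = out_dir / "report.json"
    io.write_json_report(path, report, cfg_hash)
    report["report_path"] = str(path)
    return report
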