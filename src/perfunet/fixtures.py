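"""Deterministic fixture generation: the geometries, networks, and fields
used across the test suite, emitted as plain-text files.

Everything here is produced by the library itself, so fixtures regenerate
bit-identically from a seed and round-trip through the package readers.
"""

from __future__ import annotations

from pathlib import Path

from . import io
from .geometry import correlated_density_field, make_unit_cell, voxelize
from .netflow import build_unit_network, block_edge
from .parameters import load_preset, save_parameters

__all__ = ["generate_fixtures"]

#: fixture inventory: name -> description
FIXTURES = {
    "lattice_4x4x4": "Cartesian 4×4×4 unit network with inlet/outlet faces tagged",
    "lattice_4x4x4_blocked": "same lattice with one central primary edge blocked",
    "cuboid_cell": "cuboid base unit, s=0.5 mm, R_w=0.05 mm",
    "dodeca_cell": "rhombic dodecahedral base unit, a=0.4 mm, R_w=0.05 mm",
    "density_field": "correlated density field on the cuboid cell octant",
    "params": "preset parameter files",
}


def _central_primary_edge(g):
    """A primary (x-direction) edge nearest to the lattice center."""
    import numpy as np

    coords = {n.id: np.array([n.x, n.y, n.z]) for n in g.nodes}
    center = np.mean(list(coords.values()), axis=0)
    best, best_d = None, None
    for e in g.edges:
        a, b = coords[e.node_a], coords[e.node_b]
        if abs((b - a)[0]) < 1e-12:  # not an x edge
            continue
        d = float(np.linalg.norm((a + b) / 2 - center))
        if best_d is None or d < best_d:
            best, best_d = e.id, d
    return best


def generate_fixtures(out_dir, seed: int = 0) -> list[Path]:
    """Write all fixtures to ``out_dir``; returns the created paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    g = build_unit_network(4, 4, 4, 0.5, 0.04)
    inlet = g.face_nodes(0, maximum=False)
    outlet = g.face_nodes(0, maximum=True)
    g = g.with_bc(pressure={**{n: 100.0 for n in inlet},
                            **{n: 0.0 for n in outlet}})
    g.to_csv(out / "lattice_4x4x4_nodes.csv", out / "lattice_4x4x4_edges.csv")
    paths += [out / "lattice_4x4x4_nodes.csv", out / "lattice_4x4x4_edges.csv"]

    blocked = block_edge(g, _central_primary_edge(g))
    blocked.to_csv(out / "lattice_4x4x4_blocked_nodes.csv",
                   out / "lattice_4x4x4_blocked_edges.csv")
    paths += [out / "lattice_4x4x4_blocked_nodes.csv",
              out / "lattice_4x4x4_blocked_edges.csv"]

    for name, kind, size in (("cuboid_cell", "cuboid", 0.5),
                             ("dodeca_cell", "rhombic_dodecahedron", 0.4)):
        cell = make_unit_cell(kind, size, 0.05)
        doc = {
            "kind": kind, "size": size, "R_w": 0.05,
            "volume": cell.volume,
            "segments": [
                {"id": s.id, "p0": list(s.p0), "p1": list(s.p1),
                 "R_w": s.R_w, "blocked": s.blocked}
                for s in cell.segments
            ],
        }
        path = out / f"{name}.json"
        io.write_json_report(path, doc)
        paths.append(path)

    cell = make_unit_cell("cuboid", 0.5, 0.05)
    grid = voxelize(cell, 0.0125, octant=True)
    dens = correlated_density_field(grid, 2.0e5, 0.3, 0.1, seed)
    io.density_to_csv(grid, dens, out / "density_field.csv",
                      io.config_hash({"seed": seed}))
    paths.append(out / "density_field.csv")

    for preset in ("defaults", "panelA", "panelD", "sphere_alt"):
        tissue, transport, medium = load_preset(preset)
        path = out / f"params_{preset}.json"
        save_parameters(path, tissue, transport, medium)
        paths.append(path)

    return paths
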