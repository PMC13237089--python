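"""File output: legacy-VTK image data, CSV tables, JSON reports.

Voxel fields are written as ASCII legacy VTK ``STRUCTURED_POINTS`` (plain
text, readable by ParaView and friends without extra dependencies).  Every
output file embeds the resolved-config hash of the run that produced it,
as a header comment (CSV/VTK) or a top-level field (JSON).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["config_hash", "write_vtk_image", "write_csv", "read_csv",
           "write_json_report", "density_to_csv"]


def config_hash(config: dict) -> str:
    """Stable sha256 of a JSON-serializable config document."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_vtk_image(path, grid, fields: dict[str, np.ndarray],
                    cfg_hash: str = "") -> None:
    """Write voxel-center fields as legacy VTK STRUCTURED_POINTS (ASCII).

    ``fields`` maps names to full-shape arrays on ``grid``; NaNs (voxels
    outside the tissue) are preserved.
    """
    nx, ny, nz = grid.shape
    lines = [
        "# vtk DataFile Version 3.0",
        f"perfunet voxel fields config_hash={cfg_hash}",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {grid.origin[0] + grid.h / 2} {grid.origin[1] + grid.h / 2} "
        f"{grid.origin[2] + grid.h / 2}",
        f"SPACING {grid.h} {grid.h} {grid.h}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in fields.items():
        if arr.shape != grid.shape:
            raise ValueError(f"field {name!r} shape {arr.shape} != grid {grid.shape}")
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        flat = np.asarray(arr, dtype=float).transpose(2, 1, 0).ravel()
        lines.extend(" ".join(f"{v:.7g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    Path(path).write_text("\n".join(lines) + "\n")


def write_csv(df: pd.DataFrame, path, cfg_hash: str = "") -> None:
    """CSV with a provenance header comment line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def density_to_csv(grid, density, path, cfg_hash: str = "") -> None:
    """Flat CSV of a density field: voxel indices and values."""
    i, j, k = np.nonzero(grid.tissue_mask)
    df = pd.DataFrame({"i": i, "j": j, "k": k,
                       "density": density.values[grid.tissue_mask]})
    write_csv(df, path, cfg_hash)


def write_json_report(path, report: dict, cfg_hash: str = "") -> None:
    doc = {"config_hash": cfg_hash, **report}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=str) + "\n")
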