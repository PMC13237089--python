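"""Steady Michaelis–Menten reaction–diffusion solves on voxel domains.

The tissue compartment obeys

    0 = ∇·(D_t ∇c) − ρ_T·k_ocr·c/(k_m + c),

with boundary conditions supplied by the supply network: Dirichlet at bare
channel surfaces (sacrificial templating, infinite wall permeability),
Robin with the wall permeability Π_w at porous-walled channels, and zero
flux at blocked channel surfaces and symmetry faces.

Discretization is a 7-point cell-centered finite-volume scheme on the
uniform voxel grid; channel voxels are excluded from the solve and enter
only through face transmissibilities (Dirichlet ghost value at half-cell
distance, or a Robin coefficient in series with the half-cell diffusive
resistance).  The mildly nonlinear sink is handled by Picard iteration on
the linearized coefficient ρ_T·k_ocr/(k_m + c⁽ⁿ⁾), which preserves the
discrete maximum principle at every iterate: the matrix is an M-matrix and
the right-hand side is non-negative, so concentrations stay within
[0, max boundary value] by construction.  This bound is asserted after
every solve.

Two-dimensional cross-sections and one-dimensional slabs are solved on the
same machinery using a grid that is one voxel thick along the trivial axes;
the 1D spherical problem has its own conservative radial discretization.

Units: mm, s, mol m⁻³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import (SEG_TISSUE, ChannelSegment, DensityField, GeometryError,
                       UnitCellGeometry, VoxelGrid)

__all__ = [
    "BoundarySpec",
    "ConcentrationField",
    "CrossSectionResult",
    "PicardSettings",
    "SolverError",
    "solve_steady_mm",
    "solve_sphere",
    "solve_cross_section",
    "field_stats",
    "box_grid",
]

_FACES = ("x-", "x+", "y-", "y+", "z-", "z+")
# Direct sparse factorization pays off only where fill-in stays modest:
# small systems, and quasi-2D grids (one voxel thick).  Fully 3D systems
# above a few thousand unknowns are solved with Jacobi-preconditioned CG
# warm-started from the previous Picard iterate.
_DIRECT_LIMIT = 4_000
_DIRECT_LIMIT_2D = 50_000


def _direct_limit_for(grid: "VoxelGrid") -> int:
    return _DIRECT_LIMIT_2D if min(grid.shape) == 1 else _DIRECT_LIMIT


class SolverError(RuntimeError):
    """Non-convergence or a violated discrete bound."""


@dataclass(frozen=True)
class PicardSettings:
    """Nonlinear iteration controls.

    tol: relative update (inf-norm) for convergence; relax: under-relaxation
    factor (1 = plain Picard, 0.7 recommended if a case stalls).
    """

    tol: float = 1e-6
    max_iter: int = 200
    relax: float = 1.0
    cg_rtol: float = 1e-10


@dataclass(frozen=True)
class BoundarySpec:
    """Boundary conditions for a voxel solve.

    ``channel`` applies at every unblocked channel surface and is one of
    ``("dirichlet", c)`` or ``("robin", pi_w, c_channel)``; blocked channel
    surfaces are always no-flux.  ``faces`` optionally overrides the
    external grid faces ("x-", "x+", ..., default no-flux = symmetry) with
    ``("dirichlet", c)``, ``("robin", pi, c)`` or ``("no_flux",)``.
    """

    channel: tuple | None = None
    faces: dict = field(default_factory=dict)

    def __post_init__(self):
        for key in self.faces:
            if key not in _FACES:
                raise ValueError(f"unknown face {key!r}; valid: {_FACES}")
        for cond in [self.channel, *self.faces.values()]:
            if cond is None:
                continue
            if cond[0] not in ("dirichlet", "robin", "no_flux"):
                raise ValueError(f"unknown boundary condition {cond!r}")
            if cond[0] == "robin" and not math.isfinite(cond[1]):
                raise ValueError(
                    "infinite wall permeability: use a Dirichlet condition"
                )

    @classmethod
    def dirichlet_channel(cls, c: float) -> "BoundarySpec":
        return cls(channel=("dirichlet", c))

    @classmethod
    def robin_channel(cls, pi_w: float, c_channel: float) -> "BoundarySpec":
        return cls(channel=("robin", pi_w, c_channel))

    def max_value(self) -> float:
        vals = [0.0]
        for cond in [self.channel, *self.faces.values()]:
            if cond and cond[0] == "dirichlet":
                vals.append(cond[1])
            elif cond and cond[0] == "robin":
                vals.append(cond[2])
        return max(vals)


@dataclass
class ConcentrationField:
    """Concentration on a voxel grid (NaN outside the tissue mask)."""

    values: np.ndarray
    grid: VoxelGrid | None
    iterations: int
    residual: float
    converged: bool

    def tissue_values(self) -> np.ndarray:
        if self.grid is None:
            return self.values
        return self.values[self.grid.tissue_mask]


def field_stats(values: np.ndarray, mask: np.ndarray, c_H: float):
    """(min, mean, hypoxic fraction) of a field over a tissue mask."""
    if not np.any(mask):
        raise SolverError("empty tissue mask")
    v = np.asarray(values)[mask]
    return float(v.min()), float(v.mean()), float(np.count_nonzero(v < c_H) / v.size)


def box_grid(extent, h: float) -> VoxelGrid:
    """All-tissue box grid (no channels), for slab and manufactured solves."""
    extent = tuple(float(e) for e in extent)
    shape = tuple(max(1, int(round(e / h))) for e in extent)
    cell = UnitCellGeometry(
        "cuboid", max(extent), 0.0, (), extent[0] * extent[1] * extent[2],
        ((0.0, 0.0, 0.0), extent), ((0.0, 0.0, 0.0), extent),
    )
    seg = np.full(shape, np.int16(SEG_TISSUE))
    return VoxelGrid(np.zeros(3), h, shape, seg, cell)


def _face_coef(cond, D_t: float, h: float) -> tuple[float, float]:
    """(conductance per face area [mm s⁻¹], boundary concentration)."""
    if cond[0] == "dirichlet":
        return 2.0 * D_t / h, cond[1]
    if cond[0] == "robin":
        pi_w = cond[1]
        return 1.0 / (1.0 / pi_w + h / (2.0 * D_t)), cond[2]
    return 0.0, 0.0


def _assemble(grid: VoxelGrid, D_t: float, bc: BoundarySpec):
    """Linear part of the FV system on the tissue voxels.

    Returns (L, b0, n, index, boundary_faces) where boundary_faces is a list
    of (tissue_row, conductance·area, c_boundary) for every channel face,
    used afterwards for flux integrals.
    """
    h = grid.h
    mask = grid.tissue_mask
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise GeometryError("no tissue voxels to solve on")
    index = np.full(grid.shape, -1, dtype=np.int64)
    index[mask] = np.arange(n)

    area = h * h
    g_int = D_t * h  # D_t·A/h with A = h²

    rows, cols, vals = [], [], []
    b0 = np.zeros(n)
    chan_faces = []

    blocked = grid.blocked_segment_ids()
    chan = grid.channel_mask
    if blocked:
        active_chan = chan & ~np.isin(grid.seg, list(blocked))
    else:
        active_chan = chan

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for axis in range(3):
        sl_lo = tuple(slice(0, -1) if a == axis else slice(None) for a in range(3))
        sl_hi = tuple(slice(1, None) if a == axis else slice(None) for a in range(3))
        m_lo, m_hi = mask[sl_lo], mask[sl_hi]
        # tissue-tissue interior faces
        both = m_lo & m_hi
        if both.any():
            i = index[sl_lo][both]
            j = index[sl_hi][both]
            rows.extend(i); cols.extend(i); vals.extend(np.full(i.size, g_int))
            rows.extend(j); cols.extend(j); vals.extend(np.full(j.size, g_int))
            rows.extend(i); cols.extend(j); vals.extend(np.full(i.size, -g_int))
            rows.extend(j); cols.extend(i); vals.extend(np.full(j.size, -g_int))
        # tissue voxels facing an unblocked channel voxel
        if bc.channel is not None and bc.channel[0] != "no_flux":
            g_per_area, c_b = _face_coef(bc.channel, D_t, h)
            for t_sl, c_sl in ((sl_lo, sl_hi), (sl_hi, sl_lo)):
                touch = mask[t_sl] & active_chan[c_sl]
                if touch.any():
                    i = index[t_sl][touch]
                    val = g_per_area * area
                    rows.extend(i); cols.extend(i); vals.extend(np.full(i.size, val))
                    np.add.at(b0, i, val * c_b)
                    chan_faces.append((i, val, c_b))

    # external grid faces
    for axis in range(3):
        for side, name in ((0, "-"), (-1, "+")):
            cond = bc.faces.get("xyz"[axis] + name, ("no_flux",))
            if cond[0] == "no_flux":
                continue
            g_per_area, c_b = _face_coef(cond, D_t, h)
            sl = tuple(side if a == axis else slice(None) for a in range(3))
            face_mask = mask[sl]
            if face_mask.any():
                i = index[sl][face_mask]
                val = g_per_area * area
                rows.extend(i); cols.extend(i); vals.extend(np.full(i.size, val))
                np.add.at(b0, i, val * c_b)

    L = sp.csr_matrix(
        (np.asarray(vals, dtype=float), (np.asarray(rows), np.asarray(cols))),
        shape=(n, n),
    )
    return L, b0, n, index, chan_faces


def _solve_linear(A, b, x0, rtol, direct_limit):
    n = A.shape[0]
    if n <= direct_limit:
        return spla.spsolve(A.tocsc(), b)
    M = sp.diags(1.0 / A.diagonal())
    x, info = spla.cg(A, b, x0=x0, M=M, rtol=rtol, atol=0.0, maxiter=50_000)
    if info != 0:
        raise SolverError(f"conjugate-gradient inner solve failed (info={info})")
    return x


def _picard(L, b0, q_vox, k_m, volume, c0, cmax, settings: PicardSettings,
            direct_limit: int = _DIRECT_LIMIT, stop_below: float | None = None):
    """Picard loop for the Michaelis–Menten sink; returns (c, iters, resid).

    Starting from the uniform boundary value, the Picard iterates decrease
    monotonically toward the solution (weaker lagged sink ⇒ the linearized
    solve over-estimates the field), so every iterate is an upper bound on
    the converged concentration.  ``stop_below`` exploits this for
    feasibility screening: once an iterate's minimum falls below the
    threshold, the converged minimum must too, and the loop returns early
    with residual NaN to mark the short-circuit.
    """
    c = np.full(L.shape[0], c0, dtype=float)
    history = []
    update = 1.0
    for it in range(1, settings.max_iter + 1):
        sink = q_vox * volume / (k_m + np.maximum(c, 0.0))
        A = L + sp.diags(sink)
        # inexact Picard: the inner tolerance follows the outer progress
        # (loose while the lagged sink still moves, tight near convergence)
        rtol = min(max(0.05 * update, settings.cg_rtol), 1e-4)
        c_new = _solve_linear(A, b0, c, rtol, direct_limit)
        if settings.relax != 1.0:
            c_new = settings.relax * c_new + (1.0 - settings.relax) * c
        update = np.abs(c_new - c).max() / max(np.abs(c_new).max(), 1e-300)
        history.append(update)
        c = c_new
        if stop_below is not None and c.min() < stop_below:
            return np.clip(c, 0.0, None), it, float("nan")
        if update < settings.tol:
            resid = float(np.abs(A @ c - b0).max())
            if c.min() < -1e-9 * max(cmax, 1.0):
                raise SolverError(
                    f"negative concentration {c.min():.3e} beyond round-off"
                )
            if c.max() > cmax * (1.0 + 1e-8) + 1e-12:
                raise SolverError(
                    f"maximum principle violated: {c.max():.6g} > {cmax:.6g}"
                )
            return np.clip(c, 0.0, None), it, resid
    raise SolverError(
        f"Picard iteration did not converge in {settings.max_iter} steps; "
        f"relative-update history tail: {history[-5:]}"
    )


def _density_array(density, tissue, grid):
    """Per-voxel q_max (mol m⁻³ s⁻¹) over the tissue voxels."""
    conv = tissue.k_ocr * 1.0e9
    if density is None:
        return np.full(int(np.count_nonzero(grid.tissue_mask)),
                       tissue.rho_T * conv)
    if isinstance(density, DensityField):
        return density.values[grid.tissue_mask] * conv
    arr = np.asarray(density, dtype=float)
    if arr.shape != grid.shape:
        raise GeometryError(
            f"density shape {arr.shape} does not match grid {grid.shape}"
        )
    return arr[grid.tissue_mask] * conv


def solve_steady_mm(grid: VoxelGrid, density, transport, tissue,
                    bc: BoundarySpec,
                    settings: PicardSettings = PicardSettings(),
                    stop_below: float | None = None) -> ConcentrationField:
    """Steady Michaelis–Menten reaction–diffusion on a voxelized unit cell.

    ``density`` is ``None`` (uniform ρ_T from ``tissue``), a
    :class:`~perfunet.geometry.DensityField`, or a full-shape array of cell
    densities (cells mm⁻³).  Blocked channel segments (flagged in the
    grid's cell geometry) automatically become no-flux surfaces.

    ``stop_below`` short-circuits feasibility screens: the solve returns as
    soon as the field provably dips below the given threshold (the result
    is then an upper bound, flagged by ``converged=False``).
    """
    L, b0, n, index, _ = _assemble(grid, transport.D_t, bc)
    q_vox = _density_array(density, tissue, grid)
    cmax = bc.max_value()
    c, iters, resid = _picard(L, b0, q_vox, tissue.k_m, grid.h ** 3,
                              cmax, cmax, settings, _direct_limit_for(grid),
                              stop_below)
    values = np.full(grid.shape, np.nan)
    values[grid.tissue_mask] = c
    return ConcentrationField(values, grid, iters, resid,
                              not math.isnan(resid) if stop_below is not None else True)


def solve_sphere(R: float, c_surface: float, transport, tissue,
                 density: float | None = None, n: int = 400,
                 settings: PicardSettings = PicardSettings()):
    """Steady MM reaction–diffusion in a sphere of radius R (mm).

    Solves D_t·(1/r²)(r²c′)′ = ρ_T·k_ocr·c/(k_m+c) with c(R) = c_surface and
    symmetry at the center, on a conservative radial finite-volume mesh.
    Returns ``(r_centers, c, c_center)`` wrapped in a ConcentrationField-like
    tuple: a ConcentrationField with 1D values plus the extrapolated center
    value as attribute ``center``.
    """
    if R <= 0:
        raise GeometryError(f"sphere radius must be positive, got {R!r}")
    dr = R / n
    r_faces = np.linspace(0.0, R, n + 1)
    r_cent = 0.5 * (r_faces[:-1] + r_faces[1:])
    vol = (r_faces[1:] ** 3 - r_faces[:-1] ** 3) / 3.0  # per 4π steradian

    D = transport.D_t
    g_face = D * r_faces[1:-1] ** 2 / dr          # interior faces 1..n-1
    g_surf = D * R ** 2 / (dr / 2.0)              # Dirichlet ghost at r=R

    rows, cols, vals = [], [], []
    for i, g in enumerate(g_face):
        rows += [i, i + 1, i, i + 1]
        cols += [i, i + 1, i + 1, i]
        vals += [g, g, -g, -g]
    rows.append(n - 1)
    cols.append(n - 1)
    vals.append(g_surf)
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    b0 = np.zeros(n)
    b0[n - 1] = g_surf * c_surface

    rho = tissue.rho_T if density is None else density
    q_vox = np.full(n, rho * tissue.k_ocr * 1.0e9)
    c, iters, resid = _picard(L, b0, q_vox, tissue.k_m, vol, c_surface,
                              c_surface, settings)
    # parabolic extrapolation c(r) ≈ c_center + α r² through the two
    # innermost cell centers
    c_center = c[0] - (c[1] - c[0]) * r_cent[0] ** 2 / (r_cent[1] ** 2 - r_cent[0] ** 2)
    fld = ConcentrationField(c, None, iters, resid, True)
    fld.r = r_cent
    fld.center = float(c_center)
    return fld


@dataclass
class CrossSectionResult:
    """2D cross-section solve of a long-channel element.

    ``phi`` is the wall flux per unit channel length in mol m⁻³ mm² s⁻¹
    (multiply by 1e−6 for SI mol m⁻¹ s⁻¹); ``consumption`` is the total
    Michaelis–Menten sink over the tissue area in the same units.  At
    steady state the two agree to discretization accuracy.
    """

    field: ConcentrationField
    grid: VoxelGrid
    phi: float
    consumption: float
    min_c: float


def _cross_section_grid(s: float, R_w: float, h: float) -> VoxelGrid:
    """Quarter cross-section [0, s/2]² (one voxel thick along z) with a
    quarter channel of radius R_w at the corner (= the square's center)."""
    if not s > 2.0 * R_w:
        raise GeometryError(f"cross-section edge {s} must exceed 2·R_w = {2 * R_w}")
    half = s / 2.0
    nxy = max(2, int(round(half / h)))
    shape = (nxy, nxy, 1)
    seg_geom = ChannelSegment(0, (0.0, 0.0, -h), (0.0, 0.0, 2 * h), R_w)
    cell = UnitCellGeometry(
        "long_channel", s, R_w, (seg_geom,), s * s * h,
        ((0.0, 0.0, 0.0), (half, half, h)),
        ((0.0, 0.0, 0.0), (half, half, h)),
    )
    grid = VoxelGrid(np.zeros(3), h, shape, np.empty(shape, np.int16), cell)
    x, y, _ = grid.centers()
    X, Y = np.meshgrid(x, y, indexing="ij")
    chan = (X ** 2 + Y ** 2) <= R_w ** 2
    seg = np.where(chan, np.int16(0), np.int16(SEG_TISSUE))
    grid.seg = seg[:, :, None]
    return grid


def solve_cross_section(s: float, channel, c_wall: float, density, transport,
                        tissue, pi_w: float | None = None,
                        h: float | None = None,
                        settings: PicardSettings = PicardSettings()) -> CrossSectionResult:
    """Quarter cross-section of a long channel in a square tissue column.

    ``channel`` is a :class:`~perfunet.wallmodel.ChannelSpec`; the tissue
    sees the channel at the outer radius R_w with either Dirichlet coupling
    (``pi_w=None`` or infinite: bare channels) or a Robin condition with
    finite wall permeability ``pi_w`` and channel concentration ``c_wall``.
    The square's sides are symmetry (no-flux) planes.
    """
    R_w = channel.R_w
    if h is None:
        h = min(max(s / 100.0, R_w / 10.0), R_w / 3.0)
    grid = _cross_section_grid(s, R_w, h)
    if pi_w is None or math.isinf(pi_w):
        bc = BoundarySpec.dirichlet_channel(c_wall)
    else:
        bc = BoundarySpec.robin_channel(pi_w, c_wall)
    L, b0, n, index, chan_faces = _assemble(grid, transport.D_t, bc)
    q_vox = _density_array(density, tissue, grid)
    cmax = bc.max_value()
    c, iters, resid = _picard(L, b0, q_vox, tissue.k_m, grid.h ** 3,
                              cmax, cmax, settings, _direct_limit_for(grid))
    values = np.full(grid.shape, np.nan)
    values[grid.tissue_mask] = c
    fld = ConcentrationField(values, grid, iters, resid, True)

    # wall flux per unit channel length: quarter-domain face fluxes ×4,
    # divided by the voxel thickness h (the grid is one voxel thick)
    influx = 0.0
    for i, val, c_b in chan_faces:
        influx += float(np.sum(val * (c_b - c[i])))
    phi = 4.0 * influx / grid.h
    consumption = 4.0 * float(
        np.sum(q_vox * c / (tissue.k_m + c)) * grid.h ** 3
    ) / grid.h
    return CrossSectionResult(fld, grid, phi, consumption, float(c.min()))
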