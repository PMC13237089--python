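"""Unit-cell geometries, voxelization, volume accounting, density fields.

Honeycomb supply networks are analysed one base unit at a time: a repeating
volume-filling cell (cube or rhombic dodecahedron) with channel segments
along its edges and zero-normal-flux symmetry on all faces, which embeds
the unit in an infinite lattice.  Channels shared between adjacent cells
contribute exactly their sector to each cell, which the voxel accounting
reproduces automatically by clipping full cylinders to the cell interior.

Voxels are cell-centered on a uniform isotropic grid with half-open domain
[origin, origin + shape·h); membership is decided by the voxel center
(no partial volumes), so volumes converge with first order in h.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ChannelSegment",
    "UnitCellGeometry",
    "VoxelGrid",
    "DensityField",
    "GeometryError",
    "make_unit_cell",
    "voxelize",
    "measure_volumes",
    "correlated_density_field",
]

SEG_TISSUE = -1
SEG_OUTSIDE = -2


class GeometryError(ValueError):
    """Degenerate or inconsistent geometry."""


@dataclass(frozen=True)
class ChannelSegment:
    """A straight channel segment (axis endpoints in mm, outer radius R_w)."""

    id: int
    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    R_w: float
    blocked: bool = False

    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.p1, self.p0)))


@dataclass(frozen=True)
class UnitCellGeometry:
    """A base unit: kind, characteristic size, channel segments, volume.

    kind ∈ {cuboid, rhombic_dodecahedron, long_channel, sphere}.  ``size``
    is the edge length s (cuboid), edge length a (dodecahedron), the
    cross-section edge (long_channel) or the radius (sphere), in mm.  All
    faces carry the zero-normal-flux symmetry contract.
    """

    kind: str
    size: float
    R_w: float
    segments: tuple[ChannelSegment, ...]
    volume: float                       # analytic cell volume, mm³
    bounds: tuple[tuple[float, float, float], tuple[float, float, float]]
    octant_bounds: tuple[tuple[float, float, float], tuple[float, float, float]]

    def inside(self, x, y, z):
        """Boolean membership test for points in the cell interior."""
        if self.kind == "cuboid" or self.kind == "long_channel":
            lo, hi = np.array(self.bounds[0]), np.array(self.bounds[1])
            return ((x >= lo[0]) & (x < hi[0]) & (y >= lo[1]) & (y < hi[1])
                    & (z >= lo[2]) & (z < hi[2]))
        if self.kind == "rhombic_dodecahedron":
            c = 2.0 * self.size / math.sqrt(3.0)
            ax, ay, az = np.abs(x), np.abs(y), np.abs(z)
            return (ax + ay <= c) & (ay + az <= c) & (ax + az <= c)
        if self.kind == "sphere":
            return x * x + y * y + z * z <= self.size ** 2
        raise GeometryError(f"unknown cell kind {self.kind!r}")

    def with_blocked(self, segment_ids) -> "UnitCellGeometry":
        """Copy of the cell with the given channel segments marked blocked."""
        wanted = set(segment_ids)
        missing = wanted - {s.id for s in self.segments}
        if missing:
            raise GeometryError(f"no such segment ids: {sorted(missing)}")
        segs = tuple(
            ChannelSegment(s.id, s.p0, s.p1, s.R_w, blocked=(s.id in wanted or s.blocked))
            for s in self.segments
        )
        return UnitCellGeometry(self.kind, self.size, self.R_w, segs, self.volume,
                                self.bounds, self.octant_bounds)


def make_unit_cell(kind: str, size: float, R_w: float,
                   length: float | None = None) -> UnitCellGeometry:
    """Construct a base-unit geometry.

    cuboid: cube [0, s]³ with 12 edge channels.
    rhombic_dodecahedron: centered at the origin, vertices (±u,±u,±u) and
        (±2u,0,0),(0,±2u,0),(0,0,±2u) with u = a/√3, 24 edge channels of
        length a; volume (16/9)√3·a³.
    long_channel: box [0,s]²×[0,length] with one central channel along z.
    sphere: ball of radius ``size`` with no channels.
    """
    if kind != "sphere" and not size > 2.0 * R_w:
        raise GeometryError(
            f"cell size {size} must exceed the channel diameter {2 * R_w}"
        )
    if kind == "cuboid":
        s = size
        segs = []
        sid = 0
        # 4 edges along each axis: the x-edges are the primary channels
        for axis in range(3):
            for u in (0.0, s):
                for v in (0.0, s):
                    p0, p1 = [u, u, u], [u, u, u]
                    p0[axis], p1[axis] = 0.0, s
                    other = [a for a in range(3) if a != axis]
                    p0[other[0]] = p1[other[0]] = u
                    p0[other[1]] = p1[other[1]] = v
                    segs.append(ChannelSegment(sid, tuple(p0), tuple(p1), R_w))
                    sid += 1
        return UnitCellGeometry(
            "cuboid", s, R_w, tuple(segs), s ** 3,
            ((0.0, 0.0, 0.0), (s, s, s)),
            ((0.0, 0.0, 0.0), (s / 2.0, s / 2.0, s / 2.0)),
        )
    if kind == "rhombic_dodecahedron":
        a = size
        u = a / math.sqrt(3.0)
        cube_vertices = [(sx * u, sy * u, sz * u)
                         for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        segs = []
        sid = 0
        for cx, cy, cz in cube_vertices:
            for axis, coord in enumerate((cx, cy, cz)):
                apex = [0.0, 0.0, 0.0]
                apex[axis] = 2.0 * u * (1 if coord > 0 else -1)
                segs.append(ChannelSegment(sid, (cx, cy, cz), tuple(apex), R_w))
                sid += 1
        volume = 16.0 * u ** 3  # == (16/9)·√3·a³
        ext = 2.0 * u
        return UnitCellGeometry(
            "rhombic_dodecahedron", a, R_w, tuple(segs), volume,
            ((-ext, -ext, -ext), (ext, ext, ext)),
            ((0.0, 0.0, 0.0), (ext, ext, ext)),
        )
    if kind == "long_channel":
        s = size
        L = s if length is None else length
        mid = s / 2.0
        seg = ChannelSegment(0, (mid, mid, 0.0), (mid, mid, L), R_w)
        return UnitCellGeometry(
            "long_channel", s, R_w, (seg,), s * s * L,
            ((0.0, 0.0, 0.0), (s, s, L)),
            ((0.0, 0.0, 0.0), (mid, mid, L)),
        )
    if kind == "sphere":
        r = size
        return UnitCellGeometry(
            "sphere", r, R_w, (), 4.0 / 3.0 * math.pi * r ** 3,
            ((-r, -r, -r), (r, r, r)),
            ((0.0, 0.0, 0.0), (r, r, r)),
        )
    raise GeometryError(f"unknown cell kind {kind!r}")


@dataclass
class VoxelGrid:
    """Uniform voxel discretization of a unit cell.

    ``seg`` holds one int per voxel: the channel-segment id for channel
    voxels, −1 for tissue, −2 for voxels outside the cell.  Channel and
    tissue masks partition the cell interior exactly.
    """

    origin: np.ndarray
    h: float
    shape: tuple[int, int, int]
    seg: np.ndarray
    cell: UnitCellGeometry = field(repr=False)
    octant: bool = False

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.seg == SEG_TISSUE

    @property
    def channel_mask(self) -> np.ndarray:
        return self.seg >= 0

    @property
    def inside_mask(self) -> np.ndarray:
        return self.seg != SEG_OUTSIDE

    def centers(self):
        """Voxel-center coordinate vectors (x, y, z) along each axis."""
        return tuple(self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.h
                     for a in range(3))

    def blocked_segment_ids(self) -> frozenset[int]:
        return frozenset(s.id for s in self.cell.segments if s.blocked)


def _segment_distance_field(grid_axes, seg: ChannelSegment, h: float):
    """Distance from voxel centers to a segment, on its bounding subbox.

    Returns (slices, dist) where ``dist`` covers only voxels within
    R_w + h of the segment's axis-aligned bounding box.
    """
    x, y, z = grid_axes
    p0 = np.asarray(seg.p0, dtype=float)
    p1 = np.asarray(seg.p1, dtype=float)
    pad = seg.R_w + h
    lo = np.minimum(p0, p1) - pad
    hi = np.maximum(p0, p1) + pad
    sl = []
    for axis, axvals in enumerate((x, y, z)):
        i0 = int(np.searchsorted(axvals, lo[axis]))
        i1 = int(np.searchsorted(axvals, hi[axis]))
        if i0 >= i1:
            return None, None
        sl.append(slice(i0, i1))
    X, Y, Z = np.meshgrid(x[sl[0]], y[sl[1]], z[sl[2]], indexing="ij")
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0.0:
        dist = np.sqrt((X - p0[0]) ** 2 + (Y - p0[1]) ** 2 + (Z - p0[2]) ** 2)
        return tuple(sl), dist
    t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    dist = np.sqrt((X - (p0[0] + t * d[0])) ** 2
                   + (Y - (p0[1] + t * d[1])) ** 2
                   + (Z - (p0[2] + t * d[2])) ** 2)
    return tuple(sl), dist


def voxelize(cell: UnitCellGeometry, h: float, octant: bool = False) -> VoxelGrid:
    """Discretize a unit cell on a uniform voxel grid.

    A voxel belongs to a channel iff its center lies within distance R_w of
    the segment axis (capped cylinders; overlaps resolved by lowest segment
    id).  The remainder of the cell interior is tissue.  ``octant=True``
    restricts the grid to the cell's symmetry octant.
    """
    if cell.segments:
        r_min = min(s.R_w for s in cell.segments)
        if h > r_min / 2.0:
            raise GeometryError(
                f"voxel size h={h} too coarse for channel radius {r_min}"
                " (need h <= R_w/2)"
            )
        if h > r_min / 5.0 * (1.0 + 1e-9):
            warnings.warn(
                f"voxel size h={h} above R_w/5={r_min / 5:.4g}; channel surfaces "
                "are coarsely stair-cased", stacklevel=2)
    lo, hi = (cell.octant_bounds if octant else cell.bounds)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    shape = tuple(max(1, int(round((hi[a] - lo[a]) / h))) for a in range(3))
    grid = VoxelGrid(lo, h, shape, np.empty(shape, dtype=np.int16), cell, octant)
    x, y, z = grid.centers()

    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    inside = cell.inside(X, Y, Z)
    seg = np.where(inside, np.int16(SEG_TISSUE), np.int16(SEG_OUTSIDE))
    for s in sorted(cell.segments, key=lambda s: -s.id):
        sl, dist = _segment_distance_field((x, y, z), s, h)
        if sl is None:
            continue
        hit = (dist <= s.R_w) & (seg[sl] != SEG_OUTSIDE)
        seg[sl][hit] = np.int16(s.id)
    grid.seg = seg
    if not (seg == SEG_TISSUE).any():
        raise GeometryError("empty tissue mask: channels fill the whole cell")
    return grid


def measure_volumes(grid: VoxelGrid) -> tuple[float, float, float]:
    """Volume accounting (Ω_t, Ω_net, Ω_t/Ω_net) from voxel counts × h³.

    Ω_net is the network volume (channel lumen plus wall, since channel
    voxelization uses the outer radius R_w).  The ratio is the design
    objective: tissue supplied per unit network volume.
    """
    h3 = grid.h ** 3
    omega_t = float(np.count_nonzero(grid.tissue_mask)) * h3
    omega_net = float(np.count_nonzero(grid.channel_mask)) * h3
    if omega_net == 0.0:
        raise GeometryError(
            "network volume is zero (a sphere has no supply network; "
            "the volume ratio is undefined)"
        )
    return omega_t, omega_net, omega_t / omega_net


@dataclass
class DensityField:
    """Per-voxel cell number density (cells mm⁻³) with generation metadata."""

    values: np.ndarray
    mean: float
    cv: float
    correlation_length: float
    seed: int
    clipped_fraction: float


def correlated_density_field(grid: VoxelGrid, mean: float, cv: float,
                             ell: float, seed: int) -> DensityField:
    """Spatially correlated random cell-density field on the tissue voxels.

    White noise on the voxel grid is convolved with an isotropic Gaussian
    kernel of standard deviation ``ell`` (mm), affinely rescaled to the
    target mean and coefficient of variation over the tissue voxels, and
    clipped at zero.  Deterministic for a given seed.
    """
    if mean <= 0:
        raise GeometryError(f"mean density must be positive, got {mean!r}")
    if cv < 0 or ell <= 0:
        raise GeometryError("cv must be >= 0 and correlation length > 0")
    rng = np.random.default_rng(seed)
    tissue = grid.tissue_mask
    if cv == 0.0:
        values = np.where(tissue, mean, 0.0)
        return DensityField(values, mean, 0.0, ell, seed, 0.0)
    noise = rng.standard_normal(grid.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=ell / grid.h, mode="reflect")
    sample = smooth[tissue]
    std = sample.std()
    if std == 0.0:
        scaled = np.full_like(smooth, mean)
    else:
        scaled = mean + (smooth - sample.mean()) * (mean * cv / std)
    clipped = np.count_nonzero(scaled[tissue] < 0.0) / max(1, sample.size)
    if clipped > 0.01:
        warnings.warn(
            f"{clipped:.1%} of tissue voxels clipped at zero density; the "
            "requested cv is large relative to the mean", stacklevel=2)
    values = np.where(tissue, np.clip(scaled, 0.0, None), 0.0)
    return DensityField(values, mean, cv, ell, seed, float(clipped))
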