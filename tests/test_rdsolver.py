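"""Reaction-diffusion solver: closed-form oracles, conservation, ordering,
boundary-condition consistency, and the discrete maximum principle."""

import math

import numpy as np
import pytest

from perfunet.geometry import make_unit_cell, voxelize
from perfunet.parameters import SpeciesTransport, TissueParams
from perfunet.rdsolver import (BoundarySpec, PicardSettings, SolverError,
                               box_grid, field_stats, solve_cross_section,
                               solve_sphere, solve_steady_mm)
from perfunet.wallmodel import ChannelSpec

TRANSPORT = SpeciesTransport(D_t=2e-3, D_c=3e-3)


def tissue_with(rho=2e5, kocr=1e-16, km=0.028):
    return TissueParams(rho_T=rho, k_ocr=kocr, k_m=km, c_H=0.05)


ZEROTH = tissue_with(km=1e-9)  # k_m → 0: zeroth-order (constant) sink
PANEL_A = tissue_with()


def test_no_sink_uniform_dirichlet():
    grid = box_grid((0.2, 0.1, 0.1), 0.01)
    tiny = tissue_with(rho=1e-12)
    bc = BoundarySpec(faces={"x-": ("dirichlet", 0.2)})
    fld = solve_steady_mm(grid, None, TRANSPORT, tiny, bc)
    assert np.allclose(fld.tissue_values(), 0.2, rtol=1e-9)


def test_slab_zeroth_order_closed_form():
    """1D slab, Dirichlet c0 at x=0, no-flux at x=w:
    c(x) = c0 − (q/2D)(2wx − x²), matched within 0.5%."""
    w, c0 = 0.15, 1.0
    q = ZEROTH.q_max()
    h = w / 150
    grid = box_grid((w, 5 * h, 5 * h), h)
    bc = BoundarySpec(faces={"x-": ("dirichlet", c0)})
    fld = solve_steady_mm(grid, None, TRANSPORT, ZEROTH, bc)
    x = grid.centers()[0]
    c_line = fld.values[:, 2, 2]
    c_exact = c0 - q / (2 * TRANSPORT.D_t) * (2 * w * x - x ** 2)
    assert np.max(np.abs(c_line - c_exact)) / c0 < 0.005


def test_grid_convergence_second_order():
    """Observed order ≈ 2 on the 1D Michaelis–Menten slab (Richardson)."""
    w, c0 = 0.15, 0.5
    sols = {}
    for n in (40, 80, 160):
        h = w / n
        grid = box_grid((w, 3 * h, 3 * h), h)
        bc = BoundarySpec(faces={"x-": ("dirichlet", c0)})
        fld = solve_steady_mm(grid, None, TRANSPORT, PANEL_A, bc,
                              PicardSettings(tol=1e-10))
        sols[n] = float(fld.values[-1, 1, 1])  # far-face value
    e1 = abs(sols[40] - sols[160])
    e2 = abs(sols[80] - sols[160])
    order = math.log2(e1 / e2) - 1  # Richardson with reference at 160
    # crude but effective: ratio of successive errors ≈ 4 for order 2
    assert abs(sols[40] - sols[80]) / abs(sols[80] - sols[160]) == pytest.approx(
        4.0, rel=0.35)


def test_sphere_uniform_no_reaction():
    tiny = tissue_with(rho=1e-12)
    fld = solve_sphere(0.5, 0.7, TRANSPORT, tiny)
    assert np.allclose(fld.values, 0.7, rtol=1e-9)
    assert fld.center == pytest.approx(0.7, rel=1e-9)


def test_sphere_zeroth_order_center_deficit():
    """k_m→0 limit: center deficit = q R²/(6 D_t) = 1.667·R² for the
    high-demand parameters (R in mm)."""
    for R in (0.3, 0.5):
        fld = solve_sphere(R, 1.0, TRANSPORT, ZEROTH)
        deficit = 1.0 - fld.center
        assert deficit == pytest.approx(ZEROTH.q_max() / (6 * TRANSPORT.D_t) * R * R,
                                        rel=0.01)


def test_sphere_center_monotone_in_radius():
    centers = [solve_sphere(R, 1.0, TRANSPORT, PANEL_A).center
               for R in (0.3, 0.5, 0.7)]
    assert centers[0] > centers[1] > centers[2]


def test_mm_bracketed_by_zeroth_order_and_no_reaction():
    """Voxelwise: zeroth-order solution ≤ MM solution ≤ boundary value."""
    grid = voxelize(make_unit_cell("cuboid", 0.3, 0.05), 0.01, octant=True)
    bc = BoundarySpec.dirichlet_channel(0.2)
    mm = solve_steady_mm(grid, None, TRANSPORT, PANEL_A, bc)
    zer = solve_steady_mm(grid, None, TRANSPORT, ZEROTH, bc)
    m = grid.tissue_mask
    assert np.all(mm.values[m] >= zer.values[m] - 1e-9)
    assert np.all(mm.values[m] <= 0.2 + 1e-9)


def test_robin_to_dirichlet_monotone_convergence():
    """As Π_w grows ×100, the Robin solution approaches the Dirichlet
    solution monotonically in sup-norm."""
    grid = voxelize(make_unit_cell("cuboid", 0.3, 0.05), 0.01, octant=True)
    dir_fld = solve_steady_mm(grid, None, TRANSPORT, PANEL_A,
                              BoundarySpec.dirichlet_channel(0.2))
    m = grid.tissue_mask
    gaps = []
    for pi in (0.05, 0.5, 5.0, 50.0):
        rob = solve_steady_mm(grid, None, TRANSPORT, PANEL_A,
                              BoundarySpec.robin_channel(pi, 0.2))
        gaps.append(np.max(np.abs(rob.values[m] - dir_fld.values[m])))
        # Robin always lies below Dirichlet
        assert np.all(rob.values[m] <= dir_fld.values[m] + 1e-9)
    assert gaps[0] > gaps[1] > gaps[2] > gaps[3]
    assert gaps[3] < 5e-3


def test_maximum_principle_with_random_density(rng):
    grid = voxelize(make_unit_cell("cuboid", 0.3, 0.05), 0.0125, octant=True)
    dens = rng.uniform(0.0, 4e5, grid.shape)
    fld = solve_steady_mm(grid, dens, TRANSPORT, PANEL_A,
                          BoundarySpec.dirichlet_channel(0.2))
    vals = fld.tissue_values()
    assert vals.max() <= 0.2 + 1e-9
    assert vals.min() >= 0.0


def test_blocked_channel_creates_hypoxia():
    """One blocked channel in the 0.5 mm cube (all surfaces symmetric, so
    the blockage repeats periodically) produces a hypoxic region."""
    cell = make_unit_cell("cuboid", 0.5, 0.05)
    grid_ok = voxelize(cell, 0.0125, octant=False)
    bc = BoundarySpec.dirichlet_channel(0.2)
    fld_ok = solve_steady_mm(grid_ok, None, TRANSPORT, PANEL_A, bc)
    grid_blk = voxelize(cell.with_blocked([0]), 0.0125, octant=False)
    fld_blk = solve_steady_mm(grid_blk, None, TRANSPORT, PANEL_A, bc)
    mn_ok, _, frac_ok = field_stats(fld_ok.values, grid_ok.tissue_mask, 0.05)
    mn_blk, _, frac_blk = field_stats(fld_blk.values, grid_blk.tissue_mask, 0.05)
    assert frac_blk > 0.0
    assert mn_blk < mn_ok
    assert frac_blk > frac_ok


def test_cross_section_zero_density():
    tiny = tissue_with(rho=1e-12)
    res = solve_cross_section(0.4, ChannelSpec(R_c=0.05, wall_mode="no_wall"),
                              0.8, None, TRANSPORT, tiny)
    assert np.allclose(res.field.tissue_values(), 0.8, rtol=1e-9)
    assert abs(res.phi) < 1e-9


def test_cross_section_conservation():
    """Wall influx per unit length equals total MM consumption within 1%."""
    res = solve_cross_section(0.5, ChannelSpec(R_c=0.05, wall_mode="no_wall"),
                              1.0, None, TRANSPORT, PANEL_A)
    assert res.phi == pytest.approx(res.consumption, rel=0.01)
    # Robin variant conserves too
    res_r = solve_cross_section(0.5, ChannelSpec(R_c=0.05, wall_mode="no_wall"),
                                1.0, None, TRANSPORT, PANEL_A, pi_w=0.1)
    assert res_r.phi == pytest.approx(res_r.consumption, rel=0.01)
    assert res_r.min_c < res.min_c  # finite wall resistance lowers the field


def test_field_stats():
    vals = np.full((10, 10, 1), 0.2)
    mask = np.ones_like(vals, dtype=bool)
    mn0, mean0, frac0 = field_stats(vals, mask, 0.05)
    assert (mn0, frac0) == (0.2, 0.0)
    assert mean0 == pytest.approx(0.2)
    vals[0, 0, 0] = 0.01
    mn, mean, frac = field_stats(vals, mask, 0.05)
    assert mn == pytest.approx(0.01)
    assert frac == pytest.approx(1.0 / 100.0)
    with pytest.raises(SolverError):
        field_stats(vals, np.zeros_like(mask), 0.05)


def test_nonconvergence_raises():
    grid = box_grid((0.1, 0.02, 0.02), 0.005)
    bc = BoundarySpec(faces={"x-": ("dirichlet", 0.2)})
    with pytest.raises(SolverError, match="converge"):
        solve_steady_mm(grid, None, TRANSPORT, PANEL_A, bc,
                        PicardSettings(tol=1e-6, max_iter=1))
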