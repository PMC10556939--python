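"""Stagnation metrics: brute-force oracles, monotonicity, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import graftflow as gf
from graftflow.metrics import (low_velocity_area, low_velocity_volume,
                               outlet_flow_volume, region_volume_ml)
from graftflow.voxel import cell_speeds

from conftest import make_box_channel_model, voxelize_quiet


@pytest.fixture(scope="module")
def row_grid():
    """Three fluid cells in a row along x (1-mm cubes)."""
    return gf.voxelize(make_box_channel_model(size=(3.0, 1.0, 1.0)), 1.0)


@pytest.fixture(scope="module")
def slab_grid():
    """10 x 10 x 1 mm slab for plane-section tests."""
    return gf.voxelize(make_box_channel_model(size=(10.0, 10.0, 1.0)), 1.0)


def field_with_cell_speeds(grid, speeds):
    """Build a field whose x-face averages reproduce the given cell speeds."""
    fld = gf.FlowField.at_rest(grid)
    u = np.zeros(grid.shape[0] + 1)
    for i, s in enumerate(speeds):
        u[i + 1] = 2 * s - u[i]
    fld.u[:] = u[:, None, None]
    return fld


def test_three_cell_enumeration(row_grid):
    """Speeds (0.01, 0.03, 0.04) m/s in 1-mm^3 cells: the inclusive 0.03
    threshold keeps two cells -> 2 mm^3."""
    fld = field_with_cell_speeds(row_grid, [0.01, 0.03, 0.04])
    got = low_velocity_volume(fld, row_grid, region="whole_fluid", threshold=0.03)
    assert got == pytest.approx(2e-3)  # mL


def test_zero_field_fills_region(row_grid):
    fld = gf.FlowField.at_rest(row_grid)
    v = low_velocity_volume(fld, row_grid, region="whole_fluid")
    assert v == pytest.approx(region_volume_ml(row_grid, "whole_fluid"))


def test_uniform_fast_flow_empty(row_grid):
    fld = field_with_cell_speeds(row_grid, [0.05, 0.05, 0.05])
    assert low_velocity_volume(fld, row_grid, region="whole_fluid") == 0.0


def test_empty_region_rejected(row_grid):
    fld = gf.FlowField.at_rest(row_grid)
    with pytest.raises(ValueError, match="region"):
        low_velocity_volume(fld, row_grid, region=np.zeros(row_grid.shape, bool))


@settings(max_examples=25, deadline=None)
@given(data=st.data())
def test_threshold_monotone_and_recount(data):
    """Property: LVV is nondecreasing in the threshold, and an independent
    cell-by-cell recount reproduces it exactly on small grids."""
    grid = gf.voxelize(make_box_channel_model(size=(6.0, 4.0, 3.0)), 1.0)
    rng = np.random.default_rng(data.draw(st.integers(0, 2 ** 31 - 1)))
    fld = gf.FlowField.at_rest(grid)
    fld.u[:] = rng.uniform(-0.08, 0.08, fld.u.shape)
    fld.v[:] = rng.uniform(-0.08, 0.08, fld.v.shape)
    fld.w[:] = rng.uniform(-0.08, 0.08, fld.w.shape)
    t1 = data.draw(st.floats(0.005, 0.05))
    t2 = data.draw(st.floats(0.005, 0.05))
    lo, hi = min(t1, t2), max(t1, t2)
    v_lo = low_velocity_volume(fld, grid, "whole_fluid", lo)
    v_hi = low_velocity_volume(fld, grid, "whole_fluid", hi)
    assert v_lo <= v_hi
    # brute-force recount, cell by cell
    speed = cell_speeds(grid, fld.u, fld.v, fld.w)
    n = 0
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            for k in range(grid.shape[2]):
                if grid.fluid[i, j, k] and speed[i, j, k] <= hi:
                    n += 1
    assert v_hi == n * grid.cell_volume * 1e6


def test_analysis_region_bounded_by_whole(mini_run):
    grid = mini_run.grid
    for fld in mini_run.snapshots.values():
        a = low_velocity_volume(fld, grid, "analysis_region")
        w = low_velocity_volume(fld, grid, "whole_fluid")
        assert a <= w


# ---------------------------------------------------------------------------
# plane sections
# ---------------------------------------------------------------------------

def test_plane_full_and_empty(slab_grid):
    zero = gf.FlowField.at_rest(slab_grid)
    area = low_velocity_area(zero, slab_grid, plane=("z", 0.5))
    assert area == pytest.approx(100.0)  # full 10x10 mm section
    fast = gf.FlowField.at_rest(slab_grid)
    fast.u[:] = 0.2
    assert low_velocity_area(fast, slab_grid, plane=("z", 0.5)) == 0.0


def test_plane_shear_layer_isoline(slab_grid):
    """Speed 0.01 for y < 5 mm, 0.06 above: the low-velocity area is the
    lower half-section, within one cell row."""
    fld = gf.FlowField.at_rest(slab_grid)
    ny = slab_grid.shape[1]
    prof = np.where(np.arange(ny) < ny // 2, 0.01, 0.06)
    fld.u[:] = prof[None, :, None]
    area = low_velocity_area(fld, slab_grid, plane=("z", 0.5))
    assert abs(area - 50.0) <= 10.0


def test_plane_outside_grid_rejected(slab_grid):
    fld = gf.FlowField.at_rest(slab_grid)
    with pytest.raises(ValueError, match="plane"):
        low_velocity_area(fld, slab_grid, plane=("z", 50.0))


# ---------------------------------------------------------------------------
# outlet flow volume
# ---------------------------------------------------------------------------

def test_plug_flow_volume_closed_form():
    """Constant 0.1 m/s plug through the duct outlet for 0.35 s equals
    speed x outlet area x duration."""
    grid = gf.voxelize(make_box_channel_model(size=(6.0, 4.0, 4.0)), 1.0)
    area = grid.tagged_area(4, "duct_out")      # m^2, exact for a duct
    fields = []
    for t in np.linspace(0.0, 0.35, 36):
        f = gf.FlowField.at_rest(grid)
        f.u[:] = 0.1
        f.t = t
        fields.append(f)
    got = outlet_flow_volume(fields, grid, "duct_out")
    assert got == pytest.approx(0.1 * area * 0.35 * 1e6, rel=0.005)
    # zero field -> zero volume
    rest = [gf.FlowField.at_rest(grid) for _ in range(3)]
    for i, f in enumerate(rest):
        f.t = 0.1 * i
    assert outlet_flow_volume(rest, grid, "duct_out") == 0.0


def test_unknown_outlet_rejected(mini_run):
    with pytest.raises(KeyError, match="unknown outlet"):
        mini_run.series.outlet_volume("nonexistent")


def test_outflow_sums_match_inflow(mini_run):
    """Conservation: integrated inflow equals the summed outlet volumes."""
    s = mini_run.series
    vol_in = s.outlet_volume("inlet")
    vol_out = sum(s.outlet_volume(lab) for lab in s.outlet_flux_ml_s
                  if lab != "inlet")
    assert vol_out == pytest.approx(vol_in, rel=1e-3)
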