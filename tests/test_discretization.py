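"""Voxelization: resolution checks, tagged areas, convergence, Courant."""

import math

import numpy as np
import pytest

import graftflow as gf
from graftflow.geometry import GeometryModel, SurfaceCap
from graftflow.voxel import FACE_INLET, FACE_WALL, VoxelResolutionError

from conftest import make_box_channel_model, make_cylinder_model, voxelize_quiet


def test_tube_resolution_matches_mesh_parity():
    """A 24-mm tube at 0.5-mm spacing: ~48 cells across the diameter and
    well over 36 wall nodes around one circumference."""
    model = make_cylinder_model(diameter=24.0, length=10.0)
    grid = gf.voxelize(model, 0.5)
    mid = grid.shape[0] // 2
    sect = grid.fluid[mid]
    widths = sect.sum(axis=0)
    assert widths.max() in (47, 48, 49)
    # wall faces ringing the section (y- and z-normal faces in this slice)
    ring = (np.count_nonzero(grid.face_flag[1][mid] == FACE_WALL)
            + np.count_nonzero(grid.face_flag[2][mid] == FACE_WALL))
    assert ring >= 36


def test_all_solid_model_rejected():
    model = make_cylinder_model()
    model.sdf = lambda p: np.ones(np.atleast_2d(p).shape[0])
    with pytest.raises(VoxelResolutionError, match="no fluid"):
        gf.voxelize(model, 1.0)


def test_unresolved_artery_rejected_and_marginal_warns():
    spec = gf.DesignSpec("direct")
    model = gf.build_design(spec)
    with pytest.raises(VoxelResolutionError, match="spacing"):
        gf.voxelize(model, 1.5)
    with pytest.warns(UserWarning, match="segmental artery"):
        gf.voxelize(model, 1.0)


def test_voxel_volume_first_order_convergence():
    """Richardson check: voxel volume error vs the analytic cylinder volume
    shrinks at least linearly over 1.0 -> 0.5 -> 0.25 mm."""
    model = make_cylinder_model(diameter=24.0, length=30.0)
    analytic = math.pi * 1.2 ** 2 * 3.0
    errs = []
    for h in (1.0, 0.5, 0.25):
        grid = gf.voxelize(model, h)
        errs.append(abs(grid.fluid_volume_ml() - analytic))
    assert errs[2] < errs[0]
    slope = np.polyfit(np.log([1.0, 0.5, 0.25]), np.log(np.maximum(errs, 1e-12)), 1)[0]
    assert slope >= 0.9


def test_inlet_area_close_to_disc(mini_grid):
    model = make_cylinder_model(diameter=24.0, length=20.0)
    grid = gf.voxelize(model, 1.0)
    disc = math.pi * 12.0 ** 2 * 1e-6  # m^2
    assert grid.tagged_area(FACE_INLET) == pytest.approx(disc, rel=0.05)


def test_voxel_volume_matches_fluid_volume():
    spec = gf.DesignSpec("interposition")
    model = gf.build_design(spec)
    grid = voxelize_quiet(model, 1.0)
    assert grid.fluid_volume_ml() == pytest.approx(gf.fluid_volume(model, 0.5), rel=0.05)


# ---------------------------------------------------------------------------
# Courant number
# ---------------------------------------------------------------------------

def make_uniform_field(grid, speed):
    fld = gf.FlowField.at_rest(grid)
    fld.u[:] = speed
    return fld


def test_courant_number_formula():
    model = make_box_channel_model(size=(10.0, 4.0, 4.0))
    grid = gf.voxelize(model, 1.0)
    zero = gf.FlowField.at_rest(grid)
    assert gf.courant_number(grid, zero, 1e-3) == 0.0
    fld = make_uniform_field(grid, 0.5)
    co = gf.courant_number(grid, fld, 1e-3)
    assert co == pytest.approx(0.5)
    assert gf.courant_number(grid, fld, 2e-3) == pytest.approx(2 * co)
    with pytest.raises(ValueError):
        gf.courant_number(grid, fld, 0.0)
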