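"""Shared fixtures: small geometries and pre-solved runs reused across tests."""

import numpy as np
import pytest

import graftflow as gf
from graftflow.geometry import GeometryModel, SurfaceCap, sd_box, sd_capped_cylinder


def make_cylinder_model(diameter=24.0, length=100.0):
    """A bare straight tube along x with inlet/outlet caps (mm)."""
    r = diameter / 2.0
    a = np.array([0.0, 0.0, 0.0])
    b = np.array([length, 0.0, 0.0])

    def sdf(p):
        return sd_capped_cylinder(p, a, b, r)

    return GeometryModel(
        sdf=sdf,
        bounding_box=(np.array([0.0, -r - 1, -r - 1]),
                      np.array([length, r + 1, r + 1])),
        inlet=SurfaceCap("inlet", a, np.array([-1.0, 0, 0]), r),
        outlets=[SurfaceCap("trunk_distal", b, np.array([1.0, 0, 0]), r)],
        analysis_region=lambda p: np.ones(np.atleast_2d(p).shape[0], dtype=bool),
    )


def make_box_channel_model(size=(3.0, 1.0, 1.0), outlet_both_ends=False):
    """Rectangular duct along x, walls on y/z, caps on the x ends (mm)."""
    sx, sy, sz = size
    lo = np.array([0.0, 0.0, 0.0])
    hi = np.array([sx, sy, sz])
    big = max(sy, sz)

    def sdf(p):
        return sd_box(p, lo, hi)

    mid = np.array([0.0, sy / 2, sz / 2])
    inlet = SurfaceCap("inlet", mid, np.array([-1.0, 0, 0]), big)
    out_b = SurfaceCap("duct_out", np.array([sx, sy / 2, sz / 2]),
                       np.array([1.0, 0, 0]), big)
    outlets = [out_b]
    if outlet_both_ends:
        outlets = [SurfaceCap("duct_in", mid, np.array([-1.0, 0, 0]), big), out_b]
        inlet = SurfaceCap("inlet", np.array([-99.0, 0, 0]),
                           np.array([-1.0, 0, 0]), 1e-6)  # no inlet faces
    return GeometryModel(
        sdf=sdf,
        bounding_box=(lo - np.array([0, 1.0, 1.0]), hi + np.array([0, 1.0, 1.0])),
        inlet=inlet, outlets=outlets,
        analysis_region=lambda p: np.ones(np.atleast_2d(p).shape[0], dtype=bool),
    )


def voxelize_quiet(model, spacing):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gf.voxelize(model, spacing)


# ---------------------------------------------------------------------------
# a small, fast direct-anastomosis fixture (scaled geometry, short systole)
# ---------------------------------------------------------------------------

MINI_SPEC = gf.DesignSpec("direct", trunk_diameter=8.0, branch_diameter=4.0,
                          segmental_diameter=2.0, trunk_length=24.0,
                          outlet_standoff=8.0)
MINI_WAVE = gf.PulseWaveform(systole_duration=0.1, snapshot_time=0.08,
                             peak_inlet_speed=0.4)
MINI_CFG = gf.SolverConfig(end_time=0.1)


@pytest.fixture(scope="session")
def mini_run():
    """Transient solve of the scaled direct fixture."""
    return gf.run_single_design(MINI_SPEC, MINI_CFG, MINI_WAVE, spacing=1.0)


@pytest.fixture(scope="session")
def mini_grid():
    model = gf.build_design(MINI_SPEC, MINI_WAVE)
    return voxelize_quiet(model, 1.0)


@pytest.fixture(scope="session")
def duct_steady():
    """Steady plug-fed flow in a 4x4-mm duct at 16 cells across: the
    developed-profile oracle shared by the solver and acceptance suites.
    Returns (grid, field, inlet flow rate in m^3/s)."""
    model = make_box_channel_model(size=(8.0, 4.0, 4.0))
    grid = gf.voxelize(model, 0.25)
    props = gf.FluidProperties(density=1000.0, viscosity=0.004)
    cfg = gf.SolverConfig(dt=2e-3, end_time=1.0)
    u_plug = 0.005
    fld = gf.FlowField.at_rest(grid)
    prev = None
    for _ in range(3000):
        fld = gf.advance_step(grid, fld, props, cfg, u_plug)
        cur = float(np.abs(fld.u).max())
        if prev is not None and abs(cur - prev) < 1e-9 * cur:
            break
        prev = cur
    from graftflow.voxel import FACE_INLET
    q_in = u_plug * grid.tagged_area(FACE_INLET)
    return grid, fld, q_in
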