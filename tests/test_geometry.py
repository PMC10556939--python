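"""Geometry builder: spec validation, implicit models, volumes, waveform."""

import math

import numpy as np
import pytest
from scipy import ndimage

import graftflow as gf
from graftflow.geometry import DesignError, sd_capped_cylinder, sd_union

from conftest import make_cylinder_model, voxelize_quiet


# ---------------------------------------------------------------------------
# DesignSpec validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs, needle", [
    (dict(design_kind="direct", branch_shape="hemisphere"), "hemisphere"),
    (dict(design_kind="end_graft", branch_shape="hemisphere"), "hemisphere"),
    (dict(design_kind="direct", segmental_diameter=12.0), "diameter"),
    (dict(design_kind="direct", branch_diameter=30.0), "diameter"),
    (dict(design_kind="direct", n_pairs=2), "n_pairs"),
    (dict(design_kind="direct", trunk_length=0.0), "trunk_length"),
    (dict(design_kind="nonsense"), "design_kind"),
])
def test_invalid_specs_rejected_with_field_names(kwargs, needle):
    with pytest.raises(DesignError, match=needle):
        gf.DesignSpec(**kwargs)


def test_direct_artery_meets_trunk_without_branch():
    model = gf.build_design(gf.DesignSpec("direct"))
    # artery interior: 2-mm tube rising from the trunk wall at mid-trunk
    assert model.sdf([30.0, 30.0, 0.0]) < 0
    # no wide branch: a point 3 mm off the branch axis is solid
    assert model.sdf([30.0, 20.0, 3.0]) > 0
    # trunk axis midpoint is deep inside the fluid
    assert model.sdf([30.0, 0.0, 0.0]) < -10


def test_interposition_has_wide_branch():
    spec = gf.DesignSpec("interposition", branch_length=20.0, branch_diameter=10.0)
    model = gf.build_design(spec)
    # 10-mm-diameter branch of length 20 between trunk wall (y=12) and artery
    assert model.sdf([30.0, 20.0, 3.0]) < 0      # inside the 5-mm-radius branch
    assert model.sdf([30.0, 20.0, 6.0]) > 0      # outside it
    assert model.sdf([30.0, 40.0, 0.0]) < 0      # inside the 2-mm artery above
    assert model.sdf([30.0, 40.0, 3.0]) > 0


def test_outlet_plane_shared_across_designs():
    """Every design ends its segmental artery at the same standoff."""
    tops = []
    for kind in ("direct", "interposition", "loop", "end_graft"):
        model = gf.build_design(gf.DesignSpec(kind))
        seg = [c for c in model.outlets if c.label.startswith("segmental")]
        assert len(seg) == 1
        tops.append(seg[0].center[1])
    assert np.allclose(tops, 12.0 + 40.0)


def test_hemisphere_only_on_interposition_builds():
    spec = gf.DesignSpec("interposition", branch_shape="hemisphere")
    model = gf.build_design(spec)
    # inside the 7.5-mm half-ball on the wall, but outside a tube branch
    assert model.sdf([30.0, 16.0, 5.0]) < 0
    assert spec.hardware_height() == pytest.approx(7.5)


# ---------------------------------------------------------------------------
# fluid_volume
# ---------------------------------------------------------------------------

def test_cylinder_volume_matches_closed_form():
    model = make_cylinder_model(diameter=24.0, length=100.0)
    analytic = math.pi * 1.2 ** 2 * 10.0  # 45.24 mL
    est = gf.fluid_volume(model, resolution=0.5)
    assert est == pytest.approx(analytic, rel=0.02)


def test_union_volume_below_sum_of_parts():
    a = make_cylinder_model(diameter=20.0, length=40.0)
    b_sdf = lambda p: sd_capped_cylinder(p, [20.0, -15.0, 0.0], [20.0, 15.0, 0.0], 10.0)
    both = make_cylinder_model(diameter=20.0, length=40.0)
    both.sdf = sd_union(a.sdf, b_sdf)
    both.bounding_box = (np.array([0.0, -16.0, -11.0]), np.array([40.0, 16.0, 11.0]))
    v_a = gf.fluid_volume(a, 0.5)
    v_b = math.pi * 1.0 ** 2 * 3.0
    v_union = gf.fluid_volume(both, 0.5)
    assert v_union < v_a + v_b
    assert v_union > v_a


def test_fluid_volume_monotone_in_branch_dimensions():
    base = dict(design_kind="interposition")
    vols_len = [gf.fluid_volume(gf.build_design(gf.DesignSpec(branch_length=L, **base)), 1.0)
                for L in (10.0, 20.0, 30.0)]
    assert vols_len[0] < vols_len[1] < vols_len[2]
    vols_dia = [gf.fluid_volume(gf.build_design(gf.DesignSpec(branch_diameter=d, **base)), 1.0)
                for d in (6.0, 10.0, 12.0)]
    assert vols_dia[0] < vols_dia[1] < vols_dia[2]


def test_degenerate_resolution_rejected():
    model = make_cylinder_model()
    with pytest.raises(ValueError, match="resolution"):
        gf.fluid_volume(model, 0.0)


# ---------------------------------------------------------------------------
# inlet waveform
# ---------------------------------------------------------------------------

def test_half_sine_waveform_values():
    wf = gf.PulseWaveform()
    assert gf.inlet_speed(wf, 0.0) == 0.0
    assert gf.inlet_speed(wf, wf.systole_duration / 2) == pytest.approx(0.5)
    assert gf.inlet_speed(wf, wf.systole_duration + 0.1) == 0.0
    with pytest.raises(ValueError):
        gf.inlet_speed(wf, -0.01)


def test_table_waveform_linear_interpolation():
    knots = [(0.0, 0.0), (0.1, 0.4), (0.3, 0.1)]
    wf = gf.PulseWaveform(shape="table", table=knots, systole_duration=0.3,
                          snapshot_time=0.25)
    # hand interpolation: halfway up the first segment, 1/4 down the second
    assert gf.inlet_speed(wf, 0.05) == pytest.approx(0.2)
    assert gf.inlet_speed(wf, 0.15) == pytest.approx(0.4 + (0.1 - 0.4) * 0.25)
    assert gf.inlet_speed(wf, 0.10) == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

def sweep_specs():
    specs = [gf.DesignSpec(k) for k in ("direct", "interposition", "loop", "end_graft")]
    specs += [gf.DesignSpec("interposition", branch_length=L) for L in (10.0, 30.0)]
    specs += [gf.DesignSpec("interposition", branch_diameter=d) for d in (6.0, 8.0, 12.0)]
    specs += [gf.DesignSpec("interposition", branch_shape="hemisphere")]
    specs += [gf.DesignSpec("loop", loop_shape=s) for s in ("elongated", "curved")]
    specs += [gf.DesignSpec("direct", n_pairs=3), gf.DesignSpec("interposition", n_pairs=3)]
    specs += [gf.DesignSpec("interposition", branch_angle=45.0)]
    return specs


@pytest.mark.parametrize("spec", sweep_specs(), ids=lambda s: s.label())
def test_sweep_designs_build_and_connect(spec):
    """Every design in the experiment sweeps voxelizes into a single fluid
    component that reaches the inlet and every outlet."""
    model = gf.build_design(spec)
    grid = voxelize_quiet(model, 1.0)
    labels, n = ndimage.label(grid.fluid)
    assert n == 1
    from graftflow.voxel import FACE_INLET, FACE_OUTLET
    assert grid.tagged_area(FACE_INLET) > 0
    for lab in grid.outlet_labels:
        assert grid.tagged_area(FACE_OUTLET, lab) > 0, f"outlet {lab} unreachable"


def test_sdf_is_lipschitz():
    rng = np.random.default_rng(42)
    for kind in ("direct", "interposition", "loop", "end_graft"):
        model = gf.build_design(gf.DesignSpec(kind))
        lo, hi = model.bounding_box
        a = rng.uniform(lo - 5, hi + 5, size=(400, 3))
        b = rng.uniform(lo - 5, hi + 5, size=(400, 3))
        gap = np.abs(model.sdf(a) - model.sdf(b))
        dist = np.linalg.norm(a - b, axis=1)
        assert np.all(gap <= dist + 1e-9), kind
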