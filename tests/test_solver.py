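"""Flow solver: analytic oracles, conservation, determinism, refinement."""

import math
import warnings

import numpy as np
import pytest

import graftflow as gf
from graftflow.solver import ConvergenceError

from conftest import (MINI_CFG, MINI_SPEC, MINI_WAVE, make_box_channel_model,
                      voxelize_quiet)


# ---------------------------------------------------------------------------
# closed-form duct flow (independent oracle)
# ---------------------------------------------------------------------------

def duct_series_velocity(y, z, a, b, g, nu, terms=60):
    """Steady laminar velocity in a rectangular duct |y|<=a, |z|<=b driven by
    a uniform body force g (m/s^2): classic Fourier series solution."""
    u = np.zeros_like(np.broadcast_arrays(y, z)[0], dtype=float)
    for i in range(terms):
        n = 2 * i + 1
        sgn = (-1) ** i
        u += (sgn / n ** 3 *
              (1 - np.cosh(n * math.pi * z / (2 * a)) /
               math.cosh(n * math.pi * b / (2 * a))) *
              np.cos(n * math.pi * y / (2 * a)))
    return 16 * a ** 2 * g / (nu * math.pi ** 3) * u


def duct_series_flow_rate(a, b, g, nu, terms=60):
    s = sum(math.tanh((2 * i + 1) * math.pi * b / (2 * a)) / (2 * i + 1) ** 5
            for i in range(terms))
    return (4 * b * a ** 3 * g / (3 * nu)) * (1 - 192 * a / (math.pi ** 5 * b) * s)


def test_duct_oracle_self_consistent():
    """The series flow rate equals the numerically integrated series profile."""
    a = b = 2e-3
    g, nu = 0.01, 4e-6
    y = np.linspace(-a, a, 201)
    z = np.linspace(-b, b, 201)
    yy, zz = np.meshgrid(y, z, indexing="ij")
    q_num = np.trapezoid(np.trapezoid(duct_series_velocity(yy, zz, a, b, g, nu),
                                      z, axis=1), y)
    assert q_num == pytest.approx(duct_series_flow_rate(a, b, g, nu), rel=1e-4)


def duct_oracle_errors(grid, fld, q_in):
    """(flow-rate, centerline) relative errors of the developed section
    against the rectangular-duct closed form carrying the same flow rate."""
    a = b = 2e-3
    nu = 4e-6
    sect = int(grid.shape[0] * 0.75)   # developed, away from the outlet
    uc = 0.5 * (fld.u[sect] + fld.u[sect + 1])
    q_sect = uc[grid.fluid[sect]].sum() * grid.face_area
    shape_peak = duct_series_velocity(0.0, 0.0, a, b, 1.0, nu)
    shape_q = duct_series_flow_rate(a, b, 1.0, nu)
    u_max_exact = shape_peak * q_in / shape_q
    return abs(q_sect - q_in) / q_in, abs(uc.max() - u_max_exact) / u_max_exact


def test_steady_poiseuille_duct(duct_steady):
    """Constant plug inflow into a 4x4-mm duct at 16 cells across: the
    developed profile's centerline velocity and section flow rate match the
    rectangular-duct closed form within 3%."""
    err_q, err_u = duct_oracle_errors(*duct_steady)
    assert err_q <= 1e-3               # conservation to the section
    assert err_u <= 0.03


# ---------------------------------------------------------------------------
# elementary contracts
# ---------------------------------------------------------------------------

def test_rest_state_is_fixed_point(mini_grid):
    fld = gf.FlowField.at_rest(mini_grid)
    new = gf.advance_step(mini_grid, fld, gf.FluidProperties(), MINI_CFG, 0.0)
    for arr in (new.u, new.v, new.w, new.p):
        assert np.all(arr == 0.0)


def test_no_slip_exact_on_walls(mini_run):
    from graftflow.voxel import FACE_WALL
    grid = mini_run.grid
    for fld in mini_run.snapshots.values():
        for ax, arr in enumerate(fld.velocity_arrays()):
            assert np.all(arr[grid.face_flag[ax] == FACE_WALL] == 0.0)


def test_divergence_free_and_mass_balance(mini_run):
    """Converged steps: cell divergence below 1e-6 * (peak speed / dx) and
    global mass imbalance below the 0.1% tolerance."""
    s = mini_run.series
    tol_div = 1e-6 * MINI_WAVE.peak_inlet_speed / mini_run.grid.spacing
    assert s.max_divergence.max() <= tol_div
    assert s.mass_imbalance.max() <= 1e-3


def test_transient_is_deterministic():
    r1 = gf.run_single_design(MINI_SPEC, MINI_CFG, MINI_WAVE, spacing=1.0,
                              use_cache=False)
    r2 = gf.run_single_design(MINI_SPEC, MINI_CFG, MINI_WAVE, spacing=1.0,
                              use_cache=False)
    assert np.array_equal(r1.series.low_velocity_volume,
                          r2.series.low_velocity_volume)
    for lab in r1.series.outlet_flux_ml_s:
        assert np.array_equal(r1.series.outlet_flux_ml_s[lab],
                              r2.series.outlet_flux_ml_s[lab])
    f1 = r1.snapshots[max(r1.snapshots)]
    f2 = r2.snapshots[max(r2.snapshots)]
    assert np.array_equal(f1.u, f2.u) and np.array_equal(f1.p, f2.p)


def test_time_step_refinement(mini_run):
    """Halving dt changes the low-velocity-volume series by < 5% RMS on the
    coarse direct-anastomosis fixture."""
    cfg2 = gf.SolverConfig(dt=2e-3, end_time=MINI_CFG.end_time)
    r2 = gf.run_single_design(MINI_SPEC, cfg2, MINI_WAVE, spacing=1.0)
    t2 = r2.series.times
    lvv2 = r2.series.low_velocity_volume_whole
    lvv1 = np.interp(t2, mini_run.series.times,
                     mini_run.series.low_velocity_volume_whole)
    rms_diff = np.sqrt(np.mean((lvv1 - lvv2) ** 2))
    rms_level = np.sqrt(np.mean(lvv1 ** 2))
    assert rms_diff < 0.05 * rms_level


def test_grid_refinement_converges():
    """Refining the spacing moves the time-averaged low-velocity volume
    monotonically closer to a refined-grid reference (scaled direct
    fixture, 4-mm artery)."""
    spec = gf.DesignSpec("direct", trunk_diameter=12.0, branch_diameter=6.0,
                         segmental_diameter=4.0, trunk_length=30.0,
                         outlet_standoff=10.0)
    wf = gf.PulseWaveform(systole_duration=0.1, snapshot_time=0.08,
                          peak_inlet_speed=0.4)
    cfg = gf.SolverConfig(end_time=0.1)

    def lvv(h):
        res = gf.run_single_design(spec, cfg, wf, spacing=h)
        return res.series.time_averaged_lvv("whole_fluid")

    ref = lvv(0.75)
    errs = [abs(lvv(h) - ref) for h in (2.0, 1.5, 1.0)]
    assert errs[0] > errs[1] > errs[2]


def test_inner_iteration_failure_carries_history(mini_grid):
    cfg = gf.SolverConfig(max_inner_iterations=1, min_inner_iterations=2,
                          end_time=0.1)
    fld = gf.FlowField.at_rest(mini_grid)
    with pytest.raises(ConvergenceError) as exc:
        gf.advance_step(mini_grid, fld, gf.FluidProperties(), cfg, 0.3)
    assert len(exc.value.history) >= 1


def test_large_courant_warns(mini_grid):
    fld = gf.FlowField.at_rest(mini_grid)
    with pytest.warns(UserWarning, match="Courant"):
        gf.advance_step(mini_grid, fld, gf.FluidProperties(), MINI_CFG, 5.0)


def test_symmetric_half_domain_matches_full():
    """The mirror-plane half-domain solve reproduces the full-domain
    stagnation series and outlet fluxes (full-vessel scaling included)."""
    full = gf.run_single_design(MINI_SPEC, MINI_CFG, MINI_WAVE, spacing=1.0,
                                symmetric=False)
    half = gf.run_single_design(MINI_SPEC, MINI_CFG, MINI_WAVE, spacing=1.0,
                                symmetric=True)
    assert half.grid.n_fluid < 0.6 * full.grid.n_fluid
    for lab in full.series.outlet_flux_ml_s:
        a = full.series.outlet_flux_ml_s[lab]
        b = half.series.outlet_flux_ml_s[lab]
        scale = max(np.abs(a).max(), 1e-12)
        assert np.abs(a - b).max() <= 2e-3 * scale, lab
    a = full.series.low_velocity_volume_whole
    b = half.series.low_velocity_volume_whole
    assert np.abs(a - b).max() <= 5e-3 * np.abs(a).max()
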