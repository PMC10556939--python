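"""Incompressible pulsatile flow solver on the masked staggered grid.

The scheme is an iterative predictor / pressure-correction (SIMPLE-family)
method: each inner iteration advances a momentum predictor with second-order
upwind convection and explicit diffusion from the current iterate, solves the
pressure-correction Poisson problem exactly (sparse direct factorisation,
built once per grid), corrects face velocities to a discretely divergence-free
state, and under-relaxes velocity and pressure.  Inner iterations repeat until
the global mass-balance residual and the relative change of the low-velocity
volume between iterates both drop below tolerance.

Boundary conditions: prescribed plug velocity on the inlet cap, fixed (gauge
zero) pressure on every outlet cap with zero-gradient velocity, no-slip on
stair-step walls (wall-face velocities identically zero; tangential ghosts
mirrored so the wall sits half a cell from the nearest velocity point).

Momentum is marched explicitly, so the step is split into CFL-guarded
substeps when the advective Courant number exceeds ``cfg.cfl_limit``; the
public contract of :func:`advance_step` (field at t, returns field at t+dt)
is unchanged by substepping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import GeometryModel, PulseWaveform, inlet_speed
from .units import mmhg_to_pa
from .voxel import (FACE_INLET, FACE_INTERIOR, FACE_OUTLET, VoxelGrid,
                    cell_speeds, courant_number)

__all__ = ["FluidProperties", "SolverConfig", "FlowField", "advance_step",
           "solve_transient", "ConvergenceError", "divergence", "boundary_fluxes"]


class ConvergenceError(RuntimeError):
    """Inner iterations failed to converge; carries the residual history."""

    def __init__(self, msg, history):
        super().__init__(msg)
        self.history = history


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: blood approximated with constant properties."""
    density: float = 1000.0        # kg/m^3
    viscosity: float = 0.004       # Pa s
    body_force: tuple = (0.0, 0.0, 0.0)   # m/s^2


@dataclass(frozen=True)
class SolverConfig:
    dt: float = 1e-3               # s
    end_time: float = 0.35         # s
    outlet_pressure: float = 120.0  # mmHg; only the gauge offset, see `p`
    max_inner_iterations: int = 200
    min_inner_iterations: int = 1
    mass_balance_tol: float = 1e-3
    lvv_change_tol: float = 1e-3
    under_relaxation: tuple = (0.7, 0.3)   # (velocity, pressure)
    turbulence_mode: str = "laminar"       # or "k_epsilon"
    cfl_limit: float = 0.45        # advective CFL per explicit substep
    lvv_threshold: float = 0.03    # m/s, used for the inner convergence check
    seed: int = 0                  # reserved; the solver is deterministic

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.mass_balance_tol <= 0 or self.lvv_change_tol <= 0:
            raise ValueError("tolerances must be > 0")
        for f in self.under_relaxation:
            if not 0.0 < f <= 1.0:
                raise ValueError("under-relaxation factors must lie in (0, 1]")
        if self.turbulence_mode not in ("laminar", "k_epsilon"):
            raise ValueError(f"unknown turbulence_mode {self.turbulence_mode!r}")

    @property
    def outlet_pressure_pa(self) -> float:
        return mmhg_to_pa(self.outlet_pressure)


@dataclass
class FlowField:
    """Discrete state: face-normal velocities (m/s), cell pressures (Pa,
    gauge relative to the outlets), optional turbulence scalars, time (s)."""
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    t: float = 0.0
    k: Optional[np.ndarray] = None
    eps: Optional[np.ndarray] = None

    @classmethod
    def at_rest(cls, grid: VoxelGrid, turbulence: bool = False) -> "FlowField":
        nx, ny, nz = grid.shape
        f = cls(u=np.zeros((nx + 1, ny, nz)), v=np.zeros((nx, ny + 1, nz)),
                w=np.zeros((nx, ny, nz + 1)), p=np.zeros((nx, ny, nz)), t=0.0)
        if turbulence:
            f.k = np.full((nx, ny, nz), 1e-6)
            f.eps = np.full((nx, ny, nz), 1e-6)
        return f

    def copy(self) -> "FlowField":
        return FlowField(u=self.u.copy(), v=self.v.copy(), w=self.w.copy(),
                         p=self.p.copy(), t=self.t,
                         k=None if self.k is None else self.k.copy(),
                         eps=None if self.eps is None else self.eps.copy())

    def velocity_arrays(self):
        return (self.u, self.v, self.w)


# --------------------------------------------------------------------------
# per-grid operator cache
# --------------------------------------------------------------------------

def _perm(axis):
    return (axis, (axis + 1) % 3, (axis + 2) % 3)


def _ops(grid: VoxelGrid):
    ops = grid._cache.get("ops")
    if ops is not None:
        return ops
    ops = {}
    for ax in range(3):
        flag = grid.face_flag[ax]
        active = flag == FACE_INTERIOR
        usable = flag != 0                      # a velocity value exists here
        outlet = flag == FACE_OUTLET
        inlet = flag == FACE_INLET
        sl_lo = [slice(None)] * 3
        sl_lo[ax] = 0
        sl_hi = [slice(None)] * 3
        sl_hi[ax] = -1
        ops[ax] = {
            "active": active, "usable": usable, "outlet": outlet,
            "inlet": inlet, "sign": grid.face_sign[ax],
            "coef": grid.inlet_coef[ax],
            # open (outlet) domain edges: tangential ghosts are zero-gradient
            "open_low": bool(outlet[tuple(sl_lo)].any()),
            "open_high": bool(outlet[tuple(sl_hi)].any()),
        }
    ops["fluid"] = grid.fluid
    grid._cache["ops"] = ops
    return ops


def _pressure_solver(grid: VoxelGrid):
    ps = grid._cache.get("psolver")
    if ps is not None:
        return ps
    fluid = grid.fluid
    n = int(fluid.sum())
    idx = np.full(grid.shape, -1, dtype=np.int64)
    idx[fluid] = np.arange(n)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for ax in range(3):
        flag = grid.face_flag[ax]
        n_ax = grid.shape[ax]
        # interior face f couples cells f-1 and f along ax
        inner_face = [slice(None)] * 3
        inner_face[ax] = slice(1, n_ax)
        join = (flag == FACE_INTERIOR)[tuple(inner_face)]   # faces 1..n_ax-1
        cell_lo = [slice(None)] * 3
        cell_lo[ax] = slice(0, n_ax - 1)
        cell_hi = [slice(None)] * 3
        cell_hi[ax] = slice(1, n_ax)
        a_idx = idx[tuple(cell_lo)][join]
        b_idx = idx[tuple(cell_hi)][join]
        rows.extend([a_idx, b_idx])
        cols.extend([b_idx, a_idx])
        vals.extend([-np.ones(a_idx.size), -np.ones(b_idx.size)])
        np.add.at(diag, a_idx, 1.0)
        np.add.at(diag, b_idx, 1.0)
        # outlet faces: Dirichlet p'=0 at the face itself (half-cell distance)
        outlet = flag == FACE_OUTLET
        sign = grid.face_sign[ax]
        face_r = [slice(None)] * 3
        face_r[ax] = slice(1, n_ax + 1)
        face_l = [slice(None)] * 3
        face_l[ax] = slice(0, n_ax)
        # sign +1: fluid cell sits left of the face -> cell i has face i+1
        m_p = (outlet & (sign == 1))[tuple(face_r)]
        # sign -1: fluid cell sits right of the face -> cell i has face i
        m_m = (outlet & (sign == -1))[tuple(face_l)]
        np.add.at(diag, idx[m_p], 2.0)
        np.add.at(diag, idx[m_m], 2.0)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    dx2 = grid.spacing ** 2
    A = sp.csr_matrix((np.concatenate(vals) / dx2,
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n))
    lu = spla.splu(A.tocsc())
    ps = {"lu": lu, "idx": idx, "n": n, "A": A}
    grid._cache["psolver"] = ps
    return ps


# --------------------------------------------------------------------------
# discrete operators
# --------------------------------------------------------------------------

def divergence(grid: VoxelGrid, u, v, w) -> np.ndarray:
    """Discrete divergence (1/s) in every cell (zero outside fluid)."""
    dx = grid.spacing
    div = ((u[1:] - u[:-1]) + (v[:, 1:] - v[:, :-1]) +
           (w[:, :, 1:] - w[:, :, :-1])) / dx
    return np.where(grid.fluid, div, 0.0)


def boundary_fluxes(grid: VoxelGrid, fld: FlowField) -> dict:
    """Volumetric flux (m^3/s) through the inlet and each outlet.

    Outlet fluxes are positive outward; the inlet flux is positive into the
    fluid.
    """
    ops = _ops(grid)
    A = grid.face_area * grid.symmetry_factor
    out = {}
    vel = fld.velocity_arrays()
    q_in = 0.0
    for ax in range(3):
        o = ops[ax]
        q_in += float(np.sum(vel[ax][o["inlet"]] * o["coef"][o["inlet"]])) * A
    out["inlet"] = q_in
    for j, lab in enumerate(grid.outlet_labels):
        q = 0.0
        for ax in range(3):
            o = ops[ax]
            m = o["outlet"] & (grid.outlet_id[ax] == j)
            if m.any():
                q += float(np.sum(vel[ax][m] * o["sign"][m])) * A
        out[lab] = q
    return out


def _minmod(a, b):
    return np.where(a * b > 0, np.where(np.abs(a) < np.abs(b), a, b), 0.0)


def _sou_interface(q, ok, w):
    """Limited second-order upwind interface values along axis 0.

    ``q``: (m, ...) collocated values; ``ok``: where a value exists;
    ``w``: (m-1, ...) advecting velocity at the interfaces between q[s] and
    q[s+1].  The linear-upwind correction is minmod-limited against the
    local slope so the reconstruction stays bounded at stair-step corners;
    falls back to first order where the second upstream point does not
    exist.
    """
    dq = q[1:] - q[:-1]                    # slope on interface s: q[s+1]-q[s]
    up = q[:-1].copy()
    up[1:] += 0.5 * _minmod(q[1:-1] - q[:-2], dq[1:]) * ok[:-2]
    dn = q[1:].copy()
    dn[:-1] += 0.5 * _minmod(q[1:-1] - q[2:], -dq[:-1]) * ok[2:]
    return np.where(w > 0, up, dn)


def _component_tendency(Up, Vbp, Vcp, okp, nu_face, dx, g_a,
                        edge_parity=((-1.0, -1.0), (-1.0, -1.0))):
    """Convection + diffusion tendency for one velocity component.

    All arrays are permuted so the component axis is axis 0:
    ``Up`` (n0+1, n1, n2) component values, ``Vbp`` (n0, n1+1, n2) and
    ``Vcp`` (n0, n1, n2+1) transverse components, ``okp`` usable mask for
    ``Up``.  ``edge_parity`` gives, per transverse axis, the (low, high)
    domain-edge ghost parity: -1 is the no-slip odd mirror (wall), +1 the
    even ghost used on mirror-symmetry planes and open (outlet) edges where
    the tangential velocity is zero-gradient.  Returns the tendency on the
    interior slots ``[1:-1]``.
    """
    # ---- convection, flux form -----------------------------------------
    ubar = 0.5 * (Up[:-1] + Up[1:])                       # (n0, n1, n2)
    Fx = ubar * _sou_interface(Up, okp, ubar)
    conv = (Fx[1:] - Fx[:-1]) / dx                        # (n0-1, n1, n2)

    Uc = Up[1:-1]                                         # interior face rows
    okc = okp[1:-1]
    for t_ax, V in ((1, Vbp), (2, Vcp)):
        w_edge = 0.5 * (V[:-1] + V[1:])                   # (n0-1, n1+1|.., ..)
        w_in = np.moveaxis(w_edge, t_ax, 0)[1:-1]         # interior edges only
        q = np.moveaxis(Uc, t_ax, 0)
        ok_t = np.moveaxis(okc, t_ax, 0)
        Ft = w_in * _sou_interface(q, ok_t, w_in)
        dF = np.zeros_like(q)
        dF[1:-1] = (Ft[1:] - Ft[:-1]) / dx
        # one-sided cells next to the domain edge: outer edge flux is zero
        dF[0] = Ft[0] / dx
        dF[-1] = -Ft[-1] / dx
        conv = conv + np.moveaxis(dF, 0, t_ax)

    # ---- diffusion with mirrored tangential ghosts ---------------------
    lap = (Up[:-2] - 2.0 * Uc + Up[2:]) / (dx * dx)
    for t_ax in (1, 2):
        q = np.moveaxis(Uc, t_ax, 0)
        ok_t = np.moveaxis(okc, t_ax, 0)
        low_parity, high_parity = edge_parity[t_ax - 1]
        for shift in (1, -1):
            nb = np.empty_like(q)
            if shift == 1:
                nb[:-1] = np.where(ok_t[1:], q[1:], -q[:-1])
                nb[-1] = high_parity * q[-1]
            else:
                nb[1:] = np.where(ok_t[:-1], q[:-1], -q[1:])
                nb[0] = low_parity * q[0]
            lap = lap + np.moveaxis(nb - q, 0, t_ax) / (dx * dx)
    nu_c = nu_face[1:-1] if isinstance(nu_face, np.ndarray) else nu_face
    return -conv + nu_c * lap + g_a


def _apply_boundary_values(grid, ops, vel, base, speed_now, dt):
    """Refresh prescribed / derived face values: inlet plug, wall zeros,
    convective outlet update, zeros inside solid.

    Outlet normal velocities follow the non-reflecting transport equation
    du/dt + U_c du/dn = 0 discretised upwind from the interior, with U_c the
    current bulk speed through that outlet (floored at a small positive
    value).  An instantaneous zero-gradient copy reflects deceleration-phase
    backflow disturbances and rings; the convective form advects them out.
    """
    dx = grid.spacing
    # characteristic speed per outlet tag from the substep-start state
    u_char = {}
    for j, lab in enumerate(grid.outlet_labels):
        q = 0.0
        area = 0
        for ax in range(3):
            o = ops[ax]
            m = o["outlet"] & (grid.outlet_id[ax] == j)
            if m.any():
                q += float(np.sum(base[ax][m] * o["sign"][m]))
                area += int(np.count_nonzero(m))
        u_char[j] = max(q / max(area, 1), 0.05 * abs(speed_now), 1e-3)
    for ax in range(3):
        o = ops[ax]
        arr = vel[ax]
        arr[~(o["usable"])] = 0.0
        arr[o["sign"] != 0] = 0.0            # wall/outlet/inlet reset below
        arr[o["inlet"]] = speed_now * o["coef"][o["inlet"]]
        out_p = o["outlet"] & (o["sign"] == 1)
        out_m = o["outlet"] & (o["sign"] == -1)
        for m, shift in ((out_p, 1), (out_m, -1)):
            if not m.any():
                continue
            nb = np.roll(arr, shift, axis=ax)          # predicted interior
            co = np.empty(arr.shape)
            for j in u_char:
                sel = m & (grid.outlet_id[ax] == j)
                co[sel] = np.clip(u_char[j] * dt / dx, 0.0, 1.0)
            arr[m] = base[ax][m] + co[m] * (nb[m] - base[ax][m])


def _project(grid, ops, ps, vel, dt, rho):
    """Pressure-correction solve; corrects ``vel`` in place to a discretely
    divergence-free state.  Returns the correction field p' (3-D array)."""
    div = divergence(grid, *vel)
    rhs = -(rho / dt) * div[grid.fluid]
    pvec = ps["lu"].solve(rhs)
    p3 = np.zeros(grid.shape)
    p3[grid.fluid] = pvec
    dx = grid.spacing
    for ax in range(3):
        o = ops[ax]
        arr = vel[ax]
        grad = np.diff(p3, axis=ax) / dx          # at inner faces 1..n-1
        inner = [slice(None)] * 3
        inner[ax] = slice(1, grid.shape[ax])
        act_in = o["active"][tuple(inner)]
        target = arr[tuple(inner)]
        target[act_in] -= (dt / rho) * grad[act_in]
        # outlet faces: ghost pressure 0 at the face, half-cell gradient
        pad = [(0, 0)] * 3
        pad[ax] = (1, 1)
        p_pad = np.pad(p3, pad)
        sl_l = [slice(None)] * 3
        sl_l[ax] = slice(0, grid.shape[ax] + 1)
        sl_r = [slice(None)] * 3
        sl_r[ax] = slice(1, grid.shape[ax] + 2)
        p_left = p_pad[tuple(sl_l)]
        p_right = p_pad[tuple(sl_r)]
        out = o["outlet"]
        if out.any():
            pc = np.where(o["sign"] == 1, p_left, p_right)
            arr[out] += o["sign"][out] * (2.0 * dt / (rho * dx)) * pc[out]
    return p3


def _lvv_m3(grid, vel, threshold):
    speed = cell_speeds(grid, *vel)
    return float(np.count_nonzero((speed <= threshold) & grid.fluid)) * grid.cell_volume


# --------------------------------------------------------------------------
# time stepping
# --------------------------------------------------------------------------

def advance_step(grid: VoxelGrid, fld: FlowField, props: FluidProperties,
                 cfg: SolverConfig, inlet_speed_now: float) -> FlowField:
    """Advance the flow field by one time step ``cfg.dt``.

    Inner iterations repeat until the mass-balance residual and the relative
    change of the low-velocity volume between successive iterates both fall
    below their tolerances; exceeding ``cfg.max_inner_iterations`` raises
    :class:`ConvergenceError` with the residual history attached.
    """
    ops = _ops(grid)
    ps = _pressure_solver(grid)
    rho, mu = props.density, props.viscosity
    nu: object = mu / rho
    new = fld.copy()
    vel = list(new.velocity_arrays())

    if cfg.turbulence_mode == "k_epsilon" and new.k is not None:
        from .turbulence import eddy_viscosity
        nu_t = eddy_viscosity(grid, new, nu)        # cell-centred, m^2/s
    else:
        nu_t = None

    # --- CFL bookkeeping and substepping --------------------------------
    vmax = max(abs(inlet_speed_now),
               max(float(np.abs(a).max()) for a in vel))
    co = vmax * cfg.dt / grid.spacing
    if co >= 1.0:
        # static text so repeated warnings deduplicate; the per-step Courant
        # history is recorded in the stagnation series
        warnings.warn("advective Courant number >= 1; substepping keeps the "
                      "explicit update stable", stacklevel=2)
    nsub = max(1, int(math.ceil(co / cfg.cfl_limit))) if co > 0 else 1

    alpha_u, alpha_p = cfg.under_relaxation
    history = []
    start_vel = [a.copy() for a in vel]
    start_p = new.p.copy()
    while True:                 # retried with more substeps if speeds grow
        dt_sub = cfg.dt / nsub
        for _ in range(nsub):
            base = [a.copy() for a in vel]       # substep-start state
            prev_lvv = _lvv_m3(grid, vel, cfg.lvv_threshold)
            it = 0
            while True:
                it += 1
                if it > cfg.max_inner_iterations:
                    raise ConvergenceError(
                        f"inner iterations exceeded {cfg.max_inner_iterations} "
                        f"at t={new.t:.4f}s", history)
                vel_new = _predict(grid, ops, base, vel, new.p, nu, nu_t,
                                   dt_sub, rho, props.body_force,
                                   inlet_speed_now)
                pprime = _project(grid, ops, ps, vel_new, dt_sub, rho)
                if it > 1 and alpha_u < 1.0:
                    for a in range(3):
                        vel_new[a] = alpha_u * vel_new[a] + (1.0 - alpha_u) * vel[a]
                new.p = new.p + alpha_p * pprime
                # residuals
                q_in, q_out, q_abs = _raw_fluxes(grid, ops, vel_new)
                scale = max(abs(q_in), 0.5 * q_abs, grid.face_area * 1e-9)
                mass_res = abs(q_in - q_out) / scale
                lvv = _lvv_m3(grid, vel_new, cfg.lvv_threshold)
                lvv_res = abs(lvv - prev_lvv) / max(prev_lvv, grid.cell_volume)
                history.append((mass_res, lvv_res))
                vel = vel_new
                prev_lvv = lvv
                if (it >= cfg.min_inner_iterations
                        and mass_res <= cfg.mass_balance_tol
                        and lvv_res <= cfg.lvv_change_tol):
                    break
        # velocities may have grown during the step; if the realised CFL of
        # the last substep breached the limit, redo the step finer
        vmax_end = max(float(np.abs(a).max()) for a in vel)
        co_end = vmax_end * dt_sub / grid.spacing
        if co_end <= 1.1 * cfg.cfl_limit or nsub >= 512:
            break
        nsub = max(2 * nsub,
                   int(math.ceil(co_end * nsub / cfg.cfl_limit)))
        vel = [a.copy() for a in start_vel]
        new.p = start_p.copy()

    new.u, new.v, new.w = vel
    new.t = fld.t + cfg.dt

    if cfg.turbulence_mode == "k_epsilon":
        from .turbulence import turbulence_step
        new.k, new.eps = turbulence_step(new, grid, props, cfg)
    return new


def _predict(grid, ops, base, vel, p3, nu, nu_t, dt, rho, body_force, speed_now):
    """Momentum predictor: u* = u_n + dt (tendency of the current iterate).

    ``base`` is the substep-start field, ``vel`` the current inner iterate
    whose convection/diffusion is evaluated (Picard linearisation of the
    implicit step).  Returns fresh velocity arrays with boundary values
    applied."""
    dx = grid.spacing
    out = [a.copy() for a in base]
    for ax in range(3):
        perm = _perm(ax)
        o = ops[ax]
        Up = np.transpose(vel[ax], perm)
        okp = np.transpose(o["usable"], perm)
        Vb = np.transpose(vel[perm[1]], perm)
        Vc = np.transpose(vel[perm[2]], perm)
        if nu_t is not None:
            # eddy viscosity interpolated to the component's face points
            pad = [(0, 0)] * 3
            pad[ax] = (1, 1)
            nut_pad = np.pad(nu_t, pad, mode="edge")
            sl_l = [slice(None)] * 3
            sl_l[ax] = slice(0, grid.shape[ax] + 1)
            sl_r = [slice(None)] * 3
            sl_r[ax] = slice(1, grid.shape[ax] + 2)
            nu_face = np.transpose(
                nu + 0.5 * (nut_pad[tuple(sl_l)] + nut_pad[tuple(sl_r)]), perm)
        else:
            nu_face = nu
        parity = []
        for t_ax_global in (perm[1], perm[2]):
            t_ops = ops[t_ax_global]
            low = 1.0 if ((grid.symmetry_z and t_ax_global == 2)
                          or t_ops["open_low"]) else -1.0
            high = 1.0 if t_ops["open_high"] else -1.0
            parity.append((low, high))
        tend = _component_tendency(Up, Vb, Vc, okp, nu_face, dx,
                                   body_force[ax], tuple(parity))
        # pressure gradient of the current iterate at the interior faces;
        # after permutation the component axis is 0 and np.diff already
        # reduced it to the n_ax-1 interior-face slots
        gradp_p = np.transpose(np.diff(p3, axis=ax) / dx, perm)
        Un = np.transpose(base[ax], perm).copy()
        Un[1:-1] += dt * (tend - gradp_p / rho)
        out[ax] = np.ascontiguousarray(np.transpose(Un, np.argsort(perm)))
    _apply_boundary_values(grid, ops, out, base, speed_now, dt)
    # re-zero non-active interior values overwritten above
    for ax in range(3):
        o = ops[ax]
        keep = o["active"] | o["inlet"] | o["outlet"]
        out[ax][~keep] = 0.0
    return out


def _raw_fluxes(grid, ops, vel):
    """(inlet flux, net outlet flux, gross boundary throughput) in m^3/s."""
    A = grid.face_area
    q_in = 0.0
    q_out = 0.0
    q_abs = 0.0
    for ax in range(3):
        o = ops[ax]
        f_in = float(np.sum(vel[ax][o["inlet"]] * o["coef"][o["inlet"]])) * A
        q_in += f_in
        q_abs += abs(f_in)
        m = o["outlet"]
        if m.any():
            q_out += float(np.sum(vel[ax][m] * o["sign"][m])) * A
            q_abs += float(np.sum(np.abs(vel[ax][m]))) * A
    return q_in, q_out, q_abs


def solve_transient(grid: VoxelGrid, props: FluidProperties, cfg: SolverConfig,
                    waveform: PulseWaveform, model: Optional[GeometryModel] = None,
                    store_snapshots: bool = True):
    """March from rest through the systolic waveform.

    Returns ``(snapshots, series)``: ``snapshots`` maps selected times (the
    plane-section snapshot instant and the final step) to
    :class:`FlowField` objects, and ``series`` is a
    :class:`~graftflow.metrics.StagnationSeries` with per-step low-velocity
    volumes, per-outlet fluxes and solver residuals.  The march is
    deterministic: identical inputs give bitwise-identical series.
    """
    from . import metrics as _metrics

    if cfg.end_time < waveform.systole_duration:
        raise ValueError("cfg.end_time must cover the systole "
                         f"({cfg.end_time} < {waveform.systole_duration})")
    n_steps = int(round(cfg.end_time / cfg.dt))
    snap_step = int(round(waveform.snapshot_time / cfg.dt))

    turb = cfg.turbulence_mode == "k_epsilon"
    fld = FlowField.at_rest(grid, turbulence=turb)
    region_ml = _metrics.region_volume_ml(grid, "analysis_region")

    rec = {"times": [], "lvv_analysis_ml": [], "lvv_whole_ml": [],
           "mass_imbalance": [], "max_divergence": [], "courant": []}
    flux_rec = {lab: [] for lab in grid.outlet_labels}
    flux_rec["inlet"] = []
    snapshots = {}
    plane_areas = []

    def record(f):
        rec["times"].append(f.t)
        rec["lvv_analysis_ml"].append(
            _metrics.low_velocity_volume(f, grid, region="analysis_region",
                                         threshold=cfg.lvv_threshold))
        rec["lvv_whole_ml"].append(
            _metrics.low_velocity_volume(f, grid, region="whole_fluid",
                                         threshold=cfg.lvv_threshold))
        fx = boundary_fluxes(grid, f)
        for lab in flux_rec:
            flux_rec[lab].append(fx.get(lab, 0.0) * 1e6)   # m^3/s -> mL/s
        div = divergence(grid, f.u, f.v, f.w)
        rec["max_divergence"].append(float(np.abs(div).max()))
        q_out = sum(fx[k] for k in fx if k != "inlet")
        q_abs = sum(abs(fx[k]) for k in fx)
        scale = max(abs(fx["inlet"]), 0.5 * q_abs, grid.face_area * 1e-9)
        rec["mass_imbalance"].append(abs(fx["inlet"] - q_out) / scale)
        rec["courant"].append(courant_number(grid, f, cfg.dt))

    record(fld)
    for step in range(1, n_steps + 1):
        t_new = step * cfg.dt
        speed = float(inlet_speed(waveform, t_new))
        try:
            fld = advance_step(grid, fld, props, cfg, speed)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"step to t={t_new:.4f}s failed: {err}", err.history) from err
        fld.t = t_new
        record(fld)
        if step == snap_step:
            if store_snapshots:
                snapshots[t_new] = fld.copy()
            plane_areas.append(
                (t_new, "z0",
                 _metrics.low_velocity_area(fld, grid, plane=("z", 0.0),
                                            threshold=cfg.lvv_threshold)))
    if store_snapshots:
        snapshots[fld.t] = fld.copy()

    series = _metrics.StagnationSeries(
        times=np.asarray(rec["times"]),
        low_velocity_volume=np.asarray(rec["lvv_analysis_ml"]),
        low_velocity_volume_whole=np.asarray(rec["lvv_whole_ml"]),
        threshold=cfg.lvv_threshold,
        region="analysis_region",
        region_volume_ml=region_ml,
        plane_area_snapshots=plane_areas,
        outlet_flux_ml_s={lab: np.asarray(v) for lab, v in flux_rec.items()},
        mass_imbalance=np.asarray(rec["mass_imbalance"]),
        max_divergence=np.asarray(rec["max_divergence"]),
        courant=np.asarray(rec["courant"]),
    )
    return snapshots, series
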