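"""Optional realizable k-epsilon turbulence closure.

At the scales simulated here (2-10 mm vessels, peak 0.5 m/s, blood) the
branch Reynolds numbers are transitional to laminar, so the solver default
is laminar; this closure exists as a cross-check mode.  It implements the
realizable eddy-viscosity formulation: a strain-dependent C_mu that keeps
the normal stresses non-negative, the eta-dependent production coefficient
in the epsilon equation, and positivity floors on both scalars.  Transport
is integrated explicitly with first-order upwind convection at cell
centres; the near-wall treatment is an intermittency-style laminar
suppression: the eddy viscosity is ramped down where the local Reynolds
number (speed x wall distance / nu) sits below the transitional range
1000-2000, so laminar branches stay laminar instead of being forced into a
spurious fully-turbulent state.  No log-law wall functions are applied;
walls act through the no-slip velocity field itself.
"""

from __future__ import annotations

import numpy as np

from .voxel import VoxelGrid

__all__ = ["turbulence_step", "eddy_viscosity"]

K_FLOOR = 1e-10        # m^2/s^2
EPS_FLOOR = 1e-10      # m^2/s^3
C2 = 1.9
SIGMA_K = 1.0
SIGMA_EPS = 1.2
A0 = 4.04
NUT_MAX_RATIO = 1e4    # stability cap on nu_t / nu
RE_LAMINAR = 1000.0    # below: fully suppressed eddy viscosity
RE_TURBULENT = 2000.0  # above: unsuppressed


def _cell_velocity(grid, fld):
    uc = 0.5 * (fld.u[:-1] + fld.u[1:])
    vc = 0.5 * (fld.v[:, :-1] + fld.v[:, 1:])
    wc = 0.5 * (fld.w[:, :, :-1] + fld.w[:, :, 1:])
    return uc, vc, wc


def _grad(f, axis, dx):
    g = np.zeros_like(f)
    sl_c = [slice(None)] * 3
    sl_p = [slice(None)] * 3
    sl_m = [slice(None)] * 3
    sl_c[axis] = slice(1, -1)
    sl_p[axis] = slice(2, None)
    sl_m[axis] = slice(0, -2)
    g[tuple(sl_c)] = (f[tuple(sl_p)] - f[tuple(sl_m)]) / (2 * dx)
    return g


def _strain_rotation(grid, fld):
    """Strain-rate S_ij and rotation Omega_ij tensors at cell centres."""
    dx = grid.spacing
    comps = _cell_velocity(grid, fld)
    grads = [[_grad(c, ax, dx) for ax in range(3)] for c in comps]
    S = [[0.5 * (grads[i][j] + grads[j][i]) for j in range(3)] for i in range(3)]
    O = [[0.5 * (grads[i][j] - grads[j][i]) for j in range(3)] for i in range(3)]
    return S, O


def _realizable_cmu(S, O, k, eps):
    SS = sum(S[i][j] * S[i][j] for i in range(3) for j in range(3))
    OO = sum(O[i][j] * O[i][j] for i in range(3) for j in range(3))
    s_mag = np.sqrt(np.maximum(SS, 0.0))
    u_star = np.sqrt(np.maximum(SS + OO, 0.0))
    # W = S_ij S_jk S_ki / |S|^3, clipped to the arccos domain
    SSS = sum(S[i][j] * S[j][l] * S[l][i]
              for i in range(3) for j in range(3) for l in range(3))
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(s_mag > 1e-12, SSS / np.maximum(s_mag, 1e-12) ** 3, 0.0)
    phi = np.arccos(np.clip(np.sqrt(6.0) * W, -1.0, 1.0)) / 3.0
    A_s = np.sqrt(6.0) * np.cos(phi)
    cmu = 1.0 / (A0 + A_s * k * u_star / np.maximum(eps, EPS_FLOOR))
    return cmu, s_mag


def _wall_distance(grid: VoxelGrid) -> np.ndarray:
    d = grid._cache.get("wall_distance")
    if d is None:
        from scipy.ndimage import distance_transform_edt
        d = distance_transform_edt(grid.fluid) * grid.spacing
        grid._cache["wall_distance"] = d
    return d


def _intermittency(grid: VoxelGrid, fld, nu: float) -> np.ndarray:
    """Laminar-suppression factor in [0, 1] from the local Reynolds number."""
    from .voxel import cell_speeds
    speed = cell_speeds(grid, fld.u, fld.v, fld.w)
    re_loc = speed * _wall_distance(grid) / nu
    return np.clip((re_loc - RE_LAMINAR) / (RE_TURBULENT - RE_LAMINAR), 0.0, 1.0)


def eddy_viscosity(grid: VoxelGrid, fld, nu: float = 4e-6) -> np.ndarray:
    """Cell-centred turbulent kinematic viscosity nu_t (m^2/s), including
    the laminar suppression factor."""
    if fld.k is None or fld.eps is None:
        return np.zeros(grid.shape)
    S, O = _strain_rotation(grid, fld)
    cmu, _ = _realizable_cmu(S, O, fld.k, fld.eps)
    nut = cmu * fld.k ** 2 / np.maximum(fld.eps, EPS_FLOOR)
    nut = nut * _intermittency(grid, fld, nu)
    return np.where(grid.fluid, nut, 0.0)


def _upwind_convect(phi, comps, grid, dx):
    """First-order upwind convective tendency -(v . grad phi) at cells."""
    tend = np.zeros_like(phi)
    for ax, c in enumerate(comps):
        sl_c = [slice(None)] * 3
        sl_p = [slice(None)] * 3
        sl_m = [slice(None)] * 3
        sl_c[ax] = slice(1, -1)
        sl_p[ax] = slice(2, None)
        sl_m[ax] = slice(0, -2)
        d_up = (phi[tuple(sl_c)] - phi[tuple(sl_m)]) / dx
        d_dn = (phi[tuple(sl_p)] - phi[tuple(sl_c)]) / dx
        cc = c[tuple(sl_c)]
        tend[tuple(sl_c)] -= np.where(cc > 0, cc * d_up, cc * d_dn)
    return tend


def _diffuse(phi, nu_eff, fluid, dx):
    """div(nu_eff grad phi) with zero-flux walls (solid neighbours skipped)."""
    tend = np.zeros_like(phi)
    for ax in range(3):
        for shift in (1, -1):
            nb = np.roll(phi, -shift, axis=ax)
            nb_fluid = np.roll(fluid, -shift, axis=ax)
            sl = [slice(None)] * 3
            sl[ax] = -1 if shift == 1 else 0
            nb_fluid = nb_fluid.copy()
            nb_fluid[tuple(sl)] = False
            nu_face = 0.5 * (nu_eff + np.roll(nu_eff, -shift, axis=ax))
            tend += np.where(fluid & nb_fluid, nu_face * (nb - phi) / dx ** 2, 0.0)
    return tend


def turbulence_step(fld, grid: VoxelGrid, props, cfg):
    """One explicit transport update of (k, epsilon).

    Returns the updated arrays; raises if either scalar turns non-finite.
    Positivity floors are applied after the update.
    """
    if fld.k is None or fld.eps is None:
        raise ValueError("field carries no turbulence scalars; initialise "
                         "FlowField.at_rest(grid, turbulence=True)")
    k = fld.k
    eps = fld.eps
    if not (np.isfinite(k).all() and np.isfinite(eps).all()):
        raise FloatingPointError("non-finite k or epsilon before the update")
    nu = props.viscosity / props.density
    dx = grid.spacing
    dt = cfg.dt
    comps = _cell_velocity(grid, fld)

    S, O = _strain_rotation(grid, fld)
    cmu, s_mag = _realizable_cmu(S, O, k, eps)
    nut = np.clip(cmu * k ** 2 / np.maximum(eps, EPS_FLOOR), 0.0, NUT_MAX_RATIO * nu)
    nut = nut * _intermittency(grid, fld, nu)
    prod = nut * 2.0 * s_mag ** 2          # P_k = nu_t * 2 S_ij S_ij

    eta = s_mag * k / np.maximum(eps, EPS_FLOOR)
    c1 = np.maximum(0.43, eta / (eta + 5.0))

    dk = (_upwind_convect(k, comps, grid, dx)
          + _diffuse(k, nu + nut / SIGMA_K, grid.fluid, dx)
          + prod - eps)
    deps = (_upwind_convect(eps, comps, grid, dx)
            + _diffuse(eps, nu + nut / SIGMA_EPS, grid.fluid, dx)
            + c1 * s_mag * eps
            - C2 * eps ** 2 / (k + np.sqrt(nu * np.maximum(eps, EPS_FLOOR))))

    # limit the sink terms so an explicit step cannot overshoot below zero
    k_new = np.maximum(k + dt * dk, K_FLOOR)
    eps_new = np.maximum(eps + dt * deps, EPS_FLOOR)
    k_new = np.where(grid.fluid, k_new, K_FLOOR)
    eps_new = np.where(grid.fluid, eps_new, EPS_FLOOR)
    if not (np.isfinite(k_new).all() and np.isfinite(eps_new).all()):
        raise FloatingPointError("non-finite k or epsilon after the update")
    return k_new, eps_new
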