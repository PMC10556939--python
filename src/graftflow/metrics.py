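"""Flow-stagnation statistics.

Stagnation is quantified as the *low-velocity volume* (LVV): the fluid volume
in which the speed is at or below a threshold (default 0.03 m/s), a proxy for
blood-flow stasis and hence thrombosis risk in reattached segmental arteries.
Companion statistics are the low-velocity *area* on a plane section at the
systolic snapshot instant and the time-integrated flow volume delivered
through each outlet.

Speeds are evaluated at cell centres by averaging the two opposing face
velocities per component; the threshold comparison is inclusive (<=).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .units import m2_to_mm2, m3_to_ml, mm_to_m
from .voxel import VoxelGrid, cell_speeds

__all__ = ["StagnationSeries", "low_velocity_volume", "low_velocity_area",
           "outlet_flow_volume", "region_volume_ml", "region_mask"]


def region_mask(grid: VoxelGrid, region) -> np.ndarray:
    """Resolve a region selector to a boolean cell mask."""
    if isinstance(region, np.ndarray):
        m = region & grid.fluid
    elif region == "whole_fluid":
        m = grid.fluid
    elif region == "analysis_region":
        m = grid.analysis_mask
    else:
        raise ValueError(f"unknown region {region!r}; use 'analysis_region', "
                         "'whole_fluid' or a boolean cell mask")
    if not m.any():
        raise ValueError(f"region {region!r} contains no fluid cells")
    return m


def region_volume_ml(grid: VoxelGrid, region) -> float:
    return m3_to_ml(int(region_mask(grid, region).sum()) * grid.cell_volume
                    ) * grid.symmetry_factor


def low_velocity_volume(fld, grid: VoxelGrid, region="analysis_region",
                        threshold: float = 0.03) -> float:
    """Fluid volume (mL) in ``region`` with cell-centred speed <= threshold."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    m = region_mask(grid, region)
    speed = cell_speeds(grid, fld.u, fld.v, fld.w)
    n = int(np.count_nonzero((speed <= threshold) & m))
    return m3_to_ml(n * grid.cell_volume) * grid.symmetry_factor


def low_velocity_area(fld, grid: VoxelGrid, plane=("z", 0.0),
                      threshold: float = 0.03) -> float:
    """Low-velocity area (mm^2) on an axis-aligned plane section.

    ``plane`` is ``(axis, coordinate_mm)``; the default mid-sagittal plane
    z = 0 contains both the trunk axis and the branch axis.  Speed is
    linearly interpolated between the two cell layers straddling the plane.
    """
    axis = {"x": 0, "y": 1, "z": 2}[plane[0]] if isinstance(plane[0], str) else plane[0]
    coord = mm_to_m(plane[1])
    frac = (coord - grid.origin[axis]) / grid.spacing - 0.5
    if frac < -0.5 or frac > grid.shape[axis] - 0.5:
        raise ValueError(f"plane {plane} lies outside the grid")
    j0 = int(np.clip(np.floor(frac), 0, grid.shape[axis] - 1))
    j1 = int(np.clip(j0 + 1, 0, grid.shape[axis] - 1))
    wgt = float(np.clip(frac - j0, 0.0, 1.0))
    speed = cell_speeds(grid, fld.u, fld.v, fld.w)
    sl0 = [slice(None)] * 3
    sl0[axis] = j0
    sl1 = [slice(None)] * 3
    sl1[axis] = j1
    f0, f1 = grid.fluid[tuple(sl0)], grid.fluid[tuple(sl1)]
    s0, s1 = speed[tuple(sl0)], speed[tuple(sl1)]
    both = f0 & f1
    s = np.where(both, (1 - wgt) * s0 + wgt * s1, np.where(f0, s0, s1))
    in_fluid = f0 | f1
    if not in_fluid.any():
        raise ValueError(f"plane {plane} does not intersect the fluid region")
    n = int(np.count_nonzero((s <= threshold) & in_fluid))
    # a section ON the mirror plane already shows the full cross-section;
    # any other section only covers the represented half
    factor = 1.0 if (grid.symmetry_z and axis == 2) else grid.symmetry_factor
    return m2_to_mm2(n * grid.face_area) * factor


def outlet_flow_volume(fields, grid: VoxelGrid, outlet: str,
                       window: Optional[tuple] = None) -> float:
    """Time-integrated volumetric outflow (mL) through one tagged outlet.

    ``fields`` is either a :class:`StagnationSeries` (uses its recorded
    fluxes) or a sequence of FlowField states; the flux curve is integrated
    with the trapezoidal rule over ``window`` (defaults to the full span).
    """
    if isinstance(fields, StagnationSeries):
        return fields.outlet_volume(outlet, window)
    from .solver import boundary_fluxes
    if outlet not in grid.outlet_labels and outlet != "inlet":
        raise KeyError(f"unknown outlet {outlet!r}; grid has {grid.outlet_labels}")
    times = np.array([f.t for f in fields])
    flux = np.array([boundary_fluxes(grid, f)[outlet] for f in fields])  # m^3/s
    t0, t1 = (times[0], times[-1]) if window is None else window
    if t0 < times[0] - 1e-12 or t1 > times[-1] + 1e-12:
        raise ValueError(f"window {window} outside simulated span "
                         f"[{times[0]}, {times[-1]}]")
    m = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
    return m3_to_ml(float(np.trapezoid(flux[m], times[m])))


@dataclass
class StagnationSeries:
    """Per-time-step stagnation record of one transient solve.

    ``low_velocity_volume`` is the LVV restricted to the analysis region
    (branch + segmental artery); ``low_velocity_volume_whole`` covers the
    whole fluid domain.  Fluxes are in mL/s, positive out of the domain.
    ``mass_imbalance``, ``max_divergence`` and ``courant`` are solver
    diagnostics recorded at every accepted step.
    """
    times: np.ndarray
    low_velocity_volume: np.ndarray          # mL, analysis region
    low_velocity_volume_whole: np.ndarray    # mL, whole fluid
    threshold: float
    region: str
    region_volume_ml: float
    plane_area_snapshots: list               # (time, plane id, area mm^2)
    outlet_flux_ml_s: dict                   # label -> mL/s array
    mass_imbalance: np.ndarray
    max_divergence: np.ndarray
    courant: np.ndarray

    def lvv(self, region: str = "analysis_region") -> np.ndarray:
        if region == "analysis_region":
            return self.low_velocity_volume
        if region == "whole_fluid":
            return self.low_velocity_volume_whole
        raise ValueError(f"unknown region {region!r}")

    def _window_mask(self, window):
        if window is None:
            return np.ones_like(self.times, dtype=bool)
        t0, t1 = window
        return (self.times >= t0 - 1e-12) & (self.times <= t1 + 1e-12)

    def time_averaged_lvv(self, region: str = "analysis_region",
                          window: Optional[tuple] = None) -> float:
        """Trapezoidal time average of the LVV (mL) over ``window``."""
        m = self._window_mask(window)
        t = self.times[m]
        y = self.lvv(region)[m]
        if t.size < 2:
            return float(y[0])
        return float(np.trapezoid(y, t) / (t[-1] - t[0]))

    def outlet_volume(self, label: str, window: Optional[tuple] = None) -> float:
        """Time-integrated outflow (mL) through one outlet."""
        if label not in self.outlet_flux_ml_s:
            raise KeyError(f"unknown outlet {label!r}; series has "
                           f"{sorted(self.outlet_flux_ml_s)}")
        m = self._window_mask(window)
        return float(np.trapezoid(self.outlet_flux_ml_s[label][m], self.times[m]))

    def segmental_outflow_ml(self, window: Optional[tuple] = None) -> float:
        """Total outflow (mL) through all segmental-artery outlets."""
        labs = [l for l in self.outlet_flux_ml_s if l.startswith("segmental")]
        return sum(self.outlet_volume(l, window) for l in labs)

    def snapshot_lvv(self, t_snap: float, region: str = "analysis_region") -> float:
        i = int(np.argmin(np.abs(self.times - t_snap)))
        return float(self.lvv(region)[i])

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_s": self.times,
                "low_velocity_volume_mL": self.low_velocity_volume,
                "low_velocity_volume_whole_mL": self.low_velocity_volume_whole,
                "mass_imbalance": self.mass_imbalance,
                "max_divergence_per_s": self.max_divergence,
                "courant": self.courant}
        for lab, q in self.outlet_flux_ml_s.items():
            cols[f"flux_{lab}_mL_s"] = q
        return pd.DataFrame(cols)
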