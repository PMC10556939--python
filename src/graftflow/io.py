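"""Config files and inspection exports.

Design specs and solver configs round-trip through YAML.  Geometry and
fields export as legacy-ASCII VTK STRUCTURED_POINTS (loadable by ParaView)
and ASCII STL surface triangulations; metric series as CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .geometry import DesignSpec, GeometryModel, PulseWaveform
from .metrics import StagnationSeries
from .solver import SolverConfig
from .voxel import VoxelGrid, cell_speeds

__all__ = ["save_design_spec", "load_design_spec", "save_solver_config",
           "load_solver_config", "write_vtk_cells", "export_stl",
           "write_series_csv", "write_manifest"]


def save_design_spec(spec: DesignSpec, path, waveform: PulseWaveform = None):
    doc = {"design": asdict(spec)}
    if waveform is not None:
        doc["waveform"] = asdict(waveform)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_design_spec(path):
    doc = yaml.safe_load(Path(path).read_text())
    spec = DesignSpec(**doc["design"])
    waveform = PulseWaveform(**doc["waveform"]) if "waveform" in doc else None
    return (spec, waveform) if waveform is not None else spec


def save_solver_config(cfg: SolverConfig, path):
    d = asdict(cfg)
    d["under_relaxation"] = list(d["under_relaxation"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_solver_config(path) -> SolverConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "under_relaxation" in d:
        d["under_relaxation"] = tuple(d["under_relaxation"])
    return SolverConfig(**d)


def write_vtk_cells(grid: VoxelGrid, fields: dict, path):
    """Legacy-ASCII VTK STRUCTURED_POINTS file with cell-centred scalars.

    ``fields`` maps names to (nx, ny, nz) arrays; the fluid mask is always
    included.  Coordinates are in mm for easy inspection.
    """
    nx, ny, nz = grid.shape
    dx = grid.spacing_mm
    lines = ["# vtk DataFile Version 3.0", "graftflow voxel export", "ASCII",
             "DATASET STRUCTURED_POINTS",
             f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
             f"ORIGIN {grid.origin[0]*1e3:.6g} {grid.origin[1]*1e3:.6g} "
             f"{grid.origin[2]*1e3:.6g}",
             f"SPACING {dx:.6g} {dx:.6g} {dx:.6g}",
             f"CELL_DATA {nx * ny * nz}"]
    out = {"fluid": grid.fluid.astype(float), **fields}
    for name, arr in out.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        flat = np.asarray(arr, float).transpose(2, 1, 0).ravel()
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    Path(path).write_text("\n".join(lines) + "\n")


def write_speed_vtk(grid: VoxelGrid, fld, path, threshold: float = 0.03):
    """Cell speed plus a below-threshold stagnation indicator."""
    speed = cell_speeds(grid, fld.u, fld.v, fld.w)
    stag = ((speed <= threshold) & grid.fluid).astype(float)
    write_vtk_cells(grid, {"speed_m_s": np.where(grid.fluid, speed, 0.0),
                           "stagnant": stag, "pressure_pa":
                           np.where(grid.fluid, fld.p, 0.0)}, path)


def export_stl(model: GeometryModel, path, resolution: float = 1.0):
    """Triangulate the sdf=0 isosurface (marching cubes) to ASCII STL.

    ``resolution`` in mm.  Intended for visual inspection of the designs.
    """
    from skimage.measure import marching_cubes

    lo, hi = model.bounding_box
    counts = np.maximum(np.ceil((hi - lo) / resolution).astype(int) + 3, 2)
    axes = [lo[a] - resolution + np.arange(counts[a]) * resolution for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    vol = model.sdf(pts).reshape(xx.shape)
    verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=(resolution,) * 3)
    verts = verts + np.array([axes[0][0], axes[1][0], axes[2][0]])
    with open(path, "w") as fh:
        fh.write("solid graftflow\n")
        for tri in faces:
            a, b, c = verts[tri]
            n = np.cross(b - a, c - a)
            nn = np.linalg.norm(n)
            n = n / nn if nn > 0 else n
            fh.write(f" facet normal {n[0]:.6g} {n[1]:.6g} {n[2]:.6g}\n"
                     "  outer loop\n")
            for v in (a, b, c):
                fh.write(f"   vertex {v[0]:.6g} {v[1]:.6g} {v[2]:.6g}\n")
            fh.write("  endloop\n endfacet\n")
        fh.write("endsolid graftflow\n")


def write_series_csv(series: StagnationSeries, path):
    series.to_dataframe().to_csv(path, index=False)


def write_manifest(table, path):
    """Run manifest: provenance hashes and the ranking, as JSON."""
    doc = {"provenance": table.provenance, "ranking": table.ranking,
           "table_hash": table.table_hash()}
    Path(path).write_text(json.dumps(doc, indent=2, default=str))
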