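"""Minimal legacy-VTK ASCII writers for meshes, lattices and flow fields.

Legacy VTK is a simple line-oriented text format readable by ParaView and
VTK without any binding library.  Two dataset types are emitted here:
POLYDATA for triangulated lumen surfaces (with optional per-vertex scalar
arrays such as WSS or region codes) and STRUCTURED_POINTS for voxel
lattices (site types, regions, velocity magnitude, shear rate, pressure).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .hemodynamics import FlowResult
from .reconstruction import LatticeDomain, LumenMesh


def _header(title: str, dataset: str) -> list[str]:
    return ["# vtk DataFile Version 3.0", title, "ASCII", f"DATASET {dataset}"]


def write_polydata(
    path: str | Path,
    vertices: np.ndarray,
    triangles: np.ndarray,
    point_scalars: dict[str, np.ndarray] | None = None,
    title: str = "maflow surface",
) -> Path:
    """Write a triangle mesh with optional per-vertex scalar arrays."""
    path = Path(path)
    lines = _header(title, "POLYDATA")
    lines.append(f"POINTS {len(vertices)} float")
    lines.extend(" ".join(f"{v:.6g}" for v in p) for p in vertices)
    lines.append(f"POLYGONS {len(triangles)} {4 * len(triangles)}")
    lines.extend(f"3 {a} {b} {c}" for a, b, c in triangles)
    if point_scalars:
        lines.append(f"POINT_DATA {len(vertices)}")
        for name, values in point_scalars.items():
            values = np.asarray(values, dtype=float)
            if len(values) != len(vertices):
                raise ValueError(f"scalar {name!r} length mismatch")
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.6g}" for v in values)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_mesh(path: str | Path, mesh: LumenMesh) -> Path:
    """Lumen surface with region and clot flags per vertex."""
    region_code = {"body": 1.0, "vessel_in": 2.0, "vessel_out": 3.0}
    scalars = {
        "region": np.array([region_code.get(r, 0.0) for r in mesh.region_per_vertex()]),
        "clot": mesh.clot_per_vertex().astype(float),
    }
    return write_polydata(path, mesh.vertices, mesh.triangles, scalars)


def write_imagedata(
    path: str | Path,
    origin: np.ndarray,
    spacing: float,
    arrays: dict[str, np.ndarray],
    title: str = "maflow lattice",
) -> Path:
    """Write dense per-voxel scalar arrays on a uniform grid.

    All arrays must share one (nx, ny, nz) shape; values are emitted in
    VTK's x-fastest order.
    """
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError("all arrays must share one shape")
    nx, ny, nz = shapes.pop()
    path = Path(path)
    lines = _header(title, "STRUCTURED_POINTS")
    lines.append(f"DIMENSIONS {nx} {ny} {nz}")
    lines.append(f"ORIGIN {origin[0]:.6g} {origin[1]:.6g} {origin[2]:.6g}")
    lines.append(f"SPACING {spacing:.6g} {spacing:.6g} {spacing:.6g}")
    lines.append(f"POINT_DATA {nx * ny * nz}")
    for name, values in arrays.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        flat = np.asarray(values, dtype=float).transpose(2, 1, 0).ravel()
        lines.extend(f"{v:.6g}" for v in flat)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_flow(path: str | Path, f: FlowResult, dom: LatticeDomain) -> Path:
    """Velocity magnitude, pressure, shear rate and site labels per voxel."""
    speed = np.linalg.norm(f.velocity, axis=1)
    arrays = {
        "speed_mm_s": f.grid(speed),
        "pressure_pa": f.grid(f.pressure),
        "shear_rate_s": f.grid(f.shear_rate),
        "site_type": dom.site_type.astype(float),
        "region": dom.region.astype(float),
        "clot": dom.clot.astype(float),
    }
    return write_imagedata(path, dom.origin, dom.spacing, arrays)
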