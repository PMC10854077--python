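"""Minimal legacy-ASCII VTK writers for inspection of fields.

Covers exactly what the pipeline emits: cell-labelled image data (the voxel
domain, solid scalar fields) and point clouds with scalars (interface FSS).
Legacy ASCII keeps the artifacts text-only and viewable in ParaView.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_image_data", "write_point_cloud"]


def write_image_data(path, cell_fields: dict, shape, pitch_um: float,
                     origin_um=(0.0, 0.0, 0.0)) -> None:
    """Write per-cell scalar fields on a uniform voxel grid.

    ``cell_fields`` maps name -> array of shape ``shape`` (x, y, z order).
    """
    nx, ny, nz = shape
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nmarrowflow field\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        f.write(f"ORIGIN {origin_um[0]} {origin_um[1]} {origin_um[2]}\n")
        f.write(f"SPACING {pitch_um} {pitch_um} {pitch_um}\n")
        f.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, arr in cell_fields.items():
            a = np.asarray(arr)
            if a.shape != tuple(shape):
                raise ValueError(f"field {name!r} has shape {a.shape}, "
                                 f"expected {tuple(shape)}")
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK expects x fastest
            flat = a.transpose(2, 1, 0).ravel()
            np.savetxt(f, flat[:, None], fmt="%.6g")


def write_point_cloud(path, points_um: np.ndarray, scalars: dict) -> None:
    """Write a point cloud (e.g. wall-face centers) with scalar attributes."""
    pts = np.asarray(points_um, dtype=float)
    n = len(pts)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nmarrowflow interface\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {n} float\n")
        np.savetxt(f, pts, fmt="%.6g")
        f.write(f"VERTICES {n} {2 * n}\n")
        np.savetxt(f, np.column_stack([np.ones(n, int), np.arange(n)]), fmt="%d")
        f.write(f"POINT_DATA {n}\n")
        for name, arr in scalars.items():
            a = np.asarray(arr, dtype=float).ravel()
            if len(a) != n:
                raise ValueError(f"scalar {name!r} length {len(a)} != {n}")
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, a[:, None], fmt="%.6g")
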