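"""Minimal legacy-VTK (ASCII STRUCTURED_POINTS) output for voxel fields."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_structured_points"]


def write_structured_points(path, fields: dict[str, np.ndarray],
                            spacing: float, origin=(0.0, 0.0, 0.0),
                            title: str = "mitoros field") -> None:
    """Write one or more scalar voxel fields to a legacy VTK file.

    All fields must share one (nx, ny, nz) shape; values are written as
    point data in Fortran order (x fastest), as the legacy format expects.
    """
    fields = {k: np.asarray(v) for k, v in fields.items()}
    shapes = {v.shape for v in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one shape")
    (nx, ny, nz), = shapes
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {spacing} {spacing} {spacing}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, data in fields.items():
            kind = "int" if np.issubdtype(data.dtype, np.integer) else "float"
            fh.write(f"SCALARS {name} {kind} 1\n")
            fh.write("LOOKUP_TABLE default\n")
            flat = data.transpose(2, 1, 0).ravel()
            for start in range(0, flat.size, 9):
                chunk = flat[start:start + 9]
                fh.write(" ".join(f"{v:.6g}" for v in chunk) + "\n")
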