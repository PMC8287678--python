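"""Minimal legacy-ASCII VTK polydata reader/writer.

Covers exactly the dialect this package emits: POINTS, POLYGONS (triangles),
and POINT_DATA carried as SCALARS (one component) or VECTORS (three).  Enough
for exchanging annotated wall surfaces with ParaView-style viewers; not a
general VTK parser.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_vtk_polydata", "read_vtk_polydata"]


def write_vtk_polydata(path: str | Path, vertices: np.ndarray, triangles: np.ndarray,
                       point_data: dict[str, np.ndarray] | None = None) -> None:
    vertices = np.asarray(vertices, float)
    triangles = np.asarray(triangles, np.int64)
    lines = [
        "# vtk DataFile Version 3.0",
        "apexshear surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(vertices)} double",
    ]
    lines += [" ".join(f"{x:.17g}" for x in v) for v in vertices]
    lines.append(f"POLYGONS {len(triangles)} {4 * len(triangles)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in triangles]
    if point_data:
        lines.append(f"POINT_DATA {len(vertices)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{x:.17g}" for x in arr]
            elif arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{x:.17g}" for x in row) for row in arr]
            else:
                raise ValueError(f"point-data array {name!r} must be (n,) or (n, 3)")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path: str | Path):
    """Returns ``(vertices, triangles, point_data)``; errors on non-triangles."""
    tokens = Path(path).read_text().split("\n")
    it = iter([t for t in tokens if t.strip() and not t.startswith("#")])
    verts = tris = None
    point_data: dict[str, np.ndarray] = {}
    n_points = 0
    line = next(it, None)
    while line is not None:
        parts = line.split()
        key = parts[0].upper()
        if key == "POINTS":
            n_points = int(parts[1])
            vals = []
            while len(vals) < 3 * n_points:
                vals.extend(float(x) for x in next(it).split())
            verts = np.array(vals).reshape(n_points, 3)
        elif key == "POLYGONS":
            n_poly = int(parts[1])
            rows = []
            for _ in range(n_poly):
                row = [int(x) for x in next(it).split()]
                if row[0] != 3:
                    raise ValueError("non-triangular polygon in VTK file")
                rows.append(row[1:4])
            tris = np.array(rows, dtype=np.int64)
        elif key == "POINT_DATA":
            n_points = int(parts[1])
        elif key == "SCALARS":
            name = parts[1]
            next(it)  # LOOKUP_TABLE line
            vals = []
            while len(vals) < n_points:
                vals.extend(float(x) for x in next(it).split())
            point_data[name] = np.array(vals)
        elif key == "VECTORS":
            name = parts[1]
            vals = []
            while len(vals) < 3 * n_points:
                vals.extend(float(x) for x in next(it).split())
            point_data[name] = np.array(vals).reshape(n_points, 3)
        line = next(it, None)
    if verts is None or tris is None:
        raise ValueError("not a polydata VTK file (missing POINTS or POLYGONS)")
    return verts, tris, point_data
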