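"""Triangulated vessel-wall surfaces and the mesh operators the wall metrics need.

Coordinates are millimetres throughout; stresses attached to meshes are
pascals, so tangential stress gradients come out natively in Pa/mm.

The module provides

* :class:`SurfaceMesh` — a validated triangle mesh with optional apex vertex
  and per-vertex branch labels (``trunk`` / ``branch1`` / ``branch2``),
* one-third-area vertex weights (:func:`vertex_areas`),
* geodesic / euclidean apex-patch extraction (:func:`extract_apex_patch`),
* a one-ring least-squares tangent-plane gradient
  (:func:`tangent_gradient_field`), exact for affine fields on flat meshes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from . import vtk_io

__all__ = [
    "SurfaceMesh",
    "ApexPatch",
    "MeshError",
    "load_surface_mesh",
    "save_surface_mesh",
    "vertex_areas",
    "triangle_areas",
    "extract_apex_patch",
    "geodesic_distances",
    "vertex_adjacency",
    "tangent_gradient",
    "tangent_gradient_field",
]

#: triangles below this area (mm^2) are considered degenerate and rejected
DEGENERATE_AREA = 1e-12

BRANCH_LABELS = ("trunk", "branch1", "branch2")


class MeshError(ValueError):
    """Raised for invalid or unusable surface meshes."""


@dataclass
class SurfaceMesh:
    """A triangulated vessel-wall surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    triangles : (m, 3) int array of vertex indices
    vertex_normals : (n, 3) unit vectors; computed (area-weighted) if omitted
    apex_vertex : index of the bifurcation apex (flow divider), optional
    branch_labels : (n,) array of ``trunk``/``branch1``/``branch2``, optional
    """

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_normals: np.ndarray | None = None
    apex_vertex: int | None = None
    branch_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be an (m, 3) array; non-triangular cells are not supported")
        if len(self.triangles) == 0:
            raise MeshError("empty mesh: no triangles")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
            raise MeshError("triangle references an invalid vertex index")
        areas = triangle_areas(self)
        if np.any(areas <= DEGENERATE_AREA):
            raise MeshError(
                f"{int(np.sum(areas <= DEGENERATE_AREA))} degenerate triangles "
                f"(area <= {DEGENERATE_AREA} mm^2); repair or drop them at load time"
            )
        if self.vertex_normals is None:
            self.vertex_normals = _area_weighted_vertex_normals(self.vertices, self.triangles)
        else:
            self.vertex_normals = np.asarray(self.vertex_normals, dtype=float)
            norms = np.linalg.norm(self.vertex_normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise MeshError("vertex normals must be unit length")
        if self.apex_vertex is not None:
            self.apex_vertex = int(self.apex_vertex)
            if not 0 <= self.apex_vertex < len(self.vertices):
                raise MeshError("apex_vertex index out of range")
        if self.branch_labels is not None:
            self.branch_labels = np.asarray(self.branch_labels)
            if self.branch_labels.shape != (len(self.vertices),):
                raise MeshError("branch_labels must be per-vertex")
            bad = set(np.unique(self.branch_labels)) - set(BRANCH_LABELS)
            if bad:
                raise MeshError(f"unknown branch labels: {sorted(bad)}")
        _check_orientation(self.triangles)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def surface_area(self) -> float:
        return float(triangle_areas(self).sum())


@dataclass
class ApexPatch:
    """Vertices within ``radius`` (mm) of the apex under the chosen metric."""

    vertex_indices: np.ndarray
    radius: float
    center: int
    metric: str = "geodesic"
    distances: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertex_indices = np.asarray(self.vertex_indices, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.vertex_indices)

    def __contains__(self, idx: int) -> bool:
        return bool(np.isin(idx, self.vertex_indices))

    def save(self, path: str | Path) -> None:
        """Plain-text vertex list plus a JSON sidecar with the metadata."""
        path = Path(path)
        np.savetxt(path, self.vertex_indices, fmt="%d")
        meta = {"radius_mm": self.radius, "metric": self.metric, "apex_vertex": self.center,
                "n_vertices": int(len(self))}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def _area_weighted_vertex_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    v0, v1, v2 = (vertices[triangles[:, k]] for k in range(3))
    face_n = np.cross(v1 - v0, v2 - v0)  # magnitude = 2 * area
    normals = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(normals, triangles[:, k], face_n)
    lens = np.linalg.norm(normals, axis=1)
    lens[lens == 0] = 1.0
    return normals / lens[:, None]


def _check_orientation(triangles: np.ndarray) -> None:
    """Every interior edge must be traversed once in each direction."""
    edges = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    directed: set[tuple[int, int]] = set()
    for i, j in edges:
        key = (int(i), int(j))
        if key in directed:
            raise MeshError(f"inconsistent orientation or non-manifold edge {key}")
        directed.add(key)


def triangle_areas(mesh: SurfaceMesh) -> np.ndarray:
    v0, v1, v2 = (mesh.vertices[mesh.triangles[:, k]] for k in range(3))
    return 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)


def vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    """One-third of incident triangle area per vertex (mm^2).

    Sums exactly to the total surface area, which makes it the natural
    weight for area-weighted region averages.
    """
    tri_a = triangle_areas(mesh)
    out = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(out, mesh.triangles[:, k], tri_a / 3.0)
    return out


def load_surface_mesh(path: str | Path, fmt: str | None = None,
                      drop_degenerate: bool = True) -> SurfaceMesh:
    """Load an STL / PLY / legacy-VTK polydata surface.

    Non-triangular cells raise ``MeshError("non-triangular ...")``.  Degenerate
    (area <= 1e-12 mm^2) triangles are dropped when ``drop_degenerate`` is set,
    otherwise they abort the load.
    """
    path = Path(path)
    if not path.exists():
        raise MeshError(f"mesh file not found: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "vtk":
        verts, tris, _ = vtk_io.read_vtk_polydata(path)
    elif fmt in ("stl", "ply"):
        if fmt == "ply":
            _reject_non_triangular_ply(path)
        tm = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
        if tm.is_empty or len(tm.faces) == 0:
            raise MeshError(f"empty mesh: {path}")
        if tm.faces.shape[1] != 3:
            raise MeshError("non-triangular cells in mesh file")
        verts, tris = np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64)
    else:
        raise MeshError(f"unsupported mesh format: {fmt!r} (use stl/ply/vtk)")
    if drop_degenerate:
        verts, tris = _drop_degenerate(verts, tris)
    return SurfaceMesh(vertices=verts, triangles=tris)


def _reject_non_triangular_ply(path: Path) -> None:
    """ASCII-PLY face sanity check (trimesh silently triangulates quads)."""
    head = path.read_bytes()[:2048]
    if b"format ascii" not in head:
        return
    text = path.read_text().splitlines()
    try:
        end = text.index("end_header")
    except ValueError:
        return
    n_vert = n_face = 0
    for line in text[:end]:
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_face = int(parts[2])
    for line in text[end + 1 + n_vert : end + 1 + n_vert + n_face]:
        if line.strip() and int(line.split()[0]) != 3:
            raise MeshError("non-triangular face in PLY file")


def _drop_degenerate(verts: np.ndarray, tris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v0, v1, v2 = (verts[tris[:, k]] for k in range(3))
    areas = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
    tris = tris[areas > DEGENERATE_AREA]
    if len(tris) == 0:
        raise MeshError("all triangles degenerate")
    used = np.unique(tris)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return verts[used], remap[tris]


def save_surface_mesh(path: str | Path, mesh: SurfaceMesh,
                      point_data: dict[str, np.ndarray] | None = None,
                      fmt: str | None = None) -> None:
    """Write STL/PLY (geometry only) or legacy VTK polydata with point data."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "vtk":
        vtk_io.write_vtk_polydata(path, mesh.vertices, mesh.triangles, point_data or {})
    elif fmt in ("stl", "ply"):
        if point_data:
            warnings.warn(f"{fmt} cannot carry point data; writing geometry only")
        trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False).export(str(path))
    else:
        raise MeshError(f"unsupported mesh format: {fmt!r}")


# ---------------------------------------------------------------------------
# adjacency, distances, patches


def vertex_adjacency(mesh: SurfaceMesh) -> list[np.ndarray]:
    """One-ring neighbour indices per vertex."""
    nbrs: list[set[int]] = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.triangles:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    return [np.fromiter(sorted(s), dtype=np.int64) for s in nbrs]


def geodesic_distances(mesh: SurfaceMesh, source: int) -> np.ndarray:
    """Edge-graph shortest-path (Dijkstra) distance from ``source``, mm."""
    tris = mesh.triangles
    i = np.concatenate([tris[:, 0], tris[:, 1], tris[:, 2]])
    j = np.concatenate([tris[:, 1], tris[:, 2], tris[:, 0]])
    w = np.linalg.norm(mesh.vertices[i] - mesh.vertices[j], axis=1)
    n = mesh.n_vertices
    g = coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    return dijkstra(g, directed=False, indices=source)


def extract_apex_patch(mesh: SurfaceMesh, apex: int | None = None, radius: float = 5.0,
                       metric: str = "geodesic") -> ApexPatch:
    """All vertices within ``radius`` mm of the apex.

    ``metric="geodesic"`` uses shortest paths along mesh edges (default: a
    straight-line ball could capture the opposite branch wall through space);
    ``"euclidean"`` uses straight-line distance.
    """
    if apex is None:
        apex = mesh.apex_vertex
    if apex is None:
        raise MeshError("no apex vertex given and mesh has none")
    apex = int(apex)
    if not 0 <= apex < mesh.n_vertices:
        raise MeshError("apex index out of range")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if metric == "geodesic":
        d = geodesic_distances(mesh, apex)
    elif metric == "euclidean":
        d = np.linalg.norm(mesh.vertices - mesh.vertices[apex], axis=1)
    else:
        raise ValueError(f"unknown patch metric {metric!r}")
    idx = np.flatnonzero(d <= radius)
    return ApexPatch(vertex_indices=idx, radius=float(radius), center=apex,
                     metric=metric, distances=d[idx])


# ---------------------------------------------------------------------------
# tangent-plane gradients


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(normal, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return t1, t2


def tangent_gradient_field(mesh: SurfaceMesh, fieldvals: np.ndarray,
                           adjacency: list[np.ndarray] | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex tangent-plane gradient of a scalar field (units/mm).

    For each vertex the field differences over its one-ring are fitted, in a
    least-squares sense, by a linear function of the tangent-plane coordinates
    of the edge vectors; the fitted slope, mapped back to 3-space, is the
    gradient.  Exact for fields affine in the tangent coordinates of a flat
    mesh.  Vertices with fewer than two usable (non-collinear, finite-valued)
    neighbours are flagged undefined (NaN gradient, mask False) and must be
    excluded from downstream averages.

    Returns
    -------
    grads : (n, 3) array
    defined : (n,) bool mask
    """
    fieldvals = np.asarray(fieldvals, dtype=float)
    if fieldvals.shape != (mesh.n_vertices,):
        raise ValueError("field must be per-vertex scalar")
    if adjacency is None:
        adjacency = vertex_adjacency(mesh)
    grads = np.full((mesh.n_vertices, 3), np.nan)
    defined = np.zeros(mesh.n_vertices, dtype=bool)
    for v in range(mesh.n_vertices):
        nb = adjacency[v]
        if len(nb) < 2 or not np.isfinite(fieldvals[v]):
            continue
        nb = nb[np.isfinite(fieldvals[nb])]
        if len(nb) < 2:
            continue
        n_hat = mesh.vertex_normals[v]
        t1, t2 = _tangent_basis(n_hat)
        d = mesh.vertices[nb] - mesh.vertices[v]
        A = np.column_stack([d @ t1, d @ t2])
        b = fieldvals[nb] - fieldvals[v]
        # normal equations; rank check via the 2x2 determinant
        AtA = A.T @ A
        det = AtA[0, 0] * AtA[1, 1] - AtA[0, 1] ** 2
        scale = AtA[0, 0] * AtA[1, 1]
        if scale <= 0 or det < 1e-10 * scale:
            continue  # collinear one-ring
        g2 = np.linalg.solve(AtA, A.T @ b)
        grads[v] = g2[0] * t1 + g2[1] * t2
        defined[v] = True
    return grads, defined


def tangent_gradient(mesh: SurfaceMesh, fieldvals: np.ndarray, vertex: int) -> np.ndarray:
    """Tangent-plane gradient at a single vertex; NaN vector if undefined."""
    grads, _ = tangent_gradient_field(mesh, fieldvals)
    return grads[int(vertex)]
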