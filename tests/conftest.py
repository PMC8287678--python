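import numpy as np
import pytest

from apexshear import synthetic_data as sd
from apexshear.geometry import SurfaceMesh
from apexshear.wall_metrics import TimeResolvedWallField


def make_grid_mesh(nx: int = 21, ny: int = 21, spacing: float = 0.5) -> SurfaceMesh:
    """Flat z=0 triangulated grid, consistently oriented (+z normals)."""
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(nx * ny)])
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v10 = (i + 1) * ny + j
            v01 = i * ny + j + 1
            v11 = (i + 1) * ny + j + 1
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    return SurfaceMesh(vertices=verts, triangles=np.array(tris))


def grid_interior_mask(mesh: SurfaceMesh, margin: float = 0.6) -> np.ndarray:
    v = mesh.vertices
    lo = v.min(axis=0) + margin
    hi = v.max(axis=0) - margin
    return np.all((v[:, :2] >= lo[:2]) & (v[:, :2] <= hi[:2]), axis=1)


def constant_direction_field(mesh: SurfaceMesh, magnitudes: np.ndarray,
                             direction=(1.0, 0.0, 0.0), times=None) -> TimeResolvedWallField:
    """Field with fixed direction and per-time magnitudes (same at every vertex)."""
    times = np.linspace(0.0, 1.0, len(magnitudes)) if times is None else np.asarray(times)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    vecs = np.ones((mesh.n_vertices, len(times), 1)) * magnitudes[None, :, None] * d
    return TimeResolvedWallField(mesh=mesh, times=times, vectors=vecs)


@pytest.fixture(scope="session")
def grid_mesh() -> SurfaceMesh:
    return make_grid_mesh()


@pytest.fixture(scope="session")
def bifurcation_mesh() -> SurfaceMesh:
    return sd.make_bifurcation_mesh(edge_length=0.4)
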