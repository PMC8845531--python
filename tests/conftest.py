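import numpy as np
import pytest

from afstress.cohort import generate_fibrosis, generate_mesh
from afstress.geometry import make_sheet


@pytest.fixture(scope="session")
def la_mesh():
    """One default-resolution left-atrial mesh shared across tests."""
    return generate_mesh(1, resolution=2.5)


@pytest.fixture(scope="session")
def la_fibrosis(la_mesh):
    return generate_fibrosis(la_mesh, seed=3, burden=0.3)


@pytest.fixture(scope="session")
def sheet():
    """Small calibration sheet (30 x 10 mm at 1 mm)."""
    return make_sheet(30.0, 10.0, 1.0)


def brute_force_winding(mesh, phi, valid=None):
    """Independent PS oracle: winding numbers from angle-sorted one-rings.

    Orders each interior vertex's neighbours by polar angle in the plane
    perpendicular to the vertex normal (counterclockwise about the
    outward normal), then sums wrapped phase differences. Returns
    {vertex: charge} for |winding| == 1.
    """
    if valid is None:
        valid = np.ones(mesh.n_vertices, dtype=bool)
    neighbours = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.triangles:
        neighbours[a].update((b, c))
        neighbours[b].update((a, c))
        neighbours[c].update((a, b))
    out = {}
    for v in range(mesh.n_vertices):
        if mesh.boundary_vertex_mask[v] or len(neighbours[v]) < 3 or not valid[v]:
            continue
        nb = np.array(sorted(neighbours[v]))
        if not valid[nb].all():
            continue
        n = mesh.triangle_normals[mesh.vertex_triangles[v]].mean(axis=0)
        n /= np.linalg.norm(n)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(ref @ n) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - (ref @ n) * n
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        d = mesh.vertices[nb] - mesh.vertices[v]
        ang = np.arctan2(d @ e2, d @ e1)
        ring = nb[np.argsort(ang)]
        diffs = np.angle(np.exp(1j * np.diff(phi[ring], append=phi[ring[0]])))
        w = int(np.round(diffs.sum() / (2 * np.pi)))
        if abs(w) == 1:
            out[v] = w
    return out
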