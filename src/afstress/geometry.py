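"""Triangulated surface meshes: containers, construction helpers, and queries.

Two mesh families are produced here: left-atrial shells (deformed
ellipsoids with four pulmonary-vein ostia and a mitral orifice, built by
:mod:`afstress.cohort`) and flat rectangular sheets used for conduction
calibration and small-scale tests. Everything downstream (solver,
ablation, metrics) works on the generic :class:`SurfaceMesh`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from functools import cached_property

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra


class Region(IntEnum):
    """Per-triangle anatomical region label."""

    BODY = 0
    PV1 = 1
    PV2 = 2
    PV3 = 3
    PV4 = 4
    MITRAL_RIM = 5


PV_REGIONS = (Region.PV1, Region.PV2, Region.PV3, Region.PV4)


@dataclass
class SurfaceMesh:
    """An oriented triangulated surface with optional anatomical annotation.

    Attributes
    ----------
    vertices : (n, 3) float64 array, positions in mm.
    triangles : (m, 3) int32 array, outward-oriented vertex triples.
    region_label : (m,) int8 array of :class:`Region` values.
    boundary_loops : ordered vertex cycles, one per topological boundary.
    pv_loop_index : for each PV region (PV1..PV4), the index into
        ``boundary_loops`` of its ostium rim; empty for non-atrial meshes.
    pv_distance : (n, 4) geodesic distance (mm) from each vertex to each
        PV ostium rim, or ``None`` for non-atrial meshes.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    region_label: np.ndarray = field(default=None)  # type: ignore[assignment]
    boundary_loops: list = field(default_factory=list)
    pv_loop_index: dict = field(default_factory=dict)
    pv_distance: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int32)
        if self.region_label is None:
            self.region_label = np.zeros(len(self.triangles), dtype=np.int8)

    # -- basic counts -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    # -- derived geometry (cached) ------------------------------------
    @cached_property
    def triangle_areas(self) -> np.ndarray:
        """Triangle areas in mm^2."""
        p = self.vertices[self.triangles]
        cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cr, axis=1)

    @cached_property
    def triangle_normals(self) -> np.ndarray:
        """Unit outward normals (orientation inherited from triangle winding)."""
        p = self.vertices[self.triangles]
        cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return cr / np.linalg.norm(cr, axis=1, keepdims=True)

    @cached_property
    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    @cached_property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (n_edges, 2) int array."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    @cached_property
    def edge_lengths(self) -> np.ndarray:
        d = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    @cached_property
    def vertex_graph(self) -> csr_matrix:
        """Sparse symmetric adjacency weighted by edge length."""
        e, w = self.edges, self.edge_lengths
        i = np.concatenate([e[:, 0], e[:, 1]])
        j = np.concatenate([e[:, 1], e[:, 0]])
        return csr_matrix((np.concatenate([w, w]), (i, j)),
                          shape=(self.n_vertices, self.n_vertices))

    @cached_property
    def vertex_triangles(self) -> list:
        """For each vertex, the indices of incident triangles."""
        lists: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for ti, tri in enumerate(self.triangles):
            for v in tri:
                lists[v].append(ti)
        return [np.asarray(l, dtype=np.int32) for l in lists]

    @cached_property
    def boundary_vertex_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_vertices, dtype=bool)
        for loop in self.boundary_loops:
            mask[loop] = True
        return mask

    @cached_property
    def vertex_region(self) -> np.ndarray:
        """Per-vertex region: a vertex inherits the max label of incident triangles
        (so antrum vertices on the antrum/body border count as antrum)."""
        reg = np.zeros(self.n_vertices, dtype=np.int8)
        for ti, tri in enumerate(self.triangles):
            lab = self.region_label[ti]
            for v in tri:
                reg[v] = max(reg[v], lab)
        return reg

    @cached_property
    def one_rings(self) -> list:
        """Ordered one-ring neighbour cycles for interior vertices.

        Entry ``i`` is an int array of neighbours of vertex ``i`` in the
        cyclic order induced by the outward triangle orientation, or an
        empty array for boundary / non-manifold vertices.
        """
        succ: list[dict] = [dict() for _ in range(self.n_vertices)]
        for a, b, c in self.triangles:
            # triangle (a,b,c) CCW from outside: around a, b precedes c
            succ[a][b] = c
            succ[b][c] = a
            succ[c][a] = b
        rings = []
        empty = np.empty(0, dtype=np.int32)
        for v in range(self.n_vertices):
            s = succ[v]
            if not s:
                rings.append(empty)
                continue
            start = next(iter(s))
            ring = [start]
            cur = s[start]
            ok = True
            while cur != start:
                ring.append(cur)
                cur = s.get(cur, -1)
                if cur == -1 or len(ring) > len(s):
                    ok = False
                    break
            rings.append(np.asarray(ring, dtype=np.int32) if ok and len(ring) == len(s) else empty)
        return rings

    @cached_property
    def one_ring_arrays(self):
        """Flattened one-ring structure for vectorized winding sums:
        (vertex_ids, ring_flat, ring_next_flat, offsets) where segment i
        of ring_flat/[offsets[i]:offsets[i+1]] is the ordered ring of
        vertex_ids[i] and ring_next_flat is the ring rolled by one."""
        ids, flat, nxt, offs = [], [], [], [0]
        for v, ring in enumerate(self.one_rings):
            if len(ring) < 3:
                continue
            ids.append(v)
            flat.append(ring)
            nxt.append(np.roll(ring, -1))
            offs.append(offs[-1] + len(ring))
        return (np.asarray(ids, dtype=np.int32),
                np.concatenate(flat) if flat else np.empty(0, np.int32),
                np.concatenate(nxt) if nxt else np.empty(0, np.int32),
                np.asarray(offs, dtype=np.int64))

    # -- queries -------------------------------------------------------
    def total_area(self) -> float:
        return float(self.triangle_areas.sum())

    def region_area(self, *labels: Region) -> float:
        mask = np.isin(self.region_label, [int(l) for l in labels])
        return float(self.triangle_areas[mask].sum())

    def geodesic_distance(self, sources: np.ndarray) -> np.ndarray:
        """Multi-source Dijkstra distance (mm) over the edge graph."""
        d = dijkstra(self.vertex_graph, directed=False, indices=np.asarray(sources))
        return d.min(axis=0) if d.ndim == 2 else d

    def is_connected(self) -> bool:
        return connected_components(self.vertex_graph, directed=False)[0] == 1


# ---------------------------------------------------------------------------
# Construction helpers
# ---------------------------------------------------------------------------

_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array([
    [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
    [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
    [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
], dtype=float)
_ICO_FACES = np.array([
    [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
    [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
    [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
    [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
], dtype=np.int64)


def icosphere(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere with outward-oriented triangles."""
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
    return verts, faces.astype(np.int32)


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    cache: dict[tuple[int, int], int] = {}
    vlist = list(verts)

    def midpoint(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        idx = cache.get(key)
        if idx is None:
            m = vlist[a] + vlist[b]
            m = m / np.linalg.norm(m)
            idx = len(vlist)
            vlist.append(m)
            cache[key] = idx
        return idx

    out = np.empty((4 * len(faces), 3), dtype=np.int64)
    k = 0
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        out[k] = (a, ab, ca); out[k + 1] = (b, bc, ab)
        out[k + 2] = (c, ca, bc); out[k + 3] = (ab, bc, ca)
        k += 4
    return np.asarray(vlist), out


def make_sheet(lx: float, ly: float, h: float) -> SurfaceMesh:
    """Flat rectangular sheet in the z=0 plane, right-triangle grid.

    ``lx``/``ly`` in mm, ``h`` target edge length. Triangles are oriented
    with +z normals. Used for conduction-velocity calibration and tests.
    """
    nx, ny = max(1, round(lx / h)), max(1, round(ly / h))
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])

    def vid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            v00, v10 = vid(i, j), vid(i + 1, j)
            v01, v11 = vid(i, j + 1), vid(i + 1, j + 1)
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    tris = np.asarray(tris, dtype=np.int32)
    mesh = SurfaceMesh(verts, tris)
    mesh.boundary_loops = find_boundary_loops(tris)
    return mesh


def find_boundary_loops(triangles: np.ndarray) -> list:
    """Ordered boundary vertex cycles (edges used by exactly one triangle)."""
    from collections import Counter

    count: Counter = Counter()
    directed = {}
    for a, b, c in triangles:
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            count[key] += 1
            directed[(u, v)] = None
    succ = {}
    for (u, v) in directed:
        key = (u, v) if u < v else (v, u)
        if count[key] == 1:
            succ[u] = v  # boundary edges keep interior-consistent direction
    loops = []
    seen = set()
    for start in list(succ):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = succ[start]
        while cur != start:
            loop.append(cur)
            seen.add(cur)
            cur = succ.get(cur)
            if cur is None or len(loop) > len(succ):
                raise ValueError("open or non-manifold boundary chain")
        loops.append(np.asarray(loop, dtype=np.int32))
    return loops


def drop_unused_vertices(vertices: np.ndarray, triangles: np.ndarray):
    """Compact vertex array to those referenced by triangles."""
    used = np.unique(triangles)
    remap = -np.ones(len(vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return vertices[used], remap[triangles].astype(np.int32), used


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_la_mesh(mesh: SurfaceMesh) -> None:
    """Check the left-atrial mesh contract; raise ``ValueError`` on violation.

    Requires: 5 boundary loops, positive triangle areas, no duplicate
    vertices, each PV region edge-connected and adjacent to exactly one
    boundary loop.
    """
    if len(mesh.boundary_loops) != 5:
        raise ValueError(f"expected 5 boundary loops, found {len(mesh.boundary_loops)}")
    if not (mesh.triangle_areas > 0).all():
        raise ValueError("degenerate triangle (non-positive area)")
    rounded = np.round(mesh.vertices, 9)
    if len(np.unique(rounded, axis=0)) != mesh.n_vertices:
        raise ValueError("duplicate vertices")
    if not mesh.is_connected():
        raise ValueError("mesh is disconnected")
    for reg in PV_REGIONS:
        tri_idx = np.flatnonzero(mesh.region_label == int(reg))
        if len(tri_idx) == 0:
            raise ValueError(f"region {reg.name} is empty")
        if not _triangles_edge_connected(mesh, tri_idx):
            raise ValueError(f"region {reg.name} not edge-connected")
        touched = _loops_touching(mesh, tri_idx)
        if len(touched) != 1:
            raise ValueError(f"region {reg.name} touches {len(touched)} boundary loops")


def _triangles_edge_connected(mesh: SurfaceMesh, tri_idx: np.ndarray) -> bool:
    sel = set(tri_idx.tolist())
    edge_map: dict[tuple[int, int], list[int]] = {}
    for ti in tri_idx:
        a, b, c = mesh.triangles[ti]
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            edge_map.setdefault(key, []).append(ti)
    adj: dict[int, set] = {int(t): set() for t in tri_idx}
    for tris in edge_map.values():
        if len(tris) == 2:
            adj[int(tris[0])].add(int(tris[1]))
            adj[int(tris[1])].add(int(tris[0]))
    start = int(tri_idx[0])
    stack, seen = [start], {start}
    while stack:
        t = stack.pop()
        for u in adj[t]:
            if u not in seen and u in sel:
                seen.add(u)
                stack.append(u)
    return len(seen) == len(tri_idx)


def _loops_touching(mesh: SurfaceMesh, tri_idx: np.ndarray) -> set:
    verts = set(np.unique(mesh.triangles[tri_idx]).tolist())
    touched = set()
    for li, loop in enumerate(mesh.boundary_loops):
        if verts.intersection(loop.tolist()):
            touched.add(li)
    return touched
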