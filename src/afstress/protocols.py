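"""AF initiation and simulated pulmonary-vein-isolation ablation.

Initiation uses the phase-distribution technique: a target phase field
with prescribed singularities (position + chirality) is written onto the
mesh and converted to model state by sampling a paced single-cell limit
cycle at each vertex's phase. Ablation is a wide-area circumferential
band of no-flux triangles at a fixed geodesic distance from each PV
ostium rim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .ep import SubstrateModel, limit_cycle
from .geometry import PV_REGIONS, Region, SurfaceMesh


# ---------------------------------------------------------------------------
# Initiation maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InitiationMap:
    """Phase-singularity seed descriptors: (vertex, chirality) pairs."""

    seeds: tuple                 # ((vertex_id, +/-1), ...)
    variant: str = "map_A"
    core_radius: float = 5.0     # mm; seeds must be >= 2x this apart

    def __post_init__(self):
        if len(self.seeds) < 1:
            raise ValueError("initiation map needs at least one seed")
        for _, q in self.seeds:
            if q not in (-1, 1):
                raise ValueError("chirality must be +/-1")


#: Axis placement rules per variant: (colatitude deg, azimuth deg) of the
#: positive end of each rotor axis. Each axis contributes a +1 seed at
#: that end and a -1 seed at the antipodal wall point, so the seeded
#: phase field carries exactly the prescribed singularities (an azimuth
#: field on a closed shell necessarily has a +/- pair). map_A spreads
#: two axes over posterior/anterior wall analogues; map_B rotates them;
#: map_C uses three axes (six seeds).
_MAP_RULES = {
    "map_A": [(75, 80), (75, 200)],
    "map_B": [(80, 120), (70, 240)],
    "map_C": [(75, 60), (75, 180), (75, 300)],
}
INITIATION_VARIANTS = tuple(_MAP_RULES)


def make_initiation_map(mesh: SurfaceMesh, variant: str = "map_A",
                        flip_chirality: bool = False) -> InitiationMap:
    """Place a variant's seeds at the nearest body-wall vertices.

    Axis targets are directions on the pre-deformation sphere; each axis
    yields a (+1, -1) seed pair at its two wall intersections, snapped to
    the nearest non-boundary body vertices.
    """
    if variant not in _MAP_RULES:
        raise ValueError(f"unknown initiation map {variant!r}")
    dirs = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    ok = (mesh.vertex_region == int(Region.BODY)) & ~mesh.boundary_vertex_mask
    cand = np.flatnonzero(ok)
    sign = -1 if flip_chirality else 1
    seeds = []
    for colat, azim in _MAP_RULES[variant]:
        th, ph = np.deg2rad(colat), np.deg2rad(azim)
        target = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        v_plus = int(cand[np.argmax(dirs[cand] @ target)])
        v_minus = int(cand[np.argmax(-(dirs[cand] @ dirs[v_plus]))])
        seeds.append((v_plus, sign))
        seeds.append((v_minus, -sign))
    imap = InitiationMap(seeds=tuple(seeds), variant=variant)
    _check_seed_spacing(mesh, imap)
    return imap


def _check_seed_spacing(mesh: SurfaceMesh, imap: InitiationMap) -> None:
    pts = mesh.vertices[[v for v, _ in imap.seeds]]
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.linalg.norm(pts[i] - pts[j]) < 2 * imap.core_radius:
                raise ValueError(
                    f"seeds {i} and {j} closer than 2x core radius "
                    f"({2 * imap.core_radius:.1f} mm)")


def seed_phase_field(mesh: SurfaceMesh, imap: InitiationMap) -> np.ndarray:
    """Target phase field with the map's singularities.

    Seeds come in (+q, -q) axis pairs; each pair contributes the azimuth
    angle about the axis through the positive seed, weighted by its
    chirality. The result wraps to (-pi, pi] and is singular exactly at
    the two wall points pierced by each axis.
    """
    dirs = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    phi = np.zeros(mesh.n_vertices)
    for k in range(0, len(imap.seeds) - 1, 2):
        v_plus, q = imap.seeds[k]
        u = dirs[v_plus]
        ref = np.array([1.0, 0.0, 0.0])
        if abs(ref @ u) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - (ref @ u) * u
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        phi += q * np.arctan2(dirs @ e2, dirs @ e1)
    return np.angle(np.exp(1j * phi))


def seed_phase_distribution(substrate: SubstrateModel, imap: InitiationMap,
                            cycle_length: float = 200.0) -> tuple:
    """Initial (v, h) state containing one phase singularity per seed.

    The per-vertex phase comes from :func:`seed_phase_field`; state
    variables come from a single-cell limit cycle paced at
    ``cycle_length`` ms, sampled at that phase.
    """
    mesh = substrate.mesh
    ablated_verts = np.zeros(mesh.n_vertices, dtype=bool)
    if len(substrate.ablated_triangles):
        ablated_verts[np.unique(mesh.triangles[substrate.ablated_triangles])] = True
    for v, _ in imap.seeds:
        if ablated_verts[v]:
            raise ValueError(f"seed vertex {v} lies in an ablated region")

    phi = seed_phase_field(mesh, imap)

    v_cyc, h_cyc = limit_cycle(substrate.cell, cycle_length)
    pos = ((phi + np.pi) / (2 * np.pi) * len(v_cyc)).astype(np.int64) % len(v_cyc)
    return v_cyc[pos].copy(), h_cyc[pos].copy()


# ---------------------------------------------------------------------------
# PVI lesions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionSet:
    """Circumferential PVI ablation band."""

    triangles: np.ndarray        # ablated triangle indices
    distance: float              # band inner distance from PV rim (mm)
    width: float                 # band width (mm)
    size_variant: str = "baseline"

    def __len__(self):
        return len(self.triangles)


def build_pvi_lesion(mesh: SurfaceMesh, d: float = 5.0, width: float = 6.0,
                     size_variant: str = "baseline") -> LesionSet:
    """Ablate the circumferential band at geodesic distance ``[d, d+width)``
    from the nearest PV ostium rim.

    A triangle joins the band if any of its vertices lies in the distance
    range; this guarantees (for width above the local edge length) that
    every graph path from antrum to body passes through a fully ablated
    vertex. The closed-band contract is still verified explicitly: with
    lesion triangles removed, each PV antrum's vertices must be
    graph-disconnected from the body. Bands of neighbouring PVs may
    merge; that preserves isolation.
    """
    if d <= 0:
        raise ValueError("lesion distance must be positive")
    mean_edge = float(np.mean(mesh.edge_lengths))
    if width < 2 * mean_edge:
        raise ValueError(f"lesion width {width:.1f} mm < 2x edge length "
                         f"({2 * mean_edge:.1f} mm)")
    if mesh.pv_distance is None:
        raise ValueError("mesh has no PV distance field (not an atrial mesh?)")

    vert_dist = mesh.pv_distance.min(axis=1)
    in_range = (vert_dist[mesh.triangles] >= d) & (vert_dist[mesh.triangles] < d + width)
    band = np.flatnonzero(in_range.any(axis=1))
    lesion = LesionSet(triangles=band.astype(np.int64), distance=d,
                       width=width, size_variant=size_variant)
    outer = vert_dist >= d + width  # excludes any enclosed antrum collar
    ok, bad_pv = check_isolation(mesh, lesion.triangles, body_mask=outer)
    if not ok:
        raise ValueError(f"incomplete encirclement of {Region(bad_pv).name}")
    return lesion


def check_isolation(mesh: SurfaceMesh, ablated_triangles: np.ndarray,
                    body_mask: np.ndarray | None = None):
    """Is every PV antrum vertex-disconnected from the body once the
    ablated triangles are removed? Returns (ok, offending_region).

    ``body_mask`` optionally restricts the body side (e.g. to tissue
    outside the lesion band, so an enclosed collar between antrum and
    band does not count as body)."""
    live = np.ones(mesh.n_triangles, dtype=bool)
    live[ablated_triangles] = False
    tris = mesh.triangles[live]
    n = mesh.n_vertices
    if len(tris) == 0:
        return True, None
    e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    graph = csr_matrix((np.ones(2 * len(e)),
                        (np.concatenate([e[:, 0], e[:, 1]]),
                         np.concatenate([e[:, 1], e[:, 0]]))), shape=(n, n))
    _, labels = connected_components(graph, directed=False)

    ablated_verts = np.zeros(n, dtype=bool)
    if len(ablated_triangles):
        all_ab = np.unique(mesh.triangles[ablated_triangles])
        live_verts = np.unique(tris) if len(tris) else np.empty(0, dtype=np.int64)
        ablated_verts[np.setdiff1d(all_ab, live_verts)] = True

    vreg = mesh.vertex_region
    body_sel = (vreg == int(Region.BODY)) & ~ablated_verts
    if body_mask is not None:
        body_sel &= body_mask
    body = np.flatnonzero(body_sel)
    body_labels = set(labels[body].tolist())
    for reg in PV_REGIONS:
        antrum = np.flatnonzero((vreg == int(reg)) & ~ablated_verts)
        if len(antrum) == 0:
            continue
        if body_labels.intersection(labels[antrum].tolist()):
            return False, int(reg)
    return True, None


def inject_gap(lesion: LesionSet, mesh: SurfaceMesh,
               gap_triangle: int | None = None,
               radius: float | None = None) -> LesionSet:
    """Test-only: carve a conducting corridor through the lesion band.

    Removes the lesion triangles within ``radius`` of a mid-band
    triangle's centroid (default: the triangle closest to the band
    midline, radius slightly over the band width), restoring a
    conduction path between antrum and body.
    """
    if len(lesion) == 0:
        raise ValueError("empty lesion")
    h = float(np.mean(mesh.edge_lengths))
    radius = lesion.width + 1.5 * h if radius is None else radius
    if gap_triangle is None:
        td = mesh.pv_distance.min(axis=1)[mesh.triangles[lesion.triangles]].mean(axis=1)
        mid = lesion.distance + 0.5 * lesion.width
        tri = int(lesion.triangles[np.argmin(np.abs(td - mid))])
    else:
        tri = int(gap_triangle)
    c = mesh.triangle_centroids[lesion.triangles]
    keep = np.linalg.norm(c - mesh.triangle_centroids[tri], axis=1) > radius
    return replace(lesion, triangles=lesion.triangles[keep])


def apply_ablation(substrate: SubstrateModel, lesion: LesionSet) -> SubstrateModel:
    """Return a new substrate with the lesion's triangles made no-flux holes.

    The original substrate is untouched; an empty lesion is the identity
    (modulo provenance).
    """
    return substrate.with_ablation(lesion.triangles)


def post_ablation_state(substrate_ablated: SubstrateModel, state: tuple) -> tuple:
    """Reset state inside the ablated region to rest (dead tissue)."""
    mesh = substrate_ablated.mesh
    v, h = np.array(state[0]), np.array(state[1])
    _, active, _ = substrate_ablated.operator()
    v[~active] = 0.0
    h[~active] = 1.0
    return v, h
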