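"""Synthetic virtual-patient cohorts.

Generates everything the downstream pipeline consumes in place of imaging
data: left-atrial surface meshes (deformed ellipsoids with four
pulmonary-vein ostia and a mitral orifice), spatially correlated
image-intensity-ratio (IIR) fibrosis fields with a controllable burden,
rule-based fiber-field variants, history covariates, and binary
recurrence labels drawn from a logistic model with user-supplied
("planted") coefficients.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np

from .geometry import (
    Region,
    SurfaceMesh,
    drop_unused_vertices,
    find_boundary_loops,
    icosphere,
    validate_la_mesh,
)

IIR_THRESHOLD = 1.22  # image-intensity ratio above which tissue counts as fibrotic

AF_TYPES = ("paroxysmal", "persistent", "long_standing_persistent")

#: In-plane rotation (degrees) of each fiber variant relative to the
#: circumferential base rule. The baseline battery uses fiber_A; the two
#: fiber stress-test setups use fiber_B and fiber_C.
FIBER_VARIANTS = {"fiber_A": 0.0, "fiber_B": 60.0, "fiber_C": -60.0}


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeParams:
    """Geometry knobs for the left-atrial shell generator.

    Angles are radians on the unit sphere before ellipsoidal scaling;
    radii/lengths are mm after scaling. Defaults give a shell of
    ~120-180 cm^2 total area.
    """

    radii: tuple = (42.0, 35.0, 28.0)
    pv_azimuth: tuple = (45.0, 115.0, 245.0, 315.0)  # degrees
    pv_colatitude: float = 55.0                       # degrees from +z
    pv_jitter_deg: float = 6.0
    pv_hole_angle: float = 0.17
    mitral_hole_angle: float = 0.34
    antrum_angle: float = 0.15
    mitral_rim_angle: float = 0.12
    bump_amplitude: float = 0.04

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radii))


DEFAULT_SHAPE = ShapeParams()


def generate_mesh(seed: int, resolution: float = 2.5,
                  shape_params: ShapeParams = DEFAULT_SHAPE) -> SurfaceMesh:
    """Build one left-atrial shell mesh.

    Parameters
    ----------
    seed : drives PV-placement jitter and the smooth shape bump.
    resolution : target edge length in mm.
    shape_params : see :class:`ShapeParams`.

    The result satisfies the atrial-mesh contract checked by
    :func:`afstress.geometry.validate_la_mesh` (5 boundary loops, connected
    PV antra each adjacent to exactly one ostium, positive areas) and is
    bitwise deterministic for a given ``(seed, resolution, shape_params)``.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if min(shape_params.radii) <= 2.0 * resolution:
        raise ValueError(
            f"degenerate shape_params: min radius {min(shape_params.radii):.1f} mm "
            f"<= 2 x resolution ({resolution:.1f} mm)")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA17]))
    subdiv = int(np.clip(round(np.log2(1.051 * shape_params.mean_radius / resolution)), 2, 6))

    last_err: Exception | None = None
    for _attempt in range(6):
        try:
            return _try_build(rng, subdiv, shape_params)
        except ValueError as err:  # unlucky jitter: holes merged; re-jitter
            last_err = err
    raise ValueError(f"mesh generation failed after retries: {last_err}")


def _hole_centers(rng, sp: ShapeParams) -> np.ndarray:
    az = np.deg2rad(np.asarray(sp.pv_azimuth) +
                    rng.uniform(-sp.pv_jitter_deg, sp.pv_jitter_deg, 4))
    co = np.deg2rad(sp.pv_colatitude +
                    rng.uniform(-0.6 * sp.pv_jitter_deg, 0.6 * sp.pv_jitter_deg, 4))
    pv = np.column_stack([np.sin(co) * np.cos(az), np.sin(co) * np.sin(az), np.cos(co)])
    mitral = np.array([[0.0, 0.0, -1.0]])
    return np.vstack([pv, mitral])


def _try_build(rng, subdiv: int, sp: ShapeParams) -> SurfaceMesh:
    verts_u, tris = icosphere(subdiv)
    centers = _hole_centers(rng, sp)  # rows 0-3 PVs, row 4 mitral
    hole_angles = np.array([sp.pv_hole_angle] * 4 + [sp.mitral_hole_angle])

    cen_dirs = verts_u[tris].mean(axis=1)
    cen_dirs /= np.linalg.norm(cen_dirs, axis=1, keepdims=True)
    ang = np.arccos(np.clip(cen_dirs @ centers.T, -1.0, 1.0))  # (m, 5)

    keep = (ang > hole_angles[None, :]).all(axis=1)
    tris_kept = tris[keep]
    ang_kept = ang[keep]

    # region labels from angular distance to hole centers
    labels = np.zeros(len(tris_kept), dtype=np.int8)
    in_antrum = ang_kept[:, :4] <= (sp.pv_hole_angle + sp.antrum_angle)
    nearest_pv = np.argmin(ang_kept[:, :4], axis=1)
    pv_hit = in_antrum.any(axis=1)
    labels[pv_hit] = (nearest_pv[pv_hit] + int(Region.PV1)).astype(np.int8)
    rim = (~pv_hit) & (ang_kept[:, 4] <= sp.mitral_hole_angle + sp.mitral_rim_angle)
    labels[rim] = int(Region.MITRAL_RIM)

    verts_u2, tris2, used = drop_unused_vertices(verts_u, tris_kept)

    # ellipsoid scaling with a mild smooth bump for shape variability
    theta = np.arccos(np.clip(verts_u2[:, 2], -1, 1))
    phi = np.arctan2(verts_u2[:, 1], verts_u2[:, 0])
    eps = sp.bump_amplitude
    p0, p1 = rng.uniform(0, 2 * np.pi, 2)
    bump = 1.0 + eps * np.sin(2 * theta + p0) * np.cos(phi + p1)
    verts = verts_u2 * np.asarray(sp.radii)[None, :] * bump[:, None]

    loops = find_boundary_loops(tris2)
    if len(loops) != 5:
        raise ValueError(f"hole cutting produced {len(loops)} loops")

    # associate each loop with its hole center
    loop_owner = []
    for loop in loops:
        c = verts_u2[loop].mean(axis=0)
        c /= np.linalg.norm(c)
        loop_owner.append(int(np.argmax(c @ centers.T)))
    if sorted(loop_owner) != [0, 1, 2, 3, 4]:
        raise ValueError("boundary loops merged across holes")

    mesh = SurfaceMesh(verts, tris2, labels, loops,
                       pv_loop_index={pv: loop_owner.index(pv) for pv in range(4)})
    mesh.pv_distance = np.column_stack([
        mesh.geodesic_distance(loops[mesh.pv_loop_index[pv]]) for pv in range(4)])
    validate_la_mesh(mesh)
    return mesh


# ---------------------------------------------------------------------------
# Fibrosis fields
# ---------------------------------------------------------------------------

@dataclass
class FibrosisMap:
    """Per-vertex image-intensity-ratio field (dimensionless, > 0)."""

    iir: np.ndarray
    threshold: float = IIR_THRESHOLD

    def fibrotic_vertices(self) -> np.ndarray:
        return self.iir > self.threshold

    def burden(self) -> float:
        """Fraction of vertices above threshold."""
        return float(np.mean(self.fibrotic_vertices()))


def generate_fibrosis(mesh: SurfaceMesh, seed: int, burden: float,
                      correlation_length: float = 8.0) -> FibrosisMap:
    """Spatially correlated IIR field with a target fibrotic-vertex fraction.

    A Gaussian white field is diffused over the vertex graph until its
    correlation scale reaches roughly ``correlation_length`` (mm), then
    mapped through an exponential so the empirical fraction of vertices
    with iir > 1.22 equals ``burden`` (exactly, up to quantile ties).
    """
    if not 0.0 <= burden <= 1.0:
        raise ValueError("burden must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF1B]))
    g = rng.standard_normal(mesh.n_vertices)

    h = float(np.mean(mesh.edge_lengths))
    n_iter = int(np.ceil((correlation_length / max(h, 1e-6)) ** 2))
    adj = mesh.vertex_graph.copy()
    adj.data[:] = 1.0
    deg = np.maximum(np.asarray(adj.sum(axis=1)).ravel(), 1.0)
    for _ in range(min(n_iter, 400)):
        g = 0.5 * g + 0.5 * (adj @ g) / deg
    g = (g - g.mean()) / max(g.std(), 1e-12)

    if burden <= 0.0:
        q = g.max() + 0.5
    elif burden >= 1.0:
        q = g.min() - 0.5
    else:
        q = float(np.quantile(g, 1.0 - burden))
    iir = IIR_THRESHOLD * np.exp(0.35 * (g - q))
    return FibrosisMap(iir=iir)


# ---------------------------------------------------------------------------
# Fiber fields
# ---------------------------------------------------------------------------

@dataclass
class FiberField:
    """Per-triangle unit fiber direction, tangent to the triangle plane."""

    directions: np.ndarray
    variant: str


def generate_fibers(mesh: SurfaceMesh, variant: str = "fiber_A") -> FiberField:
    """Rule-based fiber field: circumferential about the long (z) axis,
    optionally rotated in-plane by the variant's fixed angle.

    On a flat sheet the circumferential rule degenerates; the fallback
    projects the global x axis, giving a constant field there.
    """
    if variant not in FIBER_VARIANTS:
        raise ValueError(f"unknown fiber variant {variant!r}; "
                         f"choose from {sorted(FIBER_VARIANTS)}")
    n = mesh.triangle_normals
    axis = np.array([0.0, 0.0, 1.0])
    t = np.cross(np.broadcast_to(axis, n.shape), n)
    norms = np.linalg.norm(t, axis=1)
    degen = norms < 1e-8
    if degen.any():
        x = np.array([1.0, 0.0, 0.0])
        proj = x[None, :] - n[degen] * (n[degen] @ x)[:, None]
        t[degen] = proj
        norms = np.linalg.norm(t, axis=1)
    t /= norms[:, None]

    angle = np.deg2rad(FIBER_VARIANTS[variant])
    if angle != 0.0:
        # Rodrigues rotation of t about each triangle normal
        t = (t * np.cos(angle) + np.cross(n, t) * np.sin(angle)
             + n * (np.sum(n * t, axis=1, keepdims=True)) * (1 - np.cos(angle)))
        t /= np.linalg.norm(t, axis=1, keepdims=True)
    return FiberField(directions=t, variant=variant)


# ---------------------------------------------------------------------------
# Patients and cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortEffect:
    """Planted log-odds coefficients for the recurrence label model.

    The logistic linear predictor is::

        logit(base_rate) + burden*z_b + la_area*z_a + af_type*(ord - mean)
            + apd*z_apd

    where each z is the covariate standardized by its known sampling
    distribution. ``apd`` acts on a latent per-patient electrical
    phenotype (global action-potential-duration factor) that the
    simulations sense but the imaging and history blocks do not; it is
    the hook for planting a simulation-only signal.
    """

    base_rate: float = 0.4
    burden: float = 0.0
    la_area: float = 0.0
    af_type: float = 0.0
    apd: float = 0.0


# sampling distributions used for covariate standardization
_BURDEN_LO, _BURDEN_HI = 0.02, 0.55
_BURDEN_MEAN = 0.5 * (_BURDEN_LO + _BURDEN_HI)
_BURDEN_SD = (_BURDEN_HI - _BURDEN_LO) / np.sqrt(12.0)
_APD_LO, _APD_HI = 0.78, 1.30
_APD_MEAN = 0.5 * (_APD_LO + _APD_HI)
_APD_SD = (_APD_HI - _APD_LO) / np.sqrt(12.0)
_LA_SD = 0.07
_AFTYPE_PROBS = (0.43, 0.41, 0.16)
_VISUAL_EDGES = np.array([0.1525, 0.285, 0.4175])  # burden quartile edges
VISUAL_CATEGORIES = ("healthy", "mild", "moderate", "severe")


@dataclass
class PatientRecord:
    """History covariates and outcome label of one virtual patient."""

    patient_id: int
    af_type: str
    age: float
    sex: int                # 1 = female
    hypertension: int
    diabetes: int
    la_dilated: int
    visual_score: int       # 0 healthy .. 3 severe
    burden_target: float
    la_scale: float
    apd_factor: float
    recurrence: int
    recurrence_time: float | None


@dataclass
class VirtualPatient:
    """Record plus lazily built geometry and fibrosis artifacts."""

    record: PatientRecord
    mesh_seed: int
    fibrosis_seed: int
    resolution: float = 2.5
    shape_params: ShapeParams = field(default_factory=lambda: DEFAULT_SHAPE)

    @cached_property
    def mesh(self) -> SurfaceMesh:
        radii = tuple(r * self.record.la_scale for r in self.shape_params.radii)
        return generate_mesh(self.mesh_seed, self.resolution,
                             replace(self.shape_params, radii=radii))

    @cached_property
    def fibrosis(self) -> FibrosisMap:
        return generate_fibrosis(self.mesh, self.fibrosis_seed,
                                 self.record.burden_target)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(n: int, seed: int, effect: CohortEffect = CohortEffect(),
                    af_type_quota: tuple | None = None,
                    resolution: float = 2.5) -> list:
    """Sample ``n`` virtual patients.

    ``af_type_quota`` optionally fixes exact AF-type counts, e.g.
    ``(43, 41, 16)`` for a paper-like 100-patient mix; counts must sum to
    ``n``. Labels are Bernoulli draws from the planted logistic model in
    :class:`CohortEffect`; with all-zero coefficients they are independent
    of every covariate. Meshes and fibrosis maps are built lazily so
    label-level analyses at large ``n`` stay cheap.
    """
    if n < 2:
        raise ValueError("cohort size must be at least 2")
    root = np.random.SeedSequence([int(seed), 0xC0C0])
    rng = np.random.default_rng(root)

    if af_type_quota is not None:
        if len(af_type_quota) != 3 or sum(af_type_quota) != n:
            raise ValueError("af_type_quota must be 3 counts summing to n")
        types = np.repeat(np.arange(3), af_type_quota)
        rng.shuffle(types)
    else:
        types = rng.choice(3, size=n, p=_AFTYPE_PROBS)

    child_seeds = root.spawn(n)
    patients = []
    for i in range(n):
        prng = np.random.default_rng(child_seeds[i])
        burden = prng.uniform(_BURDEN_LO, _BURDEN_HI)
        la_scale = float(np.clip(prng.normal(1.0, _LA_SD), 0.82, 1.18))
        apd_factor = prng.uniform(_APD_LO, _APD_HI)
        age = float(np.clip(prng.normal(62.0, 10.0), 30.0, 88.0))
        sex = int(prng.random() < 0.33)
        hypertension = int(prng.random() < 0.45)
        diabetes = int(prng.random() < 0.12)
        la_dilated = int(la_scale > 1.05)
        af_ord = int(types[i])

        z_b = (burden - _BURDEN_MEAN) / _BURDEN_SD
        z_a = (la_scale - 1.0) / _LA_SD
        z_apd = (apd_factor - _APD_MEAN) / _APD_SD
        lin = (np.log(effect.base_rate / (1.0 - effect.base_rate))
               + effect.burden * z_b + effect.la_area * z_a
               + effect.af_type * (af_ord - 0.73) + effect.apd * z_apd)
        recurrence = int(prng.random() < _sigmoid(lin))
        if recurrence:
            t = prng.normal(189.0, 95.0)
            recurrence_time = float(np.clip(t, 91.0, 455.0))
        else:
            recurrence_time = None

        rec = PatientRecord(
            patient_id=i, af_type=AF_TYPES[af_ord], age=age, sex=sex,
            hypertension=hypertension, diabetes=diabetes, la_dilated=la_dilated,
            visual_score=int(np.searchsorted(_VISUAL_EDGES, burden)),
            burden_target=burden, la_scale=la_scale, apd_factor=apd_factor,
            recurrence=recurrence, recurrence_time=recurrence_time)
        mesh_seed, fib_seed = (int(x) for x in prng.integers(0, 2**31 - 1, 2))
        patients.append(VirtualPatient(rec, mesh_seed, fib_seed, resolution))
    return patients


#: Column order of the cohort covariate table (stable contract).
COHORT_COLUMNS = [
    "patient_id", "af_type", "age", "sex", "hypertension", "diabetes",
    "la_dilated", "visual_score", "burden_target", "la_scale", "apd_factor",
    "recurrence", "recurrence_time",
]


def cohort_table(patients: list):
    """Covariate/outcome table, one row per patient (documented column order)."""
    import pandas as pd

    rows = [{c: getattr(p.record, c) for c in COHORT_COLUMNS} for p in patients]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
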