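"""Monodomain reaction-diffusion solver on triangulated surfaces.

The reaction term is a two-variable phenomenological atrial cell model
(Mitchell-Schaeffer form) with per-vertex scalings for action-potential
duration and excitability, behind a small parameter dataclass so a more
detailed model could be swapped in. Diffusion is P1 finite elements with
mass lumping and anisotropic per-triangle conductivity aligned to a fiber
field; time stepping is explicit operator splitting with the stability
bound computed from the assembled operator (Gershgorin) and enforced.

Units: mm, ms, mV. Conductivities are effective diffusion coefficients
in mm^2/ms; conduction velocities in mm/ms (1 mm/ms = 1 m/s).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.sparse import coo_matrix, csr_matrix

from .cohort import IIR_THRESHOLD, FiberField, FibrosisMap
from .geometry import SurfaceMesh, make_sheet

V_REST = -80.0   # mV at dimensionless v = 0
V_AMP = 100.0    # mV span of the action potential
V_THRESHOLD = -40.0  # mV activation-detection threshold


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Cell model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellModelParams:
    """Phenomenological atrial cell model parameters.

    ``tau_close`` controls action-potential duration, ``tau_in`` the
    upstroke (excitability). Per-vertex heterogeneity enters through
    ``apd_scale`` (multiplies tau_close) and ``excitability_scale``
    (divides tau_in); both default to 1 everywhere.
    """

    model_id: str = "phenomenological_atrial"
    tau_in: float = 0.3
    tau_out: float = 6.0
    tau_open: float = 120.0
    tau_close: float = 100.0
    v_gate: float = 0.13
    v_rest: float = V_REST
    v_amp: float = V_AMP

    def vm(self, v: np.ndarray) -> np.ndarray:
        """Map dimensionless v to transmembrane potential (mV)."""
        return self.v_rest + self.v_amp * np.asarray(v)


def resting_state(n_vertices: int) -> tuple[np.ndarray, np.ndarray]:
    """(v, h) arrays at rest: fully repolarized, gate fully recovered."""
    return np.zeros(n_vertices), np.ones(n_vertices)


def limit_cycle(cell: CellModelParams, cycle_length: float, dt: float = 0.05,
                n_beats: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Record one paced single-cell cycle, aligned to the upstroke.

    Returns ``(v_cyc, h_cyc)`` sampled every ``dt`` over ``cycle_length``
    ms, used to map phase to state when seeding reentry.
    """
    n_per = int(round(cycle_length / dt))
    v, h = 0.0, 1.0
    v_hist = np.empty(n_per * n_beats)
    h_hist = np.empty(n_per * n_beats)
    for k in range(n_per * n_beats):
        stim = 0.6 if (k % n_per) * dt < 2.0 else 0.0
        dv = h * v * v * (1 - v) / cell.tau_in - v / cell.tau_out + stim
        dh = (1 - h) / cell.tau_open if v < cell.v_gate else -h / cell.tau_close
        v, h = min(v + dt * dv, 1.5), h + dt * dh
        v_hist[k], h_hist[k] = v, h
    return v_hist[-n_per:], h_hist[-n_per:]


# ---------------------------------------------------------------------------
# Substrate
# ---------------------------------------------------------------------------

@dataclass
class ConductivityField:
    """Per-triangle longitudinal/transverse diffusion (mm^2/ms)."""

    d_long: np.ndarray
    d_trans: np.ndarray

    def __post_init__(self):
        self.d_long = np.asarray(self.d_long, dtype=np.float64)
        self.d_trans = np.asarray(self.d_trans, dtype=np.float64)
        ok = (self.d_long >= self.d_trans) & (self.d_trans > 0)
        zero = (self.d_long == 0) & (self.d_trans == 0)
        if not (ok | zero).all():
            raise ValueError("require d_long >= d_trans > 0 (or both 0 in ablated elements)")

    @classmethod
    def uniform(cls, n_triangles: int, d_long: float, d_trans: float):
        return cls(np.full(n_triangles, d_long), np.full(n_triangles, d_trans))


@dataclass
class SubstrateModel:
    """One stress-test setup's complete physical model."""

    mesh: SurfaceMesh
    fibers: FiberField
    conductivity: ConductivityField
    cell: CellModelParams = field(default_factory=CellModelParams)
    apd_scale: np.ndarray | None = None          # per-vertex, default 1
    excitability_scale: np.ndarray | None = None  # per-vertex, default 1
    fibrosis: FibrosisMap | None = None
    decoupled_edges: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    ablated_triangles: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.mesh.n_vertices
        if self.apd_scale is None:
            self.apd_scale = np.ones(n)
        if self.excitability_scale is None:
            self.excitability_scale = np.ones(n)
        if not ((self.apd_scale > 0).all() and np.isfinite(self.apd_scale).all()):
            raise ValueError("apd_scale must be finite and positive")
        if not ((self.excitability_scale >= 0).all()
                and np.isfinite(self.excitability_scale).all()):
            raise ValueError("excitability_scale must be finite and non-negative")
        self.decoupled_edges = np.asarray(self.decoupled_edges, dtype=np.int64).reshape(-1, 2)
        self.ablated_triangles = np.asarray(self.ablated_triangles, dtype=np.int64)
        if len(self.ablated_triangles) and (
                self.ablated_triangles.max() >= self.mesh.n_triangles
                or self.ablated_triangles.min() < 0):
            raise ValueError("ablated triangle index out of range")
        if len(self.decoupled_edges) and self.decoupled_edges.max() >= n:
            raise ValueError("decoupled edge vertex index out of range")
        self._op_cache = None

    def substrate_hash(self) -> str:
        hsh = hashlib.sha256()
        for arr in (self.mesh.vertices, self.mesh.triangles,
                    self.fibers.directions, self.conductivity.d_long,
                    self.conductivity.d_trans, self.apd_scale,
                    self.excitability_scale,
                    np.sort(self.decoupled_edges, axis=0) if len(self.decoupled_edges)
                    else self.decoupled_edges,
                    np.sort(self.ablated_triangles)):
            hsh.update(np.ascontiguousarray(arr).tobytes())
        hsh.update(repr(self.cell).encode())
        return hsh.hexdigest()

    # -- assembled operator -------------------------------------------
    def operator(self):
        """(A, active, dt_max): A = lumped-mass M^-1 K (csr), the boolean
        excitable-vertex mask, and the explicit-stepping stability bound."""
        if self._op_cache is None:
            self._op_cache = _assemble_operator(
                self.mesh, self.fibers, self.conductivity,
                self.decoupled_edges, self.ablated_triangles)
        return self._op_cache

    def with_ablation(self, ablated_triangles: np.ndarray) -> "SubstrateModel":
        """Non-mutating copy with additional ablated triangles."""
        merged = np.union1d(self.ablated_triangles, np.asarray(ablated_triangles))
        return replace(self, ablated_triangles=merged,
                       provenance={**self.provenance, "ablation": int(len(merged))})


def _assemble_operator(mesh, fibers, cond, decoupled_edges, ablated):
    tris = mesh.triangles
    m = len(tris)
    live = np.ones(m, dtype=bool)
    live[ablated] = False

    p = mesh.vertices[tris[live]]
    n_hat = mesh.triangle_normals[live]
    areas = mesh.triangle_areas[live]
    f = fibers.directions[live]
    dl = cond.d_long[live]
    dt_ = cond.d_trans[live]

    # P1 shape-function gradients: grad_i = (n x e_i) / 2A, e_i opposite edge
    e = np.stack([p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]], axis=1)
    grads = np.cross(n_hat[:, None, :], e) / (2.0 * areas[:, None, None])

    # anisotropic tensor D = d_t (I - nn^T) + (d_l - d_t) ff^T
    eye = np.eye(3)[None, :, :]
    D = (dt_[:, None, None] * (eye - n_hat[:, :, None] * n_hat[:, None, :])
         + (dl - dt_)[:, None, None] * f[:, :, None] * f[:, None, :])

    Dg = np.einsum("tab,tib->tia", D, grads)
    K_loc = areas[:, None, None] * np.einsum("tia,tja->tij", grads, Dg)

    idx = tris[live]
    rows = np.repeat(idx, 3, axis=1).reshape(-1)
    cols = np.tile(idx, (1, 3)).reshape(-1)
    K = coo_matrix((K_loc.reshape(-1), (rows, cols)),
                   shape=(mesh.n_vertices, mesh.n_vertices)).tocsr()

    # interstitial decoupling: zero the pair coupling, keep zero row sums
    if len(decoupled_edges):
        K = K.tolil()
        for i, j in decoupled_edges:
            kij, kji = K[i, j], K[j, i]
            K[i, j] = 0.0
            K[j, i] = 0.0
            K[i, i] += kij
            K[j, j] += kji
        K = K.tocsr()

    # lumped mass from live triangles only
    Mv = np.zeros(mesh.n_vertices)
    np.add.at(Mv, idx.reshape(-1), np.repeat(areas / 3.0, 3))
    active = Mv > 1e-12
    inv_m = np.zeros_like(Mv)
    inv_m[active] = 1.0 / Mv[active]

    A = csr_matrix(K.multiply(inv_m[:, None]))
    A.sort_indices()
    # Gershgorin: row sums are zero, so lambda_max <= 2 * max diag(A)
    diag = A.diagonal()
    lam = 2.0 * diag.max() if len(diag) and diag.max() > 0 else 1e-9
    dt_max = 1.8 / lam  # 10% safety margin under the 2/lambda limit
    return A, active, float(dt_max)


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

@njit(cache=True)
def _step_block(indptr, indices, data, v, h, active, inv_tau_in, inv_tau_out,
                inv_tau_open, inv_tau_close, v_gate, dt, n_steps, step0,
                stim_vert, stim_amp, stim_s0, stim_s1, dv_buf):
    n = v.shape[0]
    for s in range(n_steps):
        step = step0 + s
        # pass 1: rates from the current state (Jacobi update, no sweep bias)
        for i in range(n):
            if not active[i]:
                dv_buf[i] = 0.0
                continue
            lap = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                lap += data[k] * v[indices[k]]
            vi = v[i]
            dv_buf[i] = (h[i] * vi * vi * (1.0 - vi) * inv_tau_in[i]
                         - vi * inv_tau_out - lap)
        # pass 2: apply
        for i in range(n):
            if not active[i]:
                continue
            if v[i] < v_gate:
                h[i] += dt * (1.0 - h[i]) * inv_tau_open
            else:
                h[i] -= dt * h[i] * inv_tau_close[i]
            v[i] += dt * dv_buf[i]
        for q in range(stim_vert.shape[0]):
            if stim_s0[q] <= step < stim_s1[q] and active[stim_vert[q]]:
                vi = v[stim_vert[q]] + dt * stim_amp[q]
                v[stim_vert[q]] = vi if vi < 1.5 else 1.5


@dataclass(frozen=True)
class Stimulus:
    """Square current pulse delivered to a set of vertices."""

    t_start: float            # ms
    duration: float = 2.0     # ms
    vertices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    amplitude: float = 0.6    # dimensionless dv/dt contribution (1/ms)


@dataclass
class VmMovie:
    """Transmembrane potential sampled at all vertices over time."""

    vm: np.ndarray              # (n_frames, n_vertices) mV, float32
    times: np.ndarray           # ms
    sample_interval: float      # ms
    stimulus_log: list = field(default_factory=list)
    final_state: tuple | None = None  # (v, h) at the last step

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


def simulate(substrate: SubstrateModel, duration: float,
             initial_state: tuple | None = None,
             stimuli: list | None = None,
             sample_interval: float = 5.0, dt: float = 0.1,
             t_offset: float = 0.0) -> VmMovie:
    """Run the monodomain model and sample Vm every ``sample_interval`` ms.

    Deterministic; frames at t_offset + {0, dt_s, ..., duration}
    inclusive. ``dt`` is clamped to the operator's stability bound. Raises
    :class:`SimulationError` with the offending time and vertex if the
    state leaves the finite range.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    stimuli = list(stimuli or [])
    A, active, dt_max = substrate.operator()
    cell = substrate.cell
    react_dt = 0.35 * cell.tau_in / max(float(substrate.excitability_scale.max()), 1e-9)
    dt = min(dt, dt_max, react_dt)

    steps_per_frame = max(1, int(round(sample_interval / dt)))
    dt = sample_interval / steps_per_frame
    n_frames = int(round(duration / sample_interval)) + 1

    if initial_state is None:
        v, h = resting_state(substrate.mesh.n_vertices)
    else:
        v, h = (np.array(initial_state[0], dtype=np.float64),
                np.array(initial_state[1], dtype=np.float64))

    inv_tau_in = substrate.excitability_scale / cell.tau_in
    inv_tau_close = 1.0 / (cell.tau_close * substrate.apd_scale)

    sv, sa, s0, s1 = _flatten_stimuli(stimuli, dt)
    vm = np.empty((n_frames, substrate.mesh.n_vertices), dtype=np.float32)
    vm[0] = cell.vm(v)
    dv_buf = np.empty_like(v)
    for fr in range(1, n_frames):
        _step_block(A.indptr, A.indices, A.data, v, h, active,
                    inv_tau_in, 1.0 / cell.tau_out, 1.0 / cell.tau_open,
                    inv_tau_close, cell.v_gate, dt, steps_per_frame,
                    (fr - 1) * steps_per_frame, sv, sa, s0, s1, dv_buf)
        if not np.isfinite(v).all():
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise SimulationError(
                f"non-finite state at t={fr * sample_interval:.1f} ms, vertex {bad}")
        vm[fr] = cell.vm(v)

    times = t_offset + np.arange(n_frames) * sample_interval
    return VmMovie(vm=vm, times=times, sample_interval=sample_interval,
                   stimulus_log=[(s.t_start, s.duration, len(s.vertices), s.amplitude)
                                 for s in stimuli],
                   final_state=(v, h))


def _flatten_stimuli(stimuli, dt):
    verts, amps, starts, ends = [], [], [], []
    for s in stimuli:
        vv = np.asarray(s.vertices, dtype=np.int64)
        k0 = int(round(s.t_start / dt))
        k1 = max(k0 + 1, int(round((s.t_start + s.duration) / dt)))
        verts.append(vv)
        amps.append(np.full(len(vv), s.amplitude))
        starts.append(np.full(len(vv), k0, dtype=np.int64))
        ends.append(np.full(len(vv), k1, dtype=np.int64))
    if not verts:
        z = np.empty(0, dtype=np.int64)
        return z, np.empty(0), z, z
    return (np.concatenate(verts), np.concatenate(amps),
            np.concatenate(starts), np.concatenate(ends))


# ---------------------------------------------------------------------------
# Conduction-velocity calibration
# ---------------------------------------------------------------------------

def _sheet_substrate(lx, ly, resolution, d_long, d_trans, cell,
                     fiber_angle_deg: float = 0.0):
    from .cohort import generate_fibers

    mesh = make_sheet(lx, ly, resolution)
    fibers = generate_fibers(mesh, "fiber_A")  # constant +x on a flat sheet
    if fiber_angle_deg:
        a = np.deg2rad(fiber_angle_deg)
        R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        fibers.directions = fibers.directions @ R.T
    cond = ConductivityField.uniform(mesh.n_triangles, d_long, d_trans)
    return SubstrateModel(mesh, fibers, cond, cell=cell)


def measure_cv_planar(d_long: float, d_trans: float | None = None,
                      resolution: float = 0.5,
                      cell: CellModelParams = CellModelParams(),
                      lx: float = 40.0, ly: float = 8.0, dt: float = 0.1) -> float:
    """Planar-wave conduction velocity (mm/ms) along the fiber direction.

    Paces a strip at x=0 of an ``lx`` x ``ly`` sheet and fits activation
    time against x over the central region.
    """
    if d_trans is None:
        d_trans = d_long
    sub = _sheet_substrate(lx, ly, resolution, d_long, d_trans, cell)
    mesh = sub.mesh
    left = np.flatnonzero(mesh.vertices[:, 0] < resolution * 1.01)
    stim = Stimulus(t_start=1.0, duration=2.0, vertices=left, amplitude=0.8)
    est_cv = max(0.05, 1.2 * np.sqrt(d_long / cell.tau_in))
    duration = min(2000.0, 1.2 * lx / est_cv + 60.0)
    movie = simulate(sub, duration, stimuli=[stim], sample_interval=1.0, dt=dt)

    act = activation_times(movie)
    x = mesh.vertices[:, 0]
    mid = (x > 0.25 * lx) & (x < 0.85 * lx) & np.isfinite(act)
    if mid.sum() < 10:
        raise SimulationError("planar wave did not traverse the sheet")
    slope = np.polyfit(x[mid], act[mid], 1)[0]
    if slope <= 0:
        raise SimulationError("non-positive activation-time slope")
    return float(1.0 / slope)


def activation_times(movie: VmMovie, threshold: float = V_THRESHOLD) -> np.ndarray:
    """First threshold-crossing time per vertex (NaN if never activated)."""
    above = movie.vm >= threshold
    first = above.argmax(axis=0)
    never = ~above.any(axis=0)
    t = movie.times[first].astype(float)
    t[never] = np.nan
    return t


def calibrate_cv(target_cv: float, fiber_anisotropy_ratio: float = 2.0,
                 resolution: float = 0.5,
                 cell: CellModelParams = CellModelParams(),
                 tol: float = 0.025, max_iter: int = 8) -> dict:
    """Find the longitudinal diffusion giving a planar CV of ``target_cv``.

    Exploits CV ~ sqrt(d) for fast fixed-point iteration on a calibration
    sheet at the same resolution; transverse diffusion is set from the
    CV anisotropy ratio (d_trans = d_long / ratio^2). Raises with the
    feasible range if the target cannot be met.
    """
    if target_cv <= 0:
        raise ValueError("target_cv must be positive")
    d_lo, d_hi = 1e-4, 30.0
    d = 0.3
    cv = measure_cv_planar(d, d, resolution, cell)
    for _ in range(max_iter):
        if abs(cv - target_cv) / target_cv <= tol:
            break
        d = float(np.clip(d * (target_cv / cv) ** 2, d_lo, d_hi))
        cv = measure_cv_planar(d, d, resolution, cell)
    if abs(cv - target_cv) / target_cv > 2 * tol:
        cv_lo = measure_cv_planar(d_lo, d_lo, resolution, cell) if d <= d_lo else None
        cv_hi = measure_cv_planar(d_hi, d_hi, resolution, cell) if d >= d_hi else None
        lo = cv_lo if cv_lo is not None else "?"
        hi = cv_hi if cv_hi is not None else "?"
        raise ValueError(
            f"target CV {target_cv} mm/ms unattainable at resolution "
            f"{resolution} mm (feasible range ~[{lo}, {hi}] mm/ms)")
    return {"d_long": d, "d_trans": d / fiber_anisotropy_ratio**2,
            "achieved_cv": cv, "anisotropy_ratio": fiber_anisotropy_ratio}


# ---------------------------------------------------------------------------
# IIR -> conductivity rule
# ---------------------------------------------------------------------------

def iir_to_conductivity(iir: np.ndarray, triangles: np.ndarray,
                        floor: float = 0.3, ceiling: float = 1.6,
                        threshold: float = IIR_THRESHOLD,
                        rule=None) -> np.ndarray:
    """Per-triangle conductivity scaling from a per-vertex IIR field.

    Default rule: 1.0 for iir <= threshold (threshold inclusive on the
    healthy side), linear down to ``floor`` at ``ceiling``, constant
    beyond. A custom ``rule(iir_array) -> scaling`` may be supplied but
    must be monotone non-increasing; non-monotone rules are rejected.
    Triangle scaling is the mean of its three vertex scalings.
    """
    iir = np.asarray(iir, dtype=float)
    if rule is None:
        def rule(x):
            frac = np.clip((x - threshold) / (ceiling - threshold), 0.0, 1.0)
            return 1.0 - (1.0 - floor) * frac
    grid = np.linspace(max(0.01, iir.min() if len(iir) else 0.5),
                       max(2.5, iir.max() if len(iir) else 2.5), 64)
    vals = np.asarray(rule(grid), dtype=float)
    if np.any(np.diff(vals) > 1e-12):
        raise ValueError("conductivity rule must be monotone non-increasing in iir")
    per_vertex = np.asarray(rule(iir), dtype=float)
    return per_vertex[triangles].mean(axis=1)


# ---------------------------------------------------------------------------
# Effective refractory period
# ---------------------------------------------------------------------------

def measure_erp(substrate: SubstrateModel, site_vertices: np.ndarray,
                s1_cycle_length: float = 600.0, resolution: float = 5.0,
                n_s1: int = 8, probe_vertex: int | None = None,
                dt: float = 0.1) -> float:
    """S1-S2 effective refractory period at a pacing site.

    Delivers ``n_s1`` S1 beats at ``s1_cycle_length`` then an S2 at a
    coupling interval found by bisection on a ``resolution``-ms grid;
    capture is judged by propagation to a probe vertex a few mm away.
    Returns longest non-capturing interval + resolution/2.
    """
    site = np.asarray(site_vertices, dtype=np.int64)
    if len(site) == 0 or site.max() >= substrate.mesh.n_vertices:
        raise ValueError("invalid pacing site")
    mesh = substrate.mesh
    if probe_vertex is None:
        dist = mesh.geodesic_distance(site)
        cands = np.flatnonzero((dist > 4.0) & (dist < 12.0) & np.isfinite(dist))
        if len(cands) == 0:
            cands = np.array([int(np.nanargmax(np.where(np.isfinite(dist), dist, -1)))])
        probe_vertex = int(cands[np.argmin(dist[cands])])

    def beats_at_probe(s2: float | None) -> int:
        stims = [Stimulus(t_start=k * s1_cycle_length, duration=2.0,
                          vertices=site, amplitude=0.8) for k in range(n_s1)]
        extra = 300.0
        if s2 is not None:
            t2 = (n_s1 - 1) * s1_cycle_length + s2
            stims.append(Stimulus(t_start=t2, duration=2.0, vertices=site, amplitude=0.8))
            total = t2 + extra
        else:
            total = n_s1 * s1_cycle_length + extra
        movie = simulate(substrate, total, stimuli=stims, sample_interval=2.0, dt=dt)
        sig = movie.vm[:, probe_vertex]
        up = (sig[1:] >= V_THRESHOLD) & (sig[:-1] < V_THRESHOLD)
        return int(up.sum())

    if beats_at_probe(None) < n_s1:
        raise SimulationError("baseline capture failure")

    lo = 0                                  # grid units known not to capture
    hi = int(np.ceil(s1_cycle_length / resolution))  # known (assumed) to capture
    if beats_at_probe(hi * resolution) <= n_s1:
        raise SimulationError("S2 at full cycle length fails to capture")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if beats_at_probe(mid * resolution) > n_s1:
            hi = mid
        else:
            lo = mid
    return lo * resolution + resolution / 2.0
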