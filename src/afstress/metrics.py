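"""Patient-signature metrics: phase analysis, phase singularities,
dominant frequency, and imaging area metrics.

Phase is the Hilbert-transform analytic-signal angle of mean-subtracted
Vm. A phase singularity is a vertex whose ordered one-ring carries a
+/-2*pi winding of wrapped phase differences. Dominant frequency (DF) is
the 90th percentile over non-ablated body vertices of per-vertex Welch
spectral peaks in the 1-20 Hz band; sustained AF is DF >= 4.7 Hz
(threshold inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert, welch

from .cohort import FibrosisMap
from .geometry import PV_REGIONS, Region, SurfaceMesh
from .ep import VmMovie

DF_THRESHOLD_HZ = 4.7     # sustained-AF dominant-frequency threshold
DF_BAND_HZ = (1.0, 20.0)
DF_BIN_HZ = 0.25          # maximum spectral bin width (zero-padded)
QUIESCENT_VM_SD = 0.5     # mV; below this a vertex has no defined phase/DF


# ---------------------------------------------------------------------------
# Phase
# ---------------------------------------------------------------------------

@dataclass
class PhaseMap:
    """Instantaneous phase per vertex per frame, in (-pi, pi]."""

    phase: np.ndarray          # (n_frames, n_vertices)
    valid: np.ndarray          # (n_vertices,) phase defined here
    times: np.ndarray
    method: str = "hilbert"


def compute_phase(movie: VmMovie) -> PhaseMap:
    """Analytic-signal phase of mean-subtracted Vm at every vertex.

    Vertices with (near-)constant Vm have undefined phase and are flagged
    out via ``valid``. Requires >= 1 s of signal.
    """
    if movie.duration < 1000.0:
        raise ValueError("need at least 1 s of signal for phase analysis")
    vm = movie.vm.astype(np.float64)
    centered = vm - vm.mean(axis=0, keepdims=True)
    valid = vm.std(axis=0) >= QUIESCENT_VM_SD
    phase = np.zeros_like(centered)
    if valid.any():
        analytic = hilbert(centered[:, valid], axis=0)
        phase[:, valid] = np.angle(analytic)
    return PhaseMap(phase=phase.astype(np.float32), valid=valid,
                    times=movie.times)


# ---------------------------------------------------------------------------
# Phase singularities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSObservation:
    time: float
    vertex: int
    charge: int


def _wrap(x):
    return (x + np.pi) % (2 * np.pi) - np.pi


def detect_phase_singularities(phase_map: PhaseMap, frame: int,
                               mesh: SurfaceMesh) -> list:
    """Winding-number PS detection at one frame.

    For each interior vertex the wrapped phase differences around its
    ordered one-ring are summed; a winding of +/-1 turn marks a
    singularity with that topological charge. Rings containing invalid
    (quiescent) vertices are skipped.
    """
    phi = phase_map.phase[frame].astype(np.float64)
    t = float(phase_map.times[frame])
    ids, flat, nxt, offs = mesh.one_ring_arrays
    if len(ids) == 0:
        return []
    diffs = _wrap(phi[nxt] - phi[flat])
    winding = np.round(np.add.reduceat(diffs, offs[:-1]) / (2 * np.pi)).astype(int)
    ring_ok = np.minimum.reduceat(phase_map.valid[flat].astype(np.int8), offs[:-1]) > 0
    hits = np.flatnonzero((np.abs(winding) == 1) & ring_ok & phase_map.valid[ids])
    return [PSObservation(time=t, vertex=int(ids[i]), charge=int(winding[i]))
            for i in hits]


def track_phase_singularities(phase_map: PhaseMap, mesh: SurfaceMesh,
                              frames: np.ndarray | None = None) -> list:
    """PS observations for a range of frames (list of per-frame lists)."""
    if frames is None:
        frames = np.arange(phase_map.phase.shape[0])
    return [detect_phase_singularities(phase_map, int(f), mesh) for f in frames]


def cluster_observations(observations: list, mesh: SurfaceMesh,
                         radius_edges: float = 1.6) -> list:
    """Merge same-frame, same-charge detections closer than
    ``radius_edges`` mean edge lengths into one representative.

    A singularity falling inside a triangle (rather than at a vertex)
    trips the winding criterion at each surrounding vertex; clustering
    recovers the physical count.
    """
    obs = sorted(observations, key=lambda o: o.vertex)
    if not obs:
        return []
    r = radius_edges * float(np.mean(mesh.edge_lengths))
    pts = mesh.vertices[[o.vertex for o in obs]]
    charges = np.array([o.charge for o in obs])
    # single-linkage components of the same-charge proximity graph
    parent = list(range(len(obs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(obs)):
        for j in range(i + 1, len(obs)):
            if charges[i] == charges[j] and np.linalg.norm(pts[i] - pts[j]) <= r:
                parent[find(i)] = find(j)
    reps = {}
    for i, o in enumerate(obs):
        reps.setdefault(find(i), o)
    return sorted(reps.values(), key=lambda o: o.vertex)


@dataclass
class PSStatistics:
    mean_count: float
    ps_area_cm2: float
    pv_ps_area_cm2: float


def ps_statistics(observations: list, mesh: SurfaceMesh) -> PSStatistics:
    """Time-mean PS count and visited-triangle areas.

    ``observations`` is a list of per-frame PS lists. The PS area is the
    total area of triangles incident to any PS vertex during the window;
    the PV PS area restricts that union to PV-labeled triangles.
    """
    if len(observations) == 0:
        return PSStatistics(0.0, 0.0, 0.0)
    counts = [len(frame) for frame in observations]
    visited = np.zeros(mesh.n_triangles, dtype=bool)
    for frame_obs in observations:
        for obs in frame_obs:
            visited[mesh.vertex_triangles[obs.vertex]] = True
    areas = mesh.triangle_areas
    pv_mask = np.isin(mesh.region_label, [int(r) for r in PV_REGIONS])
    return PSStatistics(
        mean_count=float(np.mean(counts)),
        ps_area_cm2=float(areas[visited].sum()) / 100.0,
        pv_ps_area_cm2=float(areas[visited & pv_mask].sum()) / 100.0)


# ---------------------------------------------------------------------------
# Dominant frequency
# ---------------------------------------------------------------------------

def dominant_frequency(movie: VmMovie, epoch: tuple | None = None,
                       vertex_mask: np.ndarray | None = None,
                       percentile: float = 90.0) -> float:
    """Robust atrial rate (Hz) from per-vertex spectral peaks.

    Welch spectra of mean-subtracted Vm over the epoch, zero-padded to
    bins <= 0.25 Hz; per-vertex DF is the argmax in 1-20 Hz (0 for
    quiescent vertices); the movie DF is the ``percentile`` of per-vertex
    DFs over ``vertex_mask`` (default: all vertices). Fully quiescent
    movies return 0 Hz by convention.
    """
    t0, t1 = (movie.times[0], movie.times[-1]) if epoch is None else epoch
    if t1 - t0 < 1000.0:
        raise ValueError("epoch must be at least 1 s")
    sel = (movie.times >= t0) & (movie.times <= t1)
    vm = movie.vm[sel].astype(np.float64)
    if vertex_mask is not None:
        vm = vm[:, vertex_mask]
    fs = 1000.0 / movie.sample_interval  # Hz

    active = vm.std(axis=0) >= QUIESCENT_VM_SD
    df_per_vertex = np.zeros(vm.shape[1])
    if active.any():
        seg = vm[:, active] - vm[:, active].mean(axis=0, keepdims=True)
        nfft = int(2 ** np.ceil(np.log2(fs / DF_BIN_HZ)))
        nper = min(seg.shape[0], nfft)
        freqs, pxx = welch(seg, fs=fs, axis=0, nperseg=nper, nfft=nfft,
                           detrend="constant")
        band = (freqs >= DF_BAND_HZ[0]) & (freqs <= DF_BAND_HZ[1])
        df_per_vertex[active] = freqs[band][np.argmax(pxx[band], axis=0)]
    return float(np.percentile(df_per_vertex, percentile))


def classify_af_sustained(df: float) -> bool:
    """Sustained AF iff DF >= 4.7 Hz (threshold inclusive)."""
    if df < 0:
        raise ValueError("dominant frequency must be non-negative")
    return df >= DF_THRESHOLD_HZ


def body_vertex_mask(mesh: SurfaceMesh,
                     ablated_triangles: np.ndarray | None = None) -> np.ndarray:
    """Non-ablated body-region vertices (the DF aggregation support)."""
    mask = mesh.vertex_region == int(Region.BODY)
    if ablated_triangles is not None and len(ablated_triangles):
        live = np.ones(mesh.n_triangles, dtype=bool)
        live[ablated_triangles] = False
        live_verts = np.zeros(mesh.n_vertices, dtype=bool)
        live_verts[np.unique(mesh.triangles[live])] = True
        mask &= live_verts
    return mask


# ---------------------------------------------------------------------------
# Imaging metrics
# ---------------------------------------------------------------------------

@dataclass
class ImagingMetrics:
    total_area_cm2: float
    pv_area_cm2: float
    fibrosis_area_cm2: float
    pv_fibrosis_area_cm2: float


def imaging_metrics(mesh: SurfaceMesh, fibrosis_map: FibrosisMap) -> ImagingMetrics:
    """Surface-area metrics (cm^2); a triangle is fibrotic iff its mean
    vertex IIR exceeds the threshold."""
    areas = mesh.triangle_areas
    pv_mask = np.isin(mesh.region_label, [int(r) for r in PV_REGIONS])
    fib_mask = fibrosis_map.iir[mesh.triangles].mean(axis=1) > fibrosis_map.threshold
    return ImagingMetrics(
        total_area_cm2=float(areas.sum()) / 100.0,
        pv_area_cm2=float(areas[pv_mask].sum()) / 100.0,
        fibrosis_area_cm2=float(areas[fib_mask].sum()) / 100.0,
        pv_fibrosis_area_cm2=float(areas[pv_mask & fib_mask].sum()) / 100.0)
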