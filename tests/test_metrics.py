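import numpy as np
import pytest

from afstress.cohort import FibrosisMap, generate_fibrosis
from afstress.ep import VmMovie
from afstress.geometry import Region, SurfaceMesh, icosphere, make_sheet
from afstress.metrics import (
    DF_THRESHOLD_HZ,
    PhaseMap,
    PSObservation,
    classify_af_sustained,
    cluster_observations,
    compute_phase,
    detect_phase_singularities,
    dominant_frequency,
    imaging_metrics,
    ps_statistics,
    track_phase_singularities,
)
from conftest import brute_force_winding


def make_movie(vm, dt_ms=5.0):
    vm = np.asarray(vm, dtype=np.float32)
    times = np.arange(vm.shape[0]) * dt_ms
    return VmMovie(vm=vm, times=times, sample_interval=dt_ms)


def phase_map_from(mesh, phi):
    return PhaseMap(phase=np.vstack([phi, phi]).astype(np.float32),
                    valid=np.ones(mesh.n_vertices, dtype=bool),
                    times=np.array([0.0, 1.0]))


class TestComputePhase:
    def test_sinusoid_phase_advance(self):
        t = np.arange(0, 2000, 5.0) / 1000.0  # s
        vm = -60 + 20 * np.sin(2 * np.pi * 6.0 * t)
        movie = make_movie(np.tile(vm[:, None], (1, 3)))
        pm = compute_phase(movie)
        # unwrap: phase advances 2*pi per 1/6 s
        ph = np.unwrap(pm.phase[:, 0].astype(float))
        cycles = (ph[-1] - ph[0]) / (2 * np.pi)
        expected = 6.0 * (t[-1] - t[0])
        assert abs(cycles - expected) <= 6.0 * 0.005 + 0.1

    def test_constant_vm_flagged_undefined(self):
        vm = np.full((400, 4), -80.0)
        vm[:, 0] = -60 + 25 * np.sin(np.linspace(0, 60, 400))
        pm = compute_phase(make_movie(vm))
        assert pm.valid[0]
        assert not pm.valid[1:].any()

    def test_short_movie_rejected(self):
        movie = make_movie(np.zeros((10, 3)))
        with pytest.raises(ValueError, match="1 s"):
            compute_phase(movie)


class TestDetector:
    def test_plane_wave_no_ps(self, sheet):
        phi = np.angle(np.exp(1j * 0.8 * sheet.vertices[:, 0]))
        assert detect_phase_singularities(phase_map_from(sheet, phi), 0, sheet) == []

    def test_single_spiral(self):
        mesh = make_sheet(20, 20, 1.0)
        c = np.array([10.0, 10.0, 0.0])
        d = mesh.vertices - c
        phi = np.arctan2(d[:, 1], d[:, 0])
        obs = detect_phase_singularities(phase_map_from(mesh, phi), 0, mesh)
        clusters = cluster_observations(obs, mesh)
        assert len(clusters) == 1
        assert clusters[0].charge == 1
        assert np.linalg.norm(mesh.vertices[clusters[0].vertex] - c) < 2.0

    def test_mirrored_spiral_flips_charge(self):
        mesh = make_sheet(20, 20, 1.0)
        d = mesh.vertices - np.array([10.0, 10.0, 0.0])
        phi = np.arctan2(-d[:, 1], d[:, 0])
        clusters = cluster_observations(
            detect_phase_singularities(phase_map_from(mesh, phi), 0, mesh), mesh)
        assert [o.charge for o in clusters] == [-1]

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_random_smooth_fields(self, seed):
        """Detector output equals the brute-force winding oracle."""
        mesh = make_sheet(16, 16, 1.0)
        rng = np.random.default_rng(seed)
        x, y = mesh.vertices[:, 0], mesh.vertices[:, 1]
        a = np.zeros(mesh.n_vertices)
        b = np.zeros(mesh.n_vertices)
        for _ in range(4):
            kx, ky = rng.uniform(-0.5, 0.5, 2)
            ph = rng.uniform(0, 2 * np.pi)
            a += rng.normal() * np.cos(kx * x + ky * y + ph)
            b += rng.normal() * np.sin(kx * x + ky * y + ph)
        phi = np.arctan2(b, a)
        obs = detect_phase_singularities(phase_map_from(mesh, phi), 0, mesh)
        got = {o.vertex: o.charge for o in obs}
        assert got == brute_force_winding(mesh, phi)

    def test_oracle_equivalence_on_la_mesh(self, la_mesh):
        v = la_mesh.vertices
        phi = np.arctan2(np.sin(0.1 * v[:, 0]), np.cos(0.12 * v[:, 1]))
        # PhaseMap stores float32; feed the oracle the same rounded values
        phi32 = phi.astype(np.float32).astype(np.float64)
        obs = detect_phase_singularities(phase_map_from(la_mesh, phi), 0, la_mesh)
        got = {o.vertex: o.charge for o in obs}
        assert got == brute_force_winding(la_mesh, phi32)

    def test_invalid_vertices_skipped(self, sheet):
        phi = np.zeros(sheet.n_vertices)
        pm = phase_map_from(sheet, phi)
        pm.valid[:] = False
        assert detect_phase_singularities(pm, 0, sheet) == []


class TestPSStatistics:
    def test_no_ps(self, la_mesh):
        st = ps_statistics([[], [], []], la_mesh)
        assert (st.mean_count, st.ps_area_cm2, st.pv_ps_area_cm2) == (0, 0, 0)

    def test_stationary_ps(self, la_mesh):
        v = int(np.flatnonzero(la_mesh.vertex_region == 0)[10])
        frames = [[PSObservation(time=t, vertex=v, charge=1)] for t in (0, 1, 2)]
        st = ps_statistics(frames, la_mesh)
        assert st.mean_count == 1.0
        nb_area = la_mesh.triangle_areas[la_mesh.vertex_triangles[v]].sum() / 100.0
        assert st.ps_area_cm2 == pytest.approx(nb_area)

    def test_ps_confined_to_pv_region(self, la_mesh):
        v = int(np.flatnonzero(la_mesh.vertex_region == int(Region.PV1))[5])
        # pick one whose whole neighbourhood is PV-labeled
        for cand in np.flatnonzero(la_mesh.vertex_region == int(Region.PV1)):
            tris = la_mesh.vertex_triangles[cand]
            if (la_mesh.region_label[tris] == int(Region.PV1)).all():
                v = int(cand)
                break
        st = ps_statistics([[PSObservation(0.0, v, 1)]], la_mesh)
        assert st.pv_ps_area_cm2 == pytest.approx(st.ps_area_cm2)


class TestDominantFrequency:
    def test_pure_tone(self):
        t = np.arange(0, 2000, 5.0) / 1000.0
        vm = -60 + 20 * np.sin(2 * np.pi * 6.0 * t)
        df = dominant_frequency(make_movie(np.tile(vm[:, None], (1, 10))))
        assert abs(df - 6.0) <= 0.25

    def test_quiescent_zero(self):
        df = dominant_frequency(make_movie(np.full((400, 10), -80.0)))
        assert df == 0.0

    def test_two_region_percentile_rule(self):
        t = np.arange(0, 2000, 5.0) / 1000.0
        vm = np.full((len(t), 10), -80.0)
        vm[:, :2] = (-60 + 20 * np.sin(2 * np.pi * 7.0 * t))[:, None]
        df = dominant_frequency(make_movie(vm))
        assert abs(df - 7.0) <= 0.25

    def test_shift_invariance(self):
        t = np.arange(0, 2000, 5.0) / 1000.0
        vm = np.tile((-60 + 20 * np.sin(2 * np.pi * 5.0 * t))[:, None], (1, 5))
        d1 = dominant_frequency(make_movie(vm))
        d2 = dominant_frequency(make_movie(vm + 17.0))
        assert d1 == d2

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            dominant_frequency(make_movie(np.zeros((50, 3))))


class TestChargeBookkeeping:
    def test_stable_rotor_conserves_charge(self):
        """On a simulated rotor movie, PSs persist with constant charge;
        they may only appear/disappear via boundary crossing or
        opposite-charge pair events (none occur for a stable rotor)."""
        from afstress.cohort import generate_fibers
        from afstress.ep import (
            CellModelParams,
            ConductivityField,
            SubstrateModel,
            limit_cycle,
            simulate,
        )

        mesh = make_sheet(60, 60, 1.5)
        cell = CellModelParams(tau_close=90.0)
        sub = SubstrateModel(mesh, generate_fibers(mesh, "fiber_A"),
                             ConductivityField.uniform(mesh.n_triangles, 0.3, 0.3),
                             cell=cell)
        d = mesh.vertices - np.array([30.0, 30.0, 0.0])
        for sign in (+1, -1):
            phi = np.arctan2(sign * d[:, 1], d[:, 0])
            vc, hc = limit_cycle(cell, 180.0)
            pos = ((phi + np.pi) / (2 * np.pi) * len(vc)).astype(int) % len(vc)
            movie = simulate(sub, 1500.0, initial_state=(vc[pos], hc[pos]),
                             sample_interval=5.0)
            pm = compute_phase(movie)
            frames = np.arange(40, 290, 10)
            per_frame = [cluster_observations(o, mesh) for o in
                         track_phase_singularities(pm, mesh, frames)]
            for obs in per_frame:
                assert len(obs) == 1
                assert obs[0].charge == sign


class TestSustainedRule:
    @pytest.mark.parametrize("df,expected", [(6.0, True), (0.0, False),
                                             (4.7, True), (4.69, False)])
    def test_threshold(self, df, expected):
        assert classify_af_sustained(df) is expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_af_sustained(-1.0)


class TestImagingMetrics:
    def test_uniform_healthy(self, la_mesh):
        fib = FibrosisMap(iir=np.ones(la_mesh.n_vertices))
        m = imaging_metrics(la_mesh, fib)
        assert m.fibrosis_area_cm2 == 0.0
        assert m.pv_fibrosis_area_cm2 == 0.0

    def test_sphere_area_closed_form(self):
        verts, faces = icosphere(4)
        mesh = SurfaceMesh(verts * 10.0, faces)  # radius 10 mm = 1 cm
        fib = FibrosisMap(iir=np.ones(mesh.n_vertices))
        m = imaging_metrics(mesh, fib)
        assert m.total_area_cm2 == pytest.approx(4 * np.pi, rel=0.01)

    def test_all_fibrotic_pv1(self, la_mesh):
        iir = np.ones(la_mesh.n_vertices)
        pv1_tris = la_mesh.region_label == int(Region.PV1)
        iir[np.unique(la_mesh.triangles[pv1_tris])] = 1.5
        m = imaging_metrics(la_mesh, FibrosisMap(iir=iir))
        pv1_area = la_mesh.region_area(Region.PV1) / 100.0
        assert m.pv_fibrosis_area_cm2 >= pv1_area * 0.99
        assert m.fibrosis_area_cm2 >= m.pv_fibrosis_area_cm2

    def test_invariant_ordering(self, la_mesh, la_fibrosis):
        m = imaging_metrics(la_mesh, la_fibrosis)
        assert 0 <= m.pv_area_cm2 <= m.total_area_cm2
        assert 0 <= m.fibrosis_area_cm2 <= m.total_area_cm2
        assert m.pv_fibrosis_area_cm2 <= min(m.pv_area_cm2, m.fibrosis_area_cm2)

    def test_area_conservation(self, la_mesh):
        pv = sum(la_mesh.region_area(r) for r in
                 (Region.PV1, Region.PV2, Region.PV3, Region.PV4))
        rest = la_mesh.region_area(Region.BODY, Region.MITRAL_RIM)
        assert pv + rest == pytest.approx(la_mesh.total_area())
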