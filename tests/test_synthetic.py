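"""Generator tests: mesh construction, parcellation contiguity and
determinism, scalar maps, AR(1)-latent time series and task runs."""
import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components

from cortnet import synthetic as syn
from cortnet.types import ConditionSpec, GroundTruth, SurfaceMesh


class TestMesh:
    def test_flat_grid_counts(self):
        m = syn.generate_mesh("flat_grid", 10)
        assert m.n_vertices == 100
        assert m.n_triangles == 2 * 9 * 9  # two triangles per grid cell
        assert m.is_connected()

    def test_icosphere_counts(self):
        m = syn.generate_mesh("icosphere", 3)
        assert m.n_vertices == 10 * 4**3 + 2
        assert m.is_connected()

    def test_landmarks_nonempty_disjoint(self, ico_mesh):
        seen = set()
        assert len(ico_mesh.landmark_sets) == 3
        for name, idx in ico_mesh.landmark_sets.items():
            assert idx.size > 0
            assert not seen & set(idx.tolist())
            seen |= set(idx.tolist())

    def test_overlapping_landmarks_rejected(self):
        with pytest.raises(ValueError, match="landmarks overlap"):
            syn.generate_mesh(
                "flat_grid", 10,
                landmark_spec=[("a", 0, 3.0), ("b", 1, 3.0)],
            )

    def test_too_small_mesh_rejected(self):
        with pytest.raises(ValueError, match="mesh too small"):
            syn.generate_mesh("flat_grid", 1)

    def test_triangle_validation(self):
        with pytest.raises(ValueError, match="repeats a vertex"):
            SurfaceMesh(np.zeros((4, 3)), [[0, 0, 1]])


class TestParcellation:
    def test_each_parcel_connected(self, ico_mesh, labeling):
        adj = ico_mesh.adjacency().tocsr()
        for pid in range(1, labeling.n_parcels + 1):
            verts = labeling.parcel_vertices(pid)
            sub = adj[np.ix_(verts, verts)]
            n_comp, _ = connected_components(sub, directed=False)
            assert n_comp == 1, f"parcel {pid} is not spatially contiguous"

    def test_determinism(self, ico_mesh):
        a = syn.generate_parcellation(ico_mesh, 30, 5, seed=7)
        b = syn.generate_parcellation(ico_mesh, 30, 5, seed=7)
        assert np.array_equal(a.vertex_parcel, b.vertex_parcel)
        assert np.array_equal(a.parcel_network, b.parcel_network)

    def test_singleton_parcels_when_saturated(self, grid_mesh):
        lab = syn.generate_parcellation(grid_mesh, grid_mesh.n_vertices, 4, seed=0)
        sizes = np.bincount(lab.vertex_parcel)[1:]
        assert (sizes == 1).all()

    def test_too_many_parcels_rejected(self, grid_mesh):
        with pytest.raises(ValueError):
            syn.generate_parcellation(grid_mesh, grid_mesh.n_vertices + 1, 2)


class TestScalarMap:
    def test_zero_noise_exact(self, labeling):
        means = np.linspace(1.6, 0.9, labeling.n_networks)
        smap, gt = syn.generate_scalar_map(labeling, means, noise_sd=0.0, seed=0)
        net_of_vertex = labeling.parcel_network[labeling.vertex_parcel - 1]
        assert np.array_equal(smap.values, means[net_of_vertex - 1])

    def test_noisy_mean_within_clt_bound(self, labeling):
        means = np.full(labeling.n_networks, 2.0)
        smap, _ = syn.generate_scalar_map(labeling, means, noise_sd=1.0, seed=3)
        for k in range(1, labeling.n_networks + 1):
            sel = labeling.parcel_network[labeling.vertex_parcel - 1] == k
            se = 1.0 / np.sqrt(sel.sum())
            assert abs(smap.values[sel].mean() - 2.0) < 3 * se

    def test_missing_mean_rejected(self, labeling):
        with pytest.raises(ValueError, match="one mean per network"):
            syn.generate_scalar_map(labeling, np.ones(labeling.n_networks - 1))


class TestTimeseries:
    def test_identity_coupling_zero_noise_block_constant(self, labeling):
        spec = syn.default_condition_spec(seed=1, sigma=0.0)
        runs, _ = syn.generate_timeseries(labeling, spec)
        c = np.corrcoef(runs[0].data, rowvar=False)
        net = labeling.parcel_network
        for k in range(1, 9):
            block = c[np.ix_(net == k, net == k)]
            assert np.allclose(block, 1.0, atol=1e-12)

    def test_lag1_autocorrelation_matches_phi(self, labeling):
        spec = syn.default_condition_spec(
            seed=2, sigma=0.0, n_timepoints=5000,
            phi=np.full(labeling.n_networks, 0.5),
        )
        runs, _ = syn.generate_timeseries(labeling, spec)
        x = runs[0].data[:, 0]
        ac1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(ac1 - 0.5) < 0.05

    def test_cross_network_correlation_monotone_in_coupling(self, labeling):
        prev = -1.0
        for c in [0.0, 0.2, 0.4, 0.6, 0.8]:
            m = np.eye(8)
            m[0, 1] = c
            spec = syn.default_condition_spec(seed=5, coupling=m, n_timepoints=2000)
            runs, _ = syn.generate_timeseries(labeling, spec)
            x = runs[0].data
            p0 = np.flatnonzero(labeling.parcel_network == 1)[0]
            p1 = np.flatnonzero(labeling.parcel_network == 2)[0]
            r = np.corrcoef(x[:, p0], x[:, p1])[0, 1]
            assert r > prev
            prev = r

    def test_determinism_and_per_run_independence(self, labeling):
        spec = syn.default_condition_spec(seed=9)
        a, _ = syn.generate_timeseries(labeling, spec, n_subjects=2, n_runs=2)
        b, _ = syn.generate_timeseries(labeling, spec, n_subjects=2, n_runs=2)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.data, rb.data)
        assert not np.allclose(a[0].data, a[1].data)

    def test_subject_subset_reproducible(self, labeling):
        spec = syn.default_condition_spec(seed=9)
        full, _ = syn.generate_timeseries(labeling, spec, n_subjects=3, n_runs=1)
        one, _ = syn.generate_timeseries(labeling, spec, n_subjects=1, n_runs=1)
        assert np.array_equal(full[0].data, one[0].data)

    def test_stationarity_variance_drift(self, labeling):
        spec = syn.default_condition_spec(seed=4, n_timepoints=600)
        runs, _ = syn.generate_timeseries(labeling, spec)
        x = runs[0].data
        half = x.shape[0] // 2
        ratio = x[:half].var(axis=0) / x[half:].var(axis=0)
        assert ((ratio > 0.5) & (ratio < 2.0)).all()

    def test_nonstationary_spec_rejected(self):
        with pytest.raises(ValueError, match="nonstationary"):
            ConditionSpec(phi=np.array([1.0]), coupling=np.eye(1))

    def test_analytic_correlation_matches_sample(self, labeling):
        m = syn.make_coupling({(4, 2): 0.5})
        spec = syn.default_condition_spec(seed=6, coupling=m, n_timepoints=8000)
        runs, _ = syn.generate_timeseries(labeling, spec)
        sample = np.corrcoef(runs[0].data, rowvar=False)
        analytic = syn.analytic_parcel_correlation(spec, labeling)
        off = ~np.eye(sample.shape[0], dtype=bool)
        assert np.abs(sample[off] - analytic[off]).max() < 0.08

    def test_coupling_on_correlation_scale(self, labeling):
        m = syn.make_coupling({(4, 2): 0.6})
        spec = syn.default_condition_spec(seed=0, sigma=0.0, coupling=m)
        corr = syn.analytic_parcel_correlation(spec, labeling)
        pa = np.flatnonzero(labeling.parcel_network == 5)[0]
        pb = np.flatnonzero(labeling.parcel_network == 3)[0]
        assert corr[pa, pb] == pytest.approx(0.6, abs=1e-12)


class TestTaskRun:
    def test_zero_effects_equal_background(self, labeling):
        spec = syn.default_condition_spec(condition="task", seed=3)
        design = syn.make_task_design(seed=1)
        bg, _ = syn.generate_timeseries(labeling, spec)
        task = syn.generate_task_run(labeling, design, GroundTruth(), spec)
        assert np.array_equal(bg[0].data, task.data)

    def test_noiseless_glm_beta_exact(self, labeling):
        from cortnet.inference import glm_univariate

        p = labeling.n_parcels
        spec = syn.default_condition_spec(
            condition="task", seed=3, sigma=0.0, coupling=np.zeros((8, 8))
        )
        design = syn.make_task_design(seed=1)
        effects = GroundTruth(glm_effects={"modulator": np.full(p, 1.0)})
        ts = syn.generate_task_run(labeling, design, effects, spec)
        res = glm_univariate([(ts, design)], model="task_mean+modulator")
        beta = res.run_betas[(ts.subject_id, ts.run_id)]["modulator"]
        assert np.abs(beta - 1.0).max() < 1e-6

    def test_negative_modulator_gives_negative_t(self, labeling):
        from cortnet.inference import glm_univariate

        p = labeling.n_parcels
        spec = syn.default_condition_spec(
            condition="task", seed=3, sigma=0.01, coupling=np.eye(8) * 0.01
        )
        design = syn.make_task_design(seed=1)
        effects = GroundTruth(glm_effects={"modulator": np.full(p, -0.5)})
        runs = [
            (syn.generate_task_run(labeling, design, effects, spec, subject=s), design)
            for s in range(1, 6)
        ]
        res = glm_univariate(runs, model="task_mean+modulator")
        assert (res.group_t < 0).all()

    def test_event_beyond_scan_rejected(self, labeling):
        spec = syn.default_condition_spec(condition="task", seed=0, n_timepoints=20)
        design = syn.make_task_design(n_events=10, seed=0)
        with pytest.raises(ValueError, match="beyond scan end"):
            syn.generate_task_run(labeling, design, GroundTruth(), spec)

    def test_modulators_demeaned(self):
        d = syn.make_task_design(n_events=15, accuracy=0.8, seed=2)
        assert abs(d.modulators[d.correct].sum()) < 1e-9
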