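"""Synthetic cortex generator.

Produces triangulated surfaces with landmark vertex sets, spatially
contiguous parcellations grouped into networks, network-graded scalar maps,
and multi-subject parcel time series whose statistical structure (temporal
autocorrelation, network-block covariance, condition-dependent coupling,
task-evoked responses) is known exactly, so that every downstream stage of
the pipeline can be validated against ground truth.

The generative model for time series is deliberately minimal: each network
n carries a latent AR(1) signal z_n(t) driven by unit-variance Gaussian
innovations, and each parcel observes a linear mixture of the latents
through the coupling matrix row of its network, plus white observation
noise.  This is the simplest model exhibiting everything the analysis
measures — per-network timescales, block-structured covariance, and
condition differences in cross-network coupling.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import trimesh
from scipy.signal import lfilter

from .hrf import convolve_hrf, events_to_boxcar
from .types import (
    ConditionSpec,
    GroundTruth,
    ParcelLabeling,
    ParcelTimeSeries,
    ScalarVertexMap,
    SurfaceMesh,
    TaskDesign,
)

__all__ = [
    "generate_mesh",
    "generate_parcellation",
    "generate_scalar_map",
    "generate_timeseries",
    "generate_task_run",
    "make_task_design",
    "generate_fd_trace",
    "analytic_parcel_correlation",
    "default_networks",
    "default_condition_spec",
    "condition_pair_specs",
    "AR_BURN_IN",
]

#: Samples discarded before returning AR series, so initial-condition
#: transients do not bias autocorrelation estimates.
AR_BURN_IN = 100

#: Default network labels for the 8-network study configuration.  The
#: frontoparietal (FPCN), dorsal-attention (DAN) and default-mode (DMN)
#: subnetworks are the systems whose interactions the pipeline contrasts.
DEFAULT_NETWORK_NAMES = [
    "Visual",
    "Somatomotor",
    "DAN-A",
    "DAN-B",
    "FPCN-A",
    "FPCN-B",
    "DMN-A",
    "DMN-B",
]

#: Per-network AR(1) coefficients: a graded timescale hierarchy from
#: fast sensory networks to slow default-mode networks.
DEFAULT_PHI = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])

#: Observation noise of the same order as the latent signal SD, putting
#: classification in the intermediate-accuracy regime where confusion
#: probabilities carry information (real parcel data is far from
#: perfectly separable).
DEFAULT_SIGMA = 1.0
DEFAULT_N_TIMEPOINTS = 400
DEFAULT_TR_S = 1.5
DEFAULT_N_PARCELS = 68
DEFAULT_N_SUBJECTS = 12
DEFAULT_N_RUNS = 2


def default_networks() -> list[str]:
    return list(DEFAULT_NETWORK_NAMES)


# ---------------------------------------------------------------------------
# meshes


def _flat_grid(resolution: int) -> tuple[np.ndarray, np.ndarray]:
    """n x n planar grid (1 mm spacing), each cell split along one diagonal."""
    if resolution < 2:
        raise ValueError("mesh too small")
    n = resolution
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    coords = np.column_stack([ii.ravel(), jj.ravel(), np.zeros(n * n)]).astype(float)

    def vid(i, j):
        return i * n + j

    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            v00, v10 = vid(i, j), vid(i + 1, j)
            v01, v11 = vid(i, j + 1), vid(i + 1, j + 1)
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    return coords, np.asarray(tris, dtype=np.int64)


def _icosphere(subdivisions: int, radius: float = 100.0) -> tuple[np.ndarray, np.ndarray]:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=np.int64)


def _cap_vertices(
    coords: np.ndarray, triangles: np.ndarray, anchor: int, radius: float
) -> np.ndarray:
    """Vertices within graph geodesic `radius` of the anchor (always
    includes the anchor itself, so radius 0 gives a point landmark)."""
    if radius <= 0:
        return np.array([anchor], dtype=np.int64)
    from scipy.sparse.csgraph import dijkstra

    mesh = SurfaceMesh(coords, triangles)
    d = dijkstra(mesh.adjacency().tocsr(), indices=[anchor], min_only=True)
    return np.flatnonzero(d <= radius)


def default_landmark_spec(kind: str) -> list[tuple[str, str, float]]:
    """Three well-separated geodesic caps emulating the primary
    somatomotor, auditory and visual landmarks (central sulcus, transverse
    temporal sulcus, calcarine sulcus)."""
    anchors = {
        "flat_grid": [("central_sulcus", "corner00", 1.5),
                      ("transverse_temporal", "corner11", 1.5),
                      ("calcarine", "corner01", 1.5)],
        "icosphere": [("central_sulcus", "pole_z", 15.0),
                      ("transverse_temporal", "pole_x", 15.0),
                      ("calcarine", "pole_neg_y", 15.0)],
    }
    return anchors[kind]


def _resolve_anchor(name_or_idx, coords: np.ndarray) -> int:
    if isinstance(name_or_idx, (int, np.integer)):
        return int(name_or_idx)
    directions = {
        "pole_z": np.array([0.0, 0.0, 1.0]),
        "pole_x": np.array([1.0, 0.0, 0.0]),
        "pole_neg_y": np.array([0.0, -1.0, 0.0]),
    }
    if name_or_idx in directions:
        return int(np.argmax(coords @ directions[name_or_idx]))
    corners = {
        "corner00": coords.min(axis=0)[:2] * np.array([1, 1]),
        "corner11": coords.max(axis=0)[:2],
        "corner01": np.array([coords[:, 0].min(), coords[:, 1].max()]),
        "corner10": np.array([coords[:, 0].max(), coords[:, 1].min()]),
    }
    if name_or_idx in corners:
        target = corners[name_or_idx]
        return int(np.argmin(np.sum((coords[:, :2] - target) ** 2, axis=1)))
    raise ValueError(f"unknown landmark anchor {name_or_idx!r}")


def generate_mesh(
    kind: str = "flat_grid",
    resolution: int = 20,
    landmark_spec: list[tuple] | None = None,
    seed: int = 0,
) -> SurfaceMesh:
    """Build a connected triangulated mesh with landmark vertex sets.

    Parameters
    ----------
    kind : {"flat_grid", "icosphere"}
        Planar n x n grid (resolution = n) or subdivided icosphere
        (resolution = number of subdivisions; vertex count 10*4^r + 2).
    landmark_spec : list of (name, anchor, radius_mm)
        Anchor is a vertex index or a named position; the landmark is the
        geodesic cap of the given radius around it.  Caps must not overlap.
    seed : int
        Unused for the deterministic mesh kinds; kept for interface
        uniformity with the other generators.
    """
    if kind == "flat_grid":
        coords, tris = _flat_grid(resolution)
    elif kind == "icosphere":
        if resolution < 0:
            raise ValueError("mesh too small")
        coords, tris = _icosphere(resolution)
    else:
        raise ValueError(f"unknown mesh kind {kind!r}")

    if landmark_spec is None:
        landmark_spec = default_landmark_spec(kind)
    landmarks: dict[str, np.ndarray] = {}
    for name, anchor, radius in landmark_spec:
        a = _resolve_anchor(anchor, coords)
        landmarks[name] = _cap_vertices(coords, tris, a, radius)
    # SurfaceMesh validation raises "landmarks overlap" on intersecting caps
    return SurfaceMesh(coords, tris, landmarks)


# ---------------------------------------------------------------------------
# parcellation


def generate_parcellation(
    mesh: SurfaceMesh,
    n_parcels: int = DEFAULT_N_PARCELS,
    n_networks: int = 8,
    seed: int = 0,
    network_names: list[str] | None = None,
) -> ParcelLabeling:
    """Spatially contiguous parcels via seeded multi-source region growing.

    Parcel seeds are drawn uniformly without replacement; parcels then claim
    unassigned neighbours in deterministic breadth-first waves, so identical
    seeds reproduce identical labelings.  Parcels are assigned to networks
    round-robin, guaranteeing every network is nonempty.
    """
    n_vertices = mesh.n_vertices
    if n_parcels > n_vertices:
        raise ValueError("n_parcels exceeds vertex count")
    if n_networks > n_parcels:
        raise ValueError("n_networks exceeds n_parcels")
    rng = np.random.default_rng(seed)
    seeds = np.sort(rng.choice(n_vertices, size=n_parcels, replace=False))
    # vertex adjacency lists (sorted for determinism)
    edges = mesh.edges()
    nbrs: list[list[int]] = [[] for _ in range(n_vertices)]
    for u, v in edges:
        nbrs[u].append(int(v))
        nbrs[v].append(int(u))
    nbrs = [sorted(x) for x in nbrs]

    assign = np.full(n_vertices, -1, dtype=np.int64)
    frontiers: list[list[int]] = []
    for pid, s in enumerate(seeds, start=1):
        assign[s] = pid
        frontiers.append([int(s)])
    remaining = n_vertices - n_parcels
    while remaining > 0:
        progress = False
        for pid in range(1, n_parcels + 1):
            new_frontier: list[int] = []
            for v in frontiers[pid - 1]:
                for w in nbrs[v]:
                    if assign[w] == -1:
                        assign[w] = pid
                        new_frontier.append(w)
                        remaining -= 1
            if new_frontier:
                progress = True
            frontiers[pid - 1] = new_frontier if new_frontier else frontiers[pid - 1]
        if not progress:
            raise ValueError("mesh is disconnected; region growing stalled")

    if network_names is None:
        if n_networks == 8:
            network_names = default_networks()
        else:
            network_names = [f"Net-{k:02d}" for k in range(1, n_networks + 1)]
    parcel_network = (np.arange(n_parcels) % n_networks) + 1
    return ParcelLabeling(assign, parcel_network, list(network_names))


# ---------------------------------------------------------------------------
# scalar maps


def generate_scalar_map(
    labeling: ParcelLabeling,
    network_means,
    noise_sd: float = 0.0,
    seed: int = 0,
    role: str = "scalar",
) -> tuple[ScalarVertexMap, GroundTruth]:
    """Vertex value = its parcel's network mean + i.i.d. Gaussian noise."""
    means = np.asarray(network_means, dtype=float)
    if means.shape != (labeling.n_networks,):
        raise ValueError("need exactly one mean per network")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    net_of_vertex = labeling.parcel_network[labeling.vertex_parcel - 1]
    values = means[net_of_vertex - 1] + noise_sd * rng.standard_normal(
        labeling.n_vertices
    )
    gt = GroundTruth(network_means={role: means})
    return ScalarVertexMap(values, role=role), gt


# ---------------------------------------------------------------------------
# time series


def _run_seed(master_seed: int, subject: int, run: int) -> np.random.Generator:
    """Independent, reproducible stream per (subject, run)."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, subject, run)))


def _simulate_latents(spec: ConditionSpec, rng: np.random.Generator) -> np.ndarray:
    """(T, K) latent AR(1) network signals after burn-in."""
    total = spec.n_timepoints + AR_BURN_IN
    innovations = rng.standard_normal((total, spec.n_networks))
    z = np.empty_like(innovations)
    for n in range(spec.n_networks):
        z[:, n] = lfilter([1.0], [1.0, -spec.phi[n]], innovations[:, n])
    return z[AR_BURN_IN:]


def _mix_to_parcels(
    z: np.ndarray, labeling: ParcelLabeling, spec: ConditionSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    net_signals = z @ spec.coupling.T  # (T, K): signal observed by network k
    x = net_signals[:, labeling.parcel_network - 1]
    if spec.sigma > 0:
        x = x + spec.sigma * rng.standard_normal(x.shape)
    return x


def generate_timeseries(
    labeling: ParcelLabeling,
    spec: ConditionSpec,
    n_subjects: int = 1,
    n_runs: int = 1,
) -> tuple[list[ParcelTimeSeries], GroundTruth]:
    """Simulate parcel time series for every subject and run of a condition.

    Innovations are independent across (subject, run); the stream for each
    pair is derived deterministically from (spec.seed, subject, run) so any
    subset of subjects is reproducible in isolation.
    """
    if spec.n_networks != labeling.n_networks:
        raise ValueError("spec and labeling disagree on network count")
    out = []
    for s in range(1, n_subjects + 1):
        for r in range(1, n_runs + 1):
            rng = _run_seed(spec.seed, s, r)
            z = _simulate_latents(spec, rng)
            x = _mix_to_parcels(z, labeling, spec, rng)
            out.append(
                ParcelTimeSeries(
                    x,
                    sampling_interval_s=spec.sampling_interval_s,
                    subject_id=f"sub-{s:02d}",
                    run_id=f"run-{r:02d}",
                    condition=spec.condition,
                )
            )
    gt = GroundTruth(
        coupling_by_condition={spec.condition: spec.coupling.copy()},
        extras={"phi": spec.phi.copy(), "sigma": spec.sigma},
    )
    return out, gt


def analytic_parcel_correlation(
    spec: ConditionSpec, labeling: ParcelLabeling
) -> np.ndarray:
    """Closed-form parcel-pair correlation implied by the generative model.

    Latent n has variance 1/(1 - phi_n^2); parcels mix the independent
    latents linearly and add sigma^2 of white noise, so the covariance is
    W diag(var) W' + sigma^2 I with W the per-parcel mixing rows.
    """
    lat_var = 1.0 / (1.0 - spec.phi**2)
    w = spec.coupling[labeling.parcel_network - 1]  # (P, K)
    cov = (w * lat_var) @ w.T
    cov[np.diag_indices_from(cov)] += spec.sigma**2
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


# ---------------------------------------------------------------------------
# task runs


def make_task_design(
    n_events: int = 20,
    trial_duration_s: float = 3.0,
    iti_s: float = 6.0,
    first_onset_s: float = 10.0,
    trial_types: np.ndarray | None = None,
    modulators: np.ndarray | None = None,
    accuracy: float = 1.0,
    seed: int = 0,
) -> TaskDesign:
    """Regular event design with an optional demeaned parametric modulator.

    Modulators are demeaned over correct trials at construction (incorrect
    trials are modelled separately as nuisance events downstream).
    """
    rng = np.random.default_rng(seed)
    onsets = first_onset_s + np.arange(n_events) * (trial_duration_s + iti_s)
    durations = np.full(n_events, trial_duration_s)
    if trial_types is None:
        trial_types = np.where(np.arange(n_events) % 2 == 0, "easy", "hard")
    correct = rng.random(n_events) < accuracy
    if not correct.any():
        correct[0] = True
    if modulators is None:
        modulators = rng.uniform(-1.0, 1.0, n_events)
    modulators = np.asarray(modulators, dtype=float).copy()
    modulators[correct] -= modulators[correct].mean()
    modulators[~correct] = 0.0
    return TaskDesign(onsets, durations, np.asarray(trial_types), modulators, correct)


def generate_task_run(
    labeling: ParcelLabeling,
    design: TaskDesign,
    effects: GroundTruth,
    spec: ConditionSpec,
    subject: int = 1,
    run: int = 1,
) -> ParcelTimeSeries:
    """Add HRF-convolved task signal to a background run.

    ``effects.glm_effects`` may contain per-parcel amplitude vectors under
    the keys "task_mean", "modulator" and "incorrect"; each scales the
    corresponding canonical-HRF-convolved regressor.  Condition-specific
    keys "easy"/"hard" scale per-trial-type regressors instead.
    """
    t_end = spec.n_timepoints * spec.sampling_interval_s
    if design.end_time() > t_end:
        raise ValueError("event beyond scan end")
    rng = _run_seed(spec.seed, subject, run)
    z = _simulate_latents(spec, rng)
    x = _mix_to_parcels(z, labeling, spec, rng)

    p = labeling.n_parcels
    tr = spec.sampling_interval_s
    nt = spec.n_timepoints

    def add(mask: np.ndarray, amplitudes: np.ndarray, betas: np.ndarray) -> None:
        if not mask.any():
            return
        stim = events_to_boxcar(
            design.onsets[mask], design.durations[mask], amplitudes[mask], nt, tr
        )
        reg = convolve_hrf(stim, tr)
        nonlocal x
        x = x + np.outer(reg, betas)

    eff = effects.glm_effects
    ones = np.ones(design.n_events)
    if "task_mean" in eff:
        add(design.correct, ones, np.broadcast_to(eff["task_mean"], (p,)))
    if "modulator" in eff:
        add(design.correct, design.modulators, np.broadcast_to(eff["modulator"], (p,)))
    for cond in ("easy", "hard"):
        if cond in eff:
            add(
                design.correct & (design.trial_types == cond),
                ones,
                np.broadcast_to(eff[cond], (p,)),
            )
    if "incorrect" in eff:
        add(~design.correct, ones, np.broadcast_to(eff["incorrect"], (p,)))

    return ParcelTimeSeries(
        x,
        sampling_interval_s=tr,
        subject_id=f"sub-{subject:02d}",
        run_id=f"run-{run:02d}",
        condition=spec.condition,
    )


# ---------------------------------------------------------------------------
# motion traces (for QC tests only)


def generate_fd_trace(
    n_frames: int,
    baseline_mm: float = 0.08,
    spike_fraction: float = 0.0,
    spike_mm: float = 0.4,
    seed: int = 0,
) -> np.ndarray:
    """Framewise-displacement trace: folded-normal baseline plus spikes."""
    rng = np.random.default_rng(seed)
    fd = np.abs(rng.normal(baseline_mm, baseline_mm / 4, n_frames))
    n_spikes = int(round(spike_fraction * n_frames))
    if n_spikes:
        idx = rng.choice(n_frames, n_spikes, replace=False)
        fd[idx] = spike_mm
    return fd


# ---------------------------------------------------------------------------
# study-condition defaults


def default_condition_spec(
    condition: str = "rest", seed: int = 0, **overrides
) -> ConditionSpec:
    """The default 8-network study configuration (timescale hierarchy,
    identity coupling, moderate observation noise)."""
    kw = dict(
        phi=DEFAULT_PHI.copy(),
        coupling=np.eye(len(DEFAULT_PHI)),
        sigma=DEFAULT_SIGMA,
        n_timepoints=DEFAULT_N_TIMEPOINTS,
        sampling_interval_s=DEFAULT_TR_S,
        condition=condition,
        seed=seed,
    )
    kw.update(overrides)
    return ConditionSpec(**kw)


def make_coupling(
    pairs: dict[tuple[int, int], float], phi: np.ndarray | None = None
) -> np.ndarray:
    """Coupling matrix from correlation-scale coupling strengths.

    ``pairs[(a, b)] = c`` makes network a's observed signal correlate with
    network b's latent at exactly c while preserving a's signal variance:
    the mixture is sqrt(1 - sum c^2) of a's standardized latent plus c of
    each partner's standardized latent, rescaled to a's latent SD.  This
    keeps coupling orthogonal to amplitude, so increasing c moves a's
    temporal fingerprint toward b without changing its variance.
    """
    if phi is None:
        phi = DEFAULT_PHI
    phi = np.asarray(phi, dtype=float)
    v = 1.0 / (1.0 - phi**2)
    k = phi.shape[0]
    m = np.eye(k)
    by_row: dict[int, dict[int, float]] = {}
    for (a, b), c in pairs.items():
        if a == b:
            raise ValueError("coupling pairs must join distinct networks")
        by_row.setdefault(a, {})[b] = float(c)
    for a, targets in by_row.items():
        total = sum(c**2 for c in targets.values())
        if total > 1.0:
            raise ValueError("summed squared couplings exceed 1 for one network")
        m[a, a] = np.sqrt(1.0 - total)
        for b, c in targets.items():
            m[a, b] = c * np.sqrt(v[a] / v[b])
    return m


def condition_pair_specs(
    seed: int = 0,
    strong: float = 0.6,
    weak: float = 0.3,
    names: tuple[str, str] = ("wm", "sem"),
) -> tuple[ConditionSpec, ConditionSpec]:
    """Two task conditions with opposite FPCN-A coupling profiles.

    In the working-memory-like condition FPCN-A couples strongly with
    DAN-A and weakly with FPCN-B; in the semantic-like condition the
    profile is reversed.  This is the condition-dependent interaction
    regime the pipeline is built to detect.
    """
    nets = default_networks()
    i_fpcn_a = nets.index("FPCN-A")
    i_dan_a = nets.index("DAN-A")
    i_fpcn_b = nets.index("FPCN-B")
    m_wm = make_coupling({(i_fpcn_a, i_dan_a): strong, (i_fpcn_a, i_fpcn_b): weak})
    m_sem = make_coupling({(i_fpcn_a, i_dan_a): weak, (i_fpcn_a, i_fpcn_b): strong})
    a = default_condition_spec(condition=names[0], seed=seed, coupling=m_wm)
    b = default_condition_spec(condition=names[1], seed=seed + 1, coupling=m_sem)
    return a, b
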