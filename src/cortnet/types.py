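"""Core data containers shared by every pipeline stage.

All containers are plain dataclasses holding numpy arrays, validated at
construction. Parcel and network identifiers are 1-based throughout (the
convention of parcellation label tables); vertex indices are 0-based.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SurfaceMesh",
    "ParcelLabeling",
    "ScalarVertexMap",
    "ParcelTimeSeries",
    "ConditionSpec",
    "TaskDesign",
    "GroundTruth",
]


@dataclass
class SurfaceMesh:
    """Triangulated cortical surface with named landmark vertex sets.

    Parameters
    ----------
    vertex_coords : (n_vertices, 3) float array, mm
    triangles : (n_triangles, 3) int array of vertex indices
    landmark_sets : mapping of landmark name -> sorted array of vertex indices
        Emulates anatomical landmarks such as the central sulcus, transverse
        temporal sulcus and calcarine sulcus.
    """

    vertex_coords: np.ndarray
    triangles: np.ndarray
    landmark_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertex_coords.ndim != 2 or self.vertex_coords.shape[1] != 3:
            raise ValueError("vertex_coords must be (n_vertices, 3)")
        n = self.n_vertices
        if n < 3:
            raise ValueError("mesh too small")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (n_triangles, 3)")
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=0) >= n:
            raise ValueError("triangle references an invalid vertex index")
        degenerate = (
            (self.triangles[:, 0] == self.triangles[:, 1])
            | (self.triangles[:, 0] == self.triangles[:, 2])
            | (self.triangles[:, 1] == self.triangles[:, 2])
        )
        if degenerate.any():
            raise ValueError("triangle repeats a vertex")
        self.landmark_sets = {
            k: np.unique(np.asarray(v, dtype=np.int64))
            for k, v in self.landmark_sets.items()
        }
        seen: set[int] = set()
        for name, idx in self.landmark_sets.items():
            if idx.size == 0:
                raise ValueError(f"landmark set {name!r} is empty")
            if idx.min() < 0 or idx.max() >= n:
                raise ValueError(f"landmark set {name!r} references invalid vertices")
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise ValueError("landmarks overlap")
            seen.update(idx.tolist())

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges (n_edges, 2), sorted pairs."""
        t = self.triangles
        pairs = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        pairs = np.sort(pairs, axis=1)
        return np.unique(pairs, axis=0)

    def adjacency(self) -> coo_matrix:
        """Symmetric vertex adjacency with Euclidean edge lengths."""
        e = self.edges()
        w = np.linalg.norm(
            self.vertex_coords[e[:, 0]] - self.vertex_coords[e[:, 1]], axis=1
        )
        n = self.n_vertices
        return coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]),
                                      np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(n, n),
        )

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency().tocsr(), directed=False)
        return n_comp == 1


@dataclass
class ParcelLabeling:
    """Vertex -> parcel and parcel -> network assignment.

    ``vertex_parcel`` holds parcel ids 1..P per vertex; ``parcel_network``
    holds network ids 1..K indexed by parcel-1; ``network_names`` is ordered
    by network id.
    """

    vertex_parcel: np.ndarray
    parcel_network: np.ndarray
    network_names: list[str]

    def __post_init__(self) -> None:
        self.vertex_parcel = np.asarray(self.vertex_parcel, dtype=np.int64)
        self.parcel_network = np.asarray(self.parcel_network, dtype=np.int64)
        p = self.n_parcels
        if p == 0:
            raise ValueError("labeling has no parcels")
        used = np.unique(self.vertex_parcel)
        if used.min() < 1 or used.max() > p:
            raise ValueError("vertex references a parcel id outside 1..n_parcels")
        if used.size != p:
            raise ValueError("every parcel must have at least one vertex")
        k = len(self.network_names)
        nets = np.unique(self.parcel_network)
        if nets.min() < 1 or nets.max() > k:
            raise ValueError("network ids must be contiguous 1..K")
        if nets.size != k:
            raise ValueError("every network must own at least one parcel")

    @property
    def n_vertices(self) -> int:
        return self.vertex_parcel.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.parcel_network.shape[0]

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    def parcel_vertices(self, parcel_id: int) -> np.ndarray:
        return np.flatnonzero(self.vertex_parcel == parcel_id)

    def network_of_parcels(self) -> np.ndarray:
        """Network id (1..K) per parcel, index parcel-1."""
        return self.parcel_network

    def parcels_in_network(self, network_id: int) -> np.ndarray:
        """Parcel ids (1-based) belonging to a network."""
        return np.flatnonzero(self.parcel_network == network_id) + 1


@dataclass
class ScalarVertexMap:
    """One scalar per vertex (myelin ratio, thickness mm, expansion, ...)."""

    values: np.ndarray
    role: str = "scalar"
    mask: np.ndarray | None = None  # True = valid; None = all valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")
            if not np.isfinite(self.values[self.mask]).all():
                raise ValueError("non-finite values inside the valid mask")
        elif not np.isfinite(self.values).all():
            raise ValueError("non-finite values without a mask")


@dataclass
class ParcelTimeSeries:
    """Run-level parcel x time data, stored as (time, parcel)."""

    data: np.ndarray
    sampling_interval_s: float
    subject_id: str = "sub-01"
    run_id: str = "run-01"
    condition: str = "rest"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("data must be (time >= 2, parcels)")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite time-series values")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclass
class ConditionSpec:
    """Statistical structure of one simulated condition.

    Latent network signals are AR(1) with coefficient ``phi[n]`` driven by
    unit-variance innovations; parcel signals mix the latents through the
    rows of ``coupling`` (network x network) plus white observation noise.
    """

    phi: np.ndarray
    coupling: np.ndarray
    sigma: float = 0.5
    n_timepoints: int = 400
    sampling_interval_s: float = 1.5
    condition: str = "rest"
    seed: int = 0

    def __post_init__(self) -> None:
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.coupling = np.atleast_2d(np.asarray(self.coupling, dtype=float))
        k = self.phi.shape[0]
        if self.coupling.shape != (k, k):
            raise ValueError("coupling must be (n_networks, n_networks)")
        if not np.isfinite(self.coupling).all():
            raise ValueError("coupling must be finite")
        if np.any(np.abs(self.phi) >= 1):
            raise ValueError("nonstationary spec")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 time points")

    @property
    def n_networks(self) -> int:
        return self.phi.shape[0]


@dataclass
class TaskDesign:
    """Event table for one task run (BIDS-style events)."""

    onsets: np.ndarray          # seconds
    durations: np.ndarray       # seconds
    trial_types: np.ndarray     # condition label per event
    modulators: np.ndarray      # demeaned parametric value per event
    correct: np.ndarray         # bool per event

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.trial_types = np.asarray(self.trial_types)
        self.modulators = np.asarray(self.modulators, dtype=float)
        self.correct = np.asarray(self.correct, dtype=bool)
        n = self.onsets.shape[0]
        for arr, name in [
            (self.durations, "durations"),
            (self.trial_types, "trial_types"),
            (self.modulators, "modulators"),
            (self.correct, "correct"),
        ]:
            if arr.shape[0] != n:
                raise ValueError(f"{name} length mismatch")
        if n and np.any(np.diff(self.onsets) < 0):
            raise ValueError("onsets must be nondecreasing")
        if n and np.any(self.durations <= 0):
            raise ValueError("durations must be positive")
        if n and abs(self.modulators[self.correct].sum()) > 1e-6 * max(
            1.0, np.abs(self.modulators).max(initial=0.0)
        ):
            raise ValueError("modulator values must be demeaned (sum ~ 0)")

    @property
    def n_events(self) -> int:
        return self.onsets.shape[0]

    def end_time(self) -> float:
        if self.n_events == 0:
            return 0.0
        return float(np.max(self.onsets + self.durations))


@dataclass
class GroundTruth:
    """Bookkeeping of the true parameters behind a synthetic dataset."""

    coupling_by_condition: dict[str, np.ndarray] = field(default_factory=dict)
    glm_effects: dict[str, np.ndarray] = field(default_factory=dict)
    network_means: Mapping[str, np.ndarray] | dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)
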