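"""Connectivity matrices and diffusion-map connectivity gradients.

The principal gradient of the diffusion embedding orders parcels along the
unimodal-transmodal axis of cortical organization.  The embedding follows
the standard diffusion-map recipe on a sparsified connectivity matrix:
per-row retention of the strongest 10% of entries (sparsity 0.9), negative
weights clamped to zero (a diffusion operator needs a nonnegative
affinity), symmetrization by averaging with the transpose, anisotropic
normalization with alpha = 0.5, and eigendecomposition of the resulting
row-stochastic operator with multiscale (diffusion-time-0) component
scaling lambda/(1-lambda).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.stats import skew

from .types import ParcelTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "GradientSet",
    "connectivity_matrix",
    "average_connectivity",
    "diffusion_gradients",
    "procrustes_align",
    "identify_principal_gradient",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric parcel x parcel correlation matrix with provenance tags."""

    matrix: np.ndarray
    subject_id: str = ""
    run_id: str = ""
    condition: str = ""
    adjusted: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectivity matrix must be square")
        finite = np.isfinite(m)
        if finite.all():
            if np.abs(m - m.T).max(initial=0.0) > 1e-10:
                raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_parcels(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GradientSet:
    """Parcel x component gradient values with explained-variance ratios."""

    values: np.ndarray
    explained_variance: np.ndarray
    sparsity: float = 0.9
    alpha: float = 0.5
    n_components: int = 10

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("gradient values must be 2-D")
        ev = self.explained_variance
        if ev.shape[0] != self.values.shape[1]:
            raise ValueError("one explained-variance ratio per component")
        if ev.size and (np.any(ev < -1e-12) or np.any(np.diff(ev) > 1e-12)):
            raise ValueError("explained variance must be nonnegative, nonincreasing")


def connectivity_matrix(ts: ParcelTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between parcel time courses.

    Zero-variance parcels get NaN rows/columns (diagonal kept at 1).
    """
    x = ts.data
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    sd = x.std(axis=0)
    dead = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c[dead, :] = np.nan
    c[:, dead] = np.nan
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(
        c, subject_id=ts.subject_id, run_id=ts.run_id, condition=ts.condition
    )


def average_connectivity(mats: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Group matrix: arithmetic mean of individual correlation matrices
    (no Fisher-z averaging)."""
    if not mats:
        raise ValueError("no matrices to average")
    stack = np.stack([m.matrix for m in mats])
    return ConnectivityMatrix(stack.mean(axis=0), subject_id="group")


def _sparsify(matrix: np.ndarray, sparsity: float) -> np.ndarray:
    """Per row, keep the largest (1 - sparsity) fraction of entries, zero
    the rest, clamp negatives to 0, then symmetrize by transpose-averaging
    (row-wise top-k breaks symmetry)."""
    p = matrix.shape[0]
    keep = max(1, int(round((1.0 - sparsity) * p)))
    a = np.array(matrix, dtype=float, copy=True)
    # zero everything below each row's k-th largest value
    thresh = np.partition(a, p - keep, axis=1)[:, p - keep]
    a[a < thresh[:, None]] = 0.0
    np.clip(a, 0.0, None, out=a)
    return 0.5 * (a + a.T)


def diffusion_gradients(
    conn: ConnectivityMatrix,
    sparsity: float = 0.9,
    n_components: int = 10,
    alpha: float = 0.5,
) -> GradientSet:
    """Diffusion-map embedding of a connectivity matrix.

    Components are ordered by eigenvalue of the diffusion operator;
    explained variance is each eigenvalue divided by the sum of all
    nontrivial nonnegative eigenvalues.  Each component's sign is fixed so
    its skewness is nonnegative (a deterministic convention applied before
    any Procrustes alignment).
    """
    m = conn.matrix
    if not np.isfinite(m).all():
        raise ValueError("connectivity matrix contains missing values")
    affinity = _sparsify(m, sparsity)
    d = affinity.sum(axis=1)
    if np.any(d == 0):
        raise ValueError("isolated parcel")
    # anisotropic normalization: W = A / (d_i^alpha d_j^alpha)
    da = d**alpha
    w = affinity / np.outer(da, da)
    d2 = w.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d2)
    s = w * np.outer(inv_sqrt, inv_sqrt)  # symmetric conjugate of D^-1 W
    s = 0.5 * (s + s.T)
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of the row-stochastic operator
    psi = evecs * inv_sqrt[:, None]
    # scale so the trivial eigenvector is ~constant 1; a scalar norm keeps
    # this well defined even when sparsification disconnects the graph
    scale0 = np.median(np.abs(psi[:, 0]))
    if scale0 > 0:
        psi = psi / scale0
    # a disconnected affinity has one unit eigenvalue per component; all
    # of them are trivial (constant within components, no diffusion
    # structure) and would blow up the multiscale scaling
    n_trivial = max(1, int(np.sum(evals > 1.0 - 1e-9)))
    nontrivial = evals[n_trivial:]
    pos = np.clip(nontrivial, 0.0, None)
    total = pos.sum()
    n_keep = min(n_components, nontrivial.shape[0])
    lam = nontrivial[:n_keep]
    # diffusion time 0: multiscale scaling lambda / (1 - lambda)
    scale = lam / (1.0 - np.clip(lam, None, 1.0 - 1e-12))
    grads = psi[:, n_trivial : n_trivial + n_keep] * scale
    sign = np.where(skew(grads, axis=0) >= 0, 1.0, -1.0)
    grads = grads * sign
    ev_ratio = (np.clip(lam, 0.0, None) / total) if total > 0 else np.zeros(n_keep)
    return GradientSet(
        grads, ev_ratio, sparsity=sparsity, alpha=alpha, n_components=n_components
    )


def procrustes_align(
    individual: GradientSet, reference: GradientSet, n_iterations: int = 10
) -> GradientSet:
    """Align an individual's gradients to a reference by orthogonal
    Procrustes rotation (no scaling; columns centred first), iterated
    against the running reference."""
    x = individual.values
    ref = reference.values
    if x.shape != ref.shape:
        raise ValueError("gradient sets must share parcel and component counts")
    xc = x - x.mean(axis=0)
    refc = ref - ref.mean(axis=0)
    aligned = xc
    for _ in range(max(1, n_iterations)):
        r, _ = orthogonal_procrustes(aligned, refc)
        aligned = aligned @ r
    return GradientSet(
        aligned + ref.mean(axis=0),
        individual.explained_variance,
        sparsity=individual.sparsity,
        alpha=individual.alpha,
        n_components=individual.n_components,
    )


def identify_principal_gradient(
    gs: GradientSet, reference_map: np.ndarray, min_abs_corr: float = 0.2
) -> dict:
    """Find the component best matching a unimodal-transmodal template.

    Returns the 0-based component index, the orientation sign that makes
    transmodal (template-high) parcels positive, whether that component is
    the first, and the matched |correlation|.  If no component reaches
    ``min_abs_corr`` the result is flagged.
    """
    template = np.asarray(reference_map, dtype=float)
    if not np.isfinite(template).all():
        raise ValueError("template must be finite")
    corrs = np.array(
        [np.corrcoef(gs.values[:, j], template)[0, 1] for j in range(gs.values.shape[1])]
    )
    corrs = np.nan_to_num(corrs)
    idx = int(np.argmax(np.abs(corrs)))
    return {
        "component": idx,
        "sign": 1.0 if corrs[idx] >= 0 else -1.0,
        "is_first": idx == 0,
        "abs_correlation": float(abs(corrs[idx])),
        "found": bool(abs(corrs[idx]) >= min_abs_corr),
    }
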