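"""Model-based interaction measures between parcel time series.

Two complementary metrics:

* **Temporally persistent redundancy** (nats): the information about the
  system's next state carried by *both* regions individually.  Under the
  Gaussian assumption every lagged mutual information has the closed form
  I = -1/2 ln(1 - rho^2), and the redundancy is the minimal-mutual-
  information (MMI) double redundancy — the minimum of the four lagged
  pairwise MIs I(x_t; x_{t+tau}), I(x_t; y_{t+tau}), I(y_t; x_{t+tau}),
  I(y_t; y_{t+tau}).

* **Autocorrelation-adjusted functional connectivity** (z): the Pearson
  correlation z-scored with a variance estimated from the Bartlett-type
  expansion over sample auto- and cross-correlations of both series
  (truncated at ceil(2*sqrt(N)) lags with a Tukey taper).  Smooth fMRI
  series violate the nominal 1/(N-3) variance of the naive Fisher z; the
  adjustment restores calibration of the implied test.

Task runs are first cleared of mean evoked responses by finite-impulse-
response (FIR) regression, and redundancy is computed on HRF-deconvolved
series by default.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hrf import canonical_hrf
from .types import ParcelTimeSeries, TaskDesign

__all__ = [
    "InteractionMatrix",
    "build_fir_basis",
    "fir_task_regression",
    "hrf_deconvolve",
    "gaussian_lagged_mi",
    "persistent_redundancy",
    "redundancy_matrix",
    "adjusted_correlation_z",
    "adjusted_fc_matrix",
    "naive_z",
]

_R_CLIP = 1.0 - 1e-7


@dataclass
class InteractionMatrix:
    """Parcel x parcel interaction values with a metric tag."""

    matrix: np.ndarray
    metric: str  # "redundancy_nats" | "fc_adjusted_z"
    lag: int = 1
    subject_id: str = ""
    run_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("interaction matrix must be square")


# ---------------------------------------------------------------------------
# FIR task regression


def build_fir_basis(
    design: TaskDesign, n_timepoints: int, sampling_interval_s: float,
    n_lags: int | None = None,
) -> np.ndarray:
    """Time x (conditions * n_lags) matrix of shifted impulse regressors.

    ``n_lags`` defaults to ceil(trial duration / sampling interval), the
    number of frames an evoked response occupies per trial.  Collinear
    columns are dropped deterministically in first-kept order.
    """
    if n_lags is None:
        n_lags = int(np.ceil(design.durations.max() / sampling_interval_s))
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    conditions = list(dict.fromkeys(design.trial_types.tolist()))
    cols = []
    for cond in conditions:
        onsets = design.onsets[design.trial_types == cond]
        frames = np.round(onsets / sampling_interval_s).astype(int)
        for lag in range(n_lags):
            col = np.zeros(n_timepoints)
            idx = frames + lag
            idx = idx[(idx >= 0) & (idx < n_timepoints)]
            col[idx] = 1.0
            cols.append(col)
    basis = np.column_stack(cols) if cols else np.zeros((n_timepoints, 0))
    # drop all-zero and collinear columns, keeping the earliest
    keep: list[int] = []
    for j in range(basis.shape[1]):
        cand = basis[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    if len(keep) < basis.shape[1]:
        warnings.warn("dropped collinear FIR columns", stacklevel=2)
    return basis[:, keep]


def fir_task_regression(
    ts: ParcelTimeSeries, design: TaskDesign, n_lags: int | None = None
) -> ParcelTimeSeries:
    """Remove the mean evoked response with an FIR model; return demeaned
    residuals.  With no events the input is simply demeaned."""
    if design.end_time() > ts.n_timepoints * ts.sampling_interval_s:
        raise ValueError("design extends beyond the scan")
    y = ts.data
    if design.n_events == 0:
        resid = y - y.mean(axis=0)
    else:
        basis = build_fir_basis(design, ts.n_timepoints, ts.sampling_interval_s, n_lags)
        x = np.column_stack([basis, np.ones(ts.n_timepoints)])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        resid = resid - resid.mean(axis=0)
    return ParcelTimeSeries(
        resid,
        sampling_interval_s=ts.sampling_interval_s,
        subject_id=ts.subject_id,
        run_id=ts.run_id,
        condition=ts.condition,
    )


# ---------------------------------------------------------------------------
# HRF deconvolution


def hrf_deconvolve(
    ts: ParcelTimeSeries, noise_level: float = 0.02
) -> ParcelTimeSeries:
    """Wiener deconvolution against the canonical double-gamma HRF.

    ``noise_level`` is the regularization constant added to |H|^2 in the
    Wiener gain; larger values damp high-frequency amplification.
    """
    if noise_level <= 0:
        raise ValueError("noise_level must be positive")
    y = ts.data
    t = ts.n_timepoints
    h = canonical_hrf(ts.sampling_interval_s)
    n_fft = int(2 ** np.ceil(np.log2(t + h.shape[0])))
    hf = np.fft.rfft(h, n_fft)
    yf = np.fft.rfft(y, n_fft, axis=0)
    gain = np.conj(hf) / (np.abs(hf) ** 2 + noise_level)
    xf = yf * gain[:, None]
    x = np.fft.irfft(xf, n_fft, axis=0)[:t]
    return ParcelTimeSeries(
        x,
        sampling_interval_s=ts.sampling_interval_s,
        subject_id=ts.subject_id,
        run_id=ts.run_id,
        condition=ts.condition,
    )


# ---------------------------------------------------------------------------
# Gaussian lagged mutual information and redundancy


def _mi_from_rho(rho: np.ndarray | float) -> np.ndarray | float:
    rho = np.clip(rho, -_R_CLIP, _R_CLIP)
    return -0.5 * np.log1p(-(rho**2))


def gaussian_lagged_mi(x: np.ndarray, y: np.ndarray, lag: int = 1) -> float:
    """I(x_t; y_{t+lag}) in nats under the Gaussian assumption."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] <= lag + 2:
        raise ValueError("series too short for the requested lag")
    a = x[: x.shape[0] - lag] if lag > 0 else x
    b = y[lag:]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    rho = np.corrcoef(a, b)[0, 1]
    return float(_mi_from_rho(rho))


def persistent_redundancy(x: np.ndarray, y: np.ndarray, lag: int = 1) -> float:
    """MMI double redundancy: min of the four lagged pairwise MIs,
    clamped at 0."""
    terms = [
        gaussian_lagged_mi(x, x, lag),
        gaussian_lagged_mi(x, y, lag),
        gaussian_lagged_mi(y, x, lag),
        gaussian_lagged_mi(y, y, lag),
    ]
    if any(np.isnan(t) for t in terms):
        return np.nan
    return float(max(0.0, min(terms)))


def _lagged_correlation_matrix(x: np.ndarray, lag: int) -> np.ndarray:
    """L[i, j] = corr(x_i(t), x_j(t + lag)) over all parcel pairs."""
    t = x.shape[0]
    a = x[: t - lag] if lag > 0 else x
    b = x[lag:]
    az = (a - a.mean(axis=0)) / a.std(axis=0)
    bz = (b - b.mean(axis=0)) / b.std(axis=0)
    return (az.T @ bz) / a.shape[0]


def redundancy_matrix(ts: ParcelTimeSeries, lag: int = 1) -> InteractionMatrix:
    """Pairwise persistent redundancy over all parcel pairs (vectorized).

    The diagonal holds each parcel's self-predictive information
    I(x_t; x_{t+lag}); it is excluded from network aggregation.
    """
    x = ts.data
    if x.shape[0] <= lag + 2:
        raise ValueError("series too short for the requested lag")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance parcel")
    lagged = _lagged_correlation_matrix(x, lag)
    mi = _mi_from_rho(lagged)
    auto = np.diag(mi)
    red = np.minimum(mi, mi.T)
    red = np.minimum(red, auto[:, None])
    red = np.minimum(red, auto[None, :])
    red = np.clip(red, 0.0, None)
    np.fill_diagonal(red, auto)
    return InteractionMatrix(
        red, "redundancy_nats", lag=lag,
        subject_id=ts.subject_id, run_id=ts.run_id, condition=ts.condition,
    )


# ---------------------------------------------------------------------------
# autocorrelation-adjusted correlation


def _tukey_taper(max_lag: int) -> np.ndarray:
    k = np.arange(1, max_lag + 1)
    return 0.5 * (1.0 + np.cos(np.pi * k / max_lag))


def _pairwise_variance(x: np.ndarray, max_lag: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(r, var(r_hat)) for every column pair of x.

    Implements the Bartlett-type asymptotic expansion of the variance of
    the sample correlation of jointly stationary Gaussian series:

        N var(r) = sum_k [ rxx(k) ryy(k) + rxy(k) ryx(k)
                           - 2 r (rxx(k) rxy(k) + ryy(k) ryx(k))
                           + r^2 (rxx(k)^2/2 + ryy(k)^2/2 + rxy(k)^2) ]

    with sample correlations truncated at ceil(2*sqrt(N)) lags and tapered
    by a Tukey window to stabilize the tail.  For i.i.d. series the sum
    collapses to (1 - r^2)^2; for independent AR(1) series with equal phi
    it gives (1 + phi^2) / (1 - phi^2).
    """
    n, p = x.shape
    if max_lag is None:
        max_lag = int(np.ceil(2.0 * np.sqrt(n)))
    max_lag = min(max_lag, n - 2)
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    r = (z.T @ z) / n  # lag-0 cross-correlation (diag = 1)
    taper = _tukey_taper(max_lag)

    acc = (1.0 - r * r) ** 2  # the k = 0 term collapses to (1 - r^2)^2
    for k in range(1, max_lag + 1):
        c = (z[: n - k].T @ z[k:]) / n  # c[i, j] = corr(x_i(t), x_j(t+k))
        ax = np.diag(c).copy()  # lag-k autocorrelation per column
        ct = c.T
        a_i = ax[:, None]
        a_j = ax[None, :]
        # lags +-k combined (the expansion is symmetric under k -> -k
        # with rxy(-k) = ryx(k)):
        term = (
            2.0 * a_i * a_j
            + 2.0 * c * ct
            - 2.0 * r * (a_i + a_j) * (c + ct)
            + r * r * (a_i**2 + a_j**2 + c**2 + ct**2)
        )
        acc = acc + taper[k - 1] * term
    var = acc / n
    floor = 1.0 / n
    bad = ~np.isfinite(var) | (var <= 0)
    if bad.any():
        off_diag = bad.copy()
        np.fill_diagonal(off_diag, False)
        if off_diag.any():
            warnings.warn("variance estimate floored at 1/N for some pairs",
                          stacklevel=2)
        var = np.where(bad, floor, var)
    return r, var


def adjusted_correlation_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(r, var(r_hat), z) for one pair of series.

    z = atanh(r) / sqrt(var(r_hat) / (1 - r^2)^2): the Fisher transform
    rescaled by the delta-method standard error under autocorrelation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 20:
        raise ValueError("need at least 20 time points")
    data = np.column_stack([x, y])
    r_mat, var_mat = _pairwise_variance(data)
    r = float(np.clip(r_mat[0, 1], -_R_CLIP, _R_CLIP))
    var = float(var_mat[0, 1])
    z = np.arctanh(r) / np.sqrt(var / (1.0 - r**2) ** 2)
    return r, var, float(z)


def naive_z(x: np.ndarray, y: np.ndarray) -> float:
    """Fisher z with the nominal sqrt(N - 3) scaling (no adjustment)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.clip(np.corrcoef(x, y)[0, 1], -_R_CLIP, _R_CLIP)
    return float(np.arctanh(r) * np.sqrt(x.shape[0] - 3))


def adjusted_fc_matrix(
    ts: ParcelTimeSeries,
    design: TaskDesign | None = None,
    adjust: bool = True,
    n_lags: int | None = None,
) -> InteractionMatrix:
    """Parcel-pair functional connectivity as (adjusted) z scores.

    For task runs pass the event design: the mean evoked response is
    removed by FIR regression before correlation, so the matrix reflects
    task-state coupling rather than co-activation.  Diagonal is 0.
    """
    if design is not None:
        ts = fir_task_regression(ts, design, n_lags=n_lags)
    x = ts.data
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance parcel")
    if adjust:
        r, var = _pairwise_variance(x)
        r = np.clip(r, -_R_CLIP, _R_CLIP)
        z = np.arctanh(r) / np.sqrt(var / (1.0 - r**2) ** 2)
    else:
        r = np.clip(np.corrcoef(x, rowvar=False), -_R_CLIP, _R_CLIP)
        z = np.arctanh(r) * np.sqrt(x.shape[0] - 3)
    z = 0.5 * (z + z.T)
    np.fill_diagonal(z, 0.0)
    return InteractionMatrix(
        z, "fc_adjusted_z" if adjust else "fc_naive_z", lag=0,
        subject_id=ts.subject_id, run_id=ts.run_id, condition=ts.condition,
    )
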