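"""Curated per-parcel time-series feature catalog, robust normalization,
feature similarity, and parcel homogeneity.

The catalog is a compact, frozen stand-in for a massive feature toolbox:
~26 features spanning distributional shape, autocorrelation structure,
spectral content, entropy/complexity, nonlinearity and stationarity —
families rich enough to discriminate networks with distinct temporal
structure.  Each feature has a closed-form or simulation oracle in the
test suite.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import kurtosis, skew

from .types import ParcelLabeling, ParcelTimeSeries

__all__ = [
    "FeatureMatrix",
    "SimilarityMatrix",
    "HomogeneityReport",
    "feature_catalog",
    "extract_features",
    "robust_sigmoid_normalize",
    "feature_similarity",
    "network_pair_average",
    "parcel_homogeneity",
]

FISHER_CLIP = 1.0 - 1e-7
MIN_TIMEPOINTS = 50


@dataclass
class FeatureMatrix:
    """Parcel x feature matrix with an ordered catalog of feature names."""

    values: np.ndarray
    feature_names: list[str]
    normalized: bool = False
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (parcels x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature name count mismatch")
        if self.normalized:
            v = self.values
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                raise ValueError("normalized features must lie in [0, 1]")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class SimilarityMatrix:
    """Parcel-pair Fisher-z similarity of feature vectors."""

    matrix: np.ndarray
    metric: str = "feature_similarity"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("similarity matrix must be square")


@dataclass
class HomogeneityReport:
    """Per-parcel homogeneity plus the size-weighted overall summary."""

    per_parcel: np.ndarray
    parcel_sizes: np.ndarray
    weighted_summary: float


# ---------------------------------------------------------------------------
# feature catalog (all functions operate on a (T, P) matrix, return (P,))


def _acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """(max_lag+1, P) sample autocorrelation (biased normalization)."""
    t, p = x.shape
    xc = x - x.mean(axis=0)
    denom = (xc * xc).sum(axis=0)
    denom = np.where(denom == 0, np.nan, denom)
    out = np.empty((max_lag + 1, p))
    out[0] = 1.0
    for k in range(1, max_lag + 1):
        out[k] = (xc[:-k] * xc[k:]).sum(axis=0) / denom
    return out


def _first_crossing(acf: np.ndarray, level: float) -> np.ndarray:
    """First lag where the ACF drops below `level`; max lag if never."""
    below = acf[1:] < level
    first = np.argmax(below, axis=0) + 1.0
    never = ~below.any(axis=0)
    first[never] = acf.shape[0] - 1
    return first


def _band_powers(x: np.ndarray) -> tuple[np.ndarray, ...]:
    """Relative power in low/mid/high thirds of the spectrum + centroid."""
    t = x.shape[0]
    xc = x - x.mean(axis=0)
    psd = np.abs(np.fft.rfft(xc, axis=0)) ** 2
    psd = psd[1:]  # drop DC
    freqs = np.fft.rfftfreq(t)[1:]
    total = psd.sum(axis=0)
    total = np.where(total == 0, np.nan, total)
    edges = np.quantile(freqs, [1 / 3, 2 / 3])
    low = psd[freqs <= edges[0]].sum(axis=0) / total
    mid = psd[(freqs > edges[0]) & (freqs <= edges[1])].sum(axis=0) / total
    high = psd[freqs > edges[1]].sum(axis=0) / total
    centroid = (freqs[:, None] * psd).sum(axis=0) / total
    return low, mid, high, centroid


def _permutation_entropy(x: np.ndarray, order: int = 3) -> np.ndarray:
    """Normalized Shannon entropy of ordinal patterns of length `order`."""
    t, p = x.shape
    n = t - order + 1
    windows = np.stack([x[i : i + n] for i in range(order)], axis=0)  # (order, n, P)
    ranks = np.argsort(np.argsort(windows, axis=0, kind="stable"), axis=0)
    # encode each pattern as an integer
    code = np.zeros((n, p), dtype=np.int64)
    for i in range(order):
        code = code * order + ranks[i]
    out = np.empty(p)
    n_patterns = math.factorial(order)
    for j in range(p):
        _, counts = np.unique(code[:, j], return_counts=True)
        prob = counts / counts.sum()
        out[j] = -(prob * np.log(prob)).sum() / np.log(n_patterns)
    return out


def _sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> np.ndarray:
    """SampEn(m=2, r=0.2*SD) per column, Chebyshev distance."""
    t, p = x.shape
    out = np.empty(p)
    for j in range(p):
        xj = x[:, j]
        r = r_factor * xj.std()
        if r == 0:
            out[j] = np.nan
            continue
        out[j] = _sampen_1d(xj, m, r)
    return out


def _sampen_1d(x: np.ndarray, m: int, r: float) -> float:
    # incremental Chebyshev template matching: a length-m match is the
    # conjunction of m single-sample matches along the diagonal
    close = np.abs(x[:, None] - x[None, :]) <= r
    # matches of length m among the n-m templates shared by both counts
    within_m = close[: -m, : -m].copy()
    for k in range(1, m):
        within_m &= close[k : k - m, k : k - m]
    within_m1 = within_m & close[m:, m:]
    np.fill_diagonal(within_m, False)
    np.fill_diagonal(within_m1, False)
    b = int(within_m.sum())
    a = int(within_m1.sum())
    if b == 0 or a == 0:
        return np.nan
    return float(-np.log(a / b))


def _time_reversal_asymmetry(x: np.ndarray, lag: int = 1) -> np.ndarray:
    """E[(x_{t+lag} - x_t)^3] / E[(x_{t+lag} - x_t)^2]^{3/2}."""
    d = x[lag:] - x[:-lag]
    num = (d**3).mean(axis=0)
    den = (d**2).mean(axis=0) ** 1.5
    den = np.where(den == 0, np.nan, den)
    return num / den


def _stat_av(x: np.ndarray, n_windows: int = 5) -> np.ndarray:
    """Sliding-window stationarity: SD of window means / overall SD."""
    t, p = x.shape
    w = t // n_windows
    means = np.stack([x[i * w : (i + 1) * w].mean(axis=0) for i in range(n_windows)])
    sd = x.std(axis=0)
    sd = np.where(sd == 0, np.nan, sd)
    return means.std(axis=0) / sd


def feature_catalog() -> list[str]:
    """Ordered names of the frozen feature catalog."""
    names = ["mean", "sd", "skewness", "kurtosis"]
    names += [f"ac_{k}" for k in range(1, 11)]
    names += ["ac_first_1e", "ac_first_zero"]
    names += ["power_low", "power_mid", "power_high", "spectral_centroid"]
    names += ["perm_entropy_3", "sample_entropy_m2"]
    names += ["time_rev_asym", "diff_mean_abs", "diff_sd", "stat_av_5"]
    return names


def extract_features(
    ts: ParcelTimeSeries, catalog: list[str] | None = None, min_timepoints: int = MIN_TIMEPOINTS
) -> FeatureMatrix:
    """Compute the feature catalog for every parcel of a run.

    Constant parcels get their distributional features; correlation-based
    features come out NaN and are cleaned up by normalization.
    """
    x = ts.data
    t, p = x.shape
    if t < min_timepoints:
        raise ValueError(f"need at least {min_timepoints} time points")
    max_lag = min(10, t - 2)
    acf_full = _acf(x, max_lag=min(40, t - 2))
    dx = np.diff(x, axis=0)
    low, mid, high, centroid = _band_powers(x)

    cols: dict[str, np.ndarray] = {
        "mean": x.mean(axis=0),
        "sd": x.std(axis=0),
        "skewness": skew(x, axis=0),
        "kurtosis": kurtosis(x, axis=0),
    }
    for k in range(1, 11):
        cols[f"ac_{k}"] = acf_full[min(k, max_lag)]
    cols["ac_first_1e"] = _first_crossing(acf_full, 1.0 / np.e)
    cols["ac_first_zero"] = _first_crossing(acf_full, 0.0)
    cols["power_low"] = low
    cols["power_mid"] = mid
    cols["power_high"] = high
    cols["spectral_centroid"] = centroid
    cols["perm_entropy_3"] = _permutation_entropy(x, order=3)
    cols["sample_entropy_m2"] = _sample_entropy(x)
    cols["time_rev_asym"] = _time_reversal_asymmetry(x)
    cols["diff_mean_abs"] = np.abs(dx).mean(axis=0)
    cols["diff_sd"] = dx.std(axis=0)
    cols["stat_av_5"] = _stat_av(x)

    names = catalog if catalog is not None else feature_catalog()
    unknown = [n for n in names if n not in cols]
    if unknown:
        raise KeyError(f"unknown features requested: {unknown}")
    values = np.column_stack([cols[n] for n in names])
    return FeatureMatrix(values, list(names), normalized=False)


def robust_sigmoid_normalize(raw: FeatureMatrix) -> FeatureMatrix:
    """Outlier-robust sigmoid across parcels, per feature.

    x -> 1 / (1 + exp(-(x - median) / (1.35 * IQR))); the 1.35*IQR scale is
    the robust-sigma convention.  Features with zero IQR (constants) or no
    finite values are dropped and recorded in ``dropped_features``.
    """
    if raw.n_parcels < 2:
        raise ValueError("need at least 2 parcels to normalize")
    v = raw.values
    kept_cols, kept_names, dropped = [], [], []
    for j, name in enumerate(raw.feature_names):
        col = v[:, j]
        finite = np.isfinite(col)
        if not finite.any():
            dropped.append(name)
            continue
        med = np.median(col[finite])
        q75, q25 = np.percentile(col[finite], [75, 25])
        iqr = q75 - q25
        # zero-IQR (constant) features carry no information across parcels,
        # and partially-missing entries cannot be imputed post-sigmoid
        if iqr == 0 or not finite.all():
            dropped.append(name)
            continue
        out = expit((col - med) / (1.35 * iqr))
        kept_cols.append(out)
        kept_names.append(name)
    if not kept_cols:
        raise ValueError("all features dropped during normalization")
    return FeatureMatrix(
        np.column_stack(kept_cols), kept_names, normalized=True, dropped_features=dropped
    )


def feature_similarity(fm: FeatureMatrix) -> SimilarityMatrix:
    """Fisher-z Pearson similarity of normalized feature vectors across
    every parcel pair.  |r| is clipped at 1 - 1e-7 before atanh so that
    duplicate parcels stay finite."""
    if not fm.normalized:
        raise ValueError("feature similarity expects a normalized matrix")
    v = fm.values
    sd = v.std(axis=1)
    dead = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(v)
    r = np.clip(r, -FISHER_CLIP, FISHER_CLIP)
    z = np.arctanh(r)
    z[dead, :] = np.nan
    z[:, dead] = np.nan
    return SimilarityMatrix(z)


def network_pair_average(
    matrix: np.ndarray | SimilarityMatrix, labeling: ParcelLabeling
) -> np.ndarray:
    """Network x network mean of a parcel-pair matrix.

    Entry (a, b) averages the matrix over all ordered parcel pairs
    (p in a, q in b, p != q); the diagonal is always excluded, so a
    single-parcel network has a NaN within-network entry.
    """
    if isinstance(matrix, SimilarityMatrix):
        matrix = matrix.matrix
    m = np.asarray(matrix, dtype=float)
    p = labeling.n_parcels
    if m.shape != (p, p):
        raise ValueError("matrix dimension does not match parcel count")
    k = labeling.n_networks
    valid = np.isfinite(m)
    np.fill_diagonal(valid, False)
    mz = np.where(valid, m, 0.0)
    # indicator (P, K)
    ind = np.zeros((p, k))
    ind[np.arange(p), labeling.parcel_network - 1] = 1.0
    sums = ind.T @ mz @ ind
    counts = ind.T @ valid.astype(float) @ ind
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return 0.5 * (out + out.T)


def parcel_homogeneity(
    vertex_ts: np.ndarray, labeling: ParcelLabeling
) -> HomogeneityReport:
    """Mean pairwise vertex-timecourse correlation within each parcel.

    The overall summary is the parcel-size-weighted mean across parcels
    with at least two vertices (single-vertex parcels are excluded along
    with their size).
    """
    x = np.asarray(vertex_ts, dtype=float)
    if x.shape[1] != labeling.n_vertices:
        raise ValueError("vertex count mismatch")
    per = np.full(labeling.n_parcels, np.nan)
    sizes = np.zeros(labeling.n_parcels, dtype=int)
    for pid in range(1, labeling.n_parcels + 1):
        idx = labeling.parcel_vertices(pid)
        sizes[pid - 1] = idx.size
        if idx.size < 2:
            continue
        c = np.corrcoef(x[:, idx], rowvar=False)
        iu = np.triu_indices(idx.size, k=1)
        vals = c[iu]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            per[pid - 1] = vals.mean()
    ok = np.isfinite(per)
    if ok.any():
        summary = float(np.average(per[ok], weights=sizes[ok]))
    else:
        summary = np.nan
    return HomogeneityReport(per, sizes, summary)
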