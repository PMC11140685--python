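"""Group-level statistics: network contrasts, FDR, max/min permutation
FWE control, parametric task GLM, and run-level quality control.

The max/min permutation test addresses comparisons of a paired
network-difference statistic across several task pairs: task labels are
exchanged within subject, the largest and smallest mean differences across
all pairs are recorded per permutation, and each observed difference is
referred to the upper tail of the max-null if positive or the lower tail
of the min-null if negative — the standard max-statistic construction for
family-wise error control in paired designs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hrf import convolve_hrf, events_to_boxcar
from .types import ParcelTimeSeries, TaskDesign

__all__ = [
    "PermutationResult",
    "GlmResult",
    "network_contrast",
    "fdr_bh",
    "maxmin_permutation_test",
    "glm_univariate",
    "run_qc_filter",
]


@dataclass
class PermutationResult:
    observed: dict[tuple, float]
    fwe_p: dict[tuple, float]
    max_null: np.ndarray
    min_null: np.ndarray
    n_permutations: int


@dataclass
class GlmResult:
    """Per-parcel effects at run, subject (fixed-effects) and group level."""

    run_betas: dict  # (subject, run) -> {regressor: (P,) array}
    subject_betas: np.ndarray  # (n_subjects, P) fixed-effects contrast
    group_t: np.ndarray  # (P,)
    group_p: np.ndarray  # (P,)
    group_q: np.ndarray  # (P,)
    contrast: str = ""
    df: int = 0


# ---------------------------------------------------------------------------
# t contrasts and FDR


def network_contrast(
    values_a: np.ndarray,
    values_b: np.ndarray | None = None,
    mode: str = "paired",
    popmean: float = 0.0,
) -> dict:
    """Standard t contrast between two per-subject metric vectors.

    modes: "paired" (matched vectors), "independent", "one_sample" (tests
    values_a against ``popmean``).  Zero-variance paired differences with a
    nonzero mean are flagged degenerate and reported at p < 1e-10.
    """
    a = np.asarray(values_a, dtype=float)
    if mode == "one_sample":
        if a.size < 3:
            raise ValueError("need at least 3 subjects")
        t, p = stats.ttest_1samp(a, popmean)
        effect = float(a.mean() - popmean)
        df = a.size - 1
        n = a.size
    elif mode == "paired":
        b = np.asarray(values_b, dtype=float)
        if a.shape != b.shape or a.size < 3:
            raise ValueError("paired mode needs matched vectors, n >= 3")
        d = a - b
        if np.allclose(d.std(), 0.0):
            m = d.mean()
            t = 0.0 if np.allclose(m, 0.0) else float(np.sign(m) * np.inf)
            p = 1.0 if t == 0.0 else 1e-10
        else:
            t, p = stats.ttest_rel(a, b)
        effect = float(d.mean())
        df = a.size - 1
        n = a.size
    elif mode == "independent":
        b = np.asarray(values_b, dtype=float)
        if a.size < 3 or b.size < 3:
            raise ValueError("need at least 3 subjects per group")
        t, p = stats.ttest_ind(a, b)
        effect = float(a.mean() - b.mean())
        df = a.size + b.size - 2
        n = a.size + b.size
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {
        "mode": mode, "t": float(t), "df": int(df), "p": float(p),
        "effect": effect, "n": int(n),
    }


def fdr_bh(p_values, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejected flags, q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, q, *_ = multipletests(p, alpha=q_level, method="fdr_bh")
    return rejected, q


# ---------------------------------------------------------------------------
# max/min permutation FWE


def maxmin_permutation_test(
    values: np.ndarray,
    task_pairs: list[tuple[int, int]] | None = None,
    n_permutations: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Max/min-statistic permutation test over task pairs.

    Parameters
    ----------
    values : (n_subjects, n_tasks) array
        Per-subject network-difference values, one column per task.
    task_pairs : list of (i, j) column index pairs; defaults to all pairs.

    The observed statistic per pair is the across-subject mean of
    column_i - column_j.  The null exchanges each subject's task labels
    (an independent random permutation of that subject's row), jointly for
    all pairs, and records the max and min pair statistic per permutation.
    A positive observed value is referred to the upper tail, a negative one
    to the lower tail; because the family is two-sided, both tails use the
    symmetric envelope max(max_null, -min_null), which keeps the joint
    family-wise error at the nominal level (referring each sign only to
    its own envelope would double the two-sided FWE).
    p = (1 + #{envelope >= |observed|}) / (1 + n_permutations).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[1] < 2:
        raise ValueError("need a (subjects, tasks >= 2) value matrix")
    if not np.isfinite(v).all():
        raise ValueError("every subject needs a value for every task")
    n_sub, n_task = v.shape
    if task_pairs is None:
        task_pairs = [(i, j) for i in range(n_task) for j in range(i + 1, n_task)]
    observed = {
        (i, j): float(np.mean(v[:, i] - v[:, j])) for i, j in task_pairs
    }
    rng = np.random.default_rng(seed)
    # permute each subject's row independently, vectorized over permutations
    tiled = np.broadcast_to(v, (n_permutations, n_sub, n_task))
    perm = rng.permuted(tiled, axis=2)
    pair_stats = np.stack(
        [perm[:, :, i].mean(axis=1) - perm[:, :, j].mean(axis=1) for i, j in task_pairs],
        axis=1,
    )  # (n_permutations, n_pairs)
    max_null = pair_stats.max(axis=1)
    min_null = pair_stats.min(axis=1)
    envelope = np.maximum(max_null, -min_null)
    fwe_p = {}
    for idx, (i, j) in enumerate(task_pairs):
        obs = observed[(i, j)]
        count = np.sum(envelope >= abs(obs))
        fwe_p[(i, j)] = float((1.0 + count) / (1.0 + n_permutations))
    return PermutationResult(observed, fwe_p, max_null, min_null, n_permutations)


# ---------------------------------------------------------------------------
# univariate task GLM


def _run_design_matrix(
    design: TaskDesign, n_timepoints: int, tr: float, model: str
) -> tuple[np.ndarray, list[str]]:
    ones = np.ones(design.n_events)
    cols, names = [], []

    def hrf_reg(mask, amplitudes):
        stim = events_to_boxcar(
            design.onsets[mask], design.durations[mask], amplitudes[mask],
            n_timepoints, tr,
        )
        return convolve_hrf(stim, tr)

    if model == "task_mean+modulator":
        cols.append(hrf_reg(design.correct, ones))
        names.append("task_mean")
        cols.append(hrf_reg(design.correct, design.modulators))
        names.append("modulator")
    elif model == "easy+hard":
        for cond in ("easy", "hard"):
            mask = design.correct & (design.trial_types == cond)
            cols.append(hrf_reg(mask, ones))
            names.append(cond)
    else:
        raise ValueError(f"unknown model {model!r}")
    if (~design.correct).any():
        cols.append(hrf_reg(~design.correct, ones))
        names.append("incorrect")
    # intercept and linear drift
    cols.append(np.ones(n_timepoints))
    names.append("intercept")
    drift = np.linspace(-0.5, 0.5, n_timepoints)
    cols.append(drift)
    names.append("drift")
    return np.column_stack(cols), names


def glm_univariate(
    runs: list[tuple[ParcelTimeSeries, TaskDesign]],
    model: str = "task_mean+modulator",
    contrast: str | None = None,
    q_level: float = 0.05,
    equal_weights: bool = False,
) -> GlmResult:
    """Run-level OLS with canonical-HRF regressors, fixed-effects
    combination across runs within subject, then a group one-sample t per
    parcel with BH-FDR across parcels.

    ``contrast`` defaults to "modulator" for the parametric model and
    "hard-easy" for the two-condition model.  Runs with no correct trials
    are skipped with a warning.  Fixed effects are inverse-variance
    weighted unless ``equal_weights``.
    """
    if contrast is None:
        contrast = "modulator" if model == "task_mean+modulator" else "hard-easy"
    run_betas: dict = {}
    per_subject: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for ts, design in runs:
        if not design.correct.any():
            warnings.warn(f"run {ts.subject_id}/{ts.run_id} has no correct trials; skipped",
                          stacklevel=2)
            continue
        if design.end_time() > ts.n_timepoints * ts.sampling_interval_s:
            raise ValueError("design extends beyond the scan")
        x, names = _run_design_matrix(design, ts.n_timepoints, ts.sampling_interval_s, model)
        y = ts.data
        beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        dof = max(ts.n_timepoints - rank, 1)
        sigma2 = (resid**2).sum(axis=0) / dof
        xtx_inv = np.linalg.pinv(x.T @ x)
        if contrast == "hard-easy":
            cvec = np.zeros(len(names))
            cvec[names.index("hard")] = 1.0
            cvec[names.index("easy")] = -1.0
        else:
            cvec = np.zeros(len(names))
            cvec[names.index(contrast)] = 1.0
        eff = cvec @ beta
        var = float(cvec @ xtx_inv @ cvec) * sigma2
        run_betas[(ts.subject_id, ts.run_id)] = dict(zip(names, beta))
        per_subject.setdefault(ts.subject_id, []).append((eff, var))
    if not per_subject:
        raise ValueError("no usable runs")
    subjects = sorted(per_subject)
    sub_betas = []
    for s in subjects:
        effs = np.stack([e for e, _ in per_subject[s]])
        variances = np.stack([v for _, v in per_subject[s]])
        if equal_weights or len(per_subject[s]) == 1:
            sub_betas.append(effs.mean(axis=0))
        else:
            w = 1.0 / np.clip(variances, 1e-30, None)
            sub_betas.append((effs * w).sum(axis=0) / w.sum(axis=0))
    sub_betas = np.stack(sub_betas)
    n_sub = sub_betas.shape[0]
    if n_sub >= 2:
        t, p = stats.ttest_1samp(sub_betas, 0.0, axis=0)
        # zero-variance parcels (e.g. noiseless simulations) -> degenerate
        sd = sub_betas.std(axis=0)
        degen = np.isclose(sd, 0.0)
        if degen.any():
            m = sub_betas.mean(axis=0)
            t = np.where(degen, np.sign(m) * np.inf, t)
            p = np.where(degen, np.where(np.isclose(m, 0.0), 1.0, 1e-10), p)
        _, q = fdr_bh(np.nan_to_num(p, nan=1.0), q_level)
    else:
        t = np.full(sub_betas.shape[1], np.nan)
        p = np.full(sub_betas.shape[1], np.nan)
        q = np.full(sub_betas.shape[1], np.nan)
    return GlmResult(
        run_betas=run_betas,
        subject_betas=sub_betas,
        group_t=np.asarray(t, dtype=float),
        group_p=np.asarray(p, dtype=float),
        group_q=np.asarray(q, dtype=float),
        contrast=contrast,
        df=n_sub - 1,
    )


# ---------------------------------------------------------------------------
# run-level quality control


def run_qc_filter(
    runs: pd.DataFrame,
    mode: str = "york",
    fd_mean_thresh: float = 0.2,
    fd_frame_thresh: float = 0.25,
    fd_frame_fraction: float = 0.15,
    hcp_frame_thresh: float = 0.2,
    hcp_frame_fraction: float = 0.25,
) -> pd.DataFrame:
    """Run-exclusion rules.

    ``runs`` is a DataFrame with columns: subject, task, run, fd_trace
    (array of per-frame FD, mm) and, in york mode, accuracy.

    york mode drops a run if (1) mean relative RMS FD > 0.2 mm, (2) more
    than 15% of frames exceed 0.25 mm, or (3) behavioural accuracy is
    more than 3 SD below the group mean; if only one run of a task
    survives for a subject, that subject's task data is dropped entirely.

    hcp mode flags a run if > 25% of frames exceed 0.2 mm FD, and excludes
    a subject who is adverse (> Q3 + 1.5 IQR) in two or more of four
    summary motion measures.
    """
    df = runs.copy()
    for col in ("subject", "task", "run", "fd_trace"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if df["fd_trace"].map(lambda a: len(np.atleast_1d(a)) == 0).any():
        raise ValueError("empty FD trace")
    df["mean_fd"] = df["fd_trace"].map(lambda a: float(np.mean(a)))
    df["frac_high_fd"] = df["fd_trace"].map(
        lambda a: float(np.mean(np.asarray(a) > (fd_frame_thresh if mode == "york"
                                                 else hcp_frame_thresh)))
    )
    reasons = [[] for _ in range(len(df))]
    if mode == "york":
        drop = np.zeros(len(df), dtype=bool)
        high_fd = df["mean_fd"].to_numpy() > fd_mean_thresh
        spiky = df["frac_high_fd"].to_numpy() > fd_frame_fraction
        for i in np.flatnonzero(high_fd):
            reasons[i].append("mean_rms_fd")
        for i in np.flatnonzero(spiky):
            reasons[i].append("fd_spikes")
        drop |= high_fd | spiky
        if "accuracy" in df.columns:
            acc = df["accuracy"].to_numpy(dtype=float)
            low = acc < (acc.mean() - 3 * acc.std())
            for i in np.flatnonzero(low):
                reasons[i].append("low_accuracy")
            drop |= low
        df["drop_run"] = drop
        # subject-task drop when a single run survives
        df["drop_subject_task"] = False
        for (sub, task), grp in df.groupby(["subject", "task"]):
            kept = (~grp["drop_run"]).sum()
            if kept == 1 and len(grp) > 1:
                idx = grp.index
                df.loc[idx, "drop_subject_task"] = True
                for i in idx:
                    reasons[df.index.get_loc(i)].append("single_surviving_run")
    elif mode == "hcp":
        df["drop_run"] = df["frac_high_fd"].to_numpy() > hcp_frame_fraction
        for i in np.flatnonzero(df["drop_run"].to_numpy()):
            reasons[i].append("fd_spikes")
        # subject exclusion by the 1.5 x IQR rule over summary measures
        df["drop_subject_task"] = False
        measure_cols = [c for c in df.columns if c.startswith("motion_measure")]
        if measure_cols:
            per_sub = df.groupby("subject")[measure_cols].mean()
            adverse = pd.DataFrame(index=per_sub.index)
            for c in measure_cols:
                q1, q3 = per_sub[c].quantile([0.25, 0.75])
                adverse[c] = per_sub[c] > q3 + 1.5 * (q3 - q1)
            bad_subjects = adverse.index[adverse.sum(axis=1) >= 2]
            mask = df["subject"].isin(bad_subjects)
            df.loc[mask, "drop_subject_task"] = True
            for i in np.flatnonzero(mask.to_numpy()):
                reasons[i].append("motion_iqr")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    df["reasons"] = [";".join(r) for r in reasons]
    return df.drop(columns=["fd_trace"])
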