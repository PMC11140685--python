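"""Composite study-level workflows built from the pipeline stages.

These are the recurring units of the analysis: build a subject's combined
run-level feature matrix, classify it against its network labels, and
contrast interaction metrics between two task conditions across a cohort.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from . import classify as clf
from . import features as feat
from . import interaction as inter
from . import synthetic as syn
from .types import ConditionSpec, ParcelLabeling, ParcelTimeSeries

__all__ = [
    "subject_feature_matrix",
    "classify_subject",
    "condition_contrast",
]


def subject_feature_matrix(
    runs: list[ParcelTimeSeries], labeling: ParcelLabeling
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized features of all runs stacked as samples, with network
    labels repeated per run (features surviving normalization in every
    run are kept, in catalog order)."""
    fms = [feat.robust_sigmoid_normalize(feat.extract_features(ts)) for ts in runs]
    common = set(fms[0].feature_names)
    for fm in fms[1:]:
        common &= set(fm.feature_names)
    order = [n for n in fms[0].feature_names if n in common]
    x = np.vstack([
        fm.values[:, [fm.feature_names.index(n) for n in order]] for fm in fms
    ])
    y = np.concatenate([labeling.parcel_network for _ in fms])
    return x, y


def classify_subject(
    runs: list[ParcelTimeSeries],
    labeling: ParcelLabeling,
    k_folds: int = 5,
    seed: int = 0,
    n_permutations: int = 0,
):
    """Within-subject network classification, optionally with a
    label-permutation null.  Returns the ClassificationResult plus the
    row-normalized confusion matrix over all networks."""
    x, y = subject_feature_matrix(runs, labeling)
    if n_permutations:
        res = clf.permutation_null(
            x, y, k_folds=k_folds, n_permutations=n_permutations, seed=seed
        )
    else:
        res = clf.cv_classify(x, y, k_folds=k_folds, seed=seed)
    cm = clf.confusion_probabilities(
        res.y_true, res.y_pred, labels=np.arange(1, labeling.n_networks + 1)
    )
    return res, cm


def condition_contrast(
    labeling: ParcelLabeling,
    spec_a: ConditionSpec,
    spec_b: ConditionSpec,
    pair_1: tuple[str, str],
    pair_2: tuple[str, str],
    n_subjects: int = 12,
    n_runs: int = 2,
    seed: int = 0,
) -> dict:
    """Paired condition contrast of (pair_1 minus pair_2) network-pair
    values for feature similarity, redundancy, adjusted FC, and confusion
    probabilities, across a cohort of subjects.

    Returns per-metric dicts with the paired t, p, and mean difference of
    the condition-A minus condition-B contrast.
    """
    nets = labeling.network_names
    ia = (nets.index(pair_1[0]), nets.index(pair_1[1]))
    ib = (nets.index(pair_2[0]), nets.index(pair_2[1]))

    def pair_diff(matrix: np.ndarray) -> float:
        return float(matrix[ia] - matrix[ib])

    values: dict[str, dict[str, list[float]]] = {
        m: {"a": [], "b": []} for m in ("feature_similarity", "redundancy",
                                        "fc_adjusted", "confusion")
    }
    for spec, tag in ((spec_a, "a"), (spec_b, "b")):
        runs, _ = syn.generate_timeseries(
            labeling, spec, n_subjects=n_subjects, n_runs=n_runs
        )
        by_subject: dict[str, list[ParcelTimeSeries]] = {}
        for ts in runs:
            by_subject.setdefault(ts.subject_id, []).append(ts)
        for sub in sorted(by_subject):
            sub_runs = by_subject[sub]
            fsim, red, fc = [], [], []
            for ts in sub_runs:
                fm = feat.robust_sigmoid_normalize(feat.extract_features(ts))
                fsim.append(feat.network_pair_average(
                    feat.feature_similarity(fm), labeling))
                red.append(feat.network_pair_average(
                    inter.redundancy_matrix(ts).matrix, labeling))
                fc.append(feat.network_pair_average(
                    inter.adjusted_fc_matrix(ts).matrix, labeling))
            values["feature_similarity"][tag].append(pair_diff(np.mean(fsim, axis=0)))
            values["redundancy"][tag].append(pair_diff(np.mean(red, axis=0)))
            values["fc_adjusted"][tag].append(pair_diff(np.mean(fc, axis=0)))
            _, cm = classify_subject(sub_runs, labeling, seed=seed)
            values["confusion"][tag].append(pair_diff(cm))
    out = {}
    for metric, v in values.items():
        a, b = np.asarray(v["a"]), np.asarray(v["b"])
        t, p = stats.ttest_rel(a, b)
        out[metric] = {"t": float(t), "p": float(p), "effect": float((a - b).mean())}
    return out
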