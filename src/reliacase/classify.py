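"""Leave-one-out linear-SVM classification over exhaustive ROI subsets.

Feature vectors are the session-averaged beta values at voxels inside the
reliability mask — the whole mask, or the union of a subset of ROIs
intersected with it; the "concatenated" task mode stacks both tasks'
vectors. Classification is a linear SVM (fixed cost C = 1, no tuning)
evaluated by leave-one-out, with features standardized by training-fold
statistics only. The power-set search evaluates every nonempty subset of
the ROI set — the classic, optimal, and computationally expensive subset
selection — and reports the best correct-classification rate per subset
size; note that for the full 17-ROI set this is 131,071 subsets (hours).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

log = logging.getLogger(__name__)

POSITIVE = "DD"
TASK_MODES = ("comparison", "calculation", "concatenated")


@dataclass
class ROISet:
    """ROI label volume plus a (label, name, hemisphere) table."""

    labels: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        names = list(self.table["name"])
        if len(set(names)) != len(names):
            raise ValueError("ROI names must be unique")

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    def mask_for(self, name: str) -> np.ndarray:
        row = self.table[self.table["name"] == name]
        if row.empty:
            raise KeyError(f"unknown ROI {name!r}")
        return self.labels == int(row["label"].iloc[0])


def _single_task_features(dataset, task: str, voxel_mask: np.ndarray) -> np.ndarray:
    avg = dataset.averaged(task)
    return avg.reshape(avg.shape[0], -1)[:, voxel_mask.ravel()]


def extract_features(dataset, mask: np.ndarray, task_mode: str,
                     rois: ROISet | None = None,
                     roi_subset: tuple[str, ...] | None = None,
                     roi_mean: bool = False) -> np.ndarray:
    """Subjects x features matrix of (masked) session-averaged betas.

    Voxel order is C order (x fastest-varying last) within the selected
    mask for whole-brain mode, and ROI-block order (subset order as given,
    C order within each ROI) for ROI mode, so a subset's features are a
    sub-block of any superset's. ``roi_mean`` collapses each ROI to its
    mean beta instead of voxelwise values.
    """
    if task_mode not in TASK_MODES:
        raise ValueError(f"task_mode must be one of {TASK_MODES}")
    mask = np.asarray(mask, dtype=bool)
    tasks = list(dataset.tasks) if task_mode == "concatenated" else [task_mode]

    if rois is None:
        blocks_per_task = [[_single_task_features(dataset, t, mask)] for t in tasks]
    else:
        subset = tuple(roi_subset) if roi_subset is not None else tuple(rois.names)
        blocks_per_task = []
        for t in tasks:
            blocks = []
            for name in subset:
                vox = rois.mask_for(name) & mask
                if not vox.any():
                    raise ValueError(f"ROI {name!r} has no voxels inside the mask")
                feats = _single_task_features(dataset, t, vox)
                if roi_mean:
                    feats = feats.mean(axis=1, keepdims=True)
                blocks.append(feats)
            blocks_per_task.append(blocks)
    return np.hstack([b for blocks in blocks_per_task for b in blocks])


@dataclass
class ClassificationResult:
    """LOO predictions and rates for one feature set."""

    subset: tuple[str, ...] | str
    task_mode: str
    subjects: list[str]
    true_labels: np.ndarray
    predictions: np.ndarray
    ccr: float          # percent
    sensitivity: float  # percent, positive class = DD
    specificity: float  # percent

    def to_dict(self) -> dict:
        return {
            "subset": list(self.subset) if not isinstance(self.subset, str) else self.subset,
            "task_mode": self.task_mode,
            "ccr": self.ccr,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "predictions": dict(zip(self.subjects, self.predictions.tolist())),
        }


def ccr_from_rates(sensitivity: float, specificity: float,
                   n_pos: int, n_neg: int) -> float:
    """Overall correct-classification rate implied by class-wise rates (%).

    CCR = (sensitivity * n_pos + specificity * n_neg) / (n_pos + n_neg).
    """
    if not (0 <= sensitivity <= 100 and 0 <= specificity <= 100):
        raise ValueError("rates must be percentages in [0, 100]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class counts must be positive")
    return (sensitivity * n_pos + specificity * n_neg) / (n_pos + n_neg)


def loo_linear_svm(features: np.ndarray, labels: np.ndarray,
                   subjects: list[str] | None = None,
                   subset: tuple[str, ...] | str = "whole-brain",
                   task_mode: str = "concatenated",
                   C: float = 1.0) -> ClassificationResult:
    """Leave-one-out linear SVM, DD as the positive class.

    Each fold standardizes features with the training fold's mean/sd (no
    leakage), fits ``SVC(kernel="linear", C=C)`` on the remaining subjects
    and predicts the left-out one.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be subjects x features matching labels")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need both classes present")
    if np.isnan(X).any():
        raise ValueError("missing feature values")
    n = X.shape[0]
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 subjects per class")
    preds = np.empty(n, dtype=y.dtype)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit((X[train] - mu) / sd, y[train])
        preds[i] = clf.predict(((X[i] - mu) / sd)[None, :])[0]
    pos = y == POSITIVE
    neg = ~pos
    sens = 100.0 * (preds[pos] == y[pos]).mean()
    spec = 100.0 * (preds[neg] == y[neg]).mean()
    ccr = ccr_from_rates(sens, spec, int(pos.sum()), int(neg.sum()))
    if subjects is None:
        subjects = [f"s{i}" for i in range(n)]
    return ClassificationResult(subset=subset, task_mode=task_mode,
                                subjects=list(subjects), true_labels=y,
                                predictions=preds, ccr=ccr,
                                sensitivity=sens, specificity=spec)


def iter_subsets(names: list[str]):
    """All nonempty subsets, smallest first, lexicographic within a size."""
    for size in range(1, len(names) + 1):
        yield from itertools.combinations(names, size)


@dataclass
class PowerSetSearchResult:
    """Best CCR per subset size and the overall winner(s)."""

    task_mode: str
    best_per_size: dict[int, float]
    argmax_per_size: dict[int, list[tuple[str, ...]]]
    best_ccr: float
    best_subsets: list[tuple[str, ...]]  # minimal size first, then lexicographic
    total_evaluated: int
    results: dict[tuple[str, ...], ClassificationResult] = field(default_factory=dict,
                                                                 repr=False)

    def to_dict(self) -> dict:
        return {
            "task_mode": self.task_mode,
            "total_evaluated": self.total_evaluated,
            "best_ccr": self.best_ccr,
            "best_subsets": [list(s) for s in self.best_subsets],
            "best_per_size": {str(k): v for k, v in self.best_per_size.items()},
            "n_argmax_per_size": {str(k): len(v)
                                  for k, v in self.argmax_per_size.items()},
        }


def powerset_search(dataset, rois: ROISet, mask: np.ndarray, task_mode: str,
                    roi_names: list[str] | None = None, max_rois: int = 17,
                    force: bool = False, C: float = 1.0,
                    keep_results: bool = False) -> PowerSetSearchResult:
    """Exhaustive LOO-SVM evaluation of every nonempty ROI subset.

    Per-ROI feature blocks are extracted once; each of the 2^R - 1 subsets
    stacks its blocks and runs the LOO SVM. The overall winner is the
    highest CCR; ties are broken toward the smallest subset, then
    lexicographic ROI-name order (all tied subsets are reported).
    """
    names = list(roi_names) if roi_names is not None else rois.names
    R = len(names)
    if R > max_rois and not force:
        est_min = (2 ** R - 1) * 0.02 / 60.0
        raise RuntimeError(
            f"{R} ROIs -> {2 ** R - 1} subsets (~{est_min:.0f} min); "
            f"pass force=True (or raise max_rois) to run anyway")
    tasks = list(dataset.tasks) if task_mode == "concatenated" else [task_mode]
    blocks = {name: np.hstack([extract_features(dataset, mask, t, rois, (name,))
                               for t in tasks])
              for name in names}
    y = dataset.groups
    subject_ids = dataset.subject_ids

    best_per_size: dict[int, float] = {}
    argmax_per_size: dict[int, list[tuple[str, ...]]] = {}
    results: dict[tuple[str, ...], ClassificationResult] = {}
    total = 0
    for subset in iter_subsets(names):
        X = np.hstack([blocks[name] for name in subset])
        res = loo_linear_svm(X, y, subjects=subject_ids, subset=subset,
                             task_mode=task_mode, C=C)
        total += 1
        size = len(subset)
        if res.ccr > best_per_size.get(size, -1.0):
            best_per_size[size] = res.ccr
            argmax_per_size[size] = [subset]
        elif res.ccr == best_per_size[size]:
            argmax_per_size[size].append(subset)
        if keep_results:
            results[subset] = res
    best_ccr = max(best_per_size.values())
    best_subsets = [s for size in sorted(best_per_size)
                    if best_per_size[size] == best_ccr
                    for s in argmax_per_size[size]]
    log.info("power-set search (%s): %d subsets, best CCR %.2f%% at %s",
             task_mode, total, best_ccr, best_subsets[0])
    return PowerSetSearchResult(task_mode=task_mode, best_per_size=best_per_size,
                                argmax_per_size=argmax_per_size, best_ccr=best_ccr,
                                best_subsets=best_subsets, total_evaluated=total,
                                results=results)
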