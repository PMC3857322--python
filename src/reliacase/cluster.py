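"""Complete-linkage hierarchical clustering of subjects on activation patterns.

Subjects are compared by the Spearman rank correlation of their masked
beta vectors (robust to outlying voxel values, invariant to monotone
scaling); the dissimilarity is d = 1 - rho, so anticorrelated patterns are
maximally distant (d = 2). Agglomeration uses the complete (maximum-
distance) linkage criterion — a strict rule that yields well-separated
clusters when they exist. The number of clusters is an explicit input; a
largest-merge-gap heuristic is reported as a suggestion but never applied
silently. Direct statistical contrasts between clusters derived from the
same data are circular and are refused unless explicitly overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

log = logging.getLogger(__name__)


def spearman_distance(features: np.ndarray,
                      subject_ids: list[str] | None = None) -> np.ndarray:
    """Condensed pairwise distance matrix d = 1 - Spearman rho.

    Ranks use average tie-handling over each subject's full feature vector
    (for concatenated tasks with equal-length blocks this weights the tasks
    equally).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need a subjects x voxels matrix with >= 3 voxels")
    if np.isnan(X).any():
        raise ValueError("missing feature values")
    const = X.std(axis=1) == 0
    if const.any():
        who = (subject_ids[int(np.flatnonzero(const)[0])] if subject_ids
               else f"row {int(np.flatnonzero(const)[0])}")
        raise ValueError(f"constant feature vector for subject {who}; "
                         "Spearman correlation undefined")
    ranks = stats.rankdata(X, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks ** 2).sum(axis=1))
    rho = (ranks @ ranks.T) / np.outer(norms, norms)
    d = 1.0 - rho
    iu = np.triu_indices(X.shape[0], k=1)
    return np.clip(d[iu], 0.0, 2.0)


def complete_linkage_tree(dist: np.ndarray) -> np.ndarray:
    """Agglomerative merge tree under the maximum-distance criterion."""
    return hierarchy.linkage(dist, method="complete")


def suggest_k(tree: np.ndarray, k_max: int = 6) -> int:
    """Number of clusters at the largest gap between successive merge heights."""
    heights = tree[:, 2]
    n = tree.shape[0] + 1
    gaps = np.diff(heights)
    ks = np.arange(n - 1, 1, -1)  # cutting above merge i leaves n-1-i clusters
    candidates = [(g, k) for g, k in zip(gaps, ks) if k <= k_max]
    if not candidates:
        return 2
    return max(candidates, key=lambda c: c[0])[1]


@dataclass
class ClusterResult:
    """Assignments at the chosen k with a per-cluster composition table."""

    tree: np.ndarray
    k: int
    assignments: np.ndarray          # cluster id per subject, 1..k
    composition: pd.DataFrame
    comparison: pd.DataFrame | None  # two-largest-cluster t-tests on age / IQ


def cut_and_characterize(tree: np.ndarray, k: int, subjects: list) -> ClusterResult:
    """Cut the merge tree into k clusters and tabulate their composition.

    The composition table lists, per cluster: size, DD/TD counts, sex
    counts, age (years) and IQ mean +- sd. When k >= 2, the two largest
    clusters are compared on age and IQ with two-sample t-tests.
    """
    n = tree.shape[0] + 1
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if len(subjects) != n:
        raise ValueError("subject list does not match tree size")
    assignments = hierarchy.fcluster(tree, t=k, criterion="maxclust")

    rows = []
    for c in sorted(set(assignments)):
        members = [s for s, a in zip(subjects, assignments) if a == c]
        ages = np.array([s.age_months for s in members], dtype=float) / 12.0
        iqs = np.array([s.iq for s in members if s.iq is not None], dtype=float)
        rows.append({
            "cluster": c,
            "n": len(members),
            "n_dd": sum(s.group == "DD" for s in members),
            "n_td": sum(s.group == "TD" for s in members),
            "n_male": sum(s.sex == "m" for s in members),
            "n_female": sum(s.sex == "f" for s in members),
            "age_mean_y": float(ages.mean()),
            "age_sd_y": float(ages.std(ddof=1)) if len(ages) > 1 else 0.0,
            "iq_mean": float(iqs.mean()) if iqs.size else np.nan,
            "iq_sd": float(iqs.std(ddof=1)) if iqs.size > 1 else np.nan,
        })
    composition = pd.DataFrame(rows).sort_values("n", ascending=False).reset_index(drop=True)

    comparison = None
    if k >= 2 and len(composition) >= 2:
        c1, c2 = composition["cluster"].iloc[:2]
        rows = []
        for var, getter in (("age_y", lambda s: s.age_months / 12.0),
                            ("iq", lambda s: s.iq)):
            a = np.array([getter(s) for s, asg in zip(subjects, assignments)
                          if asg == c1 and getter(s) is not None], dtype=float)
            b = np.array([getter(s) for s, asg in zip(subjects, assignments)
                          if asg == c2 and getter(s) is not None], dtype=float)
            if len(a) > 1 and len(b) > 1:
                t, p = stats.ttest_ind(a, b)
                rows.append({"variable": var, "t": float(t),
                             "df": len(a) + len(b) - 2, "p": float(p)})
        comparison = pd.DataFrame(rows)
    return ClusterResult(tree=tree, k=k, assignments=assignments,
                         composition=composition, comparison=comparison)


def cluster_subjects(dataset, mask: np.ndarray, task_mode: str, k: int) -> ClusterResult:
    """Distance -> tree -> cut, on masked (possibly concatenated) betas."""
    from .classify import extract_features
    X = extract_features(dataset, mask, task_mode)
    dist = spearman_distance(X, dataset.subject_ids)
    tree = complete_linkage_tree(dist)
    return cut_and_characterize(tree, k, dataset.subjects)


def cluster_group_maps(dataset, assignments: np.ndarray, task: str,
                       mask: np.ndarray, min_members: int = 3,
                       voxel_p: float = 0.01,
                       direct_contrast: bool = False,
                       allow_circular: bool = False) -> dict[int, "object"]:
    """One-sample baseline-contrast t map per cluster.

    Direct between-cluster contrasts are refused: the clusters were formed
    from the very data that would be contrasted, so any difference map
    would be circular. Pass ``allow_circular=True`` to override knowingly.
    """
    from .group import second_level_t
    if direct_contrast and not allow_circular:
        raise ValueError(
            "direct between-cluster contrasts are circular (clusters were derived "
            "from these data); pass allow_circular=True to override")
    assignments = np.asarray(assignments)
    maps = {}
    for c in sorted(set(assignments.tolist())):
        members = assignments == c
        if members.sum() < min_members:
            log.warning("cluster %d has %d < %d members; skipped", c,
                        int(members.sum()), min_members)
            continue
        maps[c] = second_level_t(dataset, task, "one_sample", mask,
                                 subject_mask=members, voxel_p=voxel_p)
    return maps


def dendrogram_figure(tree: np.ndarray, labels: list[str], path=None):
    """Save (or return) a dendrogram plot of the merge tree."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(10, 4))
    hierarchy.dendrogram(tree, labels=labels, ax=ax, color_threshold=0.0)
    ax.set_ylabel("1 - Spearman rho (complete linkage)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
        return None
    return fig
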