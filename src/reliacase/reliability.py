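"""Voxelwise test-retest reliability: ICC(2,1) maps, masking and binning.

The reliability of a contrast beta is quantified per voxel by the
Shrout-Fleiss two-way random-effects, single-measure intraclass correlation
ICC(2,1), estimated over all subjects' session-1 vs session-2 betas. Task
maps are combined by Fisher's z'-transformation (atanh - mean - tanh), and
the analysis mask keeps voxels with combined ICC strictly above a threshold
(default 0.33). Negative ICC estimates are retained as computed; they
simply fall below any positive threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.33

#: half-open ICC ranges of the reliability report, in ascending order
BIN_EDGES = (
    ("poor", 0.33, 0.40),
    ("fair", 0.40, 0.60),
    ("good", 0.60, 0.75),
    ("excellent", 0.75, np.inf),
)


def _icc_2_1_from_moments(n: int, k: int, msr: np.ndarray, msc: np.ndarray,
                          mse: np.ndarray) -> np.ndarray:
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    return np.where(denom == 0, np.nan, icc)


def icc_2_1(values: np.ndarray) -> float:
    """ICC(2,1) of an n-subjects x k-sessions matrix (may be negative).

    Two-way ANOVA decomposition: rows = subjects (random), columns =
    sessions (random), single measures, absolute agreement:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Returns NaN when the matrix carries no variance at all.
    """
    M = np.asarray(values, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected an n x k matrix")
    n, k = M.shape
    if n < 3 or k < 2:
        raise ValueError(f"need n >= 3 subjects and k >= 2 sessions, got {n} x {k}")
    if not np.isfinite(M).all():
        raise ValueError("missing or non-finite entries")
    return float(icc_2_1_map(M[:, :, None])[0])


def icc_2_1_map(values: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) over an (n, k, voxels) stack."""
    M = np.asarray(values, dtype=float)
    n, k, _ = M.shape
    grand = M.mean(axis=(0, 1))
    rows = M.mean(axis=1)       # (n, V)
    cols = M.mean(axis=0)       # (k, V)
    msr = k * ((rows - grand) ** 2).sum(axis=0) / (n - 1)
    msc = n * ((cols - grand) ** 2).sum(axis=0) / (k - 1)
    resid = M - rows[:, None, :] - cols[None, :, :] + grand
    mse = (resid ** 2).sum(axis=(0, 1)) / ((n - 1) * (k - 1))
    return _icc_2_1_from_moments(n, k, msr, msc, mse)


def fisher_combine(maps: list[np.ndarray], clip: float = 1e-7) -> np.ndarray:
    """tanh of the mean atanh of several correlation maps (equal weights)."""
    stack = np.stack([np.clip(m, -1 + clip, 1 - clip) for m in maps])
    return np.tanh(np.arctanh(stack).mean(axis=0))


@dataclass
class ReliabilityMap:
    """Per-task ICC fields, their Fisher-z combination, and the analysis mask."""

    task_icc: dict[str, np.ndarray]
    combined: np.ndarray
    mask: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    brain_mask: np.ndarray | None = None

    @property
    def n_included(self) -> int:
        return int(self.mask.sum())


def build_reliability_mask(dataset, tasks: list[str] | None = None,
                           threshold: float = DEFAULT_THRESHOLD) -> ReliabilityMap:
    """ICC(2,1) per task over all subjects' two sessions, combined and thresholded.

    Inclusion is strict: combined ICC > threshold. The mask is restricted
    to the dataset's brain mask when one is present.
    """
    tasks = tasks if tasks is not None else list(dataset.tasks)
    if len(dataset.sessions) < 2:
        raise ValueError("reliability needs at least two sessions")
    task_icc: dict[str, np.ndarray] = {}
    for task in tasks:
        ti = dataset.task_index(task)
        vals = dataset.betas[:, ti]  # (n, k, x, y, z)
        n, k = vals.shape[:2]
        flat = vals.reshape(n, k, -1)
        if not np.isfinite(flat).all():
            raise ValueError(f"non-finite betas for task {task!r}")
        task_icc[task] = icc_2_1_map(flat).reshape(dataset.grid.dims)
    combined = fisher_combine([task_icc[t] for t in tasks])
    with np.errstate(invalid="ignore"):
        mask = combined > threshold
    if dataset.brain_mask is not None:
        mask &= dataset.brain_mask.astype(bool)
    log.info("reliability mask: %d voxels above ICC %.2f", int(mask.sum()), threshold)
    return ReliabilityMap(task_icc=task_icc, combined=combined, mask=mask,
                          threshold=threshold, brain_mask=dataset.brain_mask)


def tabulate_reliability_bins(rmap: "ReliabilityMap | np.ndarray",
                              threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Reliability-level distribution table.

    Rows: total / excluded / included voxels with percentages of the total,
    then the four named included ranges (poor, fair, good, excellent) with
    counts and percentages of the included voxels. Percentages are rounded
    to one decimal.
    """
    if isinstance(rmap, ReliabilityMap):
        vals = rmap.combined
        if rmap.brain_mask is not None:
            vals = vals[rmap.brain_mask.astype(bool)]
        threshold = rmap.threshold
    else:
        vals = np.asarray(rmap, dtype=float)
    vals = vals[np.isfinite(vals)].ravel()
    total = vals.size
    included = int((vals > threshold).sum())
    excluded = total - included

    def pct(x, denom):
        return round(100.0 * x / denom, 1) if denom else 0.0

    rows = [
        {"range": "total", "bounds": "-1 <= ICC <= 1", "count": total,
         "pct_total": 100.0, "pct_included": ""},
        {"range": "excluded", "bounds": f"ICC <= {threshold}", "count": excluded,
         "pct_total": pct(excluded, total), "pct_included": ""},
        {"range": "included", "bounds": f"{threshold} < ICC <= 1", "count": included,
         "pct_total": pct(included, total), "pct_included": 100.0 if included else 0.0},
    ]
    for name, lo, hi in BIN_EDGES:
        count = int(((vals >= lo) & (vals < hi) & (vals > threshold)).sum())
        rows.append({"range": name, "bounds": f"{lo} <= ICC < {hi}", "count": count,
                     "pct_total": pct(count, total), "pct_included": pct(count, included)})
    return pd.DataFrame(rows)


def dice_overlap(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|); 0 when both maps are empty."""
    a = np.asarray(map_a, dtype=bool)
    b = np.asarray(map_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grids differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a & b).sum() / denom)
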