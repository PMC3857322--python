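"""Crawford test for a deficit: one case against a small control sample.

The Crawford-Howell statistic treats the control sample as data rather
than a population:

    t = (x_case - mean(controls)) / (sd(controls) * sqrt((n + 1) / n))

with df = n - 1, which keeps the type-I rate nominal for control samples
as small as the 16 children used here. Applied voxelwise to session-
averaged betas it yields a signed deviation map per patient; splitting the
significant voxels by sign and cluster-filtering gives over- and
under-activation masks, and the per-voxel percentage of patients with a
significant deviation gives the frequency-of-deviation maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .group import StatMap, apply_cluster_threshold

log = logging.getLogger(__name__)


def crawford_t(x_case: float, controls: np.ndarray) -> tuple[float, int, float]:
    """Crawford-Howell t, df and two-sided p for one case vs a control sample."""
    controls = np.asarray(controls, dtype=float)
    n = controls.size
    if n < 3:
        raise ValueError(f"need at least 3 controls, got {n}")
    sd = controls.std(ddof=1)
    if sd == 0:
        raise ValueError("control sample has zero variance; t undefined")
    t = (float(x_case) - controls.mean()) / (sd * np.sqrt((n + 1) / n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def crawford_t_map(case_values: np.ndarray, control_values: np.ndarray,
                   ) -> tuple[np.ndarray, int, np.ndarray]:
    """Vectorized Crawford test: case field vs (n_controls, ...) control fields."""
    controls = np.asarray(control_values, dtype=float)
    n = controls.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 controls, got {n}")
    mean = controls.mean(axis=0)
    sd = controls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (np.asarray(case_values, dtype=float) - mean) / (sd * np.sqrt((n + 1) / n))
    t = np.where(sd == 0, np.nan, t)
    df = n - 1
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p


@dataclass
class SingleCaseResult:
    """Signed deviation map of one patient with directional significance masks."""

    subject: str
    task: str
    t: np.ndarray
    df: int
    p: np.ndarray
    over_mask: np.ndarray   # t > 0, p < voxel_p, cluster-surviving
    under_mask: np.ndarray  # t < 0, p < voxel_p, cluster-surviving
    voxel_p: float
    kstar: int


def single_case_maps(dataset, case_id: str, task: str, mask: np.ndarray,
                     voxel_p: float = 0.01, kstar: int = 1,
                     connectivity: int = 6) -> SingleCaseResult:
    """Voxelwise Crawford comparison of one patient against all controls.

    The case's session-averaged beta field is tested against the TD group's
    averaged betas inside ``mask``; significant voxels are split by sign
    and each directional mask is cluster-extent filtered at ``kstar``.
    """
    ci = dataset.subject_index(case_id)
    if dataset.subjects[ci].group == "TD":
        raise ValueError(f"{case_id} is a control subject; cases must not be in the "
                         "control sample")
    mask = np.asarray(mask, dtype=bool)
    avg = dataset.averaged(task)
    controls = avg[dataset.group_mask("TD")]
    t, df, p = crawford_t_map(avg[ci], controls)
    t = np.where(mask, t, 0.0)
    p = np.where(mask, p, 1.0)
    t = np.nan_to_num(t, nan=0.0)
    smap = StatMap(t=t, df=df, p=p, mask=mask, voxel_p=voxel_p,
                   contrast=f"{case_id} vs TD ({task})")
    thresholded, _ = apply_cluster_threshold(smap, kstar, connectivity)
    return SingleCaseResult(subject=case_id, task=task, t=t, df=df, p=p,
                            over_mask=thresholded > 0, under_mask=thresholded < 0,
                            voxel_p=voxel_p, kstar=kstar)


@dataclass
class FrequencyMap:
    """Voxelwise percentage of patients with a significant directional deviation."""

    direction: str  # "over" or "under"
    task: str
    percent: np.ndarray
    n_cases: int


def frequency_map(results: list[SingleCaseResult], direction: str) -> FrequencyMap:
    """Combine single-case masks into a frequency-of-deviation map."""
    if direction not in ("over", "under"):
        raise ValueError("direction must be 'over' or 'under'")
    if not results:
        raise ValueError("no single-case results")
    tasks = {r.task for r in results}
    if len(tasks) > 1:
        raise ValueError(f"mixed tasks in frequency map: {sorted(tasks)}")
    masks = [r.over_mask if direction == "over" else r.under_mask for r in results]
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError("single-case masks are on different grids")
    counts = np.sum(masks, axis=0)
    n = len(results)
    return FrequencyMap(direction=direction, task=tasks.pop(),
                        percent=100.0 * counts / n, n_cases=n)
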