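"""Synthetic self-paced block-design studies with known ground truth.

Two entry points:

* :func:`simulate_timeseries` generates raw BOLD time courses (HRF-convolved
  boxcar signal, motion-coupled nuisance, AR(1) noise) for validating the
  first-level GLM;
* :func:`simulate_beta_dataset` generates contrast betas directly — the
  native currency of the downstream pipeline — with a controllable
  test-retest structure and planted group effects.

The beta model per voxel v, subject s, session k is

    beta(s, v, k) = mu_group(v) + deviant_s(v) + b_s(v) + e_{s,k}(v)

with b ~ N(0, sigma_b^2) stable across sessions and e ~ N(0, sigma_e^2)
session noise, so the expected voxelwise ICC(2,1) is
sigma_b^2 / (sigma_b^2 + sigma_e^2) wherever the group offsets are shared.
Outside the brain mask only session noise is present (ICC ~ 0), which is
what makes the reliability mask non-trivial.

The default world emulates a two-group child study: 16 patients (DD) and 16
controls (TD), two tasks (non-symbolic comparison: 4 blocks x 6 trials;
exact calculation: 6 blocks x 4 trials), two sessions, 0.5 s ISI, 14 s rest
baselines, TR 1.6 s, a 30x36x30 grid at 3 mm with an ellipsoidal brain mask
(~15k voxels) and 17 box ROIs named after fronto-parietal number-processing
regions. Patients share an upregulation pattern (vIPS-R, vPMC), controls a
default-network deactivation (CING); each patient additionally draws 1-3
heterogeneous deviant ROIs with large idiosyncratic shifts, encoding the
clinical observation that individual deviation loci overlap little.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm as _glm
from .io import StudyDataset, SubjectRecord, VolumeGrid

log = logging.getLogger(__name__)

TASKS = ("comparison", "calculation")
#: blocks x trials per task
TASK_LAYOUT = {"comparison": (4, 6), "calculation": (6, 4)}
ISI_S = 0.5
BASELINE_S = 14.0
DEFAULT_TR = 1.6
#: median per-trial response time (s); self-paced, so block length follows RT
RT_MEDIAN_S = {"comparison": 1.2, "calculation": 4.1}
RT_LOG_SIGMA = 0.35

#: group mean reaction times (ms) per task, used by the behavior generator
GROUP_RT_MS = {
    ("comparison", "DD"): 1427.0,
    ("comparison", "TD"): 1212.0,
    ("calculation", "DD"): 5295.0,
    ("calculation", "TD"): 4084.0,
}


# ---------------------------------------------------------------------------
# Self-paced designs
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Timing of one self-paced block-design run."""

    task: str
    block_onsets: np.ndarray     # seconds
    block_durations: np.ndarray  # seconds, subject-specific
    trials_per_block: int
    isi: float = ISI_S
    baseline: float = BASELINE_S
    tr: float = DEFAULT_TR
    n_volumes: int = 0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.block_onsets, dtype=float)
        durs = np.asarray(self.block_durations, dtype=float)
        if onsets.shape != durs.shape:
            raise ValueError("onsets and durations differ in length")
        if (durs <= 0).any():
            raise ValueError("block durations must be positive")
        offsets = onsets + durs
        if (np.diff(onsets) <= 0).any() or (onsets[1:] < offsets[:-1]).any():
            raise ValueError("blocks must be ordered and non-overlapping")
        if self.n_volumes == 0:
            self.n_volumes = int(math.ceil((offsets[-1] + self.baseline) / self.tr))
        if self.n_volumes * self.tr < offsets[-1]:
            raise ValueError("run too short for last block")
        self.block_onsets = onsets
        self.block_durations = durs

    @property
    def total_seconds(self) -> float:
        return self.n_volumes * self.tr


def make_self_paced_design(task: str,
                           rt_median_s: float | None = None,
                           rt_log_sigma: float = RT_LOG_SIGMA,
                           tr: float = DEFAULT_TR,
                           rng: np.random.Generator | int | None = None) -> DesignSpec:
    """Sample one subject's self-paced design for a task.

    Per-trial response times are lognormal (median ``rt_median_s``, log-sd
    ``rt_log_sigma``); block duration is the sum of its trials' RTs plus
    (trials - 1) x ISI. A 14 s rest baseline precedes the first block and
    follows every block.
    """
    if task not in TASK_LAYOUT:
        raise ValueError(f"unknown task {task!r}; choose from {sorted(TASK_LAYOUT)}")
    rng = np.random.default_rng(rng)
    n_blocks, n_trials = TASK_LAYOUT[task]
    if rt_median_s is None:
        rt_median_s = RT_MEDIAN_S[task]
    mu = math.log(rt_median_s)
    rts = rng.lognormal(mu, rt_log_sigma, size=(n_blocks, n_trials))
    durations = rts.sum(axis=1) + (n_trials - 1) * ISI_S
    onsets = np.empty(n_blocks)
    t = BASELINE_S
    for b in range(n_blocks):
        onsets[b] = t
        t += durations[b] + BASELINE_S
    return DesignSpec(task=task, block_onsets=onsets, block_durations=durations,
                      trials_per_block=n_trials, tr=tr)


# ---------------------------------------------------------------------------
# Time-series simulation (validates the GLM stage)
# ---------------------------------------------------------------------------

def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], rho: float,
               sigma: float) -> np.ndarray:
    """Stationary AR(1) noise along the first axis, marginal sd ``sigma``."""
    n = shape[0]
    eps = rng.standard_normal(shape)
    out = np.empty(shape)
    out[0] = eps[0]
    innov = math.sqrt(1.0 - rho ** 2)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + innov * eps[t]
    return sigma * out


def simulate_motion(rng: np.random.Generator, n_volumes: int,
                    amplitude: float) -> pd.DataFrame:
    """Six slow random-walk motion parameters (3 translations mm, 3 rotations deg)."""
    cols = ["tx", "ty", "tz", "rx", "ry", "rz"]
    steps = rng.standard_normal((n_volumes, 6)) * amplitude * 0.05
    params = np.cumsum(steps, axis=0)
    return pd.DataFrame(params, columns=cols)


def simulate_timeseries(design: DesignSpec,
                        amplitude: np.ndarray | float,
                        grid_shape: tuple[int, ...] = (4, 4, 4),
                        sigma_noise: float = 1.0,
                        rho: float = 0.0,
                        motion_amplitude: float = 0.0,
                        motion_coupling: float | None = None,
                        rng: np.random.Generator | int | None = None,
                        ) -> tuple[np.ndarray, pd.DataFrame]:
    """BOLD time series: HRF signal + motion-coupled nuisance + AR(1) noise.

    ``amplitude`` is the true task beta, scalar or per-voxel field of
    ``grid_shape``. Returns a (x, y, z, t) volume and a 6-column motion
    table aligned to the volumes.
    """
    if abs(rho) >= 1:
        raise ValueError(f"AR(1) coefficient must satisfy |rho| < 1, got {rho}")
    rng = np.random.default_rng(rng)
    amp = np.broadcast_to(np.asarray(amplitude, dtype=float), grid_shape)
    reg = _glm.block_regressor(design)  # unit peak, one value per volume
    n_t = design.n_volumes
    ts = amp[..., None] * reg  # (x,y,z,t)
    motion = simulate_motion(rng, n_t, motion_amplitude)
    if motion_amplitude > 0:
        coupling = motion_amplitude if motion_coupling is None else motion_coupling
        weights = rng.standard_normal(grid_shape + (6,)) * coupling
        ts = ts + np.einsum("...j,tj->...t", weights, motion.to_numpy())
    if sigma_noise > 0:
        noise = _ar1_noise(rng, (n_t,) + grid_shape, rho, sigma_noise)
        ts = ts + np.moveaxis(noise, 0, -1)
    return np.ascontiguousarray(ts), motion


# ---------------------------------------------------------------------------
# ROI atlas on the default grid
# ---------------------------------------------------------------------------

#: 17 fronto-parietal / subcortical ROIs (name, hemisphere, center voxel).
#: Centers are chosen so the 5x5x5 boxes are pairwise disjoint and lie
#: (mostly) inside the default ellipsoidal brain mask; box voxels falling
#: outside the mask are trimmed.
ROI_SPECS: list[tuple[str, str, tuple[int, int, int]]] = [
    ("THA-R", "R", (19, 18, 15)),
    ("vIPS-L", "L", (8, 23, 16)),
    ("vIPS-R", "R", (21, 23, 16)),
    ("hIPS-L", "L", (8, 16, 21)),
    ("hIPS-R", "R", (21, 16, 21)),
    ("aIPS-L", "L", (8, 9, 18)),
    ("aIPS-R", "R", (21, 9, 18)),
    ("PCL-B", "B", (14, 12, 22)),
    ("aPCL-B", "B", (14, 18, 24)),
    ("aFOP-L", "L", (7, 8, 10)),
    ("aFOP-R", "R", (22, 8, 10)),
    ("CINS-L", "L", (12, 13, 11)),
    ("CINS-R", "R", (17, 13, 11)),
    ("CING-L", "L", (12, 20, 10)),
    ("CING-R", "R", (17, 20, 10)),
    ("vPMC-L", "L", (5, 14, 16)),
    ("vPMC-R", "R", (24, 14, 16)),
]

ROI_HALF_WIDTH = 2  # 5x5x5 boxes


def ellipsoid_mask(grid: VolumeGrid) -> np.ndarray:
    """Ellipsoidal brain mask inscribed in the grid."""
    dims = np.asarray(grid.dims, dtype=float)
    center = (dims - 1) / 2.0
    semi = (dims - 1) / 2.0
    idx = np.indices(grid.dims).astype(float)
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def default_roi_set(grid: VolumeGrid | None = None,
                    brain_mask: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, pd.DataFrame]:
    """Label volume (0 = background) and (label, name, hemisphere) table."""
    grid = grid or VolumeGrid.default()
    if brain_mask is None:
        brain_mask = ellipsoid_mask(grid)
    labels = np.zeros(grid.dims, dtype=np.int16)
    rows = []
    for lab, (name, hemi, center) in enumerate(ROI_SPECS, start=1):
        sl = tuple(slice(max(c - ROI_HALF_WIDTH, 0), min(c + ROI_HALF_WIDTH + 1, d))
                   for c, d in zip(center, grid.dims))
        box = np.zeros(grid.dims, dtype=bool)
        box[sl] = True
        box &= brain_mask
        if (labels[box] != 0).any():
            raise RuntimeError(f"ROI {name} overlaps a previous ROI")
        labels[box] = lab
        rows.append({"label": lab, "name": name, "hemisphere": hemi,
                     "n_voxels": int(box.sum())})
    return labels, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Direct beta-map simulation
# ---------------------------------------------------------------------------

@dataclass
class RoiEffect:
    """Group mean shift (beta units) planted inside one ROI."""

    roi: str
    dd: float = 0.0
    td: float = 0.0


#: Default planted topography: a strong patient-only upregulation in right
#: ventral IPS (the discriminative ROI), a weaker shared patient pattern in
#: ventral premotor cortex, and a control-only default-network deactivation
#: in the cingulate gyrus.
DEFAULT_EFFECTS: tuple[RoiEffect, ...] = (
    RoiEffect("vIPS-R", dd=2.0),
    RoiEffect("vPMC-L", dd=1.5),
    RoiEffect("vPMC-R", dd=1.5),
    RoiEffect("CING-L", td=-2.0),
    RoiEffect("CING-R", td=-2.0),
)

#: Task-positive activation shared by both groups (horizontal IPS).
DEFAULT_COMMON: dict[str, float] = {"hIPS-L": 1.0, "hIPS-R": 1.0}

#: ROIs from which each patient draws idiosyncratic deviant blobs.
DEFAULT_DEVIANT_POOL: tuple[str, ...] = ("PCL-B", "aPCL-B", "aFOP-L", "aFOP-R")


@dataclass
class BetaSimConfig:
    """Stated world for the direct beta-map generator."""

    n_dd: int = 16
    n_td: int = 16
    tasks: tuple[str, ...] = TASKS
    n_sessions: int = 2
    sigma_b: float = 1.0   # between-subject (stable) sd
    sigma_e: float = 1.0   # session-noise sd
    effects: tuple[RoiEffect, ...] = DEFAULT_EFFECTS
    common: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COMMON))
    deviant_pool: tuple[str, ...] = DEFAULT_DEVIANT_POOL
    deviant_sd_units: float = 5.0  # deviant shift in control-SD units
    deviant_rois_range: tuple[int, int] = (1, 3)
    heterogeneity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dd < 2 or self.n_td < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("variance components must be non-negative")


def _roi_mask(labels: np.ndarray, table: pd.DataFrame, name: str) -> np.ndarray:
    row = table[table["name"] == name]
    if row.empty:
        raise ValueError(f"effect references unknown ROI {name!r}")
    return labels == int(row["label"].iloc[0])


def simulate_behavior(rng: np.random.Generator, group: str, tasks,
                      n_sessions: int) -> pd.DataFrame:
    """Per task x session mean RT (ms) and accuracy for one subject."""
    rows = []
    for task in tasks:
        base = GROUP_RT_MS[(task, group)] * rng.lognormal(0.0, 0.25)
        for sess in range(1, n_sessions + 1):
            rows.append({
                "task": task,
                "session": sess,
                "rt_ms": base * rng.lognormal(0.0, 0.05),
                "accuracy": float(np.clip(rng.normal(0.92, 0.05), 0.0, 1.0)),
            })
    return pd.DataFrame(rows)


def simulate_beta_dataset(config: BetaSimConfig | None = None,
                          grid: VolumeGrid | None = None,
                          roi_labels: np.ndarray | None = None,
                          roi_table: pd.DataFrame | None = None,
                          brain_mask: np.ndarray | None = None) -> StudyDataset:
    """Generate a full two-group, two-task, two-session beta study.

    Returns a :class:`StudyDataset` whose ``truth`` dict records everything
    that was planted: the expected ICC field, the ROI atlas, the effect
    table and each patient's deviant ROIs with signed shifts.
    """
    config = config or BetaSimConfig()
    grid = grid or VolumeGrid.default()
    if brain_mask is None:
        brain_mask = ellipsoid_mask(grid)
    if roi_labels is None:
        roi_labels, roi_table = default_roi_set(grid, brain_mask)
    elif roi_table is None:
        raise ValueError("roi_labels given without roi_table")
    if roi_labels.shape != grid.dims:
        raise ValueError(
            f"ROI label volume shape {roi_labels.shape} does not match grid {grid.dims}")
    rng = np.random.default_rng(config.seed)

    # group mean fields
    mu = {g: np.zeros(grid.dims) for g in ("DD", "TD")}
    for name, amp in config.common.items():
        m = _roi_mask(roi_labels, roi_table, name)
        mu["DD"][m] += amp
        mu["TD"][m] += amp
    for eff in config.effects:
        m = _roi_mask(roi_labels, roi_table, eff.roi)
        mu["DD"][m] += eff.dd
        mu["TD"][m] += eff.td

    control_sd = math.sqrt(config.sigma_b ** 2 + config.sigma_e ** 2 / 2.0)
    deviant_shift = config.deviant_sd_units * control_sd

    subjects: list[SubjectRecord] = []
    deviants: dict[str, dict[str, float]] = {}
    iq_params = {"DD": (99, 7), "TD": (107, 13)}
    for g, n in (("DD", config.n_dd), ("TD", config.n_td)):
        for i in range(n):
            sid = f"{g.lower()}{i + 1:02d}"
            subjects.append(SubjectRecord(
                id=sid, group=g,
                age_months=int(np.clip(rng.normal(98, 10), 77, 125)),
                iq=int(np.clip(rng.normal(*iq_params[g]), 85, 150)),
                sex="m" if i % 2 == 0 else "f",
                behavior=simulate_behavior(rng, g, config.tasks, config.n_sessions),
            ))
            if g == "DD" and config.heterogeneity and config.deviant_pool:
                lo, hi = config.deviant_rois_range
                m = int(rng.integers(lo, hi + 1))
                chosen = rng.choice(len(config.deviant_pool),
                                    size=min(m, len(config.deviant_pool)), replace=False)
                deviants[sid] = {
                    config.deviant_pool[j]: float(rng.choice([-1.0, 1.0]) * deviant_shift)
                    for j in sorted(chosen)
                }

    n_sub = len(subjects)
    n_task = len(config.tasks)
    n_sess = config.n_sessions
    shape = (n_sub, n_task, n_sess) + grid.dims
    betas = np.zeros(shape)
    b = rng.standard_normal((n_sub, n_task) + grid.dims) * config.sigma_b
    b *= brain_mask  # no stable signal outside the brain
    e = rng.standard_normal(shape) * config.sigma_e
    for si, subj in enumerate(subjects):
        base = mu[subj.group].copy()
        for roi, shift in deviants.get(subj.id, {}).items():
            base = base + shift * _roi_mask(roi_labels, roi_table, roi)
        betas[si] = base[None, None] + b[si][:, None] + e[si]

    denom = config.sigma_b ** 2 + config.sigma_e ** 2
    expected_icc = np.where(brain_mask,
                            (config.sigma_b ** 2 / denom) if denom > 0 else 0.0,
                            0.0)
    truth = {
        "sigma_b": config.sigma_b,
        "sigma_e": config.sigma_e,
        "expected_icc": expected_icc,
        "roi_labels": roi_labels,
        "roi_table": roi_table,
        "effects": [{"roi": e_.roi, "dd": e_.dd, "td": e_.td} for e_ in config.effects],
        "common": dict(config.common),
        "deviants": deviants,
        "deviant_shift": deviant_shift,
        "seed": config.seed,
    }
    log.info("simulated beta study: %d subjects, %d tasks, %d sessions, "
             "%d brain voxels", n_sub, n_task, n_sess, int(brain_mask.sum()))
    return StudyDataset(grid=grid, subjects=subjects, tasks=list(config.tasks),
                        sessions=list(range(1, n_sess + 1)), betas=betas,
                        brain_mask=brain_mask, truth=truth)
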