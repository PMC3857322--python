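"""Second-level t maps with Monte-Carlo cluster-extent correction.

One-sample (per group, against zero) and two-sample (patients vs controls)
t maps are computed on session-averaged betas inside the reliability mask.
Multiple comparisons are handled by a cluster-extent threshold calibrated
with a Monte-Carlo null simulation: smooth Gaussian noise fields are
thresholded at the voxel-level p, and the minimum surviving cluster size
k* is the smallest extent whose null exceedance probability is at most the
family-wise alpha (the AlphaSim procedure).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

log = logging.getLogger(__name__)

T_CAP = 1e6  # surrogate |t| for zero-variance voxels


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3-D adjacency footprint: 6 (faces) or 26 (faces+edges+corners)."""
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


@dataclass
class StatMap:
    """Voxelwise t field with its p values, defined inside a mask."""

    t: np.ndarray
    df: int
    p: np.ndarray
    mask: np.ndarray
    contrast: str
    voxel_p: float = 0.01
    qc_zero_variance: np.ndarray | None = None


def _one_sample(values: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(zero, np.sign(mean) * T_CAP, t)
    return t, n - 1, zero


def _two_sample(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    n1, n2 = a.shape[0], b.shape[0]
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    zero = sp2 == 0
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = np.where(zero, np.sign(diff) * T_CAP, t)
    return t, n1 + n2 - 2, zero


def second_level_t(dataset, task: str, mode: str, mask: np.ndarray,
                   group: str | None = None, voxel_p: float = 0.01,
                   subject_mask: np.ndarray | None = None) -> StatMap:
    """Second-level t map on session-averaged betas, restricted to ``mask``.

    ``mode`` is ``"one_sample"`` (betas of one group against zero; pass
    ``group`` or an explicit boolean ``subject_mask``) or ``"two_sample"``
    (patients minus controls, pooled variance). p values are two-sided.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty analysis mask")
    avg = dataset.averaged(task)  # (n_sub, x, y, z)
    flat = avg.reshape(avg.shape[0], -1)[:, mask.ravel()]
    if mode == "one_sample":
        if subject_mask is None:
            if group is None:
                raise ValueError("one_sample mode needs a group or subject_mask")
            subject_mask = dataset.group_mask(group)
        t, df, zero = _one_sample(flat[subject_mask])
        contrast = f"{task}: {group or 'subset'} > baseline"
    elif mode == "two_sample":
        t, df, zero = _two_sample(flat[dataset.group_mask("DD")],
                                  flat[dataset.group_mask("TD")])
        contrast = f"{task}: DD > TD"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out_t = np.zeros(mask.shape)
    out_p = np.ones(mask.shape)
    out_z = np.zeros(mask.shape, dtype=bool)
    out_t[mask], out_p[mask], out_z[mask] = t, p, zero
    if zero.any():
        log.warning("%s: %d zero-variance voxels capped", contrast, int(zero.sum()))
    return StatMap(t=out_t, df=df, p=out_p, mask=mask, contrast=contrast,
                   voxel_p=voxel_p, qc_zero_variance=out_z)


def estimate_smoothness(volumes: np.ndarray, mask: np.ndarray,
                        voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Per-axis smoothness (FWHM, mm) from the variance of spatial derivatives.

    For a Gaussian autocorrelation the neighbor-difference variance ratio
    x = var(d)/ (2 var) gives FWHM = voxel * sqrt(-2 ln 2 / ln(1 - x)).
    Sampled fields cannot show smoothness below the voxel size, so the
    estimate is floored there (spatially independent noise -> one voxel).
    Axes thinner than 2 voxels are excluded (NaN) with a warning.
    """
    vols = np.asarray(volumes, dtype=float)
    if vols.ndim == 3:
        vols = vols[None]
    if vols.shape[0] < 2:
        raise ValueError("need at least 2 volumes to estimate smoothness")
    mask = np.asarray(mask, dtype=bool)
    demeaned = vols - vols.reshape(vols.shape[0], -1)[:, mask.ravel()].mean(axis=1)[:, None, None, None]
    var = (demeaned ** 2)[:, mask].mean()
    if var == 0:
        raise ValueError("volumes are constant inside the mask; no gradients")
    fwhm = np.full(3, np.nan)
    for axis in range(3):
        lo = tuple(slice(0, -1) if a == axis else slice(None) for a in range(3))
        hi = tuple(slice(1, None) if a == axis else slice(None) for a in range(3))
        pair = mask[lo] & mask[hi]  # voxel pairs fully inside the mask
        if mask.shape[axis] < 2 or pair.sum() < 10:
            warnings.warn(f"axis {axis} too thin for smoothness estimation; excluded",
                          stacklevel=2)
            continue
        diffs = np.diff(demeaned, axis=axis + 1)
        vard = (diffs[:, pair] ** 2).mean()
        x = vard / (2.0 * var)
        if x >= 1.0 - 1e-12:
            fwhm[axis] = voxel_size[axis]
        else:
            est = voxel_size[axis] * np.sqrt(-2.0 * np.log(2.0) / np.log1p(-x))
            fwhm[axis] = max(est, voxel_size[axis])
    return fwhm


@dataclass
class ClusterThresholdSpec:
    """Inputs and result of the Monte-Carlo extent calibration."""

    voxel_p: float = 0.01
    alpha: float = 0.05
    iterations: int = 1000
    fwhm_mm: float | np.ndarray = 0.0
    connectivity: int = 6
    seed: int = 0
    kstar: int | None = None
    max_cluster_sizes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.iterations < 100:
            raise ValueError("need at least 100 Monte-Carlo iterations")
        if not (0 < self.voxel_p < 1) or not (0 < self.alpha <= 1):
            raise ValueError("voxel_p and alpha must be in (0, 1]")


def _max_cluster_size(binary: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def monte_carlo_cluster_extent(spec: ClusterThresholdSpec, mask: np.ndarray,
                               voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
                               ) -> ClusterThresholdSpec:
    """Calibrate the minimum cluster extent k* on smooth Gaussian null fields.

    Each iteration fills the grid with N(0,1) noise, smooths it to the
    requested FWHM, renormalizes to unit variance inside the mask,
    thresholds two-sided at the voxel p, and records the largest cluster
    over both signs. k* is the smallest extent k with
    P(max cluster >= k) <= alpha.
    """
    if spec.alpha * spec.iterations < 5:
        warnings.warn("alpha x iterations < 5: unstable tail estimate", stacklevel=2)
    mask = np.asarray(mask, dtype=bool)
    structure = connectivity_structure(spec.connectivity)
    rng = np.random.default_rng(spec.seed)
    fwhm = np.broadcast_to(np.asarray(spec.fwhm_mm, dtype=float), (3,))
    sigma_vox = np.where(np.isfinite(fwhm), fwhm, 0.0) / (2.0 * np.sqrt(2.0 * np.log(2.0))) \
        / np.asarray(voxel_size)
    zcrit = stats.norm.ppf(1.0 - spec.voxel_p / 2.0)
    maxima = np.zeros(spec.iterations, dtype=int)
    for it in range(spec.iterations):
        field_ = rng.standard_normal(mask.shape)
        if (sigma_vox > 0).any():
            field_ = ndimage.gaussian_filter(field_, sigma=sigma_vox)
        vals = field_[mask]
        field_ = (field_ - vals.mean()) / vals.std()
        supra_pos = (field_ > zcrit) & mask
        supra_neg = (field_ < -zcrit) & mask
        maxima[it] = max(_max_cluster_size(supra_pos, structure),
                         _max_cluster_size(supra_neg, structure))
    kstar = 1
    while (maxima >= kstar).mean() > spec.alpha:
        kstar += 1
    spec.kstar = int(kstar)
    spec.max_cluster_sizes = maxima
    log.info("Monte-Carlo extent threshold: k* = %d (voxel p=%g, alpha=%g, %d iters)",
             kstar, spec.voxel_p, spec.alpha, spec.iterations)
    return spec


def apply_cluster_threshold(smap: StatMap, kstar: int,
                            connectivity: int = 6) -> tuple[np.ndarray, pd.DataFrame]:
    """Remove suprathreshold clusters smaller than k*.

    Suprathreshold voxels (p < voxel-level threshold) are grouped by sign
    under the connectivity rule. Returns the thresholded t map (zero where
    removed) and a table of surviving clusters (size, peak |t|, peak voxel
    index, sign).
    """
    structure = connectivity_structure(connectivity)
    out = np.zeros_like(smap.t)
    rows = []
    for sign in (1, -1):
        supra = (smap.p < smap.voxel_p) & (np.sign(smap.t) == sign) & smap.mask
        labels, n = ndimage.label(supra, structure=structure)
        for lab in range(1, n + 1):
            members = labels == lab
            size = int(members.sum())
            if size < kstar:
                continue
            tvals = np.where(members, smap.t, 0.0)
            peak_flat = int(np.abs(tvals).argmax())
            peak = tuple(int(v) for v in np.unravel_index(peak_flat, smap.t.shape))
            out[members] = smap.t[members]
            rows.append({"size": size, "peak_t": float(smap.t[peak]),
                         "peak_x": peak[0], "peak_y": peak[1], "peak_z": peak[2],
                         "sign": sign})
    table = pd.DataFrame(rows, columns=["size", "peak_t", "peak_x", "peak_y",
                                        "peak_z", "sign"])
    if not table.empty:
        table = table.sort_values("size", ascending=False).reset_index(drop=True)
    return out, table
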