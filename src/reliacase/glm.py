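"""First-level block-design GLM with AR(1) serial-correlation correction.

The model regresses each voxel's BOLD time course on an HRF-convolved task
boxcar plus nuisance terms (six motion parameters, low-frequency cosine
drifts, intercept). Serial correlation is handled by single-pass
Cochrane-Orcutt: an OLS fit, a pooled lag-1 autocorrelation estimate from
its residuals, then one prewhitening pass and a refit. The task-regressor
coefficient is the "activation minus baseline" contrast beta, with the
unmodeled rest periods acting as the implicit baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

log = logging.getLogger(__name__)


def canonical_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds.

    SPM-style parameterization: response gamma peaking at 6 s, undershoot
    gamma peaking at 16 s, peak-to-undershoot ratio 6. Normalized to unit
    maximum.
    """
    t = np.arange(0.0, duration, dt)

    def gpdf(x, shape, scale):
        x = np.maximum(x, 1e-12)
        return np.exp((shape - 1) * np.log(x) - x / scale
                      - gammaln(shape) - shape * np.log(scale))

    # gamma mode = (shape - 1) * scale: shapes 7 / 17 put the response peak
    # at 6 s and the undershoot trough near 16 s
    h = gpdf(t, 7.0, 1.0) - gpdf(t, 17.0, 1.0) / 6.0
    return h / h.max()


def block_regressor(design, oversample_dt: float = 0.1) -> np.ndarray:
    """HRF-convolved task boxcar sampled at volume acquisition times.

    Returns one value per volume, scaled to unit peak. Convolution is done
    on an oversampled time axis so self-paced (non-TR-aligned) block onsets
    are represented faithfully.
    """
    n_fine = int(np.ceil((design.n_volumes * design.tr + 32.0) / oversample_dt))
    boxcar = np.zeros(n_fine)
    tfine = np.arange(n_fine) * oversample_dt
    for onset, dur in zip(design.block_onsets, design.block_durations):
        boxcar[(tfine >= onset) & (tfine < onset + dur)] = 1.0
    conv = np.convolve(boxcar, canonical_hrf(oversample_dt))[:n_fine]
    vol_times = np.arange(design.n_volumes) * design.tr
    reg = np.interp(vol_times, tfine, conv)
    peak = np.abs(reg).max()
    if peak == 0:
        raise ValueError("task regressor is identically zero")
    return reg / peak


@dataclass
class DesignMatrix:
    """Volumes x regressors design with named columns."""

    matrix: np.ndarray
    names: list[str]
    task_columns: list[int]
    tr: float

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


def _dct_drift(n_volumes: int, cycles: int) -> np.ndarray:
    """Discrete-cosine drift columns, ``cycles`` slow cosines (high-pass)."""
    t = (np.arange(n_volumes) + 0.5) / n_volumes
    return np.column_stack([np.cos(np.pi * k * t) for k in range(1, cycles + 1)])


def build_design_matrix(design, motion: np.ndarray | None,
                        highpass_cycles: int = 2) -> DesignMatrix:
    """Assemble [task regressor, motion, cosine drifts, intercept].

    ``motion`` is a volumes x 6 table (or None). All-zero motion columns
    are dropped with a warning; the matrix must be full column rank.
    """
    task = block_regressor(design)
    cols = [task]
    names = ["task"]
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != design.n_volumes:
            raise ValueError(
                f"motion table has {motion.shape[0]} rows, design has {design.n_volumes} volumes"
            )
        for j in range(motion.shape[1]):
            col = motion[:, j] - motion[:, j].mean()
            if np.allclose(col, 0.0):
                warnings.warn(f"motion column {j} is constant; dropped", stacklevel=2)
                continue
            cols.append(col)
            names.append(f"motion_{j}")
    if highpass_cycles > 0:
        drift = _dct_drift(design.n_volumes, highpass_cycles)
        for k in range(drift.shape[1]):
            cols.append(drift[:, k])
            names.append(f"drift_{k + 1}")
    cols.append(np.ones(design.n_volumes))
    names.append("intercept")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept):
                bad.append(names[j])
            else:
                kept.append(j)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(matrix=X, names=names, task_columns=[0], tr=design.tr)


@dataclass
class BetaImage:
    """Task-contrast beta field for one subject / task / session."""

    data: np.ndarray
    subject: str
    task: str
    session: str


@dataclass
class FirstLevelResult:
    beta: np.ndarray          # task-contrast estimate per voxel
    residuals: np.ndarray     # whitened residuals, time x voxels
    rho: float                # pooled AR(1) coefficient used for whitening
    qc_constant: np.ndarray   # voxels with (near-)constant time series
    se: np.ndarray            # AR(1)-corrected standard error of the beta


def _ols(X: np.ndarray, Y: np.ndarray):
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return coef, Y - X @ coef


def ar1_whiten(A: np.ndarray, rho: float) -> np.ndarray:
    """Apply the AR(1) prewhitening transform to rows of a time x ... array."""
    out = np.empty_like(A, dtype=float)
    out[0] = np.sqrt(1.0 - rho ** 2) * A[0]
    out[1:] = A[1:] - rho * A[:-1]
    return out


def fit_first_level(ts: np.ndarray, X: DesignMatrix) -> FirstLevelResult:
    """Fit the GLM voxelwise with one-pass Cochrane-Orcutt AR(1) correction.

    ``ts`` is either a 4-D volume (x, y, z, t) or a 2-D (t, voxels) array.
    rho is estimated once per run, pooled over voxels, from the lag-1
    autocorrelation of the OLS residuals; this is stable for the short runs
    typical of child data (a per-voxel variant would be noisy at ~100
    volumes).
    """
    spatial_shape = None
    if ts.ndim == 4:
        spatial_shape = ts.shape[:3]
        Y = ts.reshape(-1, ts.shape[3]).T
    elif ts.ndim == 2:
        Y = ts
    else:
        raise ValueError("time series must be (x,y,z,t) or (t, voxels)")
    M = X.matrix
    if Y.shape[0] != M.shape[0]:
        raise ValueError(f"time series has {Y.shape[0]} volumes, design has {M.shape[0]}")

    qc_constant = Y.std(axis=0) < 1e-12

    _, resid = _ols(M, Y)
    num = (resid[1:] * resid[:-1]).sum()
    den = (resid ** 2).sum()
    # a noise-free fit leaves only numerical round-off; do not whiten on it
    if den <= 1e-10 * max((Y ** 2).sum(), 1e-300):
        rho = 0.0
    else:
        rho = float(np.clip(num / den, -0.999, 0.999))

    Mw = ar1_whiten(M, rho)
    Yw = ar1_whiten(Y, rho)
    coef, residw = _ols(Mw, Yw)
    task_col = X.task_columns[0]
    beta = coef[task_col].copy()
    beta[qc_constant] = 0.0

    dof = Mw.shape[0] - Mw.shape[1]
    sigma2 = (residw ** 2).sum(axis=0) / max(dof, 1)
    xtx_inv = np.linalg.inv(Mw.T @ Mw)
    se = np.sqrt(sigma2 * xtx_inv[task_col, task_col])

    if spatial_shape is not None:
        beta = beta.reshape(spatial_shape)
        se = se.reshape(spatial_shape)
        qc_constant = qc_constant.reshape(spatial_shape)
    return FirstLevelResult(beta=beta, residuals=residw, rho=rho,
                            qc_constant=qc_constant, se=se)


def average_sessions(b1: BetaImage, b2: BetaImage) -> BetaImage:
    """Voxelwise mean of the two sessions' betas (measurement-error reduction)."""
    if b1.subject != b2.subject or b1.task != b2.task:
        raise ValueError(
            f"cannot average across subjects/tasks: "
            f"({b1.subject},{b1.task}) vs ({b2.subject},{b2.task})"
        )
    if b1.data.shape != b2.data.shape:
        raise ValueError("session betas are on different grids")
    return BetaImage(data=(b1.data + b2.data) / 2.0, subject=b1.subject,
                     task=b1.task, session="avg")
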