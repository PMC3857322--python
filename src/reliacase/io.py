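"""On-disk formats and in-memory containers for a test-retest beta study.

A *study* is a set of per-subject, per-task, per-session contrast (beta)
volumes on one shared voxel grid, plus subject metadata. On disk it is a
manifest TSV (one row per run), a metadata TSV (one row per subject) and
NIfTI-1 volumes; in memory it is a :class:`StudyDataset`.

Conventions: voxel indices are 0-based; masks are stored as NIfTI volumes
of 0/1; world coordinates follow the NIfTI affine. All tabular files are
TSV with a header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["subject", "task", "session", "beta_path"]
METADATA_COLUMNS = ["subject", "group", "age_months"]

GROUPS = ("DD", "TD")


class StudyValidationError(ValueError):
    """A manifest, metadata table or volume violates the study contract."""


class GridMismatchError(StudyValidationError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel grid: shape, voxel size (mm) and voxel-to-world affine."""

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        vox = tuple(float(v) for v in self.voxel_size)
        if any(d <= 0 for d in dims):
            raise StudyValidationError(f"grid dims must be positive, got {dims}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise StudyValidationError("affine must be 4x4")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise StudyValidationError("affine must be invertible")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size", vox)
        object.__setattr__(self, "affine", aff)

    @classmethod
    def default(cls, dims: tuple[int, int, int] = (30, 36, 30), voxel_mm: float = 3.0) -> "VolumeGrid":
        """Isotropic grid centered at the world origin (default 3 mm)."""
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        affine[:3, 3] = -voxel_mm * (np.asarray(dims) - 1) / 2.0
        return cls(tuple(dims), (voxel_mm,) * 3, affine)

    @classmethod
    def from_img(cls, img: nib.Nifti1Image) -> "VolumeGrid":
        zooms = img.header.get_zooms()[:3]
        return cls(tuple(img.shape[:3]), tuple(float(z) for z in zooms), np.asarray(img.affine))

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.dims == other.dims and np.allclose(self.affine, other.affine, atol=atol)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))


@dataclass
class SubjectRecord:
    """Metadata for one child: group membership, age and optional covariates."""

    id: str
    group: str
    age_months: int
    iq: int | None = None
    sex: str | None = None
    behavior: pd.DataFrame | None = None  # task x session mean RT (ms) / accuracy

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise StudyValidationError(
                f"subject {self.id!r}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if self.behavior is not None:
            rt = self.behavior.get("rt_ms")
            acc = self.behavior.get("accuracy")
            if rt is not None and (np.asarray(rt, dtype=float) <= 0).any():
                raise StudyValidationError(f"subject {self.id!r}: RT must be > 0")
            if acc is not None:
                a = np.asarray(acc, dtype=float)
                if ((a < 0) | (a > 1)).any():
                    raise StudyValidationError(f"subject {self.id!r}: accuracy must be in [0, 1]")


@dataclass
class StudyDataset:
    """All beta volumes of a study on one shared grid, with subject labels.

    ``betas`` has shape (n_subjects, n_tasks, n_sessions, nx, ny, nz), with
    axes ordered as ``subjects`` / ``tasks`` / ``sessions``.
    """

    grid: VolumeGrid
    subjects: list[SubjectRecord]
    tasks: list[str]
    sessions: list[int]
    betas: np.ndarray
    brain_mask: np.ndarray | None = None
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        expected = (len(self.subjects), len(self.tasks), len(self.sessions)) + self.grid.dims
        if self.betas.shape != expected:
            raise GridMismatchError(
                f"beta array shape {self.betas.shape} does not match study layout {expected}"
            )
        if self.brain_mask is not None and self.brain_mask.shape != self.grid.dims:
            raise GridMismatchError("brain mask does not match grid dims")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise StudyValidationError("duplicate subject ids")

    # -- indexing helpers ------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    @property
    def groups(self) -> np.ndarray:
        return np.asarray([s.group for s in self.subjects])

    def subject_index(self, subject_id: str) -> int:
        try:
            return self.subject_ids.index(subject_id)
        except ValueError:
            raise KeyError(f"unknown subject {subject_id!r}") from None

    def task_index(self, task: str) -> int:
        try:
            return self.tasks.index(task)
        except ValueError:
            raise KeyError(f"unknown task {task!r}; tasks are {self.tasks}") from None

    def group_mask(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise StudyValidationError(f"unknown group {group!r}")
        return self.groups == group

    def averaged(self, task: str) -> np.ndarray:
        """Session-averaged betas for one task, shape (n_subjects, nx, ny, nz)."""
        return self.betas[:, self.task_index(task)].mean(axis=1)

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": s.id,
                "group": s.group,
                "age_months": s.age_months,
                "iq": s.iq if s.iq is not None else "",
                "sex": s.sex if s.sex is not None else "",
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI volume I/O
# ---------------------------------------------------------------------------

def write_map(volume: np.ndarray, grid: VolumeGrid, path: str | Path) -> None:
    """Write a voxel field (float or boolean) as a NIfTI-1 volume.

    Boolean fields are stored as uint8 0/1; float fields round-trip
    bit-identically (float64 on disk). A 4-D array is written as a
    time series whose spatial dims must match the grid.
    """
    volume = np.asarray(volume)
    if volume.shape[:3] != grid.dims or volume.ndim not in (3, 4):
        raise GridMismatchError(
            f"volume shape {volume.shape} does not match grid dims {grid.dims}"
        )
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"output directory does not exist: {path.parent}")
    if volume.dtype == bool:
        data = volume.astype(np.uint8)
    else:
        data = volume.astype(np.float64)
    img = nib.Nifti1Image(data, grid.affine)
    zooms = grid.voxel_size + (1.0,) * (data.ndim - 3)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_map(path: str | Path, grid: VolumeGrid | None = None) -> tuple[np.ndarray, VolumeGrid]:
    """Read a NIfTI volume; optionally verify it sits on an expected grid."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such volume: {path}")
    img = nib.load(str(path))
    got = VolumeGrid.from_img(img)
    if grid is not None and not grid.matches(got):
        raise GridMismatchError(
            f"{path}: grid {got.dims}/{np.round(got.affine, 3).tolist()} does not match "
            f"expected {grid.dims}/{np.round(grid.affine, 3).tolist()}"
        )
    return np.asarray(img.get_fdata(dtype=np.float64)), got


# ---------------------------------------------------------------------------
# Study-level I/O
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"missing {what} file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"subject": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StudyValidationError(f"{what} {path} lacks required columns {missing}")
    return df


def read_study(manifest_path: str | Path, metadata_path: str | Path) -> StudyDataset:
    """Load a study from a run manifest and a subject-metadata table.

    The manifest lists one row per run (subject, task, session, beta_path);
    the metadata table lists one row per subject. All volumes must share one
    grid; (subject, task, session) must be unique and complete.
    """
    manifest_dir = Path(manifest_path).parent
    manifest = _read_tsv(manifest_path, MANIFEST_COLUMNS, "manifest")
    meta = _read_tsv(metadata_path, METADATA_COLUMNS, "metadata")
    if manifest.empty:
        raise StudyValidationError("no runs: manifest is empty")

    dup = manifest.duplicated(subset=["subject", "task", "session"])
    if dup.any():
        row = manifest[dup].iloc[0]
        raise StudyValidationError(
            f"duplicate run (subject={row.subject}, task={row.task}, session={row.session})"
        )

    subjects = []
    for _, row in meta.iterrows():
        iq = row.get("iq")
        sex = row.get("sex")
        subjects.append(
            SubjectRecord(
                id=str(row["subject"]),
                group=str(row["group"]),
                age_months=int(row["age_months"]),
                iq=None if pd.isna(iq) or iq == "" else int(iq),
                sex=None if pd.isna(sex) or sex == "" else str(sex),
            )
        )
    subject_ids = [s.id for s in subjects]
    tasks = sorted(manifest["task"].unique())
    sessions = sorted(int(s) for s in manifest["session"].unique())

    grid: VolumeGrid | None = None
    betas = None
    seen = np.zeros((len(subjects), len(tasks), len(sessions)), dtype=bool)
    for i, row in manifest.iterrows():
        sid = str(row["subject"])
        if sid not in subject_ids:
            raise StudyValidationError(f"manifest row {i}: subject {sid!r} not in metadata")
        p = Path(row["beta_path"])
        if not p.is_absolute():
            p = manifest_dir / p
        if not p.exists():
            raise IOError(f"manifest row {i} (subject={sid}): missing volume {p}")
        vol, got = read_map(p)
        if grid is None:
            grid = got
            betas = np.zeros((len(subjects), len(tasks), len(sessions)) + grid.dims)
        elif not grid.matches(got):
            raise GridMismatchError(
                f"manifest row {i} ({p}): grid {got.dims} does not match study grid {grid.dims}"
            )
        si = subject_ids.index(sid)
        ti = tasks.index(row["task"])
        ki = sessions.index(int(row["session"]))
        betas[si, ti, ki] = vol
        seen[si, ti, ki] = True

    if not seen.all():
        si, ti, ki = np.argwhere(~seen)[0]
        raise StudyValidationError(
            f"missing run: subject={subject_ids[si]} task={tasks[ti]} session={sessions[ki]}"
        )
    log.info("read study: %d subjects x %d tasks x %d sessions on grid %s",
             len(subjects), len(tasks), len(sessions), grid.dims)
    return StudyDataset(grid=grid, subjects=subjects, tasks=tasks,
                        sessions=sessions, betas=betas)


def write_study(dataset: StudyDataset, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a study to disk; returns (manifest_path, metadata_path)."""
    out_dir = Path(out_dir)
    beta_dir = out_dir / "betas"
    beta_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for si, subj in enumerate(dataset.subjects):
        for ti, task in enumerate(dataset.tasks):
            for ki, sess in enumerate(dataset.sessions):
                name = f"{subj.id}_{task}_{sess}_beta.nii.gz"
                write_map(dataset.betas[si, ti, ki], dataset.grid, beta_dir / name)
                rows.append({"subject": subj.id, "task": task, "session": sess,
                             "beta_path": f"betas/{name}"})
    manifest_path = out_dir / "manifest.tsv"
    metadata_path = out_dir / "metadata.tsv"
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    dataset.metadata_frame().to_csv(metadata_path, sep="\t", index=False)
    if dataset.brain_mask is not None:
        write_map(dataset.brain_mask, dataset.grid, out_dir / "brain_mask.nii.gz")
    return manifest_path, metadata_path
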