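"""Shared fixtures: the default synthetic study and small custom datasets."""

import numpy as np
import pandas as pd
import pytest

from reliacase import simulate as sim
from reliacase import reliability as rel
from reliacase.io import StudyDataset, SubjectRecord, VolumeGrid

STUDY_SEED = 3


@pytest.fixture(scope="session")
def study():
    """Default stated world: 16+16 subjects, 2 tasks, 2 sessions, 3 mm grid."""
    return sim.simulate_beta_dataset(sim.BetaSimConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def rmap(study):
    return rel.build_reliability_mask(study)


def make_tiny_dataset(n_dd=3, n_td=3, dims=(6, 6, 6), n_tasks=2, n_sessions=2,
                      sigma_b=1.0, sigma_e=1.0, seed=0, mu_dd=None, mu_td=None):
    """Small hand-built StudyDataset for unit tests (no ROI machinery)."""
    rng = np.random.default_rng(seed)
    grid = VolumeGrid.default(dims=dims)
    subjects = []
    for g, n in (("DD", n_dd), ("TD", n_td)):
        for i in range(n):
            subjects.append(SubjectRecord(id=f"{g.lower()}{i:02d}", group=g,
                                          age_months=96 + i, iq=100 + i,
                                          sex="m" if i % 2 == 0 else "f"))
    n_sub = len(subjects)
    shape = (n_sub, n_tasks) + dims
    b = rng.standard_normal(shape) * sigma_b
    betas = np.empty((n_sub, n_tasks, n_sessions) + dims)
    for k in range(n_sessions):
        betas[:, :, k] = b + rng.standard_normal(shape) * sigma_e
    if mu_dd is not None:
        betas[:n_dd] += mu_dd
    if mu_td is not None:
        betas[n_dd:] += mu_td
    tasks = ["comparison", "calculation"][:n_tasks]
    return StudyDataset(grid=grid, subjects=subjects, tasks=tasks,
                        sessions=list(range(1, n_sessions + 1)), betas=betas,
                        brain_mask=np.ones(dims, dtype=bool))


def single_voxel_roiset(dims, n_rois):
    """n single-voxel ROIs on a tiny grid, as (labels volume, table)."""
    labels = np.zeros(dims, dtype=int)
    rows = []
    for i in range(n_rois):
        labels[i % dims[0], (2 * i) % dims[1], (3 * i) % dims[2]] = i + 1
        rows.append({"label": i + 1, "name": f"roi{i:02d}", "hemisphere": "L"})
    return labels, pd.DataFrame(rows)
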