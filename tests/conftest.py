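"""Shared fixtures and helpers for the motorsig test suite."""

from __future__ import annotations

import numpy as np
import pytest

from motorsig import (
    BoldSeries,
    CohortConfig,
    RoiMask,
    VolumeGrid,
    generate_cohort,
)


def make_grid(shape=(6, 6, 3), voxel_mm=(1.5, 1.5, 1.5)) -> VolumeGrid:
    return VolumeGrid(shape, voxel_mm)


def make_series(
    data: np.ndarray,
    grid: VolumeGrid | None = None,
    voxel_index: np.ndarray | None = None,
    tr_s: float = 2.0,
    subject_id: str = "S01",
) -> BoldSeries:
    """Wrap a T x V array as a BoldSeries over the first V grid voxels."""
    data = np.asarray(data, dtype=float)
    V = data.shape[1]
    if grid is None:
        side = int(np.ceil(V ** (1 / 3))) + 1
        grid = make_grid((max(side, 2), max(side, 2), max(side, 2)))
    if voxel_index is None:
        all_idx = np.argwhere(np.ones(grid.shape, dtype=bool))
        voxel_index = all_idx[:V]
    return BoldSeries(
        subject_id=subject_id,
        data=data,
        voxel_index=np.asarray(voxel_index, dtype=int),
        tr_s=tr_s,
        grid=grid,
    )


def make_mask(grid: VolumeGrid, voxels, label: str = "roi") -> RoiMask:
    return RoiMask(label, np.asarray(voxels, dtype=int), grid)


@pytest.fixture(scope="session")
def small_cohort():
    """One small deterministic cohort shared across read-only tests."""
    cfg = CohortConfig(seed=42, n_patients=4, n_controls=3, n_timepoints=120)
    series, records, truth = generate_cohort(cfg)
    return cfg, series, records, truth


@pytest.fixture(scope="session")
def default_cohort():
    """A default-parameter cohort (full-length design) for slower checks."""
    cfg = CohortConfig(seed=7)
    series, records, truth = generate_cohort(cfg)
    return cfg, series, records, truth
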