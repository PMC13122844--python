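"""Functional connectivity: eigenvector centrality and seed-based maps.

Eigenvector centrality scores each voxel by the principal eigenvector of a
non-negative voxel-similarity matrix, so voxels connected to other
well-connected voxels score highest.  Seed maps correlate a spherical
seed's mean time course with every in-mask voxel.  Stage contrasts average
patient-minus-matched-control map differences per disease stage.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np

from .core import (
    BoldSeries,
    ClinicalRecord,
    EcMap,
    MotorsigError,
    RoiMask,
    SeedMap,
    TMap,
    logger,
)


class ConvergenceError(MotorsigError):
    """Power iteration failed to converge."""


def _masked(series: BoldSeries, mask: RoiMask | None) -> BoldSeries:
    return series if mask is None else series.restrict(mask)


def ecm(
    series: BoldSeries,
    mask: RoiMask | None = None,
    similarity: str = "shifted",
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> EcMap:
    """Eigenvector centrality of the voxel correlation graph.

    The similarity matrix is A = (r + 1) / 2 ("shifted", default) or
    max(r, 0) ("rectified"), where r is the Pearson correlation between
    voxel time courses; both are non-negative so the Perron-Frobenius
    principal eigenvector is non-negative.  Power iteration runs to a
    relative tolerance of 1e-10 (at most ``max_iter`` sweeps) and the
    result is returned with unit Euclidean norm.
    """
    sub = _masked(series, mask)
    if sub.n_voxels < 2:
        raise ValueError("need at least 2 in-mask voxels")
    sd = sub.data.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant voxel time course; cannot correlate")
    r = np.corrcoef(sub.data.T)
    if similarity == "shifted":
        A = (r + 1.0) / 2.0
    elif similarity == "rectified":
        A = np.maximum(r, 0.0)
    else:
        raise ValueError(f"unknown similarity {similarity!r}")

    x = np.full(A.shape[0], 1.0 / np.sqrt(A.shape[0]))
    for _ in range(max_iter):
        y = A @ x
        ny = np.linalg.norm(y)
        if ny == 0:
            raise ConvergenceError("similarity matrix annihilated the iterate")
        y /= ny
        if np.linalg.norm(y - x) < tol * np.linalg.norm(y):
            x = y
            break
        x = y
    else:
        raise ConvergenceError(f"power iteration did not converge in {max_iter} sweeps")
    x = np.abs(x)  # Perron vector is non-negative; clear roundoff signs
    return EcMap(x / np.linalg.norm(x), sub.voxel_index, label="ecm")


def seed_sphere(
    center: Sequence[int], voxel_index: np.ndarray, radius: float = 5.0
) -> np.ndarray:
    """Column indices of voxels within a Euclidean ball (voxel units)."""
    center = np.asarray(center, dtype=float)
    dist = np.linalg.norm(voxel_index - center, axis=1)
    return np.nonzero(dist <= radius + 1e-9)[0]


def seed_connectivity(
    series: BoldSeries,
    seed_center: Sequence[int],
    radius: float = 5.0,
    mask: RoiMask | None = None,
    label: str = "",
) -> SeedMap:
    """Correlation of the seed-sphere mean course with every in-mask voxel.

    The seed signal is the mean of the z-scored time courses within the
    radius-``radius`` ball around ``seed_center`` (voxel units, center
    included); map values are the dot products of the z-scored voxel
    courses with the z-scored seed course divided by T - 1, i.e. Pearson
    correlations.
    """
    sub = _masked(series, mask)
    inside = seed_sphere(seed_center, sub.voxel_index, radius)
    if inside.size == 0:
        raise ValueError("seed sphere contains no in-mask voxel")
    T = sub.n_timepoints

    def zs(x, axis=0):
        sd = x.std(axis=axis, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("constant signal in seed correlation")
        return (x - x.mean(axis=axis, keepdims=True)) / sd

    zdata = zs(sub.data)
    seed_sig = zdata[:, inside].mean(axis=1)
    zseed = zs(seed_sig.reshape(-1, 1)).ravel()
    vals = zdata.T @ zseed / (T - 1)
    return SeedMap(np.clip(vals, -1.0, 1.0), sub.voxel_index, label=label or "seed")


def seed_centers_from_tmaps(tmaps: Mapping[str, TMap]) -> dict[str, np.ndarray]:
    """Peak-t voxel per condition: the default seed centers."""
    centers = {}
    for cond, tm in tmaps.items():
        centers[cond] = tm.voxel_index[int(np.argmax(tm.values))]
    return centers


def stage_contrast(
    patient_maps: Mapping[tuple[str, str], SeedMap],
    control_maps: Mapping[tuple[str, str], SeedMap],
    records: Sequence[ClinicalRecord],
) -> dict[tuple[int, str], float]:
    """Patient-minus-matched-control map means, averaged per King's stage.

    ``patient_maps`` and ``control_maps`` are keyed by (patient id, seed
    label); ``control_maps[pid, seed]`` holds the matched control's map.
    Patients without a matched-control map are skipped.  Stages with no
    contributing patient are absent from the result (with a warning).
    """
    by_id = {r.patient_id: r for r in records}
    sums: dict[tuple[int, str], list[float]] = {}
    for (pid, seed), pmap in patient_maps.items():
        if (pid, seed) not in control_maps or pid not in by_id:
            continue
        cmap = control_maps[(pid, seed)]
        diff = float(pmap.values.mean() - cmap.values.mean())
        sums.setdefault((by_id[pid].kings_stage, seed), []).append(diff)
    seeds = {seed for _, seed in patient_maps}
    out: dict[tuple[int, str], float] = {}
    for stage in (1, 2, 3):
        for seed in seeds:
            vals = sums.get((stage, seed))
            if vals:
                out[(stage, seed)] = float(np.mean(vals))
    missing = {s for s in (1, 2, 3)} - {s for s, _ in out}
    if missing:
        warnings.warn(f"no patients in stage(s) {sorted(missing)}", stacklevel=2)
        logger.warning("stage contrast missing stages %s", sorted(missing))
    return out
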