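"""First-level GLM t-maps and functional localizer mask construction.

A per-voxel ordinary-least-squares GLM with HRF-convolved condition boxcars
yields a t-statistic map per movement condition; the top-k voxels of each
map form fixed-size single-subject localizers, which are intersected across
subjects and reduced to their largest connected cluster to form group masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import label as cc_label

from .core import (
    CONDITIONS,
    BoldSeries,
    DesignSchedule,
    MotorsigError,
    RoiMask,
    TMap,
    logger,
)
from .synth import condition_regressors


class EmptyIntersectionError(MotorsigError):
    """No voxel survived the across-subject mask intersection."""


@dataclass
class GlmResult:
    """Per-condition effect estimates and t-maps from one subject's GLM."""

    beta: dict[str, np.ndarray]
    tmaps: dict[str, TMap]
    dof: int


def glm_design_matrix(
    schedule: DesignSchedule, n_frames: int, tr_s: float
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: one HRF-convolved boxcar per condition plus intercept."""
    regs = condition_regressors(schedule, n_frames, tr_s)
    cols = [regs[c] for c in CONDITIONS]
    X = np.column_stack(cols + [np.ones(n_frames)])
    return X, list(CONDITIONS) + ["intercept"]


def fit_glm(series: BoldSeries, schedule: DesignSchedule) -> GlmResult:
    """Voxel-wise OLS against the block design; t = beta / SE(beta).

    The contrast for each condition is the condition-versus-baseline
    regressor weight.  Residual degrees of freedom are T - rank(design).
    All-zero (zero-residual-variance) voxels get t = 0 with a warning.
    No autocorrelation correction is applied.
    """
    X, names = glm_design_matrix(schedule, series.n_timepoints, series.tr_s)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise MotorsigError("rank-deficient GLM design matrix")
    dof = series.n_timepoints - rank
    if dof <= 0:
        raise MotorsigError("too few frames for the number of regressors")

    Y = series.data
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (n_reg, V)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)

    flat = sigma2 <= 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} zero-residual voxel(s): t set to 0", stacklevel=2
        )
        logger.warning("%s: %d zero-residual voxels", series.subject_id, flat.sum())

    betas, tmaps = {}, {}
    for j, cond in enumerate(CONDITIONS):
        se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[j, j])
        t = np.zeros_like(se)
        ok = ~flat & (se > 0)
        t[ok] = beta[j, ok] / se[ok]
        betas[cond] = beta[j].copy()
        tmaps[cond] = TMap(t, series.voxel_index, label=cond)
    return GlmResult(beta=betas, tmaps=tmaps, dof=int(dof))


def top_k_mask(tmap: TMap, grid, k: int = 1500) -> RoiMask:
    """The k voxels with largest t, ties broken by lexicographic index.

    Fixed-size selection keeps all localizers the same size so subjects
    with weaker activation are not disadvantaged.
    """
    V = tmap.values.shape[0]
    if k > V:
        raise ValueError(f"k = {k} exceeds the {V} available voxels")
    idx = tmap.voxel_index
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -tmap.values))
    return RoiMask(tmap.label or "top_k", idx[order[:k]], grid)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        s = np.zeros((3, 3, 3), dtype=bool)
        s[1, 1, :] = s[1, :, 1] = s[:, 1, 1] = True
        return s
    raise ValueError("connectivity must be 6 or 26")


def group_mask(masks: Sequence[RoiMask], connectivity: int = 26) -> RoiMask:
    """Across-subject intersection reduced to its largest connected cluster.

    Voxels must be present in every subject's mask; the surviving set is
    reduced to the largest 26-connected component (configurable to 6).
    Size ties resolve to the component containing the lexicographically
    smallest voxel.
    """
    if not masks:
        raise ValueError("need at least one mask")
    grid = masks[0].grid
    common = masks[0].voxel_set()
    for m in masks[1:]:
        if m.grid.shape != grid.shape:
            raise ValueError("masks must share one grid")
        common &= m.voxel_set()
    if not common:
        raise EmptyIntersectionError(
            "mask intersection is empty; consider fewer subjects or larger k"
        )
    vol = np.zeros(grid.shape, dtype=bool)
    idx = np.array(sorted(common))
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    labels, n = cc_label(vol, structure=_connectivity_structure(connectivity))
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        # tie: take the component containing the smallest voxel index
        for vox in idx:
            lab = labels[tuple(vox)]
            if lab in best:
                winner = lab
                break
    else:
        winner = best[0]
    return RoiMask(masks[0].label, np.argwhere(labels == winner), grid)


def combined_mask(group_masks: Mapping[str, RoiMask]) -> RoiMask:
    """Set union of per-condition group masks, labelled "combined"."""
    if not group_masks:
        raise ValueError("need at least one mask")
    grids = list(group_masks.values())
    union: set = set()
    for m in grids:
        union |= m.voxel_set()
    return RoiMask("combined", np.array(sorted(union)), grids[0].grid)


def subject_localizers(
    series: BoldSeries, schedule: DesignSchedule, k: int = 1500
) -> dict[str, RoiMask]:
    """Top-k localizer mask per condition for one subject."""
    res = fit_glm(series, schedule)
    return {c: top_k_mask(res.tmaps[c], series.grid, k) for c in CONDITIONS}
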