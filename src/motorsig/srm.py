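"""Robust Shared Response Model (rSRM) and dual-space feature construction.

The rSRM decomposes each subject's (voxel x time) data as

    X_i  ~=  W_i R + S_i,

where W_i is a subject-specific V x k matrix with orthonormal columns, R is
a k x T shared temporal response common to the group, and S_i is a sparse
subject-specific term absorbing idiosyncratic structure.  Fitting minimizes

    sum_i ||X_i - W_i R - S_i||_F^2  +  gamma * sum_i ||S_i||_1

by block-coordinate descent: W_i by orthogonal Procrustes, R in closed
form, S_i by entrywise soft-thresholding.  Each update solves its block
exactly, so the objective is non-increasing.

Two group-specific models (patient and control) define a dual feature
space: a held-out subject's run-1 data yields a basis against each frozen
group response, its run-2 data is projected through both bases, and the
two projections are concatenated as classifier features.  The sparse
individual term is discarded at projection time so the features carry only
the shared group-specific structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import BoldSeries, MotorsigError


class SrmFitError(MotorsigError):
    """Infeasible rSRM fit (k too large or degenerate input)."""


@dataclass
class SrmModel:
    """A fitted group rSRM: per-subject bases, shared response, sparse terms."""

    k: int
    gamma: float
    bases: dict[str, np.ndarray]  #: subject -> V x k, orthonormal columns
    shared: np.ndarray  #: k x T
    individual: dict[str, np.ndarray]  #: subject -> V x T
    group_label: str
    objective_trace: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def subject_ids(self) -> frozenset[str]:
        return frozenset(self.bases)

    def orthonormality_defect(self) -> float:
        return max(
            float(np.abs(W.T @ W - np.eye(self.k)).max()) for W in self.bases.values()
        )


def _soft_threshold(x: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def _procrustes(M: np.ndarray) -> np.ndarray:
    """Orthonormal-column factor closest to M: U V^T from its thin SVD."""
    u, _, vt = np.linalg.svd(M, full_matrices=False)
    return u @ vt


def default_gamma(data: Sequence[np.ndarray]) -> float:
    """Default sparsity penalty: 0.1 x median absolute data value."""
    return 0.1 * float(np.median(np.abs(np.concatenate([x.ravel() for x in data]))))


def fit_rsrm(
    group_series: Sequence[BoldSeries],
    k: int,
    gamma: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
    group_label: str = "",
) -> SrmModel:
    """Fit a group rSRM by block-coordinate descent.

    Subjects must share T and V (synchronized, in-mask series).  ``gamma``
    defaults to 0.1 x median |X|.  With ``gamma == 0`` the sparse term is
    held at zero and the fit reduces to a plain alternating-Procrustes
    shared response model (an unpenalized S would otherwise absorb the
    whole residual).  Bases are initialized as random orthonormal matrices
    drawn from ``seed``; iteration stops when the relative objective change
    falls below ``tol`` or after ``max_iter`` sweeps.
    """
    if not group_series:
        raise SrmFitError("empty group")
    X = {s.subject_id: s.data.T.astype(float) for s in group_series}  # V x T
    V, T = next(iter(X.values())).shape
    if any(x.shape != (V, T) for x in X.values()):
        raise SrmFitError("all subjects must share V and T")
    if k > min(V, T):
        raise SrmFitError(f"k = {k} exceeds min(V, T) = {min(V, T)}")
    if all(np.allclose(x, 0) for x in X.values()):
        raise SrmFitError("degenerate all-zero input")
    if gamma is None:
        gamma = default_gamma(list(X.values()))
    if gamma < 0:
        raise SrmFitError("gamma must be >= 0")

    rng = np.random.default_rng(seed)
    W = {}
    for sid in X:
        q, r = np.linalg.qr(rng.standard_normal((V, k)))
        W[sid] = q * np.sign(np.where(np.diag(r) == 0, 1.0, np.diag(r)))
    S = {sid: np.zeros((V, T)) for sid in X}
    R = np.mean([W[sid].T @ X[sid] for sid in X], axis=0)

    def objective() -> float:
        val = 0.0
        for sid in X:
            val += float(np.sum((X[sid] - W[sid] @ R - S[sid]) ** 2))
            val += gamma * float(np.abs(S[sid]).sum())
        return val

    trace = [objective()]
    for _ in range(max_iter):
        for sid in X:
            W[sid] = _procrustes((X[sid] - S[sid]) @ R.T)
        R = np.mean([W[sid].T @ (X[sid] - S[sid]) for sid in X], axis=0)
        if gamma > 0:
            for sid in X:
                S[sid] = _soft_threshold(X[sid] - W[sid] @ R, gamma / 2.0)
        obj = objective()
        if obj > trace[-1] + 1e-9 * max(1.0, abs(trace[-1])):
            raise SrmFitError("objective increased; block update error")
        rel = abs(trace[-1] - obj) / max(abs(trace[-1]), 1e-300)
        trace.append(obj)
        if rel < tol:
            break
    return SrmModel(
        k=k,
        gamma=float(gamma),
        bases=W,
        shared=R,
        individual=S,
        group_label=group_label,
        objective_trace=trace,
        seed=seed,
    )


def transfer_basis(model: SrmModel, new_run1: BoldSeries) -> np.ndarray:
    """Basis for a new subject against the frozen group shared response.

    Solves the orthogonal Procrustes problem for the new subject's run-1
    data against the model's R (which must have run-1 length), with one
    soft-thresholding pass for the subject's sparse term in between.
    """
    X = new_run1.data.T.astype(float)
    if X.shape[1] != model.shared.shape[1]:
        raise ValueError(
            f"run-1 length {X.shape[1]} does not match model's shared "
            f"response length {model.shared.shape[1]}"
        )
    R = model.shared
    W = _procrustes(X @ R.T)
    S = _soft_threshold(X - W @ R, model.gamma / 2.0) if model.gamma > 0 else 0.0
    return _procrustes((X - S) @ R.T)


def project(basis: np.ndarray, run2: BoldSeries) -> np.ndarray:
    """Project run-2 data into the shared space: basis^T X (k x T2).

    The sparse individual term is discarded: only the shared-space
    coordinates of the raw test data are kept.
    """
    basis = np.asarray(basis, dtype=float)
    defect = np.abs(basis.T @ basis - np.eye(basis.shape[1])).max()
    if defect > 1e-6:
        raise ValueError("basis columns are not orthonormal")
    if basis.shape[0] != run2.n_voxels:
        raise ValueError("basis and data voxel counts differ")
    return basis.T @ run2.data.T


def dual_space_features(
    model_als: SrmModel,
    model_ctl: SrmModel,
    subject_run1: BoldSeries,
    subject_run2: BoldSeries,
) -> np.ndarray:
    """Concatenated projections of run 2 through both group spaces.

    Run 1 learns one basis against each group model; run 2 is projected
    through both; each k x T2 projection is flattened time-major and the
    patient-space block precedes the control-space block (length 2 k T2).
    """
    if model_als.k != model_ctl.k:
        raise ValueError("group models must share k")
    feats = []
    for model in (model_als, model_ctl):
        basis = transfer_basis(model, subject_run1)
        feats.append(project(basis, subject_run2).ravel(order="F"))
    return np.concatenate(feats)
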