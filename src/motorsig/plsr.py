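"""Partial least squares regression (NIPALS), LOO cross-validation, weight
back-projection and region-wise weight statistics.

PLSR decomposes centered predictors and responses as X = T P^T + F_X and
Y = U Q^T + F_Y, with the inner relation U = T D, choosing each weight pair
(w, c) to maximize cov(Xw, Yc).  Components are extracted sequentially by
the NIPALS algorithm with deflation of X; the regression matrix is
B = W (P^T W)^{-1} C^T so that Y_hat = (X - x_mean) B + y_mean.

The back-projection of first-component weights into voxel space asks
whether the predictive signal is topographic (concentrated in one body-part
field) or atopographic (distributed); region-wise mean absolute weights are
compared by a one-way repeated-measures ANOVA with Holm-corrected paired
post hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import BoldSeries, ClinicalRecord, MotorsigError, RoiMask, ScalarMap


class PlsrError(MotorsigError):
    """Infeasible PLSR fit (rank, variance or convergence failure)."""


@dataclass
class PlsrModel:
    """Scores, loadings and weights of a fitted latent decomposition."""

    L: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    T_scores: np.ndarray  #: n x L X-scores
    U_scores: np.ndarray  #: n x L Y-scores
    P_load: np.ndarray  #: p x L X-loadings
    Q_load: np.ndarray  #: q x L Y-loadings (on U)
    W_weights: np.ndarray  #: p x L X-weights, unit columns
    C_weights: np.ndarray  #: q x L Y-weights (regression of Y on t)
    D_inner: np.ndarray  #: L x L diagonal inner relation U ~= T D
    coef: np.ndarray  #: p x q regression matrix

    @property
    def x_rotations(self) -> np.ndarray:
        """R = W (P^T W)^{-1}: maps centered X to T-scores."""
        return self.W_weights @ np.linalg.inv(self.P_load.T @ self.W_weights)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Latent coordinates of new observations."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.x_rotations


def fit_plsr(
    X: np.ndarray,
    Y: np.ndarray,
    L: int,
    max_iter: int = 500,
    tol: float = 1e-12,
    standardize_x: bool = False,
) -> PlsrModel:
    """Fit an L-component PLSR by NIPALS with X-deflation.

    The first weight vector equals the dominant left singular vector of
    X_c^T Y_c (up to sign); at L = rank(X_c) the training predictions
    coincide with ordinary least squares.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    n, p = X.shape
    q = Y.shape[1]
    if n < 2:
        raise PlsrError("need at least 2 observations")
    if L > min(n - 1, p):
        raise PlsrError(f"L = {L} exceeds min(n - 1, p) = {min(n - 1, p)}")
    if np.allclose(Y.std(axis=0), 0):
        raise PlsrError("zero-variance response")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    if standardize_x:
        sd = Xc.std(axis=0)
        Xc = Xc / np.where(sd == 0, 1.0, sd)
    Yc = Y - y_mean

    Tm = np.zeros((n, L))
    Um = np.zeros((n, L))
    Pm = np.zeros((p, L))
    Qm = np.zeros((q, L))
    Wm = np.zeros((p, L))
    Cm = np.zeros((q, L))
    d = np.zeros(L)

    for comp in range(L):
        u = Yc[:, int(np.argmax(Yc.var(axis=0)))].copy()
        if np.allclose(u, 0):
            raise PlsrError(f"response residual vanished at component {comp + 1}")
        t_old = None
        for _ in range(max_iter):
            w = Xc.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise PlsrError("predictor weights vanished (zero covariance)")
            w /= nw
            t = Xc @ w
            tt = float(t @ t)
            if tt == 0:
                raise PlsrError("degenerate X-score")
            c = Yc.T @ t / tt
            u = Yc @ c / max(float(c @ c), 1e-300)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        else:
            if q > 1:
                raise PlsrError("inner NIPALS loop did not converge")
        tt = float(t @ t)
        pvec = Xc.T @ t / tt
        uu = float(u @ u)
        qvec = Yc.T @ u / uu if uu > 0 else np.zeros(q)
        d[comp] = float(u @ t) / tt
        Tm[:, comp], Um[:, comp] = t, u
        Pm[:, comp], Qm[:, comp] = pvec, qvec
        Wm[:, comp], Cm[:, comp] = w, c
        Xc = Xc - np.outer(t, pvec)
        Yc = Yc - np.outer(t, c)

    coef = Wm @ np.linalg.inv(Pm.T @ Wm) @ Cm.T
    return PlsrModel(
        L=L,
        x_mean=x_mean,
        y_mean=y_mean,
        T_scores=Tm,
        U_scores=Um,
        P_load=Pm,
        Q_load=Qm,
        W_weights=Wm,
        C_weights=Cm,
        D_inner=np.diag(d),
        coef=coef,
    )


@dataclass(frozen=True)
class LooFold:
    """One leave-one-out split: its error and latent projection."""

    fold: int
    mse: float
    latent_xy: tuple[float, float]
    y_true: np.ndarray
    y_pred: np.ndarray


def loo_cv(X: np.ndarray, Y: np.ndarray, L: int, **fit_kwargs) -> list[LooFold]:
    """Leave-one-out cross-validation: per-fold MSE and latent coordinates.

    Each fold refits on n - 1 subjects; the MSE is the mean squared
    prediction error over the response dimensions of the single held-out
    subject, and the latent coordinates are its first two X-scores in the
    training model's latent space.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    n = X.shape[0]
    if n < 3:
        raise PlsrError("need at least 3 observations for LOO CV")
    folds = []
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_plsr(X[keep], Y[keep], L, **fit_kwargs)
        pred = model.predict(X[i])
        mse = float(np.mean((Y[i] - pred[0]) ** 2))
        scores = model.transform(X[i])[0]
        lv = (float(scores[0]), float(scores[1]) if L >= 2 else 0.0)
        folds.append(LooFold(i, mse, lv, Y[i].copy(), pred[0].copy()))
    return folds


class WeightMap(ScalarMap):
    """Voxel map of PLSR weights (first component by default)."""


def backproject_weights(
    model: PlsrModel, mask: RoiMask, component: int = 0, use_coef: bool = False
) -> WeightMap:
    """Project model weights back into voxel space over ``mask``.

    Requires one predictor column per mask voxel (same order).  Returns the
    requested weight column (or the regression coefficients with
    ``use_coef``) aligned with the mask's voxel index.
    """
    vals = model.coef[:, 0] if use_coef else model.W_weights[:, component]
    if vals.shape[0] != mask.size:
        raise ValueError(
            f"model has {vals.shape[0]} predictors but mask {mask.label!r} "
            f"has {mask.size} voxels"
        )
    return WeightMap(vals, mask.voxel_index, label=f"plsr_w{component + 1}")


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = p.shape[0]
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


@dataclass(frozen=True)
class RegionWeightStats:
    """Repeated-measures ANOVA + Holm-corrected paired comparisons."""

    anova_F: float
    dof: tuple[int, int]
    p: float
    holm_table: dict[tuple[str, str], float]
    region_means: dict[str, float]


def region_weight_stats(
    weight_maps: Sequence[ScalarMap],
    rois: Mapping[str, RoiMask],
) -> RegionWeightStats:
    """One-way repeated-measures ANOVA on region-wise mean |weight|.

    One observation per map (subject/fold) per region: the mean absolute
    weight over the region's voxels.  F = MS_region / MS_(region x subject)
    with dof (r - 1, (r - 1)(n - 1)); pairwise paired t-tests are Holm
    step-down corrected.
    """
    region_names = list(rois)
    r = len(region_names)
    n = len(weight_maps)
    if n < 2:
        raise ValueError("need at least 2 maps")
    if r < 2:
        raise ValueError("need at least 2 regions")

    table = np.zeros((n, r))
    for si, wmap in enumerate(weight_maps):
        lut = {tuple(v): j for j, v in enumerate(wmap.voxel_index)}
        for ri, name in enumerate(region_names):
            cols = [lut[tuple(v)] for v in rois[name].voxel_index if tuple(v) in lut]
            if not cols:
                raise ValueError(f"region {name!r} not covered by map {si}")
            table[si, ri] = np.abs(wmap.values[cols]).mean()

    grand = table.mean()
    ss_region = n * float(((table.mean(axis=0) - grand) ** 2).sum())
    ss_subject = r * float(((table.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((table - grand) ** 2).sum())
    ss_err = ss_total - ss_region - ss_subject
    df1, df2 = r - 1, (r - 1) * (n - 1)
    ms_region = ss_region / df1
    ms_err = ss_err / df2
    # rounding in the means leaves O(eps^2) residue in the sums of squares
    # even for an exactly constant table; judge degeneracy on that scale
    tiny = 1e-24 * table.size * max(grand * grand, np.finfo(float).tiny)
    if ms_err <= tiny:
        F, p = (0.0, 1.0) if ms_region <= tiny else (np.inf, 0.0)
    else:
        F = ms_region / ms_err
        p = float(stats.f.sf(F, df1, df2))

    pairs = [
        (region_names[i], region_names[j])
        for i in range(r)
        for j in range(i + 1, r)
    ]
    raw = []
    for a, b in pairs:
        ia, ib = region_names.index(a), region_names.index(b)
        diff = table[:, ia] - table[:, ib]
        if np.allclose(diff.std(ddof=1), 0):
            raw.append(1.0 if np.allclose(diff.mean(), 0) else 0.0)
        else:
            raw.append(float(stats.ttest_rel(table[:, ia], table[:, ib]).pvalue))
    adj = holm_adjust(raw)
    return RegionWeightStats(
        anova_F=float(F),
        dof=(df1, df2),
        p=p,
        holm_table={pair: float(v) for pair, v in zip(pairs, adj)},
        region_means={name: float(table[:, i].mean()) for i, name in enumerate(region_names)},
    )


# ---------------------------------------------------------------------------
# End-to-end PLSR analysis
# ---------------------------------------------------------------------------

@dataclass
class PlsrReport:
    """Results of one predictor/response PLSR analysis over a cohort."""

    predictor: str
    response: str
    folds: list[LooFold]
    weight_map: WeightMap | None
    region_stats: RegionWeightStats | None
    latent_table: list[dict]
    mean_mse: float


def _predictor_matrix(
    predictor: str,
    cohort: Sequence[BoldSeries],
    combined: RoiMask,
    schedule=None,
) -> np.ndarray:
    from .connectivity import ecm as ecm_fn
    from .localizer import fit_glm

    rows = []
    for series in cohort:
        sub = series.restrict(combined)
        if predictor == "ecm":
            rows.append(ecm_fn(sub).values)
        elif predictor == "activation":
            if schedule is None:
                raise ValueError("activation predictor requires a schedule")
            res = fit_glm(sub, schedule)
            rows.append(np.mean([tm.values for tm in res.tmaps.values()], axis=0))
        elif predictor == "timeseries":
            rows.append(sub.data.ravel(order="F"))
        else:
            raise ValueError(f"unknown predictor {predictor!r}")
    return np.vstack(rows)


def run_plsr_analysis(
    cohort: Sequence[BoldSeries],
    records: Sequence[ClinicalRecord],
    predictor: str = "ecm",
    response: str = "alsfrs",
    L: int = 2,
    combined: RoiMask | None = None,
    schedule=None,
    region_rois: Mapping[str, RoiMask] | None = None,
    **fit_kwargs,
) -> PlsrReport:
    """LOO-cross-validated PLSR of clinical scores on voxel-wise features.

    ``predictor`` selects the feature construction over the combined mask:
    "ecm" (voxel centralities), "activation" (voxel GLM t-values averaged
    over conditions) or "timeseries" (flattened masked time series).
    ``response`` is "alsfrs" or "pumns".  Weight back-projection and
    region statistics are produced when the predictor is voxel-aligned.
    """
    if combined is None:
        raise ValueError("a combined mask is required")
    by_id = {r.patient_id: r for r in records}
    cohort = [s for s in cohort if s.subject_id in by_id]
    if len(cohort) < 3:
        raise PlsrError("need at least 3 patients with clinical records")
    recs = [by_id[s.subject_id] for s in cohort]
    y = np.array(
        [r.alsfrs_total if response == "alsfrs" else r.pumns for r in recs],
        dtype=float,
    )
    if np.allclose(y.std(), 0):
        raise PlsrError(f"zero-variance response {response!r}")
    X = _predictor_matrix(predictor, cohort, combined, schedule)

    folds = loo_cv(X, y, L, **fit_kwargs)
    full = fit_plsr(X, y, L, **fit_kwargs)
    wmap = None
    stats_out = None
    if X.shape[1] == combined.size:
        wmap = backproject_weights(full, combined)
        if region_rois:
            fold_maps = []
            for i in range(len(cohort)):
                keep = np.arange(len(cohort)) != i
                m = fit_plsr(X[keep], y[keep], L, **fit_kwargs)
                fold_maps.append(backproject_weights(m, combined))
            stats_out = region_weight_stats(fold_maps, region_rois)
    latent = [
        {
            "patient_id": recs[f.fold].patient_id,
            "lv1": f.latent_xy[0],
            "lv2": f.latent_xy[1],
            "mse": f.mse,
            "kings_stage": recs[f.fold].kings_stage,
            "onset_type": recs[f.fold].onset_type,
        }
        for f in folds
    ]
    return PlsrReport(
        predictor=predictor,
        response=response,
        folds=folds,
        weight_map=wmap,
        region_stats=stats_out,
        latent_table=latent,
        mean_mse=float(np.mean([f.mse for f in folds])),
    )
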