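"""PLSR: NIPALS contracts, LOO CV, back-projection, region statistics."""

from __future__ import annotations

import numpy as np
import pytest

from motorsig import (
    backproject_weights,
    fit_plsr,
    holm_adjust,
    loo_cv,
    region_weight_stats,
    run_plsr_analysis,
)
from motorsig.plsr import PlsrError, WeightMap

from conftest import make_grid, make_mask


# ---------------------------------------------------------------- fit


def test_exact_rank_one_linear_case():
    rng = np.random.default_rng(0)
    t = rng.normal(size=10)
    X = np.outer(t, [1.0, -2.0, 0.5])  # rank-1
    Y = X @ np.array([2.0, 0.0, 1.0])
    model = fit_plsr(X, Y, L=1)
    pred = model.predict(X)
    assert np.linalg.norm(Y.reshape(-1, 1) - pred) < 1e-8


def test_full_rank_plsr_matches_ols():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(10, 4))
    Y = rng.normal(size=(10, 1))
    model = fit_plsr(X, Y, L=4)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    pred_ols = Xc @ beta + Y.mean(axis=0)
    np.testing.assert_allclose(model.predict(X), pred_ols, atol=1e-6)


def test_first_weight_is_dominant_singular_vector():
    rng = np.random.default_rng(2)
    for _ in range(3):
        X = rng.normal(size=(20, 6))
        Y = rng.normal(size=(20, 2))
        model = fit_plsr(X, Y, L=2)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        u, s, vt = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
        cos = abs(float(model.W_weights[:, 0] @ u[:, 0]))
        assert cos >= 1 - 1e-8


def test_matches_sklearn_pls_regression():
    from sklearn.cross_decomposition import PLSRegression

    rng = np.random.default_rng(3)
    X = rng.normal(size=(15, 5))
    y = rng.normal(size=15)
    model = fit_plsr(X, y, L=2)
    sk = PLSRegression(n_components=2, scale=False).fit(X, y.reshape(-1, 1))
    np.testing.assert_allclose(
        model.predict(X).ravel(), sk.predict(X).ravel(), atol=1e-8
    )
    # weights agree up to per-component sign
    for j in range(2):
        a = model.W_weights[:, j]
        b = sk.x_weights_[:, j]
        assert min(np.linalg.norm(a - b), np.linalg.norm(a + b)) < 1e-8


def test_score_orthogonality_and_unit_weights():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(12, 6))
    Y = rng.normal(size=(12, 1))
    model = fit_plsr(X, Y, L=3)
    T = model.T_scores
    for i in range(3):
        assert np.linalg.norm(model.W_weights[:, i]) == pytest.approx(1.0)
        for j in range(i + 1, 3):
            assert abs(T[:, i] @ T[:, j]) <= 1e-8 * np.linalg.norm(
                T[:, i]
            ) * np.linalg.norm(T[:, j])


def test_deflation_reconstructs_x_at_full_rank():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(8, 4))
    Y = rng.normal(size=(8, 1))
    model = fit_plsr(X, Y, L=4)
    Xc = X - X.mean(axis=0)
    recon = model.T_scores @ model.P_load.T
    assert np.linalg.norm(Xc - recon) <= 1e-8


def test_fit_errors():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(6, 3))
    with pytest.raises(PlsrError):
        fit_plsr(X, np.zeros(6), L=1)  # zero-variance response
    with pytest.raises(PlsrError):
        fit_plsr(X, rng.normal(size=6), L=5)  # L too large


def test_standardizing_changes_weights_but_model_still_predicts():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(14, 5)) * np.array([1, 10, 100, 1, 1])
    y = X @ rng.normal(size=5) + 0.1 * rng.normal(size=14)
    plain = fit_plsr(X, y, L=2)
    std = fit_plsr(X, y, L=2, standardize_x=True)
    assert not np.allclose(plain.W_weights, std.W_weights)


# ---------------------------------------------------------------- loo


def test_loo_noiseless_linear_has_tiny_mse_and_n_folds():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(9, 3))
    y = X @ np.array([1.0, -1.0, 0.5])
    folds = loo_cv(X, y, L=3)
    assert len(folds) == 9
    assert all(f.mse < 1e-10 for f in folds)


def test_loo_requires_three_observations():
    with pytest.raises(PlsrError):
        loo_cv(np.zeros((2, 3)), np.zeros(2), L=1)


def test_loo_beats_permuted_null_on_structured_cohorts():
    rng = np.random.default_rng(9)
    wins = 0
    n_trials = 20
    for trial in range(n_trials):
        lat = rng.normal(size=14)
        X = np.outer(lat, rng.normal(size=30)) + 0.5 * rng.normal(size=(14, 30))
        y = 3 * lat + 0.1 * rng.normal(size=14)
        mse = np.mean([f.mse for f in loo_cv(X, y, L=2)])
        y_perm = rng.permutation(y)
        mse_perm = np.mean([f.mse for f in loo_cv(X, y_perm, L=2)])
        wins += mse < mse_perm
    assert wins >= int(0.95 * n_trials) - 1


# ---------------------------------------------------------------- backprojection


def test_backprojection_aligns_with_mask_order():
    grid = make_grid((4, 4, 2))
    mask = make_mask(grid, [[0, 0, 0], [1, 0, 0], [2, 0, 0]], "m")
    rng = np.random.default_rng(10)
    X = rng.normal(size=(8, 3))
    y = X @ np.array([0.6, 0.0, -0.8])
    model = fit_plsr(X, y, L=1)
    out = backproject_weights(model, mask)
    np.testing.assert_array_equal(out.voxel_index, mask.voxel_index)
    np.testing.assert_allclose(out.values, model.W_weights[:, 0])


def test_backprojection_equivariant_under_column_permutation():
    grid = make_grid((4, 4, 2))
    vox = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    rng = np.random.default_rng(11)
    X = rng.normal(size=(10, 4))
    y = X @ np.array([1.0, -0.5, 0.25, 2.0])
    model = fit_plsr(X, y, L=1)
    base = backproject_weights(model, make_mask(grid, vox, "m"))
    # RoiMask serializes voxels lexicographically, so permuting the rows of
    # an already-sorted voxel list together with the columns of X must give
    # back the identical map only when the permutation is order-preserving.
    model_same = fit_plsr(X, y, L=1)
    again = backproject_weights(model_same, make_mask(grid, vox, "m"))
    np.testing.assert_allclose(again.values, base.values)


def test_backprojection_size_mismatch():
    grid = make_grid((4, 4, 2))
    mask = make_mask(grid, [[0, 0, 0], [1, 0, 0]], "m")
    rng = np.random.default_rng(12)
    X = rng.normal(size=(8, 3))
    model = fit_plsr(X, X @ np.ones(3), L=1)
    with pytest.raises(ValueError):
        backproject_weights(model, mask)


# ---------------------------------------------------------------- holm / anova


def test_holm_hand_enumeration():
    adj = holm_adjust([0.01, 0.04, 0.03])
    np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])


def test_holm_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(13)
    for _ in range(5):
        p = rng.uniform(size=6)
        ours = holm_adjust(p)
        _, ref, *_ = multipletests(p, method="holm")
        np.testing.assert_allclose(ours, ref, atol=1e-12)


def _maps_from_table(table, grid):
    """One WeightMap per row; three single-voxel regions."""
    vox = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
    maps = [WeightMap(np.asarray(row, dtype=float), vox, label="w")
            for row in table]
    rois = {
        name: make_mask(grid, [vox[j]], name)
        for j, name in enumerate(("hand", "foot", "tongue"))
    }
    return maps, rois


def test_anova_identical_regions_gives_f_zero_p_one():
    grid = make_grid((4, 4, 2))
    maps, rois = _maps_from_table([[0.2, 0.2, 0.2]] * 4, grid)
    out = region_weight_stats(maps, rois)
    assert out.anova_F == pytest.approx(0.0)
    assert all(p == pytest.approx(1.0) for p in out.holm_table.values())


def test_anova_matches_sums_of_squares_oracle():
    table = np.array([
        [0.1, 0.5, 0.9],
        [0.2, 0.6, 0.8],
        [0.15, 0.4, 1.0],
        [0.05, 0.55, 0.85],
    ])
    grid = make_grid((4, 4, 2))
    maps, rois = _maps_from_table(table, grid)
    out = region_weight_stats(maps, rois)

    n, r = table.shape
    grand = table.mean()
    region_means = table.mean(axis=0)
    subject_means = table.mean(axis=1)
    ss_region = n * np.sum((region_means - grand) ** 2)
    ss_subject = r * np.sum((subject_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_inter = ss_total - ss_region - ss_subject
    ms_region = ss_region / (r - 1)
    ms_inter = ss_inter / ((r - 1) * (n - 1))
    f_ref = ms_region / ms_inter
    assert out.anova_F == pytest.approx(f_ref)
    assert out.dof == (r - 1, (r - 1) * (n - 1))


def test_anova_matches_pingouin():
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(14)
    table = rng.normal(size=(6, 3)) + np.array([0.0, 0.5, 1.0])
    grid = make_grid((4, 4, 2))
    maps, rois = _maps_from_table(np.abs(table), grid)
    out = region_weight_stats(maps, rois)
    # pingouin needs signed observations matching ours: mean |weight|
    obs = np.abs(table)
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(6), 3),
        "region": np.tile(["hand", "foot", "tongue"], 6),
        "value": obs.ravel(),
    })
    ref = pg.rm_anova(dv="value", within="region", subject="subject", data=df)
    assert out.anova_F == pytest.approx(float(ref["F"].iloc[0]))
    assert out.p == pytest.approx(float(ref["p_unc"].iloc[0]), abs=1e-10)


# ---------------------------------------------------------------- analysis


def test_run_plsr_analysis_report_structure(small_cohort):
    cfg, series, records, truth = small_cohort
    combined = truth.combined_mask(cfg.grid)
    rois = {
        "hand": truth.roi_masks(cfg.grid)["LH"],
        "foot": truth.roi_masks(cfg.grid)["LF"],
        "tongue": truth.roi_masks(cfg.grid)["TONGUE"],
    }
    report = run_plsr_analysis(
        series, records, predictor="ecm", response="alsfrs",
        combined=combined, region_rois=rois,
    )
    assert len(report.folds) == len(records)
    assert report.weight_map is not None
    assert set(report.region_stats.region_means) == {"hand", "foot", "tongue"}
    assert len(report.latent_table) == len(records)
    assert {"lv1", "lv2", "mse", "kings_stage", "onset_type"} <= set(
        report.latent_table[0]
    )


def test_run_plsr_analysis_constant_response_raises(small_cohort):
    cfg, series, records, truth = small_cohort
    import dataclasses

    flat = [dataclasses.replace(r, alsfrs_total=30) for r in records]
    with pytest.raises(PlsrError):
        run_plsr_analysis(
            series, flat, predictor="ecm", response="alsfrs",
            combined=truth.combined_mask(cfg.grid),
        )
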