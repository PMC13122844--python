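"""Leave-one-subject-out group classification on dual-shared-space features.

Each fold freezes one subject out, fits one rSRM per group on the training
subjects' run-1 data within an ROI, builds dual-space features (run-2 data
projected through both group spaces) for everyone, trains a linear
maximum-margin classifier and records the held-out prediction.  Chance
level for the binary patient/control task is 0.5.  A two-sample pooled
t-test then contrasts fold accuracies between first-affected and
non-first-affected ROIs of the patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .core import GROUP_ALS, GROUP_CTL, BoldSeries, ClinicalRecord, MotorsigError, RoiMask
from .preprocess import split_runs
from .srm import SrmModel, dual_space_features, fit_rsrm


class InsufficientGroupError(MotorsigError):
    """A group has fewer than 2 training subjects after holdout."""


@dataclass(frozen=True)
class FoldAccuracy:
    """Outcome of one (held-out subject, ROI) cross-validation fold."""

    held_out_subject: str
    roi_label: str
    predicted: str
    truth: str
    correct: int

    def __post_init__(self):
        object.__setattr__(self, "correct", int(self.predicted == self.truth))


def _fit_group_models(
    run1s: Mapping[str, BoldSeries],
    labels: Mapping[str, str],
    exclude: str,
    k: int,
    gamma: float | None,
    seed: int,
    max_iter: int,
    tol: float,
) -> tuple[SrmModel, SrmModel]:
    groups = {GROUP_ALS: [], GROUP_CTL: []}
    for sid, series in run1s.items():
        if sid != exclude and sid in labels:
            groups[labels[sid]].append(series)
    for g, members in groups.items():
        if len(members) < 2:
            raise InsufficientGroupError(
                f"group {g} has {len(members)} training subjects after "
                f"holding out {exclude!r}"
            )
    model_als = fit_rsrm(
        groups[GROUP_ALS], k, gamma, max_iter, tol, seed=seed, group_label=GROUP_ALS
    )
    model_ctl = fit_rsrm(
        groups[GROUP_CTL], k, gamma, max_iter, tol, seed=seed + 1, group_label=GROUP_CTL
    )
    return model_als, model_ctl


def loso_classify(
    cohort: Sequence[tuple[BoldSeries, str]],
    roi_masks: Mapping[str, RoiMask],
    k: int = 10,
    gamma: float | None = None,
    seed: int = 0,
    C: float = 1.0,
    srm_max_iter: int = 100,
    srm_tol: float = 1e-6,
    balance_training: bool = True,
) -> list[FoldAccuracy]:
    """Leave-one-subject-out dual-space classification, one fold per
    (subject, ROI).

    For every ROI and held-out subject: fit a patient rSRM and a control
    rSRM on the remaining subjects' run-1 data, build dual-space features
    from everyone's runs, train a linear SVM (C = 1, balanced class
    weights) on the training features and predict the held-out subject.
    The held-out subject's data never enters model fitting or classifier
    training (asserted on the fitted models' subject rosters).

    With ``balance_training`` (the default) each fold drops randomly
    chosen subjects from the larger training class until both classes are
    the same size.  Without it, holding out a subject leaves its own
    class under-represented in training, which biases high-dimensional
    classifiers toward the other class and drags null (permuted-label)
    accuracy measurably below the nominal 0.5 chance level.
    """
    labels = {s.subject_id: g for s, g in cohort}
    if len(labels) != len(cohort):
        raise ValueError("duplicate subject ids in cohort")
    for g in (GROUP_ALS, GROUP_CTL):
        if sum(1 for v in labels.values() if v == g) < 2:
            raise InsufficientGroupError(f"need at least 2 subjects in group {g}")

    folds: list[FoldAccuracy] = []
    for roi_index, (roi_label, mask) in enumerate(roi_masks.items()):
        run1s, run2s = {}, {}
        for series, _ in cohort:
            r1, r2 = split_runs(series.restrict(mask))
            run1s[series.subject_id] = r1
            run2s[series.subject_id] = r2
        for fold_index, held_out in enumerate(labels):
            train_ids = [sid for sid in labels if sid != held_out]
            if balance_training:
                rng = np.random.default_rng([seed, roi_index, fold_index])
                by_group = {
                    g: [sid for sid in train_ids if labels[sid] == g]
                    for g in (GROUP_ALS, GROUP_CTL)
                }
                excess = len(by_group[GROUP_ALS]) - len(by_group[GROUP_CTL])
                bigger = GROUP_ALS if excess > 0 else GROUP_CTL
                for _ in range(abs(excess)):
                    members = by_group[bigger]
                    dropped = members[int(rng.integers(len(members)))]
                    members.remove(dropped)
                    train_ids.remove(dropped)
            train_labels = {sid: labels[sid] for sid in train_ids}
            model_als, model_ctl = _fit_group_models(
                run1s, train_labels, held_out, k, gamma, seed, srm_max_iter, srm_tol
            )
            assert held_out not in model_als.subject_ids
            assert held_out not in model_ctl.subject_ids
            feats = {
                sid: dual_space_features(model_als, model_ctl, run1s[sid], run2s[sid])
                for sid in train_ids + [held_out]
            }
            clf = SVC(kernel="linear", C=C, class_weight="balanced")
            clf.fit(
                np.vstack([feats[sid] for sid in train_ids]),
                [labels[sid] for sid in train_ids],
            )
            pred = str(clf.predict(feats[held_out].reshape(1, -1))[0])
            folds.append(
                FoldAccuracy(held_out, roi_label, pred, labels[held_out], 0)
            )
    return folds


def overall_accuracy(folds: Sequence[FoldAccuracy]) -> float:
    return float(np.mean([f.correct for f in folds]))


def label_permutation_accuracies(
    cohort: Sequence[tuple[BoldSeries, str]],
    roi_masks: Mapping[str, RoiMask],
    n_permutations: int,
    k: int = 10,
    gamma: float | None = None,
    seed: int = 0,
    **loso_kwargs,
) -> np.ndarray:
    """Mean LOSO accuracy under random label permutations (null calibration).

    Group labels are randomly reassigned among subjects (group sizes
    preserved) and the full dual-space LOSO pipeline is rerun; returns one
    mean fold accuracy per permutation.
    """
    rng = np.random.default_rng(seed)
    series = [s for s, _ in cohort]
    base_labels = [g for _, g in cohort]
    out = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = rng.permutation(len(base_labels))
        shuffled = list(zip(series, [base_labels[i] for i in perm]))
        folds = loso_classify(
            shuffled, roi_masks, k=k, gamma=gamma, seed=seed + 1 + p, **loso_kwargs
        )
        out[p] = overall_accuracy(folds)
    return out


@dataclass(frozen=True)
class AffectedContrast:
    """First-affected vs non-first-affected fold-accuracy comparison."""

    mean_first: float
    mean_nonfirst: float
    t: float
    dof: int
    p: float
    degenerate: bool = False


def affected_contrast(
    folds: Sequence[FoldAccuracy], records: Sequence[ClinicalRecord]
) -> AffectedContrast:
    """Pooled-variance two-sample t-test on patient fold accuracies.

    Patient folds are tagged by whether their ROI belongs to that patient's
    first-affected set; control folds are ignored.  When both groups have
    zero variance, equal means give t = 0, p = 1 and unequal means are
    flagged degenerate with the conventional t = +/-inf, p = 0.
    """
    by_id = {r.patient_id: r for r in records}
    first, nonfirst = [], []
    for f in folds:
        rec = by_id.get(f.held_out_subject)
        if rec is None:
            continue
        (first if f.roi_label in rec.first_affected_rois else nonfirst).append(
            float(f.correct)
        )
    if not first or not nonfirst:
        raise ValueError("both fold groups must be non-empty")
    a, b = np.asarray(first), np.asarray(nonfirst)
    n1, n2 = len(a), len(b)
    dof = n1 + n2 - 2
    pooled = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / dof if dof > 0 else 0.0
    diff = a.mean() - b.mean()
    if pooled <= 0:
        if diff == 0:
            return AffectedContrast(a.mean(), b.mean(), 0.0, dof, 1.0)
        return AffectedContrast(
            a.mean(), b.mean(), float(np.sign(diff) * np.inf), dof, 0.0, True
        )
    t = diff / np.sqrt(pooled * (1 / n1 + 1 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), dof))
    return AffectedContrast(float(a.mean()), float(b.mean()), float(t), dof, p)
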