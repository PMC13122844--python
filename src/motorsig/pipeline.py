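"""End-to-end orchestration: simulate -> preprocess -> localize ->
connectivity -> classify -> plsr, with CSV/JSON summaries and a manifest.

Every figure-style output is written as CSV or JSON; the manifest records
the package version, the full configuration and its hash, and the seed, so
a run can be replayed bit-identically from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    CONDITIONS,
    GROUP_ALS,
    GROUP_CTL,
    BoldSeries,
    ClinicalRecord,
    RoiMask,
    logger,
    write_clinical_table,
)
from .classify import affected_contrast, loso_classify, overall_accuracy
from .connectivity import ecm, seed_centers_from_tmaps, seed_connectivity, stage_contrast
from .localizer import combined_mask, fit_glm, group_mask, subject_localizers
from .preprocess import bandpass, synchronize_blocks
from .synth import CohortConfig, generate_cohort

ALL_STAGES = (
    "simulate",
    "preprocess",
    "localize",
    "connectivity",
    "classify",
    "plsr",
    "report",
)


@dataclass
class PipelineConfig:
    """Everything a full synthetic-cohort run needs."""

    output_dir: str = "motorsig_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    band_hz: tuple[float, float] = (0.01, 0.1)
    filter_order: int = 4
    top_k: int = 60  #: voxels per single-subject localizer
    srm_k: int = 5
    srm_gamma: float | None = None
    svm_C: float = 1.0
    plsr_L: int = 2
    classification_rois: tuple[str, ...] | None = None  #: None = all conditions
    seed_radius: float = 5.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in dataclasses.asdict(self.cohort).items()
            if k != "roi_layout"
        }
        d["cohort"]["roi_layout"] = {
            lbl: np.asarray(idx).tolist() for lbl, idx in self.cohort.roi_layout.items()
        }
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        cohort = dict(d.pop("cohort", {}))
        if "roi_layout" in cohort and cohort["roi_layout"] is not None:
            cohort["roi_layout"] = {
                lbl: np.asarray(idx, dtype=int)
                for lbl, idx in cohort["roi_layout"].items()
            }
        cohort.pop("n_voxels", None)
        for key in ("grid_shape", "voxel_size_mm", "stage_proportions", "onset_proportions"):
            if key in cohort and cohort[key] is not None:
                cohort[key] = tuple(cohort[key])
        if "stage_connectivity_offsets" in cohort:
            cohort["stage_connectivity_offsets"] = {
                int(k): float(v) for k, v in cohort["stage_connectivity_offsets"].items()
            }
        for key in ("band_hz", "classification_rois"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(cohort=CohortConfig(**cohort), **d)


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    series: list[BoldSeries]
    records: list[ClinicalRecord]
    truth: object
    group_masks: dict[str, RoiMask]
    combined: RoiMask
    stage_contrasts: dict[tuple[int, str], float]
    folds: list
    classification_summary: dict
    plsr_reports: dict[str, object]
    manifest: dict


def _stage_logger(stage: str) -> logging.LoggerAdapter:
    return logging.LoggerAdapter(logger, {"stage": stage})


def run_pipeline(
    config: PipelineConfig,
    stages: Sequence[str] = ALL_STAGES,
    write_volumes: bool = False,
) -> PipelineResult:
    """Run the synthetic-cohort pipeline and write summaries + manifest.

    Stages always run in canonical order; later stages require earlier
    ones.  Rerunning with an identical configuration rewrites bit-identical
    summaries (all randomness descends from the configured seeds).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "package": "motorsig",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": chash,
        "stages": [],
        "outputs": {},
    }

    # --- simulate ----------------------------------------------------------
    log = _stage_logger("simulate")
    log.info("generating cohort (seed=%d)", config.cohort.seed)
    series, records, truth = generate_cohort(config.cohort)
    labels = {
        s.subject_id: (GROUP_ALS if s.subject_id.startswith("P") else GROUP_CTL)
        for s in series
    }
    if "simulate" in stages:
        write_clinical_table(records, out / "clinical.csv")
        (out / "design.json").write_text(
            json.dumps(
                [
                    {"condition": e.condition, "onset_s": e.onset_s, "duration_s": e.duration_s}
                    for e in truth.design.events
                ],
                indent=1,
            )
        )
        manifest["stages"].append("simulate")
        manifest["outputs"]["clinical"] = "clinical.csv"
        if write_volumes:
            from .core import write_bold

            vol_dir = out / "volumes"
            vol_dir.mkdir(exist_ok=True)
            for s in series:
                write_bold(s, vol_dir / f"{s.subject_id}.nii.gz")
            manifest["outputs"]["volumes"] = "volumes/"

    roi_masks = truth.roi_masks(config.cohort.grid)

    result = PipelineResult(
        config=config,
        series=series,
        records=records,
        truth=truth,
        group_masks={},
        combined=truth.combined_mask(config.cohort.grid),
        stage_contrasts={},
        folds=[],
        classification_summary={},
        plsr_reports={},
        manifest=manifest,
    )
    wanted = set(stages)
    if wanted <= {"simulate"}:
        _write_manifest(manifest, out)
        return result

    # --- preprocess --------------------------------------------------------
    log = _stage_logger("preprocess")
    log.info("band-pass %s Hz + block synchronization", config.band_hz)
    filtered = [
        bandpass(s, *config.band_hz, order=config.filter_order) for s in series
    ]
    synced = [synchronize_blocks(s, truth.design) for s in filtered]
    manifest["stages"].append("preprocess")

    # --- localize ----------------------------------------------------------
    if wanted & {"localize", "connectivity", "classify", "plsr", "report"}:
        log = _stage_logger("localize")
        k = min(config.top_k, synced[0].n_voxels)
        log.info("per-subject top-%d localizers", k)
        # GLM regressors are built from the schedule, so localizers must see
        # the data in acquisition order (synchronization permutes frames)
        per_subject = {
            s.subject_id: subject_localizers(s, truth.design, k=k) for s in filtered
        }
        gmasks = {
            c: group_mask([per_subject[sid][c] for sid in per_subject])
            for c in CONDITIONS
        }
        result.group_masks = gmasks
        result.combined = combined_mask(gmasks)
        mask_summary = {
            c: {"n_voxels": m.size, "voxels": m.voxel_index.tolist()}
            for c, m in gmasks.items()
        }
        (out / "group_masks.json").write_text(json.dumps(mask_summary, indent=1))
        manifest["stages"].append("localize")
        manifest["outputs"]["group_masks"] = "group_masks.json"

    # --- connectivity ------------------------------------------------------
    if wanted & {"connectivity", "plsr", "report"}:
        log = _stage_logger("connectivity")
        combined = result.combined
        tmaps_by_subject = {
            s.subject_id: fit_glm(s.restrict(combined), truth.design).tmaps
            for s in filtered
        }
        mean_tmaps = {}
        for c in CONDITIONS:
            first = next(iter(tmaps_by_subject.values()))[c]
            vals = np.mean(
                [tm[c].values for tm in tmaps_by_subject.values()], axis=0
            )
            mean_tmaps[c] = type(first)(vals, first.voxel_index, label=c)
        centers = seed_centers_from_tmaps(mean_tmaps)
        pmaps, cmaps = {}, {}
        synced_by_id = {s.subject_id: s for s in synced}
        for pid, cid in truth.matched_controls.items():
            for cond, center in centers.items():
                pmaps[(pid, cond)] = seed_connectivity(
                    synced_by_id[pid], center, config.seed_radius, combined, label=cond
                )
                cmaps[(pid, cond)] = seed_connectivity(
                    synced_by_id[cid], center, config.seed_radius, combined, label=cond
                )
        result.stage_contrasts = stage_contrast(pmaps, cmaps, records)
        rows = [
            {"kings_stage": st, "seed": seed, "patient_minus_control": v}
            for (st, seed), v in sorted(result.stage_contrasts.items())
        ]
        pd.DataFrame(rows).to_csv(out / "stage_contrast.csv", index=False)
        ec_rows = [
            {"subject_id": s.subject_id, "group": labels[s.subject_id],
             "ecm_mean": float(ecm(s.restrict(combined)).values.mean())}
            for s in synced
        ]
        pd.DataFrame(ec_rows).to_csv(out / "ecm_summary.csv", index=False)
        manifest["stages"].append("connectivity")
        manifest["outputs"]["stage_contrast"] = "stage_contrast.csv"

    # --- classify ----------------------------------------------------------
    if wanted & {"classify", "report"}:
        log = _stage_logger("classify")
        roi_names = config.classification_rois or CONDITIONS
        cls_masks = {c: roi_masks[c] for c in roi_names}
        cohort_lab = [(s, labels[s.subject_id]) for s in synced]
        folds = loso_classify(
            cohort_lab,
            cls_masks,
            k=config.srm_k,
            gamma=config.srm_gamma,
            seed=config.cohort.seed,
            C=config.svm_C,
        )
        result.folds = folds
        contrast = affected_contrast(folds, records)
        result.classification_summary = {
            "overall_accuracy": overall_accuracy(folds),
            "accuracy_first_affected": contrast.mean_first,
            "accuracy_non_first_affected": contrast.mean_nonfirst,
            "t": contrast.t,
            "dof": contrast.dof,
            "p": contrast.p,
        }
        pd.DataFrame([dataclasses.asdict(f) for f in folds]).to_csv(
            out / "classification_folds.csv", index=False
        )
        (out / "classification_summary.json").write_text(
            json.dumps(result.classification_summary, indent=1)
        )
        manifest["stages"].append("classify")
        manifest["outputs"]["classification"] = "classification_summary.json"

    # --- plsr --------------------------------------------------------------
    if wanted & {"plsr", "report"}:
        log = _stage_logger("plsr")
        from .plsr import run_plsr_analysis

        region_rois = {
            "hand": _merge_masks(roi_masks, ("LH", "RH"), "hand"),
            "foot": _merge_masks(roi_masks, ("LF", "RF"), "foot"),
            "tongue": roi_masks["TONGUE"],
        }
        patients = [s for s in synced if labels[s.subject_id] == GROUP_ALS]
        specs = [("ecm", "alsfrs"), ("timeseries", "pumns")]
        for predictor, response in specs:
            rep = run_plsr_analysis(
                patients,
                records,
                predictor=predictor,
                response=response,
                L=config.plsr_L,
                combined=result.combined,
                schedule=truth.design,
                region_rois=region_rois if predictor == "ecm" else None,
            )
            result.plsr_reports[f"{predictor}_{response}"] = rep
            payload = {
                "predictor": predictor,
                "response": response,
                "mean_mse": rep.mean_mse,
                "latents": rep.latent_table,
            }
            if rep.region_stats is not None:
                payload["region_anova"] = {
                    "F": rep.region_stats.anova_F,
                    "dof": list(rep.region_stats.dof),
                    "p": rep.region_stats.p,
                    "holm": {f"{a}_vs_{b}": v for (a, b), v in rep.region_stats.holm_table.items()},
                    "region_means": rep.region_stats.region_means,
                }
            (out / f"plsr_{predictor}_{response}.json").write_text(
                json.dumps(payload, indent=1)
            )
        manifest["stages"].append("plsr")

    _write_manifest(manifest, out)
    return result


def _merge_masks(masks: Mapping[str, RoiMask], names: Sequence[str], label: str) -> RoiMask:
    idx = np.vstack([masks[n].voxel_index for n in names])
    return RoiMask(label, idx, masks[names[0]].grid)


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def replay_from_manifest(path: str | Path, stages: Sequence[str] = ALL_STAGES) -> PipelineResult:
    """Re-run a pipeline from its manifest (bit-identical summaries)."""
    manifest = json.loads(Path(path).read_text())
    config = PipelineConfig.from_dict(manifest["config"])
    return run_pipeline(config, stages=stages)
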