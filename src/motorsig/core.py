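"""Domain types and I/O for the sensorimotor phenotyping pipeline.

The pipeline operates on already-aligned voxel arrays: a subject's BOLD
acquisition is a ``time x voxel`` matrix sampled on a shared
:class:`VolumeGrid`, together with a block-design movement schedule and a
clinical table (age, onset type, ALSFRS-R, King's stage, PUMNS).  Volumes
are exchanged as NIfTI-1 (via nibabel), clinical tables as CSV, and masks
as NIfTI label volumes with a JSON metadata sidecar.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("motorsig")

#: Movement conditions in canonical order: left/right hand, left/right foot,
#: tongue (bulbar).  Every schedule, mask and map uses these labels.
CONDITIONS: tuple[str, ...] = ("LH", "RH", "LF", "RF", "TONGUE")

#: Onset-site to first-affected ROI mapping.  Bulbar onset is bilateral by
#: clinical convention; the limb onsets are mapped bilaterally as well since
#: laterality is not recorded in the clinical table.
ONSET_TO_ROIS: dict[str, frozenset[str]] = {
    "UL": frozenset({"LH", "RH"}),
    "LL": frozenset({"LF", "RF"}),
    "B": frozenset({"TONGUE"}),
}

GROUP_ALS = "ALS"
GROUP_CTL = "CTL"


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class MotorsigError(Exception):
    """Base class for package errors."""


class MissingFileError(MotorsigError):
    """A referenced input file does not exist."""


class NotFourDimensionalError(MotorsigError):
    """A BOLD NIfTI input is not a 4-D volume."""


class MaskOutOfBoundsError(MotorsigError):
    """A mask refers to voxels outside the volume grid."""


class ClinicalParseError(MotorsigError):
    """A clinical-table row failed validation; carries the row id."""

    def __init__(self, row_id: object, message: str):
        super().__init__(f"row {row_id!r}: {message}")
        self.row_id = row_id


# ---------------------------------------------------------------------------
# Volume grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeGrid:
    """Coordinate frame of a voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis, each >= 1.
    voxel_size_mm : tuple of float
        Edge length per axis in mm; must match the affine column norms.
    affine : (4, 4) ndarray
        Voxel-index to world-mm mapping; must be invertible.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    affine: np.ndarray | None = None

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel sizes must be positive")
        affine = self.affine
        if affine is None:
            affine = np.diag(list(vs) + [1.0])
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        norms = np.linalg.norm(affine[:3, :3], axis=0)
        if not np.allclose(norms, vs, atol=1e-6):
            raise ValueError(
                f"voxel_size_mm {vs} inconsistent with affine column norms {norms}"
            )
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_mm", vs)
        object.__setattr__(self, "affine", affine)

    def contains(self, voxel_index: np.ndarray) -> np.ndarray:
        """Boolean array: which of the (N, 3) indices are inside the grid."""
        idx = np.asarray(voxel_index)
        return np.all((idx >= 0) & (idx < np.array(self.shape)), axis=-1)


def _canonical_voxel_order(voxel_index: np.ndarray) -> np.ndarray:
    """Permutation sorting (N, 3) indices lexicographically (x, then y, z)."""
    idx = np.asarray(voxel_index)
    return np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))


# ---------------------------------------------------------------------------
# BOLD series
# ---------------------------------------------------------------------------

@dataclass
class BoldSeries:
    """One subject's BOLD acquisition as a time x voxel matrix.

    ``data[t, j]`` is the signal of voxel ``voxel_index[j]`` at frame ``t``
    (frames are ``tr_s`` seconds apart, acquisition order).
    """

    subject_id: str
    data: np.ndarray
    voxel_index: np.ndarray
    tr_s: float
    grid: VolumeGrid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("data must be T x V with T >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.voxel_index.shape != (self.data.shape[1], 3):
            raise ValueError("voxel_index must be (V, 3)")
        if not np.all(self.grid.contains(self.voxel_index)):
            raise MaskOutOfBoundsError(
                f"{self.subject_id}: voxel indices outside grid {self.grid.shape}"
            )
        if len({tuple(v) for v in self.voxel_index}) != len(self.voxel_index):
            raise ValueError("voxel_index entries must be unique")
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        """Copy of this series with replaced data (metadata preserved)."""
        return dataclasses.replace(self, data=np.asarray(data, dtype=float))

    def restrict(self, mask: "RoiMask") -> "BoldSeries":
        """Sub-series of the columns inside ``mask`` (in mask order)."""
        lut = {tuple(v): j for j, v in enumerate(self.voxel_index)}
        try:
            cols = [lut[tuple(v)] for v in mask.voxel_index]
        except KeyError as err:
            raise MaskOutOfBoundsError(
                f"mask {mask.label!r} has voxels not covered by series "
                f"{self.subject_id!r}"
            ) from err
        return dataclasses.replace(
            self,
            data=self.data[:, cols],
            voxel_index=np.asarray(mask.voxel_index, dtype=int),
        )


# ---------------------------------------------------------------------------
# Design schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignEvent:
    condition: str
    onset_s: float
    duration_s: float


@dataclass(frozen=True)
class DesignSchedule:
    """Block-design schedule: movement events on a rest background."""

    events: tuple[DesignEvent, ...]
    total_duration_s: float

    def __post_init__(self):
        events = tuple(
            e if isinstance(e, DesignEvent) else DesignEvent(*e) for e in self.events
        )
        for e in events:
            if e.condition not in CONDITIONS:
                raise ValueError(f"unknown condition {e.condition!r}")
            if e.onset_s < 0 or e.duration_s <= 0:
                raise ValueError("onsets must be >= 0 and durations > 0")
            if e.onset_s + e.duration_s > self.total_duration_s + 1e-9:
                raise ValueError("event exceeds total duration")
        ordered = sorted(events, key=lambda e: e.onset_s)
        for a, b in zip(ordered, ordered[1:]):
            if a.onset_s + a.duration_s > b.onset_s + 1e-9:
                raise ValueError("events overlap in time")
        present = {e.condition for e in events}
        if not set(CONDITIONS) <= present:
            raise ValueError(f"missing conditions: {set(CONDITIONS) - present}")
        object.__setattr__(self, "events", events)

    def events_sorted(self) -> list[DesignEvent]:
        return sorted(self.events, key=lambda e: e.onset_s)


# ---------------------------------------------------------------------------
# Clinical records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's clinical assessment.

    ALSFRS-R total (0-48; lower = more impaired), King's stage (1-3 involved
    CNS regions), PUMNS (0-32; higher = more upper-motor-neuron impairment)
    and the onset site, from which the first-affected ROI set is derived.
    """

    patient_id: str
    age_years: float
    sex: str
    onset_type: str
    alsfrs_total: int
    kings_stage: int
    pumns: int
    first_affected_rois: frozenset[str] = field(default=frozenset())
    has_matched_control: bool = True

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.onset_type not in ONSET_TO_ROIS:
            raise ValueError(f"unknown onset type {self.onset_type!r}")
        if not self.age_years > 0:
            raise ValueError("age must be positive")
        if not 0 <= self.alsfrs_total <= 48:
            raise ValueError(f"ALSFRS-R total out of range: {self.alsfrs_total}")
        if self.kings_stage not in (1, 2, 3):
            raise ValueError(f"King's stage must be 1-3, got {self.kings_stage}")
        if not 0 <= self.pumns <= 32:
            raise ValueError(f"PUMNS out of range: {self.pumns}")
        rois = self.first_affected_rois or ONSET_TO_ROIS[self.onset_type]
        if not rois:
            raise ValueError("first_affected_rois must be non-empty")
        object.__setattr__(self, "first_affected_rois", frozenset(rois))


# ---------------------------------------------------------------------------
# Masks and scalar maps
# ---------------------------------------------------------------------------

@dataclass
class RoiMask:
    """Unordered voxel set on a grid, serialized in lexicographic order."""

    label: str
    voxel_index: np.ndarray
    grid: VolumeGrid

    def __post_init__(self):
        idx = np.asarray(self.voxel_index, dtype=int).reshape(-1, 3)
        if idx.shape[0] == 0:
            raise ValueError(f"mask {self.label!r} is empty")
        if not np.all(self.grid.contains(idx)):
            raise MaskOutOfBoundsError(f"mask {self.label!r} outside grid")
        idx = idx[_canonical_voxel_order(idx)]
        if len({tuple(v) for v in idx}) != len(idx):
            raise ValueError(f"mask {self.label!r} has duplicate voxels")
        self.voxel_index = idx

    @property
    def size(self) -> int:
        return self.voxel_index.shape[0]

    def voxel_set(self) -> frozenset[tuple[int, int, int]]:
        return frozenset(map(tuple, self.voxel_index))


@dataclass
class ScalarMap:
    """Voxel-wise scalar map aligned with a voxel index list."""

    values: np.ndarray
    voxel_index: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.voxel_index = np.asarray(self.voxel_index, dtype=int).reshape(-1, 3)
        if self.values.shape[0] != self.voxel_index.shape[0]:
            raise ValueError("values and voxel_index lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map values must be finite")


class TMap(ScalarMap):
    """GLM t-statistic map for one movement condition."""


class SeedMap(ScalarMap):
    """Seed-based correlation map; values lie in [-1, 1]."""


class EcMap(ScalarMap):
    """Eigenvector-centrality map: non-negative with unit Euclidean norm."""

    def __post_init__(self):
        super().__post_init__()
        if np.any(self.values < -1e-12):
            raise ValueError("eigenvector centrality must be non-negative")
        if abs(np.linalg.norm(self.values) - 1.0) > 1e-8:
            raise ValueError("eigenvector centrality must have unit norm")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_bold(
    path: str | Path,
    mask: RoiMask | None = None,
    tr_s: float = 2.0,
    subject_id: str | None = None,
) -> BoldSeries:
    """Read a 4-D NIfTI into a time x voxel :class:`BoldSeries`.

    Columns are the in-mask voxels (whole grid when ``mask`` is None) in
    lexicographic index order; rows are frames in acquisition order.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim != 4:
        raise NotFourDimensionalError(f"{path}: expected 4-D, got {arr.ndim}-D")
    shape = arr.shape[:3]
    sizes = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = VolumeGrid(shape, sizes, np.asarray(img.affine, dtype=float))
    if mask is None:
        idx = np.argwhere(np.ones(shape, dtype=bool))
    else:
        if not np.all(grid.contains(mask.voxel_index)):
            raise MaskOutOfBoundsError(f"mask {mask.label!r} outside volume {shape}")
        idx = mask.voxel_index
    data = arr[idx[:, 0], idx[:, 1], idx[:, 2], :].T.astype(float)
    hdr_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    return BoldSeries(
        subject_id=subject_id or path.stem.replace(".nii", ""),
        data=data,
        voxel_index=idx,
        tr_s=tr_s if tr_s else hdr_tr,
        grid=grid,
    )


def write_bold(series: BoldSeries, path: str | Path) -> None:
    """Write a :class:`BoldSeries` as a 4-D NIfTI (off-mask voxels are 0)."""
    arr = np.zeros(series.grid.shape + (series.n_timepoints,), dtype=np.float64)
    vi = series.voxel_index
    arr[vi[:, 0], vi[:, 1], vi[:, 2], :] = series.data.T
    img = nib.Nifti1Image(arr, series.grid.affine)
    img.header.set_zooms(series.grid.voxel_size_mm + (series.tr_s,))
    nib.save(img, str(path))


def save_mask(mask: RoiMask, path: str | Path) -> None:
    """Write a mask as a NIfTI label volume plus a JSON metadata sidecar."""
    arr = np.zeros(mask.grid.shape, dtype=np.int16)
    vi = mask.voxel_index
    arr[vi[:, 0], vi[:, 1], vi[:, 2]] = 1
    nib.save(nib.Nifti1Image(arr, mask.grid.affine), str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz/.nii
    meta = {"label": mask.label, "n_voxels": int(mask.size)}
    Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=1))


def load_mask(path: str | Path, label: str | None = None) -> RoiMask:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    sizes = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = VolumeGrid(arr.shape, sizes, np.asarray(img.affine, dtype=float))
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
    if label is None and sidecar.exists():
        label = json.loads(sidecar.read_text()).get("label")
    return RoiMask(label or path.stem, np.argwhere(arr > 0), grid)


# ---------------------------------------------------------------------------
# Clinical table I/O
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "onset_type",
    "alsfrs_total",
    "kings_stage",
    "pumns",
)


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Parse a clinical CSV (comma-separated, UTF-8, header required).

    Required columns: patient_id, age_years, sex, onset_type, alsfrs_total,
    kings_stage, pumns.  Optional: matched_control (yes/no).  The
    first-affected ROI set is derived from the onset site (UL -> hands,
    LL -> feet, B -> tongue).
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ClinicalParseError("<header>", f"missing columns {missing}")
    if df.empty:
        warnings.warn(f"clinical table {path} is empty", stacklevel=2)
        logger.warning("clinical table %s is empty", path)
        return []
    records = []
    for _, row in df.iterrows():
        rid = row["patient_id"]
        try:
            records.append(
                ClinicalRecord(
                    patient_id=str(rid),
                    age_years=float(row["age_years"]),
                    sex=str(row["sex"]).strip(),
                    onset_type=str(row["onset_type"]).strip(),
                    alsfrs_total=int(row["alsfrs_total"]),
                    kings_stage=int(row["kings_stage"]),
                    pumns=int(row["pumns"]),
                    has_matched_control=(
                        str(row.get("matched_control", "yes")).strip().lower()
                        in ("yes", "true", "1")
                    ),
                )
            )
        except (ValueError, KeyError) as err:
            raise ClinicalParseError(rid, str(err)) from err
    return records


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "age_years": r.age_years,
            "sex": r.sex,
            "matched_control": "yes" if r.has_matched_control else "no",
            "onset_type": r.onset_type,
            "alsfrs_total": r.alsfrs_total,
            "kings_stage": r.kings_stage,
            "pumns": r.pumns,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_reference_clinical() -> list[ClinicalRecord]:
    """The packaged 14-patient reference clinical table."""
    with importlib.resources.as_file(
        importlib.resources.files("motorsig.data") / "table1_clinical.csv"
    ) as p:
        return read_clinical_table(p)
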