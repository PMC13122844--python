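"""Synthetic task-fMRI cohort generator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes for a
patient/control movement-mapping study: per-group low-dimensional shared
temporal responses mixed through subject-specific orthonormal spatial bases,
somatotopic ROI clusters (left/right hand, left/right foot, tongue) carrying
condition-locked HRF-convolved block responses, a sparse subject-specific
term, disease-stage-dependent inter-ROI coupling following an inverted-U
profile (reduced at stage 1, raised at stage 2, reduced again at stage 3),
and clinical scores (ALSFRS-R, PUMNS) tied to a per-patient severity latent
that also modulates connectivity in configurable "driver" regions.

Every random draw descends from a single integer seed through a
counter-based splitting scheme (one child stream per purpose and subject),
so stages can be regenerated independently and cohorts are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import (
    CONDITIONS,
    GROUP_ALS,
    GROUP_CTL,
    ONSET_TO_ROIS,
    BoldSeries,
    ClinicalRecord,
    DesignEvent,
    DesignSchedule,
    RoiMask,
    VolumeGrid,
)

BLOCK_S = 12.0  #: movement block duration (s)
REST_S = 15.0  #: rest interval duration (s); rest also leads and trails the run
N_REPEATS = 4  #: repetitions of each movement condition in one run


def _rng(seed: int, *tags: object) -> np.random.Generator:
    """Child generator for (seed, tags): counter-based stream splitting."""
    words = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        words.append(zlib.crc32(str(t).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))


def _smooth_standardized(rng: np.random.Generator, shape, sigma: float = 3.0):
    """Temporally smooth signals with zero mean and unit population SD."""
    x = gaussian_filter1d(rng.standard_normal(shape), sigma=sigma, axis=-1)
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd == 0, 1.0, sd)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def default_roi_layout(
    grid_shape: tuple[int, int, int] = (16, 16, 4),
) -> dict[str, np.ndarray]:
    """Five disjoint cuboid clusters totalling 200 voxels.

    The hand fields are the largest somatotopic representations in the
    motor cortex, so they get the biggest clusters (60 voxels each); the
    foot fields are smallest (20 each) and the tongue field intermediate
    (40), mirroring the relative extents of the motor homunculus.
    """
    regions = {
        "LH": ((1, 1, 1), (5, 6, 2)),
        "RH": ((1, 8, 1), (5, 6, 2)),
        "LF": ((8, 1, 1), (5, 2, 2)),
        "RF": ((8, 4, 1), (5, 2, 2)),
        "TONGUE": ((8, 7, 1), (5, 4, 2)),
    }
    layout = {}
    for label, ((x0, y0, z0), size) in regions.items():
        if any(c + s > g for c, s, g in zip((x0, y0, z0), size, grid_shape)):
            raise ValueError(f"grid {grid_shape} too small for default ROI layout")
        xs, ys, zs = (np.arange(c, c + s) for c, s in zip((x0, y0, z0), size))
        layout[label] = np.array(
            [(x, y, z) for x in xs for y in ys for z in zs], dtype=int
        )
    return layout


#: Relative strength with which each ROI's voxels carry the severity latent.
#: Foot and tongue fields carry it most, the hand fields least, so a
#: regression from voxel-wise connectivity onto clinical scores should weight
#: foot/tongue above hand.
DEFAULT_SEVERITY_ROI_WEIGHTS: dict[str, float] = {
    "LH": 0.2,
    "RH": 0.2,
    "LF": 0.8,
    "RF": 0.8,
    "TONGUE": 1.0,
}


@dataclass
class CohortConfig:
    """Study-design and effect-size parameters of the generator.

    The defaults mirror the emulated study: 14 patients and 12 matched
    controls, a 2 s TR, 12 s movement blocks with 15 s rest, five movement
    conditions repeated four times, and stage-wise patient-minus-control
    connectivity offsets of -0.10 / +0.12 / -0.20 correlation units for
    King's stages 1 / 2 / 3 (the inverted-U profile).
    """

    n_patients: int = 14
    n_controls: int = 12
    grid_shape: tuple[int, int, int] = (16, 16, 4)
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    roi_layout: dict[str, np.ndarray] | None = None
    k_true: int = 5
    snr: float = 3.0
    stage_connectivity_offsets: dict[int, float] = field(
        default_factory=lambda: {1: -0.10, 2: +0.12, 3: -0.20}
    )
    clinical_noise_sd: float = 0.1
    seed: int = 0
    tr_s: float = 2.0
    #: override the number of frames (default: full 20-trial schedule)
    n_timepoints: int | None = None
    sparsity: float = 0.05  #: expected nonzero fraction of the sparse term
    s_amplitude: float = 0.5
    activation_amplitude: float = 1.0
    #: baseline coupling weight of the subject-level latent shared by all ROIs
    coupling_base: float = 0.6
    #: nominal control-group ROI-pair correlation used to map the stage
    #: offsets (correlation units) onto coupling weights
    nominal_coupling_r: float = 0.45
    severity_gain: float = 0.6
    #: amplitude of the shared low-rank component; None scales W_i R_g to
    #: unit average per-voxel variance (sqrt(V / k_true))
    shared_strength: float | None = None
    severity_roi_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_ROI_WEIGHTS)
    )
    baseline: float = 100.0
    stage_proportions: tuple[float, float, float] = (6, 4, 4)
    onset_proportions: tuple[float, float, float] = (8, 3, 3)  # UL, LL, B

    def __post_init__(self):
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("need at least one subject per group")
        if self.roi_layout is None:
            self.roi_layout = default_roi_layout(self.grid_shape)
        seen: set[tuple[int, int, int]] = set()
        for label, idx in self.roi_layout.items():
            vox = set(map(tuple, np.asarray(idx, dtype=int)))
            if seen & vox:
                raise ValueError(f"ROI {label!r} overlaps another ROI")
            seen |= vox
        self.n_voxels = len(seen)
        if self.k_true > self.n_voxels:
            raise ValueError("k_true exceeds the number of in-ROI voxels")
        if not self.snr > 0:
            raise ValueError("snr must be > 0")
        if self.clinical_noise_sd < 0:
            raise ValueError("clinical_noise_sd must be >= 0")

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid(self.grid_shape, self.voxel_size_mm)

    def n_frames(self) -> int:
        if self.n_timepoints is not None:
            return int(self.n_timepoints)
        total = schedule_total_duration()
        return int(np.floor(total / self.tr_s))


def schedule_total_duration() -> float:
    """Run length: 20 movement blocks with rest before, between and after."""
    n_blocks = len(CONDITIONS) * N_REPEATS
    return n_blocks * BLOCK_S + (n_blocks + 1) * REST_S


# ---------------------------------------------------------------------------
# Design schedule and HRF
# ---------------------------------------------------------------------------

def generate_design(config: CohortConfig | None = None, seed: int | None = None) -> DesignSchedule:
    """Randomized block-design schedule: 5 conditions x 4 repetitions.

    Each 12 s movement block is preceded and followed by 15 s of rest
    (rest leads the first and trails the last block), so the run lasts
    20 x 12 + 21 x 15 = 555 s.  Block order is a seeded permutation.
    """
    if config is not None and seed is None:
        seed = config.seed
    rng = _rng(seed or 0, "design")
    order = list(CONDITIONS) * N_REPEATS
    perm = rng.permutation(len(order))
    events = []
    for j, pos in enumerate(perm):
        onset = REST_S + j * (BLOCK_S + REST_S)
        events.append(DesignEvent(order[pos], onset, BLOCK_S))
    return DesignSchedule(tuple(events), schedule_total_duration())


def hrf(t) -> np.ndarray | float:
    """Canonical double-gamma haemodynamic response, unit peak.

    Positive lobe peaking near 5 s with an undershoot around 15 s; the
    value at t = 0 is exactly 0.  Raises on negative times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("hrf is defined for t >= 0")
    from scipy.stats import gamma as gamma_dist

    peak = gamma_dist.pdf(t_arr, a=6, scale=1.0)
    undershoot = gamma_dist.pdf(t_arr, a=16, scale=1.0)
    h = peak - undershoot / 6.0
    # unit peak normalization (analytic mode of the dominant lobe is ~5 s)
    grid = np.arange(0, 32, 0.01)
    hmax = np.max(gamma_dist.pdf(grid, a=6, scale=1.0) - gamma_dist.pdf(grid, a=16, scale=1.0) / 6.0)
    out = h / hmax
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def condition_regressors(
    schedule: DesignSchedule, n_frames: int, tr_s: float
) -> dict[str, np.ndarray]:
    """HRF-convolved condition boxcars sampled at the frame times.

    When ``n_frames`` exceeds the schedule duration the schedule repeats
    cyclically; shorter series truncate it.
    """
    sched_frames = int(np.floor(schedule.total_duration_s / tr_s))
    sched_frames = max(sched_frames, 1)
    t_kernel = np.arange(0, 32.0, tr_s)
    kernel = hrf(t_kernel)
    regs = {}
    for cond in CONDITIONS:
        box = np.zeros(sched_frames)
        for e in schedule.events:
            if e.condition != cond:
                continue
            a = int(np.ceil(e.onset_s / tr_s - 1e-9))
            b = int(np.ceil((e.onset_s + e.duration_s) / tr_s - 1e-9))
            box[a:min(b, sched_frames)] = 1.0
        conv = np.convolve(box, kernel)[:sched_frames]
        reps = int(np.ceil(n_frames / sched_frames))
        regs[cond] = np.tile(conv, reps)[:n_frames]
    return regs


# ---------------------------------------------------------------------------
# Cohort truth
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Generative ground truth stored for recovery tests."""

    shared: dict[str, np.ndarray]  #: group -> k x T shared response
    bases: dict[str, np.ndarray]  #: subject -> V x k orthonormal basis
    individual: dict[str, np.ndarray]  #: subject -> V x T sparse term
    severity_latent: dict[str, float]  #: patient -> severity latent
    coupling_weight: dict[str, float]  #: subject -> coupling weight a_i
    severity_loadings: np.ndarray  #: per-voxel severity driver weight
    noiseless: dict[str, np.ndarray]  #: subject -> T x V noise-free data
    matched_controls: dict[str, str]  #: patient -> matched control id
    design: DesignSchedule
    roi_layout: dict[str, np.ndarray]
    voxel_index: np.ndarray
    roi_of_voxel: np.ndarray  #: ROI label per column

    def roi_masks(self, grid: VolumeGrid) -> dict[str, RoiMask]:
        return {
            label: RoiMask(label, idx, grid) for label, idx in self.roi_layout.items()
        }

    def combined_mask(self, grid: VolumeGrid) -> RoiMask:
        return RoiMask("combined", np.vstack(list(self.roi_layout.values())), grid)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _coupling_weight(config: CohortConfig, stage: int | None) -> float:
    """Map a stage's correlation offset onto a latent coupling weight.

    Uses the odds transform r/(1-r): the squared weight scales with the
    target correlation odds relative to the nominal control odds, which
    reproduces the offset's sign exactly and its magnitude approximately
    (the offsets are specified in correlation units).
    """
    a0 = config.coupling_base
    if stage is None:
        return a0
    r0 = config.nominal_coupling_r
    target = float(np.clip(r0 + config.stage_connectivity_offsets[stage], 0.02, 0.98))
    ratio = (target / (1 - target)) / (r0 / (1 - r0))
    return a0 * float(np.sqrt(ratio))


def _orthonormal_basis(rng: np.random.Generator, v: int, k: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((v, k)))
    return q * np.sign(np.where(np.diag(r) == 0, 1.0, np.diag(r)))


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[BoldSeries], list[ClinicalRecord], CohortTruth]:
    """Generate a full cohort (patients first, then controls) with truth.

    Per subject the signal decomposes as baseline + activation +
    (W_i R_g)^T + coupling latents + S_i^T + Gaussian noise, with the noise
    SD set to rms(clean signal)/snr.
    """
    seed = config.seed
    design = generate_design(config)
    T = config.n_frames()
    if config.k_true > T:
        raise ValueError("k_true exceeds the number of time points")

    layout = {label: np.asarray(idx, dtype=int) for label, idx in config.roi_layout.items()}
    voxel_index = np.vstack([layout[c] for c in CONDITIONS if c in layout])
    order = np.lexsort((voxel_index[:, 2], voxel_index[:, 1], voxel_index[:, 0]))
    roi_of = np.concatenate(
        [np.repeat(c, len(layout[c])) for c in CONDITIONS if c in layout]
    )
    voxel_index, roi_of = voxel_index[order], roi_of[order]
    V = voxel_index.shape[0]
    grid = config.grid

    regs = condition_regressors(design, T, config.tr_s)
    act = np.zeros((T, V))
    for cond in CONDITIONS:
        cols = roi_of == cond
        act[:, cols] = config.activation_amplitude * regs[cond][:, None]
    d_v = np.array([config.severity_roi_weights.get(r, 0.0) for r in roi_of])

    strength = (
        config.shared_strength
        if config.shared_strength is not None
        else float(np.sqrt(V / config.k_true))
    )
    shared = {
        g: strength * _smooth_standardized(_rng(seed, "shared", g), (config.k_true, T))
        for g in (GROUP_ALS, GROUP_CTL)
    }

    # --- clinical structure -------------------------------------------------
    rng_clin = _rng(seed, "clinical")
    p_stage = np.asarray(config.stage_proportions, dtype=float)
    p_stage /= p_stage.sum()
    p_onset = np.asarray(config.onset_proportions, dtype=float)
    p_onset /= p_onset.sum()
    stages = rng_clin.choice([1, 2, 3], size=config.n_patients, p=p_stage)
    onsets = rng_clin.choice(["UL", "LL", "B"], size=config.n_patients, p=p_onset)
    sev = (stages - 2) + 0.3 * rng_clin.standard_normal(config.n_patients)
    ages = np.clip(rng_clin.normal(56.0, 15.0, config.n_patients), 25, 80)
    sexes = np.where(np.arange(config.n_patients) % 2 == 0, "F", "M")

    records: list[ClinicalRecord] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        alsfrs = int(np.clip(round(
            40.0 - 6.0 * sev[i] + 6.0 * config.clinical_noise_sd * rng_clin.standard_normal()
        ), 0, 48))
        pumns = int(np.clip(round(
            4.0 + 8.0 * (onsets[i] == "UL") + 3.0 * sev[i]
            + 8.0 * config.clinical_noise_sd * rng_clin.standard_normal()
        ), 0, 32))
        records.append(
            ClinicalRecord(
                patient_id=pid,
                age_years=float(round(ages[i], 1)),
                sex=str(sexes[i]),
                onset_type=str(onsets[i]),
                alsfrs_total=alsfrs,
                kings_stage=int(stages[i]),
                pumns=pumns,
                has_matched_control=i < config.n_controls,
            )
        )

    # --- subject time series ------------------------------------------------
    subjects: list[tuple[str, str, int | None, float]] = []
    for i in range(config.n_patients):
        subjects.append((f"P{i + 1:02d}", GROUP_ALS, int(stages[i]), float(sev[i])))
    for i in range(config.n_controls):
        subjects.append((f"C{i + 1:02d}", GROUP_CTL, None, 0.0))

    series: list[BoldSeries] = []
    bases, individual, noiseless = {}, {}, {}
    coupling = {}
    infinite_snr = np.isinf(config.snr)
    for sid, group, stage, ell in subjects:
        rs = _rng(seed, "subject", sid)
        W = _orthonormal_basis(rs, V, config.k_true)
        S = np.where(
            rs.random((V, T)) < config.sparsity,
            rs.normal(0.0, config.s_amplitude, (V, T)),
            0.0,
        )
        z = _smooth_standardized(rs, T)
        y = _smooth_standardized(rs, T)
        a_i = _coupling_weight(config, stage)
        b_i = config.severity_gain * (1.0 + 0.4 * ell)
        clean = (
            act
            + (W @ shared[group]).T
            + a_i * np.outer(z, np.ones(V))
            + np.outer(y, b_i * d_v)
        )
        if infinite_snr:
            noise = np.zeros_like(clean)
        else:
            sd = float(np.sqrt(np.mean(clean**2))) / config.snr
            noise = rs.normal(0.0, sd, clean.shape)
        data = config.baseline + clean + S.T + noise
        series.append(
            BoldSeries(
                subject_id=sid,
                data=data,
                voxel_index=voxel_index,
                tr_s=config.tr_s,
                grid=grid,
            )
        )
        bases[sid] = W
        individual[sid] = S
        noiseless[sid] = clean
        coupling[sid] = a_i

    matched = {
        f"P{i + 1:02d}": f"C{i + 1:02d}"
        for i in range(min(config.n_patients, config.n_controls))
    }
    truth = CohortTruth(
        shared=shared,
        bases=bases,
        individual=individual,
        severity_latent={f"P{i + 1:02d}": float(sev[i]) for i in range(config.n_patients)},
        coupling_weight=coupling,
        severity_loadings=d_v,
        noiseless=noiseless,
        matched_controls=matched,
        design=design,
        roi_layout=layout,
        voxel_index=voxel_index,
        roi_of_voxel=roi_of,
    )
    return series, records, truth
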