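"""Temporal preprocessing: band-pass filtering, voxel standardization,
block synchronization, run splitting and per cent signal change.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import CONDITIONS, BoldSeries, DesignSchedule, MotorsigError, RoiMask, logger


class FilterBandError(MotorsigError):
    """Requested band is infeasible for the sampling rate or series length."""


class ScheduleMismatchError(MotorsigError):
    """Schedule and series cover different durations."""


def bandpass(
    series: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.1, order: int = 4
) -> BoldSeries:
    """Zero-phase Butterworth band-pass (default 0.01-0.1 Hz) per voxel.

    The filter is applied forward and backward (zero phase), so the
    effective attenuation is twice the single-pass order-``order`` rolloff.
    """
    fs = 1.0 / series.tr_s
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise FilterBandError(
            f"band ({low_hz}, {high_hz}) Hz infeasible at Nyquist {nyq} Hz"
        )
    sos = butter(order, [low_hz, high_hz], btype="bandpass", output="sos", fs=fs)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if series.n_timepoints <= padlen:
        raise FilterBandError(
            f"series too short ({series.n_timepoints} frames) for filter padding"
        )
    return series.with_data(sosfiltfilt(sos, series.data, axis=0))


def zscore_voxels(series: BoldSeries) -> BoldSeries:
    """Standardize every voxel column to mean 0, population SD 1.

    Constant columns become all-zero with a warning.
    """
    x = series.data
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} zero-variance voxel(s) set to zero", stacklevel=2
        )
        logger.warning("%s: %d zero-variance voxels", series.subject_id, flat.sum())
    z = (x - mean) / np.where(flat, 1.0, sd)
    z[:, flat] = 0.0
    return series.with_data(z)


def _frame_segments(
    schedule: DesignSchedule, n_frames: int, tr_s: float
) -> list[tuple[str, np.ndarray]]:
    """Assign every frame to its design segment.

    Frames before the first movement block form a "prefix" rest segment;
    each movement block then owns its 12 s window plus all frames up to the
    next block's onset (i.e. the following rest window).
    """
    times = np.arange(n_frames) * tr_s
    events = schedule.events_sorted()
    bounds = [e.onset_s for e in events] + [np.inf]
    segments: list[tuple[str, np.ndarray]] = []
    prefix = np.nonzero(times < bounds[0])[0]
    segments.append(("prefix", prefix))
    for j, e in enumerate(events):
        frames = np.nonzero((times >= bounds[j]) & (times < bounds[j + 1]))[0]
        segments.append((e.condition, frames))
    return segments


def synchronize_blocks(series: BoldSeries, schedule: DesignSchedule) -> BoldSeries:
    """Reorder frames so condition blocks follow the canonical order.

    After reordering, blocks appear as LH, RH, LF, RF, TONGUE (repetitions
    in temporal order), each block carrying its movement window plus the
    following rest window; the leading rest stays first.  Applying this to
    every subject of a cohort aligns condition timing across subjects
    regardless of each subject's randomized block order.
    """
    if schedule.total_duration_s < (series.n_timepoints - 1) * series.tr_s - 1e-9:
        raise ScheduleMismatchError(
            f"schedule covers {schedule.total_duration_s} s but series lasts "
            f"{series.n_timepoints * series.tr_s} s"
        )
    segments = _frame_segments(schedule, series.n_timepoints, series.tr_s)
    prefix = [f for label, f in segments if label == "prefix"]
    blocks = [(label, f) for label, f in segments if label != "prefix"]
    ordered = sorted(
        range(len(blocks)), key=lambda i: (CONDITIONS.index(blocks[i][0]), i)
    )
    perm = np.concatenate(prefix + [blocks[i][1] for i in ordered])
    if perm.shape[0] != series.n_timepoints:
        raise ScheduleMismatchError("frame assignment is not a permutation")
    return series.with_data(series.data[perm])


def block_label_sequence(
    schedule: DesignSchedule, n_frames: int, tr_s: float
) -> list[str]:
    """Per-frame condition labels after :func:`synchronize_blocks`."""
    segments = _frame_segments(schedule, n_frames, tr_s)
    prefix = [(label, f) for label, f in segments if label == "prefix"]
    blocks = [(label, f) for label, f in segments if label != "prefix"]
    ordered = sorted(
        range(len(blocks)), key=lambda i: (CONDITIONS.index(blocks[i][0]), i)
    )
    labels: list[str] = []
    for label, frames in prefix:
        labels += ["rest"] * len(frames)
    for i in ordered:
        label, frames = blocks[i]
        labels += [label] * len(frames)
    return labels


def split_runs(series: BoldSeries) -> tuple[BoldSeries, BoldSeries]:
    """Split into run 1 (first half) and run 2 (second half, odd remainder)."""
    T = series.n_timepoints
    if T < 4:
        raise ValueError("need at least 4 frames to split runs")
    half = T // 2
    return series.with_data(series.data[:half]), series.with_data(series.data[half:])


def percent_signal_change(
    series: BoldSeries,
    schedule: DesignSchedule,
    region: RoiMask,
    raw_series: BoldSeries | None = None,
    zscore_denominator: bool = False,
) -> float:
    """Per cent signal change of task blocks over flanking rest.

    For each movement block, the numerator is the mean in-region signal of
    the block's movement window minus the mean of its flanking rest windows
    (the rest immediately before and after); block values are averaged over
    all blocks.  The denominator is the mean raw rest-interval signal in the
    region, taken from ``raw_series`` when given (use it when ``series`` has
    been filtered or standardized, which destroys the baseline level), and
    from ``series`` itself otherwise.  With ``zscore_denominator`` the
    denominator uses ``series`` regardless (the all-standardized variant).
    """
    sub = series.restrict(region)
    times = np.arange(sub.n_timepoints) * sub.tr_s
    events = schedule.events_sorted()
    task = np.zeros(sub.n_timepoints, dtype=bool)
    for e in events:
        task |= (times >= e.onset_s) & (times < e.onset_s + e.duration_s)
    rest = ~task

    region_mean = sub.data.mean(axis=1)
    block_vals = []
    for j, e in enumerate(events):
        in_block = (times >= e.onset_s) & (times < e.onset_s + e.duration_s)
        prev_onset = events[j - 1].onset_s + events[j - 1].duration_s if j > 0 else 0.0
        next_onset = events[j + 1].onset_s if j + 1 < len(events) else np.inf
        flank = rest & (times >= prev_onset) & (times < next_onset)
        if not in_block.any() or not flank.any():
            continue
        block_vals.append(region_mean[in_block].mean() - region_mean[flank].mean())
    if not block_vals:
        raise ValueError("schedule produced no usable blocks for this series")

    if zscore_denominator or raw_series is None:
        denom_series = sub
    else:
        denom_series = raw_series.restrict(region)
    denom = denom_series.data[rest[: denom_series.n_timepoints]].mean()
    if abs(denom) < 1e-12:
        raise ZeroDivisionError("rest baseline is zero; cannot form per cent change")
    return 100.0 * float(np.mean(block_vals)) / float(denom)
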