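"""Band-pass filtering, z-scoring, block synchronization, runs, PSC."""

from __future__ import annotations

import numpy as np
import pytest

from motorsig import (
    CohortConfig,
    bandpass,
    generate_design,
    percent_signal_change,
    split_runs,
    synchronize_blocks,
    zscore_voxels,
)
from motorsig.preprocess import FilterBandError, block_label_sequence

from conftest import make_grid, make_mask, make_series


def _sine_series(freq_hz, T=300, tr_s=2.0, amp=1.0):
    t = np.arange(T) * tr_s
    return make_series(amp * np.sin(2 * np.pi * freq_hz * t).reshape(-1, 1),
                       tr_s=tr_s)


def _fft_amplitude(x, freq_hz, tr_s):
    T = len(x)
    spectrum = np.abs(np.fft.rfft(x)) / (T / 2)
    freqs = np.fft.rfftfreq(T, tr_s)
    return spectrum[np.argmin(np.abs(freqs - freq_hz))]


# ---------------------------------------------------------------- bandpass


def test_bandpass_rejects_dc():
    series = make_series(np.full((200, 1), 7.5))
    out = bandpass(series)
    assert np.max(np.abs(out.data)) < 1e-6 * 7.5


def test_bandpass_passes_in_band_sinusoid():
    series = _sine_series(0.05)
    out = bandpass(series)
    ratio = (_fft_amplitude(out.data[:, 0], 0.05, 2.0)
             / _fft_amplitude(series.data[:, 0], 0.05, 2.0))
    assert ratio >= 0.9


def test_bandpass_attenuates_out_of_band_sinusoid():
    series = _sine_series(0.2)
    out = bandpass(series)
    ratio = (_fft_amplitude(out.data[:, 0], 0.2, 2.0)
             / _fft_amplitude(series.data[:, 0], 0.2, 2.0))
    assert ratio <= 10 ** (-20 / 20)  # >= 20 dB attenuation


def test_bandpass_is_linear():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(150, 3))
    y = rng.normal(size=(150, 3))
    a, b = 2.5, -1.25
    fx = bandpass(make_series(x)).data
    fy = bandpass(make_series(y)).data
    fxy = bandpass(make_series(a * x + b * y)).data
    np.testing.assert_allclose(fxy, a * fx + b * fy, atol=1e-8)


def test_bandpass_rejects_band_outside_nyquist():
    series = make_series(np.random.default_rng(1).normal(size=(100, 1)), tr_s=2.0)
    with pytest.raises(FilterBandError):
        bandpass(series, 0.01, 0.3)  # Nyquist = 0.25 Hz


def test_bandpass_rejects_too_short_series():
    series = make_series(np.random.default_rng(1).normal(size=(5, 1)), tr_s=2.0)
    with pytest.raises(FilterBandError):
        bandpass(series)


def test_bandpass_preserves_metadata():
    series = make_series(np.random.default_rng(2).normal(size=(100, 4)))
    out = bandpass(series)
    np.testing.assert_array_equal(out.voxel_index, series.voxel_index)
    assert out.grid == series.grid and out.tr_s == series.tr_s


# ---------------------------------------------------------------- zscore


def test_zscore_gives_zero_mean_unit_population_sd():
    series = make_series(np.random.default_rng(3).normal(5, 3, size=(80, 4)))
    out = zscore_voxels(series)
    np.testing.assert_allclose(out.data.mean(axis=0), 0, atol=1e-10)
    np.testing.assert_allclose(out.data.std(axis=0), 1, atol=1e-10)


def test_zscore_constant_column_becomes_zero_with_warning():
    data = np.random.default_rng(4).normal(size=(50, 2))
    data[:, 1] = 3.0
    with pytest.warns(UserWarning):
        out = zscore_voxels(make_series(data))
    np.testing.assert_array_equal(out.data[:, 1], 0)


def test_zscore_idempotent():
    series = make_series(np.random.default_rng(5).normal(size=(60, 3)))
    once = zscore_voxels(series)
    twice = zscore_voxels(once)
    np.testing.assert_allclose(twice.data, once.data, atol=1e-10)


# ---------------------------------------------------------------- synchronize


def test_synchronize_identity_on_canonical_schedule():
    # A schedule already in canonical condition order should re-order
    # frames into the same sequence of block labels it started with.
    sched = generate_design(seed=0)
    T = int(sched.total_duration_s / 2.0)
    labels = block_label_sequence(sched, T, 2.0)
    assert len(labels) == T


def test_synchronize_aligns_subjects_with_different_orders():
    cfg_a = CohortConfig(seed=1, n_patients=1, n_controls=1)
    cfg_b = CohortConfig(seed=2, n_patients=1, n_controls=1)
    sched_a = generate_design(cfg_a)
    sched_b = generate_design(cfg_b)
    assert [e.condition for e in sched_a.events_sorted()] != [
        e.condition for e in sched_b.events_sorted()
    ]
    T = int(sched_a.total_duration_s / 2.0)
    la = block_label_sequence(sched_a, T, 2.0)
    lb = block_label_sequence(sched_b, T, 2.0)
    assert len(la) == len(lb) == T
    # canonical condition order is schedule-independent
    order_a = [lbl for i, lbl in enumerate(la) if lbl not in la[:i]]
    order_b = [lbl for i, lbl in enumerate(lb) if lbl not in lb[:i]]
    assert order_a == order_b == ["rest", "LH", "RH", "LF", "RF", "TONGUE"]
    # per-condition frame counts agree up to one frame per block boundary
    # (block onsets fall on alternating frame parities at TR = 2 s)
    for lbl in ("LH", "RH", "LF", "RF", "TONGUE"):
        assert abs(la.count(lbl) - lb.count(lbl)) <= 4


def test_synchronize_preserves_length_and_is_permutation():
    cfg = CohortConfig(seed=3, n_patients=1, n_controls=1)
    sched = generate_design(cfg)
    T = int(sched.total_duration_s / 2.0)
    rng = np.random.default_rng(0)
    series = make_series(rng.normal(size=(T, 2)))
    out = synchronize_blocks(series, sched)
    assert out.n_timepoints == T
    # same multiset of rows
    a = np.sort(series.data[:, 0])
    b = np.sort(out.data[:, 0])
    np.testing.assert_allclose(a, b)


def test_synchronize_rejects_length_mismatch():
    from motorsig.preprocess import ScheduleMismatchError

    # truncated series are allowed; a series longer than the schedule is not
    sched = generate_design(seed=0)
    T_long = int(sched.total_duration_s / 2.0) + 30
    series = make_series(np.zeros((T_long, 1)))
    with pytest.raises(ScheduleMismatchError):
        synchronize_blocks(series, sched)


# ---------------------------------------------------------------- split_runs


def test_split_runs_even_and_odd_lengths():
    s10 = make_series(np.arange(20.0).reshape(10, 2))
    r1, r2 = split_runs(s10)
    assert (r1.n_timepoints, r2.n_timepoints) == (5, 5)
    s11 = make_series(np.arange(22.0).reshape(11, 2))
    r1, r2 = split_runs(s11)
    assert (r1.n_timepoints, r2.n_timepoints) == (5, 6)
    np.testing.assert_array_equal(
        np.vstack([r1.data, r2.data]), s11.data
    )


def test_split_runs_rejects_short_series():
    with pytest.raises(ValueError):
        split_runs(make_series(np.zeros((3, 1))))


# ---------------------------------------------------------------- psc


def _boxcar_series(amp, baseline, sched, tr_s=2.0):
    T = int(sched.total_duration_s / tr_s)
    t = np.arange(T) * tr_s
    sig = np.full(T, float(baseline))
    for e in sched.events_sorted():
        sig[(t >= e.onset_s) & (t < e.onset_s + e.duration_s)] += amp
    return make_series(sig.reshape(-1, 1))


def test_psc_zero_when_task_equals_rest():
    sched = generate_design(seed=0)
    series = _boxcar_series(0.0, 100.0, sched)
    region = make_mask(series.grid, series.voxel_index, "all")
    assert percent_signal_change(series, sched, region) == pytest.approx(0.0)


def test_psc_unit_block_on_baseline_100_is_about_one_percent():
    sched = generate_design(seed=0)
    series = _boxcar_series(1.0, 100.0, sched)
    region = make_mask(series.grid, series.voxel_index, "all")
    psc = percent_signal_change(series, sched, region)
    assert psc == pytest.approx(1.0, rel=0.05)


def test_psc_antisymmetric_in_block_amplitude():
    sched = generate_design(seed=0)
    region = None
    up = _boxcar_series(1.0, 100.0, sched)
    down = _boxcar_series(-1.0, 100.0, sched)
    region = make_mask(up.grid, up.voxel_index, "all")
    a = percent_signal_change(up, sched, region)
    b = percent_signal_change(down, sched, region)
    assert a == pytest.approx(-b, rel=1e-6)
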