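"""Sliding-window counting, epoch RMS and onset/peak detection."""

import numpy as np
import pytest

import npcdecode as npc
from npcdecode.task import TrialRecord
from npcdecode.timecourse import (NPCTimeCourse, _gaussian_smooth,
                                  detect_onset_peak, detect_saccade_onset,
                                  epoch_bounds, epoch_rms, sliding_counts)


def make_trial(spike_times, trial_end=3000.0, align_at=1500.0):
    ev = {"fixation_on": 0.0, "fixation_acquired": 200.0, "target_on": align_at,
          "target_off": align_at + 300, "go_cue": align_at + 1600,
          "saccade_onset": align_at + 1800 if align_at + 1800 < trial_end else trial_end - 3,
          "fixation1_acquired": trial_end - 2, "fixation2_acquired": trial_end - 1,
          "trial_end": trial_end}
    spikes = {0: np.sort(np.asarray(spike_times, dtype=float) + align_at)}
    return TrialRecord(0, 0, 0, 0, ev, spikes)


def test_sliding_counts_causal_half_open_window():
    # spikes at -100, -50, +20 ms relative to the alignment event
    trial = make_trial([-100.0, -50.0, 20.0], trial_end=4000.0)
    counts, _ = sliding_counts(trial, 1, "target_on", np.array([0.0]), 250.0,
                               warn_clipped=False)
    assert counts[0, 0] == 2  # window [-250, 0) excludes the spike at +20
    # a spike exactly at t is excluded; exactly at t-250 is included
    trial = make_trial([0.0, -250.0])
    counts, _ = sliding_counts(trial, 1, "target_on", np.array([0.0]), 250.0,
                               warn_clipped=False)
    assert counts[0, 0] == 1


def test_sliding_counts_empty_train_and_clipping():
    trial = make_trial([], trial_end=2000.0)
    times = np.array([-1400.0, 0.0, 600.0])
    with pytest.warns(UserWarning, match="clipped"):
        counts, clipped = sliding_counts(trial, 1, "target_on", times, 250.0)
    assert (counts == 0).all()
    assert clipped.tolist() == [True, False, True]  # 600 > trial_end - align


def test_homogeneous_train_mean_count(space):
    """A 20 spk/s homogeneous train averages ~5 spikes per 250 ms window."""
    rng = np.random.default_rng(0)
    times = np.arange(-1000.0, 1000.0, 10.0)
    means = []
    for _ in range(60):
        n = rng.poisson(20.0 * 3.0)
        trial = make_trial(np.sort(rng.uniform(-1500, 1500, n)))
        counts, _ = sliding_counts(trial, 1, "target_on", times, 250.0,
                                   warn_clipped=False)
        means.append(counts.mean())
    assert np.mean(means) == pytest.approx(5.0, abs=0.3)


def test_shifting_spikes_shifts_counts_exactly():
    rng = np.random.default_rng(1)
    spikes = np.sort(rng.uniform(-1000, 1000, 80))
    delta = 130.0
    t1 = make_trial(spikes)
    t2 = make_trial(spikes + delta)
    times = np.arange(-500.0, 500.0, 10.0)
    c1, _ = sliding_counts(t1, 1, "target_on", times, 250.0, warn_clipped=False)
    c2, _ = sliding_counts(t2, 1, "target_on", times + delta, 250.0, warn_clipped=False)
    assert np.array_equal(c1, c2)


def make_tc(times, values, chance=0.125):
    return NPCTimeCourse(times=np.asarray(times, float), npc=np.asarray(values, float),
                         sem=None, behavior="direction", align_event="target_on",
                         chance=chance)


def test_epoch_rms_closed_forms():
    times = np.arange(0, 100, 10.0)
    assert epoch_rms(make_tc(times, np.full(10, 0.4)), (0, 90))[0] == pytest.approx(0.4)
    vals = np.array([0.0, 1.0] * 5)  # half 0, half 1 over equal durations
    assert epoch_rms(make_tc(times, vals), (0, 90))[0] == pytest.approx(np.sqrt(0.5))
    with pytest.raises(ValueError):
        epoch_rms(make_tc(times, vals), (200, 300))


def test_epoch_rms_step_invariant_for_constant_signal():
    a = make_tc(np.arange(0, 1000, 10.0), np.full(100, 0.6))
    b = make_tc(np.arange(0, 1000, 50.0), np.full(20, 0.6))
    assert epoch_rms(a, (0, 950))[0] == pytest.approx(epoch_rms(b, (0, 950))[0])


def test_smoothing_preserves_interior_mean():
    rng = np.random.default_rng(2)
    y = 0.5 + 0.2 * np.sin(np.linspace(0, 6, 400)) + rng.normal(0, 0.01, 400)
    s = _gaussian_smooth(y, 10.0, 50.0, 125.0)
    assert s[50:-50].mean() == pytest.approx(y[50:-50].mean(), abs=0.005)


def test_onset_detected_at_ramp_breakpoint():
    t = np.arange(-1000, 1500, 10.0)
    y = np.interp(t, [-1000, 200, 700, 1500], [0.125, 0.125, 0.9, 0.9])
    marks = detect_onset_peak((t, y), seed=0)
    assert marks.onset_ms == pytest.approx(200.0, abs=20.0)


def test_peak_detected_at_triangular_apex_and_follows_onset():
    t = np.arange(-1000, 1500, 10.0)
    y = np.interp(t, [-1000, -200, 300, 800, 1500], [0.1, 0.1, 0.9, 0.1, 0.1])
    marks = detect_onset_peak((t, y), seed=0)
    assert marks.peak_ms == pytest.approx(300.0, abs=20.0)
    assert marks.onset_ms is not None and marks.onset_ms <= marks.peak_ms


def test_flat_timecourse_yields_absent_marks():
    t = np.arange(0, 2000, 10.0)
    marks = detect_onset_peak((t, np.full_like(t, 0.3)), seed=0)
    assert marks.onset_ms is None and marks.peak_ms is None
    assert marks.onset_reason == "flat"


def test_pure_noise_rarely_yields_marks():
    """Structureless noise produces no marks in >= 95% of traces."""
    rng = np.random.default_rng(3)
    t = np.arange(-1000, 1500, 10.0)
    spurious = 0
    n_rep = 40
    for s in range(n_rep):
        y = 0.3 + rng.normal(0, 0.05, len(t))
        marks = detect_onset_peak((t, y), seed=1000 + s)
        spurious += (marks.onset_ms is not None) or (marks.peak_ms is not None)
    assert spurious / n_rep <= 0.05


def test_untuned_population_timecourse_flat_at_chance(space, untuned_trials):
    tcs = npc.decode_timecourse(untuned_trials, space, "target_on", -600, 1400,
                                step_ms=200.0, n_boot=60, seed=4)
    for b in ("presaccade", "direction", "postsaccade"):
        tc = tcs[b]
        assert np.all(np.abs(tc.npc - tc.chance) <= np.maximum(4 * tc.sem, 0.06))


def test_direction_at_chance_in_fixation_and_elevated_in_memory(space, tuned_trials):
    tc = npc.npc_timecourse(tuned_trials, space, "direction", "target_on",
                            -200, 1400, step_ms=400.0, n_boot=60, seed=4)
    fix = tc.npc[tc.times <= 0]
    mem = tc.npc[tc.times >= 1000]
    sem_mem = tc.sem[tc.times >= 1000]
    assert np.all(np.abs(fix - 0.125) < 0.1)
    assert np.all(mem > fix.max() + 3 * sem_mem)


def test_epoch_bounds_intersect_across_trials(space, session3):
    lo, hi = epoch_bounds(session3, "target_on", "target_off", "go_cue")
    assert lo == pytest.approx(300.0)
    timing = npc.TimingConfig()
    assert 300.0 + timing.memory_min_ms <= hi <= 300.0 + timing.memory_max_ms
    with pytest.raises(ValueError):
        epoch_bounds(session3, "target_on", "go_cue", "target_off")


def test_velocity_threshold_saccade_detector():
    t = np.arange(0, 1000.0, 1.0)
    x = np.where(t < 500, 0.0, np.minimum((t - 500) * 0.2, 8.0))  # 200 deg/s ramp
    onset = detect_saccade_onset(t, x, np.zeros_like(t), threshold_deg_s=50.0)
    assert onset == pytest.approx(500.0, abs=5.0)
    assert detect_saccade_onset(t, np.zeros_like(t), np.zeros_like(t)) is None
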