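"""NPC time courses: sliding-window decoding, epoch RMS, onset/peak detection.

Spike times are aligned to a task event (target onset or saccade onset) and
counted in causal boxcar windows of 250 ms sliding in 10 ms steps; each count
is timestamped at the window END, so the count at time t covers [t-250, t)
and never includes spikes at or after t.  The full decode pipeline (LOO fit,
MAP, accuracy, bootstrap) runs independently at every step, so inference
always uses intervals of identical length across the task.

Epoch-level accuracy is the root mean square of the time course between the
events bounding the epoch, which compares epochs of different lengths on an
equal footing.  Onsets and peaks are found on a Gaussian-smoothed trace by
maximizing the difference between the mean derivative after and before each
candidate step (after-minus-before for onsets, before-minus-after for
peaks); a mark is only reported when its score exceeds what smoothed noise
of the trace's own residual scale produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoder import _per_behavior_mean, loo_decode
from .task import BEHAVIOR_NAMES, BehaviorSpace, TrialRecord, combo_labels

WINDOW_MS_DEFAULT = 250.0
STEP_MS_DEFAULT = 10.0


@dataclass
class NPCTimeCourse:
    """Decoding accuracy vs time for one behavior and alignment event."""

    times: np.ndarray          # window-end times, ms relative to align event
    npc: np.ndarray
    sem: np.ndarray | None
    behavior: str
    align_event: str
    window_ms: float = WINDOW_MS_DEFAULT
    step_ms: float = STEP_MS_DEFAULT
    chance: float = np.nan
    boot: np.ndarray | None = None   # (n_boot, n_times) replicate accuracies
    clipped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.npc = np.asarray(self.npc, dtype=float)
        steps = np.diff(self.times)
        if len(steps) and not np.allclose(steps, steps[0]):
            raise ValueError("time axis must have a constant step")
        if ((self.npc < -1e-12) | (self.npc > 1 + 1e-12)).any():
            raise ValueError("accuracies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.times, "npc": self.npc})
        if self.sem is not None:
            df["sem"] = self.sem
        return df


@dataclass
class EventMarks:
    """Onset and peak times of a time course; None with a reason when undetected."""

    onset_ms: float | None
    peak_ms: float | None
    onset_reason: str | None = None
    peak_reason: str | None = None


# ---------------------------------------------------------------------------
# spike counting

def sliding_counts(trial: TrialRecord, n_neurons: int, align_event: str,
                   times: np.ndarray, window_ms: float = WINDOW_MS_DEFAULT,
                   warn_clipped: bool = True):
    """Causal boxcar counts for one trial at the given window-end times.

    Returns ``(counts, clipped)`` with counts (n_times, n_neurons) and a
    boolean flag per time marking windows extending beyond the trial bounds
    (counted from the spikes that exist, never padded).
    """
    if align_event not in trial.event_times:
        raise ValueError(f"trial {trial.trial_id} has no event {align_event!r}")
    if trial.spikes is None:
        raise ValueError(f"trial {trial.trial_id} has no spikes")
    times = np.asarray(times, dtype=float)
    t0 = trial.event_times[align_event]
    counts = np.empty((len(times), n_neurons), dtype=int)
    for nid in range(n_neurons):
        s = trial.spikes[nid] - t0
        counts[:, nid] = (np.searchsorted(s, times, side="left")
                          - np.searchsorted(s, times - window_ms, side="left"))
    lo, hi = -t0, trial.event_times["trial_end"] - t0
    clipped = (times - window_ms < lo) | (times > hi)
    if warn_clipped and clipped.any():
        warnings.warn(
            f"trial {trial.trial_id}: {int(clipped.sum())} windows extend beyond "
            "the trial bounds and were clipped", stacklevel=2)
    return counts, clipped


def count_tensor(trials: list[TrialRecord], n_neurons: int, align_event: str,
                 times: np.ndarray, window_ms: float = WINDOW_MS_DEFAULT):
    """Counts (n_times, n_trials, n_neurons) plus a per-time any-trial clip flag."""
    counts = np.empty((len(times), len(trials), n_neurons), dtype=int)
    clipped = np.zeros(len(times), dtype=bool)
    for t, trial in enumerate(trials):
        c, cl = sliding_counts(trial, n_neurons, align_event, times, window_ms,
                               warn_clipped=False)
        counts[:, t, :] = c
        clipped |= cl
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} of {len(times)} windows extend beyond some "
            "trial's bounds and were clipped", stacklevel=2)
    return counts, clipped


def window_times(t_start: float, t_stop: float, step_ms: float = STEP_MS_DEFAULT) -> np.ndarray:
    return np.arange(t_start, t_stop + step_ms * 1e-9, step_ms)


# ---------------------------------------------------------------------------
# time courses

def decode_timecourse(trials: list[TrialRecord], space: BehaviorSpace,
                      align_event: str, t_start: float, t_stop: float,
                      window_ms: float = WINDOW_MS_DEFAULT,
                      step_ms: float = STEP_MS_DEFAULT,
                      model_kind: str = "poisson", mode: str = "joint",
                      prior_mode: str = "full", n_boot: int = 1000,
                      seed: int = 0,
                      behaviors: tuple[str, ...] = BEHAVIOR_NAMES,
                      ) -> dict[str, NPCTimeCourse]:
    """Run the full decode pipeline at every window, for all three behaviors.

    The bootstrap uses one shared set of trial resamples across time steps so
    epoch statistics can be computed per replicate.
    """
    n_neurons = len(trials[0].spikes)
    times = window_times(t_start, t_stop, step_ms)
    counts, clipped = count_tensor(trials, n_neurons, align_event, times, window_ms)
    labels = combo_labels(trials)
    T = len(trials)

    ss = np.random.SeedSequence(seed)
    boot_seed, *step_seeds = ss.spawn(len(times) + 1)
    boot_idx = (np.random.default_rng(boot_seed).integers(0, T, (n_boot, T))
                if n_boot > 0 else None)

    n_behav = {"presaccade": space.n_presaccade, "direction": space.n_directions,
               "postsaccade": space.n_postsaccade}
    npc = {b: np.empty(len(times)) for b in behaviors}
    sem = {b: np.empty(len(times)) for b in behaviors}
    boot = {b: (np.empty((n_boot, len(times))) if n_boot > 0 else None)
            for b in behaviors}
    for k, t in enumerate(times):
        try:
            res = loo_decode(counts[k], labels, space, model_kind=model_kind,
                             mode=mode, prior_mode=prior_mode, seed=step_seeds[k])
        except Exception as exc:
            raise RuntimeError(f"decoding failed at window ending {t:g} ms "
                               f"({align_event}-aligned): {exc}") from exc
        for b in behaviors:
            correct = res.correct(b).astype(float)
            acc, present = _per_behavior_mean(res.truths[b], correct, n_behav[b])
            npc[b][k] = acc[present].mean()
            if n_boot > 0:
                for j, idx in enumerate(boot_idx):
                    acc_j, pres_j = _per_behavior_mean(res.truths[b][idx],
                                                       correct[idx], n_behav[b])
                    boot[b][j, k] = acc_j[pres_j].mean()
                sem[b][k] = float(np.std(boot[b][:, k], ddof=1))
    return {
        b: NPCTimeCourse(times=times, npc=npc[b],
                         sem=(sem[b] if n_boot > 0 else None), behavior=b,
                         align_event=align_event, window_ms=window_ms,
                         step_ms=step_ms, chance=space.chance_level(b),
                         boot=boot[b], clipped=clipped)
        for b in behaviors
    }


def npc_timecourse(trials, space, behavior: str, align_event: str,
                   t_start: float, t_stop: float, **kwargs) -> NPCTimeCourse:
    """Time course of the NPC for one behavior (see :func:`decode_timecourse`)."""
    return decode_timecourse(trials, space, align_event, t_start, t_stop,
                             behaviors=(behavior,), **kwargs)[behavior]


# ---------------------------------------------------------------------------
# epoch statistics

def epoch_bounds(trials: list[TrialRecord], align_event: str,
                 start_event: str, end_event: str) -> tuple[float, float]:
    """Epoch bounds relative to the alignment event, intersected across trials."""
    starts = [t.event_times[start_event] - t.event_times[align_event] for t in trials]
    ends = [t.event_times[end_event] - t.event_times[align_event] for t in trials]
    lo, hi = max(starts), min(ends)
    if hi <= lo:
        raise ValueError(
            f"epoch ({start_event}, {end_event}) has no common range across trials")
    return lo, hi


def epoch_rms(tc: NPCTimeCourse, epoch: tuple[float, float]) -> tuple[float, float]:
    """Root-mean-square of the time course over an epoch, with bootstrap SEM.

    Equivalent to the area under the (squared) time course normalized by the
    epoch length, so epochs of different durations are comparable.
    """
    lo, hi = epoch
    mask = (tc.times >= lo) & (tc.times <= hi)
    if not mask.any():
        raise ValueError(f"epoch ({lo}, {hi}) contains no time steps")
    rms = float(np.sqrt(np.mean(tc.npc[mask] ** 2)))
    sem = np.nan
    if tc.boot is not None and len(tc.boot) > 1:
        reps = np.sqrt(np.mean(tc.boot[:, mask] ** 2, axis=1))
        sem = float(np.std(reps, ddof=1))
    return rms, sem


# ---------------------------------------------------------------------------
# onset / peak detection

def _gaussian_smooth(y: np.ndarray, step: float, sd_ms: float,
                     halfwidth_ms: float) -> np.ndarray:
    """Truncated-Gaussian smoothing, kernel renormalized at the edges."""
    m = max(1, int(round(halfwidth_ms / step)))
    x = np.arange(-m, m + 1) * step
    k = np.exp(-x ** 2 / (2.0 * sd_ms ** 2))
    num = np.convolve(y, k, mode="same")
    den = np.convolve(np.ones_like(y), k, mode="same")
    return num / den


def _derivative(y: np.ndarray, step: float) -> np.ndarray:
    return np.gradient(y, step)


def _deriv_diff_scores(y: np.ndarray, step: float, span_ms: float):
    """After-minus-before mean-derivative difference at each interior step."""
    d = _derivative(y, step)
    k = max(1, int(round(span_ms / step)))
    n = len(y)
    idx = np.arange(k, n - k)
    if len(idx) == 0:
        return None, None
    csum = np.concatenate([[0.0], np.cumsum(d)])
    after = (csum[idx + 1 + k] - csum[idx + 1]) / k
    before = (csum[idx] - csum[idx - k]) / k
    return idx, after - before


def detect_onset_peak(tc, smooth_sd_ms: float = 50.0,
                      smooth_halfwidth_ms: float = 125.0,
                      deriv_span_ms: float = 100.0,
                      n_null: int = 200, alpha: float = 0.01,
                      seed: int = 0) -> EventMarks:
    """Onset and peak of a time course by the derivative-difference rule.

    The trace is smoothed with a Gaussian kernel (SD 50 ms) truncated to a
    250 ms window; the onset maximizes the mean derivative after minus before
    a step, the peak the reverse.  Significance is assessed against the same
    statistic computed on ``n_null`` smoothed noise traces whose scale is the
    robust (MAD) residual of the observed trace; marks below the (1-alpha)
    null quantile are reported absent.
    """
    if isinstance(tc, NPCTimeCourse):
        times, values = tc.times, tc.npc
    else:
        times, values = tc
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
    step = float(times[1] - times[0])
    if np.ptp(values) == 0:
        return EventMarks(None, None, "flat", "flat")

    smooth = _gaussian_smooth(values, step, smooth_sd_ms, smooth_halfwidth_ms)
    idx, onset_scores = _deriv_diff_scores(smooth, step, deriv_span_ms)
    if idx is None:
        return EventMarks(None, None, "too-short", "too-short")
    peak_scores = -onset_scores

    # noise scale from the smoothing residual, corrected for the variance the
    # linear smoother removes: resid = (I - W) noise, so Var(resid) =
    # sigma^2 (1 - 2 w0 + sum w^2) for interior points of a kernel w
    m = max(1, int(round(smooth_halfwidth_ms / step)))
    w = np.exp(-(np.arange(-m, m + 1) * step) ** 2 / (2.0 * smooth_sd_ms ** 2))
    w = w / w.sum()
    attenuation = np.sqrt(max(1.0 - 2.0 * w.max() + np.sum(w ** 2), 1e-12))
    resid = values - smooth
    sigma = 1.4826 * np.median(np.abs(resid - np.median(resid))) / attenuation
    # guard the sharp max-statistic against sampling noise of the MAD scale:
    # null traces use an upper-confidence noise SD (2 sampling SDs above)
    sigma *= 1.0 + 2.0 * 1.11 / np.sqrt(len(values))
    if sigma > 0:
        rng = np.random.default_rng(seed)
        null_on = np.empty(n_null)
        null_pk = np.empty(n_null)
        for j in range(n_null):
            noise = _gaussian_smooth(rng.normal(0.0, sigma, len(values)), step,
                                     smooth_sd_ms, smooth_halfwidth_ms)
            _, sc = _deriv_diff_scores(noise, step, deriv_span_ms)
            null_on[j] = sc.max()
            null_pk[j] = (-sc).max()
        thr_on = float(np.quantile(null_on, 1.0 - alpha))
        thr_pk = float(np.quantile(null_pk, 1.0 - alpha))
    else:
        thr_on = thr_pk = 0.0

    onset = peak = None
    onset_reason = peak_reason = None
    if onset_scores.max() > thr_on:
        onset = float(times[idx[np.argmax(onset_scores)]])
    else:
        onset_reason = "below-noise-threshold"
    if peak_scores.max() > thr_pk:
        peak = float(times[idx[np.argmax(peak_scores)]])
    else:
        peak_reason = "below-noise-threshold"
    return EventMarks(onset, peak, onset_reason, peak_reason)


# ---------------------------------------------------------------------------
# optional eye-velocity saccade detector (synthetic trials carry ground truth)

def detect_saccade_onset(times_ms: np.ndarray, x_deg: np.ndarray, y_deg: np.ndarray,
                         threshold_deg_s: float = 50.0) -> float | None:
    """First time eye speed crosses a threshold (deg/s); None if it never does."""
    times_ms = np.asarray(times_ms, dtype=float)
    vx = np.gradient(np.asarray(x_deg, dtype=float), times_ms / 1000.0)
    vy = np.gradient(np.asarray(y_deg, dtype=float), times_ms / 1000.0)
    speed = np.hypot(vx, vy)
    above = np.flatnonzero(speed > threshold_deg_s)
    return float(times_ms[above[0]]) if len(above) else None
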