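"""Recursive Neuronal Elimination: greedy importance ranking of neurons.

At each iteration RNE removes the neuron whose removal maximizes the decoding
accuracy of the remaining population, producing a ranking from least to most
important and an accuracy-vs-population-size curve.  The objective averages
the three behaviors' accuracies, each measured as the RMS of per-window NPCs
over the task epoch that best mediates it: the memory epoch for saccade
direction, the fixation epoch for presaccade position, and fixation II for
postsaccade position.

Scoring every candidate removal from scratch would decode the whole dataset
O(N^2) times; instead, per-neuron leave-one-out log-likelihood cubes are
precomputed once per window, so a candidate subset is scored by subtracting
one neuron's slice from the running population log-likelihood.

Once an 'optimized' subset is ranked, its accuracy can be used to correct an
empirical population's NPC for sampling bias, by scaling the empirical time
course so its epoch-average accuracy matches the optimized reference.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .decoder import (_map_rows, _log_prior_matrix, _per_behavior_mean,
                      direction_marginalization_matrix,
                      postsaccade_marginalization_matrix,
                      presaccade_marginalization_matrix)
from .encoding import per_neuron_loo_loglik
from .task import BehaviorSpace, TrialRecord, combo_labels
from .timecourse import WINDOW_MS_DEFAULT, count_tensor, epoch_bounds

#: behavior -> (epoch start event, epoch end event, alignment event)
DEFAULT_OBJECTIVE_EPOCHS: dict[str, tuple[str, str, str]] = {
    "direction": ("target_off", "go_cue", "target_on"),
    "presaccade": ("fixation_acquired", "target_on", "target_on"),
    "postsaccade": ("fixation2_acquired", "trial_end", "saccade_onset"),
}


@dataclass
class RNERanking:
    """Result of recursive elimination.

    ``order`` lists neuron ids from least to most important (elimination
    order, the survivor last); ``accuracy_at_size[k]`` is the objective of
    the best-k subset (the last k entries of ``order``).
    """

    order: list[int]
    accuracy_at_size: dict[int, float]
    objective_spec: dict

    def retained(self, k: int) -> list[int]:
        return self.order[-k:]


def validate_min_trials(trials: list[TrialRecord], space: BehaviorSpace,
                        min_trials: int = 9) -> None:
    """Enforce the pooling filter: every combo needs >= min_trials trials."""
    nb = np.bincount(combo_labels(trials), minlength=space.n_combos)
    bad = np.flatnonzero(nb < min_trials)
    if len(bad):
        raise ValueError(
            f"{len(bad)} behaviors have fewer than {min_trials} trials "
            f"(combo indices {bad.tolist()[:10]}...)")


class _ObjectiveEvaluator:
    """Precomputed per-window cubes; scores neuron subsets by cube subtraction."""

    def __init__(self, trials, space: BehaviorSpace, model_kind: str,
                 window_ms: float, n_windows: int,
                 objective_epochs: dict[str, tuple[str, str, str]],
                 prior_mode: str):
        self.space = space
        labels = combo_labels(trials)
        self.labels = labels
        self.n_neurons = len(trials[0].spikes)
        self.marg = {
            "presaccade": presaccade_marginalization_matrix(space),
            "direction": direction_marginalization_matrix(space),
            "postsaccade": postsaccade_marginalization_matrix(space),
        }
        nd = space.n_directions
        self.truths = {
            "presaccade": labels // nd,
            "direction": labels % nd,
            "postsaccade": space.combo_to_postsaccade()[labels],
        }
        self.n_behav = {"presaccade": space.n_presaccade,
                        "direction": space.n_directions,
                        "postsaccade": space.n_postsaccade}
        self.log_prior = _log_prior_matrix(labels, space.n_combos, prior_mode)
        # one cube (T, 72, N) per (behavior, window)
        self.windows: dict[str, list[np.ndarray]] = {}
        for behavior, (ev0, ev1, align) in objective_epochs.items():
            lo, hi = epoch_bounds(trials, align, ev0, ev1)
            if hi < lo + window_ms:
                raise ValueError(
                    f"epoch ({ev0}, {ev1}) is shorter than the {window_ms} ms window")
            ends = np.linspace(lo + window_ms, hi, n_windows)
            counts, _ = count_tensor(trials, self.n_neurons, align, ends, window_ms)
            self.windows[behavior] = [
                per_neuron_loo_loglik(counts[k], labels, space.n_combos, model_kind)
                for k in range(len(ends))
            ]

    def subset_sums(self, mask: np.ndarray) -> dict[str, list[np.ndarray]]:
        return {b: [cube[:, :, mask].sum(axis=2) for cube in cubes]
                for b, cubes in self.windows.items()}

    def _window_accuracy(self, logpost: np.ndarray, behavior: str,
                         rng: np.random.Generator) -> float:
        probs = np.exp(logpost - logsumexp(logpost, axis=1)[:, None])
        marg = probs @ self.marg[behavior]
        est = _map_rows(marg, rng)
        acc, present = _per_behavior_mean(self.truths[behavior], est == self.truths[behavior],
                                          self.n_behav[behavior])
        return float(acc[present].mean())

    def objective(self, sums: dict[str, list[np.ndarray]],
                  rng: np.random.Generator,
                  minus: dict[str, list[np.ndarray]] | None = None) -> float:
        per_behavior = []
        for behavior, loglist in sums.items():
            accs = []
            for k, L in enumerate(loglist):
                if minus is not None:
                    L = L - minus[behavior][k]
                accs.append(self._window_accuracy(L + self.log_prior, behavior, rng))
            per_behavior.append(np.sqrt(np.mean(np.square(accs))))
        return float(np.mean(per_behavior))


def rne_rank(trials: list[TrialRecord], space: BehaviorSpace,
             model_kind: str = "poisson", window_ms: float = WINDOW_MS_DEFAULT,
             n_windows: int = 3,
             objective_epochs: dict[str, tuple[str, str, str]] | None = None,
             prior_mode: str = "full", seed: int = 0, batch: int = 1,
             min_trials: int | None = None) -> RNERanking:
    """Rank neurons from least to most important by greedy elimination.

    One neuron is removed per iteration by default; ``batch > 1`` removes the
    k neurons with the highest single-removal scores jointly.  Objective ties
    are broken toward the lower neuron id, so the ranking is deterministic
    given the dataset and seed.
    """
    if min_trials is not None:
        validate_min_trials(trials, space, min_trials)
    objective_epochs = objective_epochs or DEFAULT_OBJECTIVE_EPOCHS
    ev = _ObjectiveEvaluator(trials, space, model_kind, window_ms, n_windows,
                             objective_epochs, prior_mode)
    N = ev.n_neurons
    spec = {"epochs": objective_epochs, "window_ms": window_ms,
            "n_windows": n_windows, "model_kind": model_kind,
            "prior_mode": prior_mode, "batch": batch}
    rng = np.random.default_rng(seed)

    remaining = list(range(N))
    mask = np.ones(N, dtype=bool)
    sums = ev.subset_sums(mask)
    accuracy_at_size = {N: ev.objective(sums, rng)}
    order: list[int] = []
    if N == 1:
        accuracy_at_size[1] = accuracy_at_size[N]
        return RNERanking([0], accuracy_at_size, spec)

    while len(remaining) > 1:
        scores = []
        for nid in remaining:
            minus = {b: [cube[:, :, nid] for cube in ev.windows[b]]
                     for b in ev.windows}
            scores.append(ev.objective(sums, rng, minus=minus))
        scores = np.asarray(scores)
        k = min(batch, len(remaining) - 1)
        # highest remaining-population objective first; ties -> lower id
        drop_pos = sorted(range(len(remaining)),
                          key=lambda i: (-scores[i], remaining[i]))[:k]
        for i in sorted(drop_pos, key=lambda i: remaining[i]):
            order.append(remaining[i])
        dropped = [remaining[i] for i in drop_pos]
        for nid in dropped:
            for b in sums:
                for kw, cube in enumerate(ev.windows[b]):
                    sums[b][kw] = sums[b][kw] - cube[:, :, nid]
        remaining = [nid for nid in remaining if nid not in dropped]
        accuracy_at_size[len(remaining)] = (
            float(scores[drop_pos[0]]) if k == 1 else ev.objective(sums, rng))
        # fill intermediate sizes when batching
        for size in range(len(remaining) + 1, len(remaining) + k):
            accuracy_at_size.setdefault(size, accuracy_at_size[len(remaining)])
    order.append(remaining[0])
    return RNERanking(order, accuracy_at_size, spec)


def accuracy_vs_size(ranking: RNERanking) -> tuple[np.ndarray, np.ndarray]:
    """Objective accuracy as a function of retained population size (1..N)."""
    sizes = np.array(sorted(ranking.accuracy_at_size), dtype=int)
    return sizes, np.array([ranking.accuracy_at_size[s] for s in sizes])


def bias_correct(tc, optimized_value: float,
                 epoch: tuple[float, float] | None = None,
                 chance: float | None = None):
    """Scale an empirical NPC time course to match an optimized subset's accuracy.

    The factor is optimized / empirical epoch-RMS (whole-trace RMS when no
    epoch is given); scaled accuracies are clipped to [chance, 1].  Returns
    the corrected time course and the scaling factor.
    """
    from .timecourse import NPCTimeCourse, epoch_rms  # local to avoid cycle

    if not optimized_value > 0:
        raise ValueError("optimized reference accuracy must be > 0")
    if epoch is None:
        empirical = float(np.sqrt(np.mean(tc.npc ** 2)))
    else:
        empirical, _ = epoch_rms(tc, epoch)
    if empirical == 0:
        raise ValueError("empirical accuracy is zero; scaling undefined")
    factor = optimized_value / empirical
    lo = chance if chance is not None else (tc.chance if np.isfinite(tc.chance) else 0.0)
    scaled = np.clip(tc.npc * factor, lo, 1.0)
    out = dataclasses.replace(
        tc, npc=scaled,
        sem=(tc.sem * factor if tc.sem is not None else None),
        boot=(np.clip(tc.boot * factor, lo, 1.0) if tc.boot is not None else None))
    return out, factor
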