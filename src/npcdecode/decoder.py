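"""Bayesian MAP decoding of oculomotor behaviors from population spike counts.

The posterior p(b|r) ∝ p(r|b) p(b) is evaluated under leave-one-out
cross-validation: each trial is decoded with tuning parameters fit on all
other trials.  Presaccade position and saccade direction can be decoded from
a single joint posterior over the 72 (position, direction) combos (default)
or from separately fit per-variable models; the postsaccade eye position is
always obtained by marginalization — summing posterior mass over all
(position, direction) pairs whose vector sum lands on the same node.

Decoding accuracy (the neuronal population code, NPC) is the unweighted mean
over behaviors of the per-behavior fraction of veridical MAP estimates, with
a bootstrap standard error across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .encoding import TuningModel, loo_loglik_matrix, population_loglik
from .task import BEHAVIOR_NAMES, BehaviorSpace

_TIE_RTOL = 1e-12


@dataclass
class PriorDistribution:
    """p(b) over a discrete behavior set, from occurrence counts."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("prior must be non-negative and sum to 1")


@dataclass
class PosteriorDistribution:
    """p(b|r) over a behavior set for one decoded response, plus log p(r)."""

    probs: np.ndarray
    log_evidence: float = np.nan

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("posterior must be non-negative and sum to 1")


@dataclass
class NPCResult:
    """Accuracy of the neuronal population code for one behavior variable."""

    per_behavior_accuracy: np.ndarray  # NaN where the behavior has no trials
    npc: float
    sem: float
    n_boot: int


def compute_prior(labels, n_behaviors: int | None = None) -> PriorDistribution:
    """Prior from occurrence counts; behaviors absent from the labels get 0."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("cannot compute a prior from zero trials")
    n_behaviors = n_behaviors or int(labels.max()) + 1
    counts = np.bincount(labels, minlength=n_behaviors)
    return PriorDistribution(counts / counts.sum())


def posterior(r_vec, model: TuningModel, prior: PriorDistribution) -> PosteriorDistribution:
    """Single-response Bayes inversion over the model's behavior set."""
    if len(prior.probs) != model.n_behaviors:
        raise ValueError("model and prior must cover the same behavior set")
    if not prior.probs.sum() > 0:
        raise ValueError("prior has no mass on the behavior set")
    with np.errstate(divide="ignore"):
        log_post = np.array([
            population_loglik(r_vec, model, b) + np.log(prior.probs[b])
            if prior.probs[b] > 0 else -np.inf
            for b in range(model.n_behaviors)
        ])
    log_ev = logsumexp(log_post)
    return PosteriorDistribution(np.exp(log_post - log_ev), float(log_ev))


def map_estimate(post, rng=None) -> int:
    """Argmax behavior; exact ties broken uniformly from the seeded stream."""
    probs = post.probs if isinstance(post, PosteriorDistribution) else np.asarray(post)
    mx = probs.max()
    ties = np.flatnonzero(probs >= mx * (1.0 - _TIE_RTOL))
    if len(ties) == 1:
        return int(ties[0])
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return int(rng.choice(ties))


# ---------------------------------------------------------------------------
# marginalization

def presaccade_marginalization_matrix(space: BehaviorSpace) -> np.ndarray:
    m = np.zeros((space.n_combos, space.n_presaccade))
    m[np.arange(space.n_combos), space.combos[:, 0]] = 1.0
    return m


def direction_marginalization_matrix(space: BehaviorSpace) -> np.ndarray:
    m = np.zeros((space.n_combos, space.n_directions))
    m[np.arange(space.n_combos), space.combos[:, 1]] = 1.0
    return m


def postsaccade_marginalization_matrix(space: BehaviorSpace) -> np.ndarray:
    m = np.zeros((space.n_combos, space.n_postsaccade))
    m[np.arange(space.n_combos), space.combo_to_postsaccade()] = 1.0
    return m


def marginalize_postsaccade(joint_post, space: BehaviorSpace):
    """Sum combo-posterior mass over all (pre, dir) pairs composing to each node.

    Total probability mass is conserved exactly (each combo maps to exactly
    one postsaccade position).
    """
    probs = (joint_post.probs if isinstance(joint_post, PosteriorDistribution)
             else np.asarray(joint_post, dtype=float))
    if probs.shape[-1] != space.n_combos:
        raise ValueError(
            f"joint posterior must cover the {space.n_combos} combos, got {probs.shape[-1]}")
    out = probs @ postsaccade_marginalization_matrix(space)
    if isinstance(joint_post, PosteriorDistribution):
        return PosteriorDistribution(out, joint_post.log_evidence)
    return out


# ---------------------------------------------------------------------------
# leave-one-out decoding

def _log_prior_matrix(labels: np.ndarray, n_behaviors: int, mode: str) -> np.ndarray:
    """(T, B) log prior per decoded trial; under ``loo`` the trial's own label
    count is reduced by one (prior refit on the training fold)."""
    T = len(labels)
    nb = np.bincount(labels, minlength=n_behaviors).astype(float)
    with np.errstate(divide="ignore"):
        if mode == "full":
            lp = np.log(nb) - np.log(T)
            return np.broadcast_to(lp, (T, n_behaviors)).copy()
        if mode == "loo":
            lp = np.log(nb) - np.log(T - 1)
            out = np.broadcast_to(lp, (T, n_behaviors)).copy()
            out[np.arange(T), labels] = np.log(nb[labels] - 1.0) - np.log(T - 1)
            return out
    raise ValueError(f"unknown prior mode {mode!r}")


def _softmax_rows(logp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    log_ev = logsumexp(logp, axis=1)
    return np.exp(logp - log_ev[:, None]), log_ev


def _map_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    est = np.argmax(probs, axis=1)
    mx = probs[np.arange(len(probs)), est]
    n_top = (probs >= mx[:, None] * (1.0 - _TIE_RTOL)).sum(axis=1)
    for t in np.flatnonzero(n_top > 1):
        est[t] = rng.choice(np.flatnonzero(probs[t] >= mx[t] * (1.0 - _TIE_RTOL)))
    return est


def loo_posteriors(counts, labels, n_behaviors: int, model_kind: str = "poisson",
                   prior_mode: str = "full") -> tuple[np.ndarray, np.ndarray]:
    """Per-trial LOO posteriors (T, B) and log evidences over one behavior set."""
    labels = np.asarray(labels, dtype=int)
    L = loo_loglik_matrix(counts, labels, n_behaviors, kind=model_kind)
    return _softmax_rows(L + _log_prior_matrix(labels, n_behaviors, prior_mode))


@dataclass
class DecodeResult:
    """Per-trial MAP estimates, truths and marginal posteriors for the three behaviors."""

    estimates: dict[str, np.ndarray]
    truths: dict[str, np.ndarray]
    posteriors: dict[str, np.ndarray]
    joint_posteriors: np.ndarray | None
    mode: str
    model_kind: str

    def correct(self, behavior: str) -> np.ndarray:
        return self.estimates[behavior] == self.truths[behavior]

    def posterior_of_truth(self, behavior: str) -> np.ndarray:
        """Posterior probability each trial assigned to its true behavior."""
        p = self.posteriors[behavior]
        return p[np.arange(len(p)), self.truths[behavior]]


def loo_decode(counts, combo_labels, space: BehaviorSpace,
               model_kind: str = "poisson", mode: str = "joint",
               prior_mode: str = "full", seed: int = 0) -> DecodeResult:
    """Decode presaccade position, direction and postsaccade position per trial.

    ``joint`` fits tuning over the 72 combos and reads each variable from the
    corresponding marginal of the joint posterior (the postsaccade posterior
    is the sum over combos with the same vector sum).  ``marginal`` fits and
    decodes position (9-way) and direction (8-way) separately, forming the
    postsaccade posterior from the product of the two marginals.
    """
    combo_labels = np.asarray(combo_labels, dtype=int)
    nd = space.n_directions
    truths = {
        "presaccade": combo_labels // nd,
        "direction": combo_labels % nd,
        "postsaccade": space.combo_to_postsaccade()[combo_labels],
    }
    rng = np.random.default_rng(seed)
    if mode == "joint":
        joint, _ = loo_posteriors(counts, combo_labels, space.n_combos,
                                  model_kind, prior_mode)
        posts = {
            "presaccade": joint @ presaccade_marginalization_matrix(space),
            "direction": joint @ direction_marginalization_matrix(space),
            "postsaccade": joint @ postsaccade_marginalization_matrix(space),
        }
    elif mode == "marginal":
        pre, _ = loo_posteriors(counts, truths["presaccade"], space.n_presaccade,
                                model_kind, prior_mode)
        direc, _ = loo_posteriors(counts, truths["direction"], space.n_directions,
                                  model_kind, prior_mode)
        joint = None
        # pre and dir are independent by task design; their product plays the
        # role of the joint posterior in the postsaccade marginalization
        outer = pre[:, :, None] * direc[:, None, :]
        posts = {
            "presaccade": pre,
            "direction": direc,
            "postsaccade": outer.reshape(len(pre), -1)
            @ postsaccade_marginalization_matrix(space),
        }
    else:
        raise ValueError(f"unknown decode mode {mode!r}")
    estimates = {b: _map_rows(posts[b], rng) for b in BEHAVIOR_NAMES}
    return DecodeResult(estimates=estimates, truths=truths, posteriors=posts,
                        joint_posteriors=joint, mode=mode, model_kind=model_kind)


# ---------------------------------------------------------------------------
# NPC accuracy with bootstrap uncertainty

def _per_behavior_mean(truth, correct, n_behaviors):
    nb = np.bincount(truth, minlength=n_behaviors).astype(float)
    hits = np.bincount(truth, weights=correct, minlength=n_behaviors)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = hits / nb
    return acc, nb > 0


def npc_accuracy(estimates, truths, n_behaviors: int, n_boot: int = 1000,
                 seed: int = 0, boot_indices: np.ndarray | None = None,
                 stratified: bool = False) -> NPCResult:
    """Unweighted mean per-behavior fraction correct, with bootstrap SEM.

    The bootstrap resamples trials with replacement (uniformly by default, or
    within behavior if ``stratified``); behaviors absent from a resample are
    dropped from that resample's mean.
    """
    estimates = np.asarray(estimates, dtype=int)
    truths = np.asarray(truths, dtype=int)
    if estimates.size == 0 or estimates.shape != truths.shape:
        raise ValueError("estimates and truths must be equal-length and non-empty")
    T = len(truths)
    correct = (estimates == truths).astype(float)
    acc, present = _per_behavior_mean(truths, correct, n_behaviors)
    npc = float(acc[present].mean())

    if n_boot <= 0:
        return NPCResult(np.where(present, acc, np.nan), npc, np.nan, 0)
    if boot_indices is None:
        rng = np.random.default_rng(seed)
        if stratified:
            boot_indices = np.empty((n_boot, T), dtype=int)
            for b in np.flatnonzero(present):
                idx = np.flatnonzero(truths == b)
                boot_indices[:, idx] = idx[rng.integers(0, len(idx), (n_boot, len(idx)))]
        else:
            boot_indices = rng.integers(0, T, (n_boot, T))
    reps = np.empty(len(boot_indices))
    for j, idx in enumerate(boot_indices):
        acc_j, pres_j = _per_behavior_mean(truths[idx], correct[idx], n_behaviors)
        reps[j] = acc_j[pres_j].mean()
    sem = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
    return NPCResult(np.where(present, acc, np.nan), npc, sem, int(len(boot_indices)))
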