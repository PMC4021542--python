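"""Tuning-curve estimation and spike-count likelihood models.

The population response is the vector of per-neuron spike counts in a
counting window.  Two single-neuron likelihood families are supported:

* ``poisson`` — p(r|b) = mu(b)^r / r! * exp(-mu(b)), one parameter per
  (neuron, behavior): the mean count mu(b) (the tuning curve).
* ``truncgauss`` — a Gaussian in r with mean mu(b) and variance sigma(b)^2,
  renormalized by its continuous integral over [0, inf), evaluated at the
  integer counts; two parameters per (neuron, behavior).

Neurons are treated as independent, so the population log-likelihood is the
sum of per-neuron log-likelihoods.  All likelihood math is done in log space;
before evaluation, means are floored at ``MU_FLOOR`` and variances at
``VAR_FLOOR`` so behaviors whose training counts are all zero never produce
a degenerate zero-probability likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, log_ndtr

#: epsilon floors applied to fitted parameters before likelihood evaluation
MU_FLOOR = 0.05
VAR_FLOOR = 0.25

MODEL_KINDS = ("poisson", "truncgauss")


class UnfittableBehaviorError(ValueError):
    """A behavior lacks the training trials needed to fit its tuning."""

    def __init__(self, behaviors, needed):
        self.behaviors = [int(b) for b in behaviors]
        super().__init__(
            f"behaviors {self.behaviors} have fewer than {needed} training trials")


@dataclass
class TuningModel:
    """Per-neuron, per-behavior likelihood parameters.

    ``mu``/``sigma2`` are (n_neurons, n_behaviors); ``sigma2`` is None for the
    Poisson model.  ``window`` records the counting window the counts came
    from, purely as provenance.
    """

    mu: np.ndarray
    sigma2: np.ndarray | None
    kind: str
    behavior_set: str = "combo"
    window: tuple[float, float] | None = None

    @property
    def n_neurons(self) -> int:
        return self.mu.shape[0]

    @property
    def n_behaviors(self) -> int:
        return self.mu.shape[1]

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if not np.all(np.isfinite(self.mu)) or (self.mu < 0).any():
            raise ValueError("mu must be finite and >= 0")
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "truncgauss":
            if self.sigma2 is None:
                raise ValueError("truncgauss model requires sigma2")
            self.sigma2 = np.asarray(self.sigma2, dtype=float)
            if self.sigma2.shape != self.mu.shape or (self.sigma2 < 0).any():
                raise ValueError("sigma2 must match mu's shape and be >= 0")


def fit_tuning(counts: np.ndarray, labels: np.ndarray, n_behaviors: int,
               model: str = "poisson", behavior_set: str = "combo",
               window: tuple[float, float] | None = None) -> TuningModel:
    """Fit mean (and, for truncgauss, unbiased variance) counts per behavior.

    ``counts`` is (n_trials, n_neurons); ``labels`` gives each trial's
    behavior index in [0, n_behaviors).
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if counts.ndim != 2 or len(labels) != counts.shape[0]:
        raise ValueError("counts must be (n_trials, n_neurons) aligned with labels")
    if model not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model!r}")
    nb = np.bincount(labels, minlength=n_behaviors)
    needed = 2 if model == "truncgauss" else 1
    bad = np.flatnonzero(nb < needed)
    if len(bad):
        raise UnfittableBehaviorError(bad, needed)

    sums = np.zeros((n_behaviors, counts.shape[1]))
    np.add.at(sums, labels, counts)
    mu = (sums / nb[:, None]).T  # (N, B)
    sigma2 = None
    if model == "truncgauss":
        sq = np.zeros_like(sums)
        np.add.at(sq, labels, counts ** 2)
        var = (sq - nb[:, None] * (sums / nb[:, None]) ** 2) / (nb[:, None] - 1)
        sigma2 = np.clip(var, 0.0, None).T
    return TuningModel(mu=mu, sigma2=sigma2, kind=model,
                       behavior_set=behavior_set, window=window)


def write_count_matrix(counts: np.ndarray, labels: np.ndarray, path, labels_path,
                       meta: dict | None = None) -> None:
    """Write a trial x neuron count matrix and its parallel label column."""
    import pandas as pd

    from .io import write_table

    counts = np.asarray(counts)
    df = pd.DataFrame(counts, columns=[f"neuron_{i}" for i in range(counts.shape[1])])
    df.insert(0, "trial_id", np.arange(counts.shape[0]))
    write_table(df, path, meta=meta, float_format="%g")
    write_table(pd.DataFrame({"trial_id": np.arange(len(labels)),
                              "behavior": np.asarray(labels, dtype=int)}),
                labels_path, meta=meta)


def read_count_matrix(path, labels_path) -> tuple[np.ndarray, np.ndarray]:
    from .io import read_table

    df = read_table(path)
    lab = read_table(labels_path)
    neuron_cols = [c for c in df.columns if c.startswith("neuron_")]
    if not neuron_cols:
        raise ValueError(f"{path}: no neuron_* columns found")
    if "behavior" not in lab.columns or len(lab) != len(df):
        raise ValueError(f"{labels_path}: needs a 'behavior' column aligned with {path}")
    return df[neuron_cols].to_numpy(), lab["behavior"].to_numpy(dtype=int)


# ---------------------------------------------------------------------------
# single-value likelihoods (reference forms; the decoder uses the matrix forms)

def _check_counts(r) -> np.ndarray:
    r = np.asarray(r)
    if not np.issubdtype(r.dtype, np.number) or np.any(r < 0) or np.any(r != np.floor(r)):
        raise ValueError("spike counts must be non-negative integers")
    return r.astype(float)


def poisson_likelihood(r, mu):
    """Poisson pmf mu^r/r! exp(-mu); at mu=0 a point mass at r=0 (0^0 = 1)."""
    r = _check_counts(r)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = r * np.log(mu) - mu - gammaln(r + 1)
    logp = np.where((mu == 0) & (r == 0), 0.0, logp)
    logp = np.where((mu == 0) & (r > 0), -np.inf, logp)
    return np.exp(logp) if logp.shape else float(np.exp(logp))


def truncgauss_likelihood(r, mu, sigma2):
    """Gaussian density in r renormalized over [0, inf), evaluated at integer r.

    The normalizer is the continuous upper-tail integral, Phi(mu/sigma) in
    closed form.
    """
    r = _check_counts(r)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be > 0")
    sd = np.sqrt(sigma2)
    logp = (-0.5 * np.log(2 * np.pi * sigma2) - (r - mu) ** 2 / (2 * sigma2)
            - log_ndtr(mu / sd))
    return np.exp(logp) if logp.shape else float(np.exp(logp))


def population_loglik(r_vec, model: TuningModel, b: int) -> float:
    """Log p(r|b) = sum_i log p(r_i|b) with the epsilon floors applied."""
    r = _check_counts(r_vec)
    if r.shape != (model.n_neurons,):
        raise ValueError(
            f"expected a count per neuron ({model.n_neurons}), got shape {r.shape}")
    mu = np.maximum(model.mu[:, b], MU_FLOOR)
    if model.kind == "poisson":
        return float(np.sum(r * np.log(mu) - mu - gammaln(r + 1)))
    var = np.maximum(model.sigma2[:, b], VAR_FLOOR)
    sd = np.sqrt(var)
    return float(np.sum(-0.5 * np.log(2 * np.pi * var) - (r - mu) ** 2 / (2 * var)
                        - log_ndtr(mu / sd)))


# ---------------------------------------------------------------------------
# vectorized leave-one-out machinery (used by the decoder and RNE)

@dataclass
class LooStats:
    """Sufficient statistics for tuning fits and their leave-one-out variants.

    ``mu_full``/``var_full`` are (B, N) fits on all trials; ``mu_loo``/
    ``var_loo`` are (T, N): the fit of each trial's own behavior with that
    trial held out (other behaviors' fits are unaffected by the held-out
    trial).  Floors are applied at likelihood evaluation, not here.
    """

    n_per_behavior: np.ndarray
    mu_full: np.ndarray
    mu_loo: np.ndarray
    var_full: np.ndarray | None
    var_loo: np.ndarray | None


def loo_stats(counts: np.ndarray, labels: np.ndarray, n_behaviors: int,
              need_var: bool = False) -> LooStats:
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    nb = np.bincount(labels, minlength=n_behaviors).astype(float)
    bad = np.flatnonzero(nb < 2)
    if len(bad):
        raise UnfittableBehaviorError(bad, 2)
    sums = np.zeros((n_behaviors, counts.shape[1]))
    np.add.at(sums, labels, counts)
    mu_full = sums / nb[:, None]
    n_own = nb[labels][:, None]
    mu_loo = (sums[labels] - counts) / (n_own - 1)
    var_full = var_loo = None
    if need_var:
        sq = np.zeros_like(sums)
        np.add.at(sq, labels, counts ** 2)
        var_full = np.clip((sq - nb[:, None] * mu_full ** 2) / np.maximum(nb[:, None] - 1, 1),
                           0.0, None)
        n1 = n_own - 1
        var_loo = (sq[labels] - counts ** 2 - n1 * mu_loo ** 2) / np.maximum(n1 - 1, 1)
        var_loo = np.where(n1 >= 2, np.clip(var_loo, 0.0, None), 0.0)
    return LooStats(nb, mu_full, mu_loo, var_full, var_loo)


def _poisson_terms(mu):
    """Matrix-form Poisson pieces: per-behavior log mu and constant."""
    return np.log(mu), -mu.sum(axis=1)


def loo_loglik_matrix(counts: np.ndarray, labels: np.ndarray, n_behaviors: int,
                      kind: str = "poisson") -> np.ndarray:
    """(T, B) population log-likelihoods with each trial's own column refit LOO."""
    counts = np.asarray(counts, dtype=float)
    T = counts.shape[0]
    stats = loo_stats(counts, labels, n_behaviors, need_var=(kind == "truncgauss"))
    if kind == "poisson":
        mu = np.maximum(stats.mu_full, MU_FLOOR)          # (B, N)
        lgc = gammaln(counts + 1).sum(axis=1)             # (T,)
        L = counts @ np.log(mu).T + (-mu.sum(axis=1))[None, :] - lgc[:, None]
        mu_o = np.maximum(stats.mu_loo, MU_FLOOR)         # (T, N)
        L_own = (counts * np.log(mu_o)).sum(axis=1) - mu_o.sum(axis=1) - lgc
    elif kind == "truncgauss":
        mu = np.maximum(stats.mu_full, MU_FLOOR)
        var = np.maximum(stats.var_full, VAR_FLOOR)
        a = 1.0 / (2.0 * var)                             # (B, N)
        const = (-(mu ** 2) * a - 0.5 * np.log(2 * np.pi * var)
                 - log_ndtr(mu / np.sqrt(var))).sum(axis=1)
        L = -(counts ** 2) @ a.T + counts @ (2.0 * mu * a).T + const[None, :]
        mu_o = np.maximum(stats.mu_loo, MU_FLOOR)
        var_o = np.maximum(stats.var_loo, VAR_FLOOR)
        L_own = np.sum(-0.5 * np.log(2 * np.pi * var_o)
                       - (counts - mu_o) ** 2 / (2.0 * var_o)
                       - log_ndtr(mu_o / np.sqrt(var_o)), axis=1)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    L[np.arange(T), np.asarray(labels, dtype=int)] = L_own
    return L


def per_neuron_loo_loglik(counts: np.ndarray, labels: np.ndarray, n_behaviors: int,
                          kind: str = "poisson") -> np.ndarray:
    """(T, B, N) per-neuron LOO log-likelihood cube; summing over N gives the
    population log-likelihood.  Used by recursive elimination, where subsets
    of neurons must be re-scored cheaply."""
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    T, N = counts.shape
    stats = loo_stats(counts, labels, n_behaviors, need_var=(kind == "truncgauss"))
    r = counts[:, None, :]                                 # (T, 1, N)
    if kind == "poisson":
        mu = np.maximum(stats.mu_full, MU_FLOOR)[None, :, :]   # (1, B, N)
        cube = r * np.log(mu) - mu - gammaln(r + 1)
        mu_o = np.maximum(stats.mu_loo, MU_FLOOR)
        own = counts * np.log(mu_o) - mu_o - gammaln(counts + 1)
    elif kind == "truncgauss":
        mu = np.maximum(stats.mu_full, MU_FLOOR)[None, :, :]
        var = np.maximum(stats.var_full, VAR_FLOOR)[None, :, :]
        cube = (-0.5 * np.log(2 * np.pi * var) - (r - mu) ** 2 / (2 * var)
                - log_ndtr(mu / np.sqrt(var)))
        mu_o = np.maximum(stats.mu_loo, MU_FLOOR)
        var_o = np.maximum(stats.var_loo, VAR_FLOOR)
        own = (-0.5 * np.log(2 * np.pi * var_o)
               - (counts - mu_o) ** 2 / (2 * var_o)
               - log_ndtr(mu_o / np.sqrt(var_o)))
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    cube[np.arange(T), labels, :] = own
    return cube
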