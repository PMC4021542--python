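"""Priors, posteriors, MAP decoding, marginalization and NPC accuracy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import npcdecode as npc
from npcdecode.decoder import loo_posteriors
from npcdecode.encoding import TuningModel
from npcdecode.task import combo_labels

from conftest import memory_counts


def test_prior_from_occurrence_counts():
    p = npc.compute_prior([0, 0, 0, 1], 3)
    assert p.probs.tolist() == [0.75, 0.25, 0.0]
    with pytest.raises(ValueError):
        npc.compute_prior([], 3)


def test_balanced_session_prior_is_uniform(space, session3):
    p = npc.compute_prior(combo_labels(session3), space.n_combos)
    assert np.allclose(p.probs, 1 / 72)


def test_posterior_uniform_under_equal_likelihoods():
    model = TuningModel(mu=np.full((2, 4), 3.0), sigma2=None, kind="poisson")
    prior = npc.compute_prior([0, 1, 2, 3], 4)
    post = npc.posterior(np.array([2, 5]), model, prior)
    assert np.allclose(post.probs, 0.25)
    assert post.probs.sum() == pytest.approx(1.0, abs=1e-12)


def test_posterior_hand_computed_two_behavior_case():
    """1 neuron, mu=(1,2), uniform prior, r=2: p(b2) = 2e^-2/(e^-1/2 + 2e^-2)."""
    model = TuningModel(mu=np.array([[1.0, 2.0]]), sigma2=None, kind="poisson")
    prior = npc.compute_prior([0, 1], 2)
    post = npc.posterior(np.array([2]), model, prior)
    expected = 2 * math.exp(-2) / (0.5 * math.exp(-1) + 2 * math.exp(-2))
    assert post.probs[1] == pytest.approx(expected, rel=1e-10)
    assert post.probs[1] == pytest.approx(0.5953903248, abs=1e-8)


def test_map_estimate_and_tie_breaking():
    assert npc.map_estimate(np.array([0.7, 0.2, 0.1]), rng=0) == 0
    picks = [npc.map_estimate(np.array([0.5, 0.5]), rng=s) for s in range(400)]
    frac = np.mean(picks)
    assert 0.4 < frac < 0.6


def test_uniform_posterior_decodes_at_chance_against_random_truth():
    rng = np.random.default_rng(2)
    truth = rng.integers(0, 8, 3000)
    est = np.array([npc.map_estimate(np.full(8, 1 / 8), rng=rng) for _ in truth])
    assert np.mean(est == truth) == pytest.approx(1 / 8, abs=0.03)


def test_postsaccade_marginalization_uniform_joint(space):
    post = npc.marginalize_postsaccade(np.full(72, 1 / 72), space)
    coords = space.postsaccade_positions
    center = int(np.flatnonzero((coords == 0).all(axis=1))[0])
    assert post[center] == pytest.approx(1 / 9, abs=1e-15)
    corners = np.flatnonzero((np.abs(coords) == 16).all(axis=1))
    assert np.allclose(post[corners], 1 / 72)
    assert post.sum() == pytest.approx(1.0, abs=1e-12)


def test_marginalization_point_mass_and_conservation(space):
    joint = np.zeros(72)
    joint[17] = 1.0
    post = npc.marginalize_postsaccade(joint, space)
    q = space.combo_to_postsaccade()[17]
    assert post[q] == 1.0 and post.sum() == 1.0
    rng = np.random.default_rng(0)
    for _ in range(20):
        j = rng.dirichlet(np.ones(72))
        m = npc.marginalize_postsaccade(j, space)
        assert abs(m.sum() - j.sum()) < 1e-12
        assert (m >= 0).all()
    with pytest.raises(ValueError):
        npc.marginalize_postsaccade(np.ones(10) / 10, space)


def brute_force_posterior(r, mu, prior):
    """Direct high-precision Bayes: products of pmfs, no log-space tricks."""
    weights = []
    for b in range(mu.shape[1]):
        p = prior[b]
        for i in range(mu.shape[0]):
            p *= (mu[i, b] ** r[i] / math.factorial(int(r[i]))
                  * math.exp(-mu[i, b]))
        weights.append(p)
    total = sum(weights)
    return np.array([w / total for w in weights])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.data())
def test_posterior_matches_brute_force_bayes(data):
    n = data.draw(st.integers(1, 3))
    b = data.draw(st.integers(2, 4))
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    mu = rng.uniform(0.1, 5.0, size=(n, b))
    r = rng.integers(0, 6, size=n)
    prior_counts = rng.integers(1, 5, size=b)
    prior = prior_counts / prior_counts.sum()
    model = TuningModel(mu=mu, sigma2=None, kind="poisson")
    post = npc.posterior(r, model, npc.PriorDistribution(prior))
    expected = brute_force_posterior(r, mu, prior)
    assert np.max(np.abs(post.probs - expected)) < 1e-10


@pytest.mark.parametrize("prior_mode", ["full", "loo"])
def test_loo_posteriors_match_hand_unrolled_cross_validation(prior_mode):
    """Each trial decoded with means (and prior, in loo mode) refit without it."""
    counts = np.array([[1.0], [2.0], [5.0], [6.0], [4.0]])
    labels = np.array([0, 0, 1, 1, 1])
    probs, _ = loo_posteriors(counts, labels, 2, "poisson", prior_mode)
    T = len(labels)
    for t in range(T):
        train = np.delete(np.arange(T), t)
        mus = [max(counts[train][labels[train] == b].mean(), 0.05) for b in (0, 1)]
        if prior_mode == "loo":
            pri = [np.sum(labels[train] == b) / (T - 1) for b in (0, 1)]
        else:
            pri = [np.sum(labels == b) / T for b in (0, 1)]
        w = [mus[b] ** counts[t, 0] / math.factorial(int(counts[t, 0]))
             * math.exp(-mus[b]) * pri[b] for b in (0, 1)]
        expected = np.array(w) / sum(w)
        assert np.allclose(probs[t], expected, atol=1e-12)


def test_posterior_rows_normalize(space, tuned_trials):
    counts = memory_counts(tuned_trials, 20)
    res = npc.loo_decode(counts, combo_labels(tuned_trials), space, seed=1)
    assert np.allclose(res.joint_posteriors.sum(axis=1), 1.0, atol=1e-9)
    for b in ("presaccade", "direction", "postsaccade"):
        assert np.allclose(res.posteriors[b].sum(axis=1), 1.0, atol=1e-9)


def test_noiseless_separable_counts_decode_perfectly(space):
    """Counts exactly equal to well-separated means give 100% on all behaviors.

    Seventeen label-line neurons: neuron p fires 40 when the presaccade
    position is p (else 2), neuron 9+d fires 40 for direction d, so every
    combo has a unique, strongly separated mean vector.
    """
    labels = np.tile(np.arange(72), 2)
    mu = np.full((17, 72), 2.0)
    for c in range(72):
        mu[c // 8, c] = 40.0
        mu[9 + c % 8, c] = 40.0
    counts = mu[:, labels].T
    res = npc.loo_decode(counts, labels, space, seed=0)
    for b in ("presaccade", "direction", "postsaccade"):
        assert (res.estimates[b] == res.truths[b]).all()


def test_adding_an_informative_neuron_never_hurts_noiseless_accuracy(space):
    labels = np.tile(np.arange(72), 2)
    rng = np.random.default_rng(3)
    mu1 = rng.uniform(1, 3, 72).round(1)   # weakly separated, many near-ties
    mu2 = np.arange(72, dtype=float) + 1   # strictly different across behaviors
    c1 = mu1[labels][:, None]
    c2 = np.column_stack([c1, mu2[labels]])
    acc1 = np.mean(npc.loo_decode(c1, labels, space, seed=5).correct("direction"))
    acc2 = np.mean(npc.loo_decode(c2, labels, space, seed=5).correct("direction"))
    assert acc2 >= acc1


def test_marginal_mode_decodes_each_variable(space, tuned_trials):
    counts = memory_counts(tuned_trials, 20)
    res = npc.loo_decode(counts, combo_labels(tuned_trials), space,
                         mode="marginal", seed=1)
    assert res.joint_posteriors is None
    assert res.posteriors["direction"].shape == (len(counts), 8)
    assert np.mean(res.correct("direction")) > 0.8
    assert np.allclose(res.posteriors["postsaccade"].sum(axis=1), 1.0, atol=1e-9)


def test_npc_accuracy_closed_forms():
    r = npc.npc_accuracy([1, 1, 0], [1, 1, 0], 2, n_boot=100, seed=0)
    assert r.npc == 1.0 and r.sem == 0.0
    # behavior 0 decoded perfectly, behavior 1 half right: unweighted mean 0.75
    est = np.array([0, 0, 1, 0])
    tru = np.array([0, 0, 1, 1])
    r = npc.npc_accuracy(est, tru, 2, n_boot=0)
    assert r.per_behavior_accuracy.tolist() == [1.0, 0.5]
    assert r.npc == pytest.approx(0.75)
    with pytest.raises(ValueError):
        npc.npc_accuracy([], [], 2)


def test_bootstrap_sem_matches_binomial_closed_form():
    """One behavior, Bernoulli(0.5) agreement: SEM ~ sqrt(p(1-p)/n)."""
    rng = np.random.default_rng(7)
    n = 400
    truth = np.zeros(n, dtype=int)
    est = rng.integers(0, 2, n)
    r = npc.npc_accuracy(est, truth, 1, n_boot=1000, seed=3)
    p = r.npc
    assert r.sem == pytest.approx(math.sqrt(p * (1 - p) / n), rel=0.15)
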