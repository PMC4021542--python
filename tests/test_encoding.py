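"""Likelihood models: tuning fits, Poisson and truncated-Gaussian pmfs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

import npcdecode as npc
from npcdecode.encoding import (MU_FLOOR, TuningModel, UnfittableBehaviorError,
                                loo_loglik_matrix, per_neuron_loo_loglik)


def test_fit_tuning_hand_values():
    counts = np.array([[3.0], [5.0], [1.0], [1.0]])
    labels = np.array([0, 0, 1, 1])
    m = npc.fit_tuning(counts, labels, 2, model="truncgauss")
    assert m.mu[0, 0] == 4.0
    assert m.sigma2[0, 0] == 2.0  # unbiased, n-1 denominator
    assert m.mu[0, 1] == 1.0
    assert m.sigma2[0, 1] == 0.0


def test_fit_tuning_all_zero_counts_floored_in_likelihood():
    counts = np.zeros((4, 1))
    labels = np.array([0, 0, 1, 1])
    m = npc.fit_tuning(counts, labels, 2)
    assert m.mu[0, 0] == 0.0
    # likelihood evaluation uses the epsilon floor, so log p is finite
    ll = npc.population_loglik(np.array([0]), m, 0)
    assert np.isfinite(ll)
    assert ll == pytest.approx(-MU_FLOOR)


def test_fit_tuning_names_unfittable_behavior():
    counts = np.ones((3, 2))
    labels = np.array([0, 0, 2])
    with pytest.raises(UnfittableBehaviorError, match=r"\[1\]"):
        npc.fit_tuning(counts, labels, 3)  # behavior 1 has zero trials
    with pytest.raises(UnfittableBehaviorError):
        npc.fit_tuning(counts, labels, 3, model="truncgauss")  # behavior 2 has 1 trial


def test_poisson_likelihood_reference_values():
    assert npc.poisson_likelihood(0, 0.0) == 1.0  # 0^0 = 1 convention
    assert npc.poisson_likelihood(3, 0.0) == 0.0
    assert npc.poisson_likelihood(1, 1.0) == pytest.approx(math.exp(-1), rel=1e-12)
    assert npc.poisson_likelihood(4, 2.5) == pytest.approx(
        2.5 ** 4 / math.factorial(4) * math.exp(-2.5), rel=1e-12)


def test_poisson_likelihood_rejects_invalid_counts():
    with pytest.raises(ValueError):
        npc.poisson_likelihood(-1, 1.0)
    with pytest.raises(ValueError):
        npc.poisson_likelihood(1.5, 1.0)
    with pytest.raises(ValueError):
        npc.poisson_likelihood(1, -0.5)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(mu=st.floats(0.01, 40.0))
def test_poisson_likelihood_normalizes(mu):
    r = np.arange(0, 300)
    assert npc.poisson_likelihood(r, mu).sum() == pytest.approx(1.0, abs=1e-9)


def test_truncgauss_likelihood_reference_values():
    # mean at the boundary: truncation doubles the density
    assert npc.truncgauss_likelihood(0, 0.0, 1.0) == pytest.approx(
        2.0 / math.sqrt(2 * math.pi), rel=1e-12)
    # far from the boundary the truncation is negligible
    assert npc.truncgauss_likelihood(10, 10.0, 1.0) == pytest.approx(
        1.0 / math.sqrt(2 * math.pi), rel=1e-9)


def test_truncgauss_likelihood_matches_quadrature():
    mu, sigma2, r = 1.0, 1.0, 2
    normalizer, _ = quad(lambda x: norm.pdf(x, mu, math.sqrt(sigma2)), 0, np.inf)
    expected = norm.pdf(r, mu, math.sqrt(sigma2)) / normalizer
    assert npc.truncgauss_likelihood(r, mu, sigma2) == pytest.approx(expected, rel=1e-9)


def test_population_loglik_composition():
    mu = np.array([[1.0, 2.0], [3.0, 0.5], [0.8, 4.0]])
    model1 = TuningModel(mu=mu[:1], sigma2=None, kind="poisson")
    model3 = TuningModel(mu=mu, sigma2=None, kind="poisson")
    model_dup = TuningModel(mu=mu[[0, 0]], sigma2=None, kind="poisson")
    r = np.array([2, 1, 0])
    # N=1 equals the single-neuron log pmf
    assert npc.population_loglik(r[:1], model1, 0) == pytest.approx(
        math.log(npc.poisson_likelihood(2, 1.0)), rel=1e-12)
    # a duplicated neuron doubles the log-likelihood
    assert npc.population_loglik(np.array([2, 2]), model_dup, 1) == pytest.approx(
        2 * math.log(npc.poisson_likelihood(2, 2.0)), rel=1e-12)
    # N=3 matches the term-by-term product
    expected = sum(math.log(npc.poisson_likelihood(int(r[i]), mu[i, 1]))
                   for i in range(3))
    assert npc.population_loglik(r, model3, 1) == pytest.approx(expected, rel=1e-12)


def test_population_loglik_dimension_mismatch():
    model = TuningModel(mu=np.ones((2, 3)), sigma2=None, kind="poisson")
    with pytest.raises(ValueError):
        npc.population_loglik(np.array([1, 2, 3]), model, 0)


def test_poisson_loglik_maximized_at_mu_equals_r():
    r = np.array([7])
    model = lambda mu: npc.population_loglik(
        r, TuningModel(mu=np.array([[mu]]), sigma2=None, kind="poisson"), 0)
    grid = np.linspace(1.0, 20.0, 96)
    vals = np.array([model(m) for m in grid])
    best = grid[np.argmax(vals)]
    assert abs(best - 7.0) < 0.25
    # unimodal: increasing then decreasing
    d = np.diff(vals)
    assert np.all(d[grid[:-1] < best - 0.3] > 0)
    assert np.all(d[grid[1:] > best + 0.3] < 0)


@pytest.mark.parametrize("kind", ["poisson", "truncgauss"])
def test_loo_loglik_matrix_matches_explicit_refits(kind):
    """The vectorized LOO path equals refitting the model without each trial."""
    rng = np.random.default_rng(0)
    counts = rng.poisson(3.0, size=(12, 2))
    labels = np.array([0, 1, 2] * 4)
    L = loo_loglik_matrix(counts, labels, 3, kind=kind)
    for t in range(12):
        train = np.delete(np.arange(12), t)
        model = npc.fit_tuning(counts[train], labels[train], 3,
                               model=kind if kind == "truncgauss" else "poisson")
        expected = npc.population_loglik(counts[t], model, labels[t])
        assert L[t, labels[t]] == pytest.approx(expected, rel=1e-10)
        # other columns use the all-trials fit (the held-out trial is not in them)
        full = npc.fit_tuning(counts, labels, 3, model=kind)
        other = (labels[t] + 1) % 3
        assert L[t, other] == pytest.approx(
            npc.population_loglik(counts[t], full, other), rel=1e-10)


def test_count_matrix_round_trip(tmp_path):
    from npcdecode.encoding import read_count_matrix, write_count_matrix

    rng = np.random.default_rng(5)
    counts = rng.poisson(3.0, size=(9, 4))
    labels = rng.integers(0, 3, size=9)
    write_count_matrix(counts, labels, tmp_path / "c.csv", tmp_path / "l.csv")
    c2, l2 = read_count_matrix(tmp_path / "c.csv", tmp_path / "l.csv")
    assert np.array_equal(c2, counts) and np.array_equal(l2, labels)


@pytest.mark.parametrize("kind", ["poisson", "truncgauss"])
def test_per_neuron_cube_sums_to_population_loglik(kind):
    rng = np.random.default_rng(1)
    counts = rng.poisson(2.0, size=(10, 4))
    labels = rng.integers(0, 2, size=10)
    labels[:4] = [0, 0, 1, 1]
    cube = per_neuron_loo_loglik(counts, labels, 2, kind=kind)
    L = loo_loglik_matrix(counts, labels, 2, kind=kind)
    assert np.allclose(cube.sum(axis=2), L, rtol=1e-12, atol=1e-10)
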