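"""SPIB components: label initialization, Gaussian encoder, categorical
decoder, mixture-of-posteriors prior, the objective, label refinement,
and MSM estimation."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from geomtok.autodiff import Tensor, no_grad
from geomtok.errors import InputError
from geomtok.spib import (SpibConfig, SpibModel, StateLabels, build_msm,
                          init_labels, train_spib)
from geomtok.synthetic import simulate_markov_chain, two_state_chain

CFG = SpibConfig(latent_dim=2, beta=0.01, lag=2, init_k=5, n_pseudo=3, seed=0)


@pytest.fixture()
def model():
    rng = np.random.default_rng(0)
    return SpibModel(3, CFG, rng.normal(size=(3, 3)))


# -- label initialization -----------------------------------------------------

def test_init_labels_k1_and_range():
    cv = np.random.default_rng(1).normal(size=(50, 2))
    labels = init_labels(cv, 1, 0)
    assert labels.populated_count == 1 and np.all(labels.labels == 0)
    labels5 = init_labels(cv, 5, 0)
    assert labels5.labels.min() >= 0 and labels5.labels.max() < 5
    with pytest.raises(InputError):
        init_labels(cv, 100, 0)


def test_init_labels_recovers_separated_blobs():
    rng = np.random.default_rng(2)
    truth = rng.integers(0, 3, size=600)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    cv = centers[truth] + 0.1 * rng.normal(size=(600, 2))
    labels = init_labels(cv, 3, 0)
    assert adjusted_rand_score(truth, labels.labels) > 0.99


# -- encoder / decoder --------------------------------------------------------

def test_latent_sampling_moments_and_determinism(model):
    x = np.array([[0.5, -1.0, 2.0]])
    z1, (mu, logvar) = model.encode_latent(np.repeat(x, 10_000, axis=0),
                                           np.random.default_rng(3))
    sigma = np.exp(0.5 * logvar.data[0])
    assert np.abs(z1.data.mean(axis=0) - mu.data[0]).max() < 3 * sigma.max() / 100
    za, _ = model.encode_latent(x, np.random.default_rng(7))
    zb, _ = model.encode_latent(x, np.random.default_rng(7))
    np.testing.assert_array_equal(za.data, zb.data)
    # z is exactly the reparameterized transform of the drawn noise
    eps = np.random.default_rng(7).normal(size=(1, CFG.latent_dim))
    np.testing.assert_allclose(za.data, mu.data[:1] + sigma * eps, atol=1e-12)


def test_decoder_rows_normalized(model):
    z = np.random.default_rng(4).normal(size=(20, CFG.latent_dim))
    probs = model.decode_state(z).data
    assert np.all(probs >= 0)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_zeroed_decoder_head_gives_uniform(model):
    model.dec.layers[-1].weight.data[:] = 0.0
    model.dec.layers[-1].bias.data[:] = 0.0
    probs = model.decode_state(np.zeros((3, CFG.latent_dim))).data
    np.testing.assert_allclose(probs, 1.0 / CFG.init_k, atol=1e-12)
    entropy = -(probs[0] * np.log(probs[0])).sum()
    assert entropy == pytest.approx(np.log(CFG.init_k), abs=1e-9)


# -- prior --------------------------------------------------------------------

def test_single_component_prior_equals_posterior_pdf():
    cfg = SpibConfig(latent_dim=2, lag=1, init_k=4, n_pseudo=1, seed=1)
    m = SpibModel(3, cfg, np.random.default_rng(5).normal(size=(1, 3)))
    z = np.random.default_rng(6).normal(size=(10, 2))
    with no_grad():
        mu, logvar = m.posterior(m.pseudo)
    var = np.exp(logvar.data[0])
    manual = np.exp(-0.5 * (((z - mu.data[0]) ** 2) / var
                            + np.log(var) + np.log(2 * np.pi)).sum(axis=1))
    np.testing.assert_allclose(m.vamp_prior_density(z), manual, rtol=1e-10)


def test_prior_weight_normalization(model):
    z = np.random.default_rng(7).normal(size=(5, CFG.latent_dim))
    a = model.vamp_prior_density(z)
    model.log_omega.data += np.log(2.0)       # scaling all ω leaves r(z) fixed
    b = model.vamp_prior_density(z)
    np.testing.assert_allclose(a, b, rtol=1e-12)


def test_prior_integrates_to_one(model):
    """Grid quadrature of r(z) over the 2-D latent space ≈ 1."""
    g = np.linspace(-8, 8, 321)
    xx, yy = np.meshgrid(g, g)
    z = np.stack([xx.ravel(), yy.ravel()], axis=1)
    dens = model.vamp_prior_density(z).reshape(xx.shape)
    integral = np.trapezoid(np.trapezoid(dens, g, axis=1), g)
    assert integral == pytest.approx(1.0, abs=0.02)


# -- loss ---------------------------------------------------------------------

def test_beta_zero_loss_is_negative_log_likelihood(model):
    rng_data = np.random.default_rng(8)
    x = rng_data.normal(size=(32, 3))
    labels = rng_data.integers(0, CFG.init_k, size=32)
    cfg0 = SpibConfig(latent_dim=2, beta=0.0, lag=2, init_k=5, n_pseudo=3,
                      seed=0)
    m = SpibModel(3, cfg0, np.random.default_rng(0).normal(size=(3, 3)))
    loss = m.loss(x, labels, np.random.default_rng(9))
    z, _ = m.encode_latent(x, np.random.default_rng(9))
    with no_grad():
        logq = m.dec(z.detach()).log_softmax(axis=-1).data
    manual = -logq[np.arange(32), labels].mean()
    assert loss.item() == pytest.approx(manual, rel=1e-10)


def test_loss_finite_with_gradients(model):
    rng = np.random.default_rng(10)
    loss = model.loss(rng.normal(size=(16, 3)), rng.integers(0, 5, 16),
                      np.random.default_rng(11))
    loss.backward()
    assert np.isfinite(loss.item())
    assert all(np.all(np.isfinite(p.grad)) for p in model.parameters()
               if p.grad is not None)


# -- refinement ---------------------------------------------------------------

def test_constant_decoder_collapses_to_single_state(model):
    model.dec.layers[-1].weight.data[:] = 0.0
    model.dec.layers[-1].bias.data[:] = 0.0
    labels = model.refine_labels(np.random.default_rng(12).normal(size=(40, 3)))
    # all logits tie → argmax picks the lowest label index everywhere
    assert labels.populated_count == 1 and np.all(labels.labels == 0)


def test_refinement_bounded_by_init_k(model):
    labels = model.refine_labels(np.random.default_rng(13).normal(size=(50, 3)))
    assert labels.populated_count <= CFG.init_k
    assert labels.labels.max() < CFG.init_k


def test_likelihood_improves_with_frozen_labels():
    """β = 0, fixed separable labels: training raises the log-likelihood."""
    rng = np.random.default_rng(14)
    truth = rng.integers(0, 2, size=2000)
    x = np.array([[-2.0], [2.0]])[truth] + 0.3 * rng.normal(size=(2000, 1))
    cfg = SpibConfig(latent_dim=1, beta=0.0, lag=1, init_k=4, n_pseudo=2,
                     batch_size=256, seed=0)
    m = SpibModel(1, cfg, x[:2])
    from geomtok.nn import Adam
    opt = Adam(m.parameters(), lr=2e-3)
    losses = []
    rng2 = np.random.default_rng(15)
    for step in range(100):
        i = rng2.choice(len(x) - 1, 256)
        loss = m.loss(x[i], truth[i + 1], rng2)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    assert np.mean(losses[-10:]) < np.mean(losses[:10])


# -- markov state model -------------------------------------------------------

def test_msm_deterministic_cycle_is_permutation():
    labels = np.tile([0, 1, 2], 30)
    P, occ, ids = build_msm(labels, lag=1)
    np.testing.assert_allclose(P, np.roll(np.eye(3), 1, axis=1), atol=1e-12)
    np.testing.assert_allclose(occ, 1 / 3, atol=0.02)


def test_msm_rows_stochastic_and_sparse_labels():
    rng = np.random.default_rng(16)
    labels = rng.choice([3, 7, 11], size=500)
    P, occ, ids = build_msm(labels, lag=2)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_array_equal(ids, [3, 7, 11])


def test_msm_estimator_consistency():
    spec = two_state_chain()
    seq = simulate_markov_chain(spec, 100_000, np.random.default_rng(17))
    P, occ, _ = build_msm(seq, lag=1)
    assert np.abs(P - spec.P).max() < 0.02


def test_msm_zero_outgoing_row_imputed():
    labels = np.array([0, 0, 0, 1])          # state 1 never transitions
    with pytest.warns(UserWarning):
        P, _, _ = build_msm(labels, lag=1)
    assert P[1, 1] == 1.0


def test_state_count_recovery_two_state_chain():
    """A hidden 2-state chain observed through noisy 2-D features
    collapses from 8 initial clusters to the 2 metastable states."""
    spec = two_state_chain()
    seq = simulate_markov_chain(spec, 6000, np.random.default_rng(18))
    rng = np.random.default_rng(19)
    x = np.array([[-1.0, 0.5], [1.0, -0.5]])[seq] + 0.15 * rng.normal(size=(6000, 2))
    cfg = SpibConfig(latent_dim=2, beta=0.01, lag=2, init_k=8,
                     refresh_interval=600, n_steps=2400, batch_size=512,
                     seed=0)
    res = train_spib(x, cfg, (np.arange(3000), np.arange(3000, 6000)))
    assert res.final_populated_count == 2
    counts = [c for _, c in res.populated_trace]
    assert counts[-1] <= counts[0]
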