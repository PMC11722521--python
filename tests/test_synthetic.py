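"""Ground-truth generators: chains, Langevin dynamics, conformer
templates, embedding, and the temporal split."""

import numpy as np
import pytest

from geomtok.errors import InputError, NumericalError
from geomtok.synthetic import (LangevinSpec, MarkovChainSpec,
                               embed_states_as_conformers, gen_toy_conformers,
                               kabsch_rmsd, make_template_set,
                               potential_energy, potential_gradient,
                               simulate_langevin_2d, simulate_markov_chain,
                               temporal_split, three_state_chain,
                               two_state_chain)


# -- Markov chains ------------------------------------------------------------

def test_chain_specs_have_designed_spectra():
    two = two_state_chain()
    np.testing.assert_allclose(np.sort(np.real(two.eigenvalues)), [0.7, 1.0])
    np.testing.assert_allclose(two.stationary, [2 / 3, 1 / 3])
    three = three_state_chain()
    np.testing.assert_allclose(np.sort(np.real(three.eigenvalues)),
                               [0.7, 0.9, 1.0], atol=1e-12)
    np.testing.assert_allclose(three.stationary, np.full(3, 1 / 3))
    np.testing.assert_allclose(three.P, three.P.T)   # reversible at uniform π
    assert abs(three.vamp2_oracle() - 2.30) < 1e-12


def test_non_stochastic_matrix_rejected():
    with pytest.raises(InputError):
        MarkovChainSpec(np.array([[0.5, 0.6], [0.2, 0.8]]))


def test_identity_chain_is_constant():
    spec = MarkovChainSpec(np.eye(3))
    seq = simulate_markov_chain(spec, 50, np.random.default_rng(0))
    assert len(np.unique(seq)) == 1


def test_empirical_transition_matrix_consistency():
    spec = two_state_chain()
    seq = simulate_markov_chain(spec, 100_000, np.random.default_rng(1))
    C = np.zeros((2, 2))
    np.add.at(C, (seq[:-1], seq[1:]), 1.0)
    P_hat = C / C.sum(axis=1, keepdims=True)
    assert np.abs(P_hat - spec.P).max() < 0.01
    occ = np.bincount(seq) / len(seq)
    assert np.abs(occ - spec.stationary).max() < 0.01


def test_chain_seed_reproducible():
    spec = three_state_chain()
    a = simulate_markov_chain(spec, 500, np.random.default_rng(5))
    b = simulate_markov_chain(spec, 500, np.random.default_rng(5))
    assert np.array_equal(a, b)


# -- Langevin dynamics --------------------------------------------------------

@pytest.mark.parametrize("potential,minimum", [
    ("double_well", (1.0, 0.0)),
    ("triple_well", (2.0, 0.0)),
])
def test_zero_noise_descends_to_minimum(potential, minimum):
    spec = LangevinSpec(potential=potential, kT=0.0, n_steps=5000, stride=5000,
                        x0=(minimum[0] + 0.2, 0.3))
    end = simulate_langevin_2d(spec, np.random.default_rng(0))[-1]
    assert np.abs(potential_gradient(spec, end)).max() < 1e-4
    np.testing.assert_allclose(end, minimum, atol=1e-3)


def test_symmetric_double_well_occupancy_balanced():
    spec = LangevinSpec(potential="double_well", barrier=1.0,
                        n_steps=400_000, stride=10)
    xy = simulate_langevin_2d(spec, np.random.default_rng(0))
    pA = (xy[:, 0] < 0).mean()
    assert abs(pA - (1 - pA)) < 0.02


def test_tilted_double_well_matches_boltzmann_ratio():
    """Well occupancy ratio under a 1 kT free-energy tilt: the simulation
    must match the Boltzmann quadrature oracle, which is itself within
    10% of e¹."""
    spec = LangevinSpec(potential="double_well", barrier=3.0, tilt=0.5,
                        n_steps=400_000, stride=10)
    xs = np.linspace(-3, 3, 4001)
    V = potential_energy(spec, np.stack([xs, np.zeros_like(xs)], axis=1))
    w = np.exp(-V / spec.kT)
    oracle = w[xs < 0].sum() / w[xs > 0].sum()
    assert abs(oracle - np.e) / np.e < 0.10
    xy = simulate_langevin_2d(spec, np.random.default_rng(1))
    ratio = (xy[:, 0] < 0).mean() / (xy[:, 0] > 0).mean()
    assert abs(ratio - np.e) / np.e < 0.10


def test_divergence_detected():
    spec = LangevinSpec(potential="double_well", dt=5.0, n_steps=1000)
    with pytest.raises(NumericalError):
        simulate_langevin_2d(spec, np.random.default_rng(0))


# -- conformer templates and embedding ---------------------------------------

def test_templates_are_distinguishable(templates):
    K = templates.n_states
    for i in range(K):
        for j in range(i + 1, K):
            assert kabsch_rmsd(templates.templates[i],
                               templates.templates[j]) > 5 * templates.jitter


def test_toy_conformers_preserve_bonds(templates):
    rng = np.random.default_rng(2)
    coords, which = gen_toy_conformers(500, templates, rng)
    assert coords.shape == (500, templates.n_atoms, 3)
    assert np.all(np.isfinite(coords))
    for i, j in templates.bonds:
        ref = np.linalg.norm(templates.templates[which][:, i]
                             - templates.templates[which][:, j], axis=1)
        actual = np.linalg.norm(coords[:, i] - coords[:, j], axis=1)
        assert np.all(np.abs(actual - ref) / ref < 0.10)


def test_toy_conformers_seed_reproducible(templates):
    a, _ = gen_toy_conformers(20, templates, np.random.default_rng(3))
    b, _ = gen_toy_conformers(20, templates, np.random.default_rng(3))
    assert np.array_equal(a, b)


def test_discrete_embedding_recoverable(templates):
    rng = np.random.default_rng(4)
    path = rng.integers(0, 3, size=300)
    frames, truth = embed_states_as_conformers(path, templates, rng)
    assert frames.shape[0] == 300 and truth["kind"] == "discrete"
    # nearest-template classification recovers the hidden states
    d = np.linalg.norm(frames[:, None] - templates.templates[None], axis=(2, 3))
    assert (d.argmin(axis=1) == path).mean() > 0.99


def test_zero_jitter_embedding_exact(templates):
    import dataclasses
    t0 = dataclasses.replace(templates, jitter=0.0)
    path = np.array([0, 1, 2, 1])
    frames, _ = embed_states_as_conformers(path, t0, np.random.default_rng(0))
    np.testing.assert_array_equal(frames, t0.templates[path])


def test_continuous_embedding_and_errors(templates):
    rng = np.random.default_rng(5)
    xy = rng.normal(size=(50, 2))
    frames, truth = embed_states_as_conformers(xy, templates, rng)
    assert frames.shape == (50, templates.n_atoms, 3)
    assert truth["kind"] == "continuous"
    with pytest.raises(InputError):
        embed_states_as_conformers(np.array([0, 5]), templates, rng)


def test_template_draw_deterministic():
    a = make_template_set(2, n_residues=3, seed=42)
    b = make_template_set(2, n_residues=3, seed=42)
    assert np.array_equal(a.templates, b.templates)


# -- temporal split -----------------------------------------------------------

def test_split_halves_at_default():
    train, val = temporal_split(100, 0.5, 1)
    assert np.array_equal(train, np.arange(50))
    assert np.array_equal(val, np.arange(50, 100))


def test_split_segments_stay_in_first_half():
    rng = np.random.default_rng(0)
    train, val = temporal_split(2000, 0.25, 20, rng)
    assert len(train) == 500               # 10 of 20 fifty-frame segments
    assert train.max() < 1000
    assert np.array_equal(val, np.arange(1000, 2000))
    # segments disjoint and internally ordered
    assert len(np.unique(train)) == len(train)
    assert np.all(np.diff(train) >= 1)


def test_split_rejects_fraction_beyond_half():
    with pytest.raises(InputError):
        temporal_split(100, 0.6, 4)


from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(deadline=None, max_examples=50, derandomize=True)
@given(T=st.integers(10, 2000), frac=st.floats(0.05, 0.5),
       nseg=st.integers(1, 12), seed=st.integers(0, 5))
def test_split_never_trains_on_validation_half(T, frac, nseg, seed):
    """Invariant: whatever the configuration, training indices stay in
    the first half, the validation set is exactly the second half, and
    indices never repeat."""
    rng = np.random.default_rng(seed)
    try:
        train, val = temporal_split(T, frac, nseg, rng)
    except InputError:
        # degenerate configurations only: segments too small to cut, or a
        # fraction rounding to zero frames
        assert nseg > T // 2 or int(round(frac * T)) == 0
        return
    assert np.array_equal(val, np.arange(T // 2, T))
    assert len(train) > 0 and train.max() < T // 2
    assert len(np.unique(train)) == len(train)
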