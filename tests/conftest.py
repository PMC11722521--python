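"""Shared fixtures.

The expensive pipeline products (pretrained encoder, featurized synthetic
trajectories) are built once per session and shared between the unit
tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from geomtok.encoder import EncoderConfig
from geomtok.featurize import infer_trajectory, partition_by_residue, select_atoms
from geomtok.pretrain import DenoiseConfig, train_denoiser
from geomtok.synthetic import (LangevinSpec, embed_states_as_conformers,
                               gen_toy_conformers, make_template_set,
                               simulate_langevin_2d, simulate_markov_chain,
                               three_state_chain)


@pytest.fixture(scope="session")
def templates():
    """Three distinguishable 12-atom chain templates (3 residues)."""
    return make_template_set(3, n_residues=3, seed=7)


@pytest.fixture(scope="session")
def toy_conformers(templates):
    rng = np.random.default_rng(100)
    coords, which = gen_toy_conformers(400, templates, rng)
    return coords, which


@pytest.fixture(scope="session")
def pretrained(templates, toy_conformers):
    """Denoising-pretrained encoder (d=32, 2 layers, 20 epochs)."""
    coords, _ = toy_conformers
    enc_cfg = EncoderConfig(d=32, n_layers=2, n_rbf=16, seed=0)
    cfg = DenoiseConfig(sigma=0.2, epochs=20, batch_size=64, seed=0)
    return train_denoiser(coords, templates.atom_numbers, enc_cfg, cfg)


def _featurize(traj, templates, encoder):
    sel = select_atoms(templates.atom_numbers, "all")
    part = partition_by_residue(templates.residue_ids, sel)
    return infer_trajectory(traj, encoder, templates.atom_numbers, "all",
                            part, batch_size=256)


@pytest.fixture(scope="session")
def markov_tokens(templates, pretrained):
    """Hidden 3-state chain (eigenvalues 1, 0.9, 0.7) embedded as
    conformers and featurized with the frozen pretrained encoder."""
    spec = three_state_chain()
    rng = np.random.default_rng(0)
    seq = simulate_markov_chain(spec, 10_000, rng)
    traj, _ = embed_states_as_conformers(seq, templates, rng)
    store = _featurize(traj, templates, pretrained.encoder)
    return {"spec": spec, "states": seq,
            "scalars": np.asarray(store.scalars, dtype=np.float64),
            "store": store}


@pytest.fixture(scope="session")
def double_well_tokens(templates, pretrained):
    """Double-well Langevin path embedded as conformers and featurized."""
    spec = LangevinSpec(potential="double_well", barrier=3.0,
                        n_steps=100_000, stride=10)
    rng = np.random.default_rng(11)
    xy = simulate_langevin_2d(spec, rng)
    traj, _ = embed_states_as_conformers(xy, templates, rng)
    store = _featurize(traj, templates, pretrained.encoder)
    return {"xy": xy, "scalars": np.asarray(store.scalars, dtype=np.float64)}


@pytest.fixture(scope="session")
def triple_well_path():
    """Metastable triple-well trajectory (basins at x = -2, 0, 2)."""
    spec = LangevinSpec(potential="triple_well", barrier=4.0,
                        n_steps=200_000, stride=10)
    return simulate_langevin_2d(spec, np.random.default_rng(3))
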