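"""Atom selection, coarse-graining into tokens, pooling, trajectory
inference, and the feature cache."""

import numpy as np
import pytest

from geomtok.encoder import EncoderConfig, GeometricEncoder, NodeFeatures, build_graph
from geomtok.errors import ConfigurationError, InputError
from geomtok.featurize import (FeatureStore, Partition, coarse_grain,
                               global_pool, infer_trajectory,
                               partition_by_residue, select_atoms)

CFG = EncoderConfig(d=8, n_layers=1, n_rbf=8, seed=0)


def _features(rng, n=8, d=4):
    return NodeFeatures(rng.normal(size=(n, d)), rng.normal(size=(n, 3, d)))


# -- selection ----------------------------------------------------------------

def test_select_all_and_heavy():
    numbers = np.array([8, 1, 1])                       # water
    np.testing.assert_array_equal(select_atoms(numbers, "all"), [0, 1, 2])
    np.testing.assert_array_equal(select_atoms(numbers, "non-hydrogen"), [0])


def test_select_explicit_and_residue():
    numbers = np.array([6, 6, 7, 8])
    res = np.array([0, 0, 1, 1])
    np.testing.assert_array_equal(select_atoms(numbers, [3, 1, 1]), [1, 3])
    np.testing.assert_array_equal(
        select_atoms(numbers, ("residue", 1), residue_ids=res), [2, 3])


def test_empty_selection_rejected():
    with pytest.raises(InputError):
        select_atoms(np.array([1, 1]), "non-hydrogen")


# -- partition ----------------------------------------------------------------

def test_partition_validation():
    with pytest.raises(InputError):
        Partition([[0, 1], [1, 2]])        # overlap
    with pytest.raises(InputError):
        Partition([[0], []])               # empty subset
    p = Partition([[2, 0], [1]])
    assert p.n_tokens == 2
    np.testing.assert_array_equal(p.indices, [0, 1, 2])


def test_partition_file_roundtrip(tmp_path):
    p = Partition([[0, 1, 2], [3], [4, 5]])
    path = tmp_path / "part.txt"
    p.to_file(path)
    q = Partition.from_file(path)
    assert all(np.array_equal(a, b) for a, b in zip(p.subsets, q.subsets))
    assert p.hash() == q.hash()


# -- coarse graining ----------------------------------------------------------

def test_singleton_partition_is_identity():
    f = _features(np.random.default_rng(0))
    tokens = coarse_grain(f, Partition([[i] for i in range(8)]))
    np.testing.assert_array_equal(tokens.scalars, f.scalars)
    np.testing.assert_array_equal(tokens.vectors, f.vectors)


def test_single_subset_is_column_sum():
    f = _features(np.random.default_rng(1))
    tokens = coarse_grain(f, Partition([list(range(8))]))
    np.testing.assert_allclose(tokens.scalars[0], f.scalars.sum(axis=0))
    np.testing.assert_allclose(tokens.vectors[0], f.vectors.sum(axis=0))


def test_partition_conserves_totals_and_linearity():
    rng = np.random.default_rng(2)
    f1, f2 = _features(rng), _features(rng)
    part = Partition([[0, 3], [1, 2, 4], [5, 6, 7]])
    t1 = coarse_grain(f1, part)
    assert np.abs(t1.scalars.sum(0) - f1.scalars.sum(0)).max() < 1e-6
    mix = NodeFeatures(2 * f1.scalars - 3 * f2.scalars,
                       2 * f1.vectors - 3 * f2.vectors)
    tmix = coarse_grain(mix, part)
    t2 = coarse_grain(f2, part)
    np.testing.assert_allclose(tmix.scalars, 2 * t1.scalars - 3 * t2.scalars)


def test_out_of_range_partition_rejected():
    f = _features(np.random.default_rng(3))
    with pytest.raises(InputError):
        coarse_grain(f, Partition([[0, 99]]))


def test_partition_by_residue_token_count():
    res = np.array([0, 0, 1, 1, 2, 2, 2])
    part = partition_by_residue(res, np.arange(7))
    assert part.n_tokens == 3


# -- global pooling -----------------------------------------------------------

def test_sum_pool_equals_atom_pooling():
    """Summing residue tokens equals pooling the atomic features."""
    f = _features(np.random.default_rng(4))
    residue_tokens = coarse_grain(f, Partition([[0, 1], [2, 3], [4, 5, 6, 7]]))
    atom_tokens = coarse_grain(f, Partition([[i] for i in range(8)]))
    a = global_pool(residue_tokens, "sum")
    b = global_pool(atom_tokens, "sum")
    np.testing.assert_allclose(a.scalars, b.scalars, atol=1e-10)
    np.testing.assert_allclose(a.vectors, b.vectors, atol=1e-10)


def test_pool_symmetry_and_mean():
    from geomtok.featurize import TokenArray
    rng = np.random.default_rng(5)
    t = TokenArray(rng.normal(size=(4, 6)), rng.normal(size=(4, 3, 6)))
    perm = TokenArray(t.scalars[::-1].copy(), t.vectors[::-1].copy())
    np.testing.assert_allclose(global_pool(t, "sum").scalars,
                               global_pool(perm, "sum").scalars)
    single = TokenArray(t.scalars[:1], t.vectors[:1])
    np.testing.assert_allclose(global_pool(single, "mean").scalars,
                               single.scalars)
    with pytest.raises(InputError):
        global_pool(t, "median")


# -- trajectory inference -----------------------------------------------------

@pytest.fixture(scope="module")
def tiny_system():
    rng = np.random.default_rng(6)
    numbers = np.array([6, 6, 7, 8, 6, 6])
    residues = np.array([0, 0, 0, 1, 1, 1])
    frames = rng.normal(scale=1.5, size=(5, 6, 3))
    encoder = GeometricEncoder(CFG)
    sel = select_atoms(numbers, "all")
    part = partition_by_residue(residues, sel)
    return frames, numbers, part, encoder


def test_store_shape_and_composition(tiny_system):
    frames, numbers, part, encoder = tiny_system
    store = infer_trajectory(frames, encoder, numbers, "all", part)
    assert store.scalars.shape == (5, 2, CFG.d)
    assert store.vectors.shape == (5, 2, 3, CFG.d)
    # identical to per-frame encode → coarse_grain
    f = encoder.encode(build_graph(frames[2], numbers, CFG.cutoff))
    tokens = coarse_grain(f, part)
    np.testing.assert_allclose(store.scalars[2], tokens.scalars, atol=1e-5)


def test_batching_does_not_change_results(tiny_system):
    frames, numbers, part, encoder = tiny_system
    a = infer_trajectory(frames, encoder, numbers, "all", part, batch_size=1)
    b = infer_trajectory(frames, encoder, numbers, "all", part, batch_size=5)
    assert np.abs(a.scalars - b.scalars).max() < 1e-6


def test_rotated_frames_leave_scalars_unchanged(tiny_system):
    from scipy.spatial.transform import Rotation
    frames, numbers, part, encoder = tiny_system
    R = Rotation.random(random_state=0).as_matrix()
    a = infer_trajectory(frames, encoder, numbers, "all", part)
    b = infer_trajectory(frames @ R.T, encoder, numbers, "all", part)
    assert np.abs(a.scalars - b.scalars).max() < 1e-4


def test_store_roundtrip_bit_identical(tmp_path, tiny_system):
    frames, numbers, part, encoder = tiny_system
    store = infer_trajectory(frames, encoder, numbers, "all", part,
                             checkpoint_id="abc")
    path = tmp_path / "store.h5"
    store.write(path)
    back = FeatureStore.read(path)
    assert np.array_equal(back.scalars, store.scalars.astype(np.float32))
    assert np.array_equal(back.vectors, store.vectors.astype(np.float32))
    assert back.metadata["checkpoint_id"] == "abc"


def test_corrupted_metadata_detected(tmp_path, tiny_system):
    import h5py
    frames, numbers, part, encoder = tiny_system
    store = infer_trajectory(frames, encoder, numbers, "all", part)
    path = tmp_path / "store.h5"
    store.write(path)
    with h5py.File(path, "r+") as f:
        f.attrs["metadata"] = f.attrs["metadata"] + " "
    with pytest.raises(ConfigurationError):
        FeatureStore.read(path)
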