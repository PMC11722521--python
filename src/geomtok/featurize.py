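"""Frozen-encoder featurization: atom selection, coarse-graining into
structural tokens, and cached per-frame token arrays.

A partition 𝒮 = {S₁, …, S_M} groups the selected atoms into structural
units (for proteins, residues).  Token m is the plain sum of the
per-atom features over S_m — a parameter-free linear reduction that
preserves the scalar/vector equivariance contract.  Per-frame token
arrays are cached in an HDF5 store keyed by content hashes of the
checkpoint, selection and partition so stale caches are detected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .encoder import GeometricEncoder, NodeFeatures
from .errors import ConfigurationError, InputError

__all__ = ["Partition", "TokenArray", "FeatureStore", "select_atoms",
           "partition_by_residue", "coarse_grain", "global_pool",
           "infer_trajectory"]

_HYDROGEN = 1


def _digest(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(np.ascontiguousarray(p).tobytes())
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


@dataclass
class Partition:
    """Disjoint, non-empty index subsets covering the selected atoms."""

    subsets: list

    def __post_init__(self):
        subsets = [np.asarray(s, dtype=np.intp) for s in self.subsets]
        if not subsets or any(len(s) == 0 for s in subsets):
            raise InputError("every partition subset must be non-empty")
        flat = np.concatenate(subsets)
        if len(np.unique(flat)) != len(flat):
            raise InputError("partition subsets overlap")
        self.subsets = subsets

    @property
    def n_tokens(self) -> int:
        return len(self.subsets)

    @property
    def indices(self) -> np.ndarray:
        return np.sort(np.concatenate(self.subsets))

    def hash(self) -> str:
        return _digest([s.tolist() for s in self.subsets])

    @classmethod
    def from_file(cls, path) -> "Partition":
        """Text format: one line of whitespace-separated atom indices per
        token."""
        subsets = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    subsets.append([int(x) for x in line.split()])
        return cls(subsets)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.subsets:
                fh.write(" ".join(map(str, s.tolist())) + "\n")


@dataclass
class TokenArray:
    """Per-token pooled features: scalars [M, d], vectors [M, 3, d]."""

    scalars: np.ndarray
    vectors: np.ndarray

    @property
    def n_tokens(self) -> int:
        return self.scalars.shape[0]


def select_atoms(atom_numbers, rule, residue_ids=None, chain_ids=None):
    """Resolve a selection rule to sorted unique atom indices.

    rule: "all" | "non-hydrogen" | explicit index sequence |
    ("residue", ids) | ("chain", ids).
    """
    atom_numbers = np.asarray(atom_numbers)
    n = len(atom_numbers)
    if isinstance(rule, str):
        if rule == "all":
            idx = np.arange(n)
        elif rule in ("non-hydrogen", "heavy"):
            idx = np.nonzero(atom_numbers != _HYDROGEN)[0]
        else:
            raise InputError(f"unknown selection rule {rule!r}")
    elif isinstance(rule, tuple) and len(rule) == 2 and rule[0] in ("residue", "chain"):
        key = residue_ids if rule[0] == "residue" else chain_ids
        if key is None:
            raise InputError(f"selection by {rule[0]} needs {rule[0]}_ids")
        idx = np.nonzero(np.isin(np.asarray(key), np.atleast_1d(rule[1])))[0]
    else:
        idx = np.unique(np.asarray(rule, dtype=np.intp))
        if len(idx) and (idx.min() < 0 or idx.max() >= n):
            raise InputError("explicit selection index out of range")
    if len(idx) == 0:
        raise InputError("selection matched no atoms")
    return np.sort(np.unique(idx))


def partition_by_residue(residue_ids, selected) -> Partition:
    """One token per residue present in the selection; subset indices are
    positions within the selected-atom array."""
    residue_ids = np.asarray(residue_ids)[np.asarray(selected)]
    subsets = [np.nonzero(residue_ids == r)[0]
               for r in np.unique(residue_ids)]
    return Partition(subsets)


def coarse_grain(features: NodeFeatures, partition: Partition) -> TokenArray:
    """Token m = Σ_{i ∈ S_m} h_i (exact sums, no parameters)."""
    N = features.scalars.shape[0]
    flat = partition.indices
    if len(flat) and (flat[0] < 0 or flat[-1] >= N):
        raise InputError("partition index out of range")
    scalars = np.stack([features.scalars[s].sum(axis=0)
                        for s in partition.subsets])
    vectors = np.stack([features.vectors[s].sum(axis=0)
                        for s in partition.subsets])
    return TokenArray(scalars, vectors)


def global_pool(tokens: TokenArray, mode: str = "sum") -> TokenArray:
    """Order-independent reduction over tokens to one (1+3)d feature."""
    if mode == "sum":
        red = lambda a: a.sum(axis=0, keepdims=True)
    elif mode == "mean":
        red = lambda a: a.mean(axis=0, keepdims=True)
    else:
        raise InputError(f"unknown pooling mode {mode!r}")
    return TokenArray(red(tokens.scalars), red(tokens.vectors))


@dataclass
class FeatureStore:
    """Stack of per-frame token arrays with provenance metadata.

    scalars: float32 [T, M, d]; vectors: float32 [T, M, 3, d].
    Metadata records the encoder checkpoint hash, partition hash,
    selection hash, frame stride and units; a hash of the metadata is
    verified on read-back.
    """

    scalars: np.ndarray
    vectors: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.scalars.shape[0]

    @property
    def n_tokens(self) -> int:
        return self.scalars.shape[1]

    def write(self, path) -> None:
        meta = dict(self.metadata)
        meta_json = json.dumps(meta, sort_keys=True, default=str)
        with h5py.File(path, "w") as f:
            f.create_dataset("scalars", data=self.scalars.astype(np.float32))
            f.create_dataset("vectors", data=self.vectors.astype(np.float32))
            f.attrs["metadata"] = meta_json
            f.attrs["metadata_hash"] = hashlib.sha256(
                meta_json.encode()).hexdigest()

    @classmethod
    def read(cls, path) -> "FeatureStore":
        with h5py.File(path, "r") as f:
            meta_json = f.attrs["metadata"]
            if hashlib.sha256(meta_json.encode()).hexdigest() \
                    != f.attrs["metadata_hash"]:
                raise ConfigurationError("feature store metadata corrupted")
            return cls(f["scalars"][...], f["vectors"][...],
                       json.loads(meta_json))


def infer_trajectory(frames: np.ndarray, encoder: GeometricEncoder,
                     atom_numbers, selection, partition: Partition,
                     batch_size: int = 64, stride: int = 1,
                     checkpoint_id: str = "") -> FeatureStore:
    """Run the frozen encoder over trajectory frames and coarse-grain.

    frames: [T, N, 3] Å sharing one topology.  Selection restricts the
    graph to the selected atoms; the partition indexes positions within
    the selected set.  Results are identical to per-frame
    encode → coarse_grain composition; encoder parameters are not
    touched.
    """
    frames = np.asarray(frames, dtype=np.float64)[::stride]
    sel = select_atoms(atom_numbers, selection)
    numbers_sel = np.asarray(atom_numbers)[sel]
    if partition.indices[-1] >= len(sel):
        raise InputError("partition index outside the selected-atom range")
    T = frames.shape[0]
    M, d = partition.n_tokens, encoder.config.d
    scalars = np.empty((T, M, d), dtype=np.float32)
    vectors = np.empty((T, M, 3, d), dtype=np.float32)
    # token sums via segment matrix for the whole batch at once
    seg = np.zeros((M, len(sel)))
    for m, s in enumerate(partition.subsets):
        seg[m, s] = 1.0
    for start in range(0, T, batch_size):
        chunk = frames[start:start + batch_size][:, sel, :]
        x, v = encoder.encode_frames(chunk, numbers_sel)
        scalars[start:start + batch_size] = np.einsum("mn,bnd->bmd", seg, x)
        vectors[start:start + batch_size] = np.einsum("mn,bncd->bmcd", seg, v)
    meta = {
        "checkpoint_id": checkpoint_id,
        "encoder_config": str(encoder.config),
        "partition_hash": partition.hash(),
        "selection_hash": _digest(sel),
        "stride": stride,
        "units": "angstrom",
        "n_frames": T,
    }
    return FeatureStore(scalars, vectors, meta)
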