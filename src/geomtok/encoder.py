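"""Equivariant geometric graph encoder.

Maps atomic coordinates (Å) to per-atom representations with ``d``
rotation-invariant scalar channels and ``d`` rotation-equivariant
3-vector channels.  The architecture is a message-passing network in the
TorchMD-ET / PaiNN family: radial-basis edge filters with a cosine cutoff
envelope drive separate update paths for scalar and vector features, and
a node-wise gated update mixes information between the two.  Scalars are
built only from distances, vector norms and scalar-vector dot products;
vectors are built only from unit bond directions and existing vector
channels with invariant coefficients — so invariance/equivariance under
rigid motion holds by construction.

A gated equivariant head turns the per-atom features into one 3-vector
per atom (used as the displacement predictor during denoising
pretraining).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat, scatter_sum, no_grad
from .errors import ConfigurationError, InputError
from .nn import Embedding, Linear, MLP, Module

__all__ = [
    "EncoderConfig",
    "AtomicGraph",
    "NodeFeatures",
    "build_graph",
    "GeometricEncoder",
    "GatedEquivariantHead",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of the encoder.

    d: hidden channels per atom (scalar and vector alike).
    n_layers: message-passing layers.
    cutoff: neighbor cutoff in Å.
    n_rbf: number of radial basis functions on [0, cutoff].
    max_z: largest atomic number with an embedding.
    seed: fixes parameter initialization.
    """

    d: int = 64
    n_layers: int = 4
    cutoff: float = 5.0
    n_rbf: int = 32
    max_z: int = 54
    seed: int = 0

    def __post_init__(self):
        if min(self.d, self.n_layers, self.n_rbf) < 1 or self.cutoff <= 0:
            raise ConfigurationError("encoder config fields must be positive")


@dataclass
class AtomicGraph:
    """Cutoff graph over one conformation.

    ``edge_index`` is ``[2, E]`` (source row, destination row); the edge
    set is symmetric and contains (i, j) iff 0 < ‖r_i − r_j‖ ≤ cutoff.
    """

    atom_numbers: np.ndarray
    coords: np.ndarray
    edge_index: np.ndarray
    cutoff: float


@dataclass
class NodeFeatures:
    """Per-atom representation: scalars [N, d], vectors [N, 3, d]."""

    scalars: np.ndarray
    vectors: np.ndarray


def build_graph(coords, atom_numbers, cutoff: float) -> AtomicGraph:
    """Brute-force O(N²) neighbor search (systems here have ≲ a few hundred
    atoms; swap in a cell list for larger ones)."""
    coords = np.asarray(coords, dtype=np.float64)
    atom_numbers = np.asarray(atom_numbers, dtype=np.intp)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise InputError("coords must be [N, 3] with N >= 1")
    if not np.all(np.isfinite(coords)):
        raise InputError("coords contain non-finite values")
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    dst, src = np.nonzero(dist <= cutoff)
    return AtomicGraph(atom_numbers, coords, np.stack([src, dst]), float(cutoff))


def _batched_edges(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Edge index of the disjoint union of B frames of the same topology."""
    B, N, _ = coords.shape
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    idx = np.arange(N)
    dist[:, idx, idx] = np.inf
    b, i, j = np.nonzero(dist <= cutoff)
    return np.stack([b * N + j, b * N + i])


def _rbf(dist: np.ndarray, cutoff: float, n_rbf: int) -> np.ndarray:
    """Gaussian radial basis on [0, cutoff], modulated by a cosine envelope
    so filters vanish smoothly at the cutoff."""
    centers = np.linspace(0.0, cutoff, n_rbf)
    width = cutoff / n_rbf
    basis = np.exp(-((dist[:, None] - centers[None, :]) ** 2) / (2 * width ** 2))
    envelope = 0.5 * (np.cos(np.pi * dist / cutoff) + 1.0) * (dist <= cutoff)
    return basis * envelope[:, None]


class _InteractionLayer(Module):
    def __init__(self, d: int, n_rbf: int, rng):
        self.filter = Linear(n_rbf, 3 * d, rng)
        self.msg_mlp = MLP([d, d, 3 * d], rng)
        self.upd_u = Linear(d, d, rng, bias=False)
        self.upd_v = Linear(d, d, rng, bias=False)
        self.upd_mlp = MLP([2 * d, d, 3 * d], rng)
        self._d = d

    def forward(self, x: Tensor, v: Tensor, edges, rbf, rhat, n_atoms):
        d = self._d
        src, dst = edges
        # message phase: edge filters gate per-neighbor contributions
        w = self.filter(Tensor(rbf))
        phi = self.msg_mlp(x[src]) * w
        a1 = phi[:, :d]
        a2 = phi[:, d:2 * d].reshape(-1, 1, d)
        a3 = phi[:, 2 * d:].reshape(-1, 1, d)
        dx = scatter_sum(a1, dst, n_atoms)
        dv = scatter_sum(a2 * v[src] + a3 * Tensor(rhat[:, :, None]), dst, n_atoms)
        x = x + dx
        v = v + dv
        # update phase: node-local mixing of scalar and vector channels
        u_ch = v @ self.upd_u.weight
        v_ch = v @ self.upd_v.weight
        vnorm = (v_ch * v_ch).sum(axis=1)
        a = self.upd_mlp(concat([x, vnorm], axis=-1))
        uv_dot = (u_ch * v_ch).sum(axis=1)
        x = x + a[:, :d] + a[:, d:2 * d] * uv_dot
        v = v + a[:, 2 * d:].reshape(-1, 1, d) * u_ch
        return x, v


class GeometricEncoder(Module):
    """Stack of interaction layers; activations after the last layer are
    the representation (no task head)."""

    def __init__(self, config: EncoderConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.embedding = Embedding(config.max_z + 1, config.d, rng)
        self.layers = [
            _InteractionLayer(config.d, config.n_rbf, rng)
            for _ in range(config.n_layers)
        ]

    def _forward_flat(self, atom_numbers, coords, edge_index):
        cfg = self.config
        if atom_numbers.max(initial=0) > cfg.max_z or atom_numbers.min(initial=1) < 1:
            raise ConfigurationError(
                f"atomic number outside embedding range [1, {cfg.max_z}]"
            )
        src, dst = edge_index
        rvec = coords[dst] - coords[src]
        dist = np.sqrt((rvec ** 2).sum(-1))
        rhat = rvec / np.maximum(dist, 1e-12)[:, None]
        rbf = _rbf(dist, cfg.cutoff, cfg.n_rbf)
        x = self.embedding(atom_numbers)
        v = Tensor(np.zeros((coords.shape[0], 3, cfg.d)))
        for layer in self.layers:
            x, v = layer(x, v, (src, dst), rbf, rhat, coords.shape[0])
        return x, v

    def encode(self, graph: AtomicGraph) -> NodeFeatures:
        """Inference on a single graph (no gradient tape)."""
        with no_grad():
            x, v = self._forward_flat(
                graph.atom_numbers, graph.coords, graph.edge_index
            )
        return NodeFeatures(x.data, v.data)

    def encode_frames(self, coords: np.ndarray, atom_numbers: np.ndarray):
        """Batched inference over frames sharing one topology.

        coords: [B, N, 3] → (scalars [B, N, d], vectors [B, N, 3, d]).
        Frames are merged into one disjoint graph so a batch costs a single
        forward pass.
        """
        coords = np.asarray(coords, dtype=np.float64)
        B, N, _ = coords.shape
        edges = _batched_edges(coords, self.config.cutoff)
        flat_numbers = np.tile(np.asarray(atom_numbers, dtype=np.intp), B)
        with no_grad():
            x, v = self._forward_flat(flat_numbers, coords.reshape(-1, 3), edges)
        d = self.config.d
        return x.data.reshape(B, N, d), v.data.reshape(B, N, 3, d)

    def forward_trainable(self, coords: np.ndarray, atom_numbers: np.ndarray):
        """Batched forward with the tape attached (for pretraining)."""
        coords = np.asarray(coords, dtype=np.float64)
        B, N, _ = coords.shape
        edges = _batched_edges(coords, self.config.cutoff)
        flat_numbers = np.tile(np.asarray(atom_numbers, dtype=np.intp), B)
        return self._forward_flat(flat_numbers, coords.reshape(-1, 3), edges)


class GatedEquivariantHead(Module):
    """Scalar-gated linear map of vector channels → one 3-vector per atom.

    Two channel-mixing maps act on the vector features; the norms of the
    first are concatenated with the scalars and passed through a 2-layer
    MLP whose output gates the second map, which is then contracted to a
    single 3-vector.  With the gates held fixed the output is linear in
    the vector channels, and all-zero vector channels give a zero output.
    """

    def __init__(self, d: int, rng=None, seed: int = 0):
        if rng is None:
            rng = np.random.default_rng(seed)
        self.w1 = Linear(d, d, rng, bias=False)
        self.w2 = Linear(d, d, rng, bias=False)
        self.gate_mlp = MLP([2 * d, d, d], rng)
        self.contract = Linear(d, 1, rng, bias=False)
        self._d = d

    def forward(self, scalars: Tensor, vectors: Tensor) -> Tensor:
        if scalars.shape[-1] != self._d:
            raise ConfigurationError(
                f"head built for d={self._d}, got {scalars.shape[-1]} channels"
            )
        v1 = vectors @ self.w1.weight
        v2 = vectors @ self.w2.weight
        norms = ((v1 * v1).sum(axis=1) + 1e-12).sqrt()
        gates = self.gate_mlp(concat([scalars, norms], axis=-1))
        gated = v2 * gates.reshape(gates.shape[0], 1, gates.shape[1])
        return (gated @ self.contract.weight).reshape(-1, 3)

    def predict(self, features: NodeFeatures) -> np.ndarray:
        with no_grad():
            out = self.forward(Tensor(features.scalars), Tensor(features.vectors))
        return out.data


# -- checkpoints --------------------------------------------------------------

def save_checkpoint(path, config: EncoderConfig, encoder_state: dict,
                    head_state: dict | None = None, meta: dict | None = None):
    """Single-file archive: JSON config header + named parameter arrays."""
    header = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": asdict(config),
        "meta": meta or {},
    }
    arrays = {f"encoder/{k}": v for k, v in encoder_state.items()}
    if head_state is not None:
        arrays.update({f"head/{k}": v for k, v in head_state.items()})
    arrays["__header__"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path, expect_config: EncoderConfig | None = None):
    """Load a checkpoint; refuses to load if the stored config disagrees
    with ``expect_config``.  Returns (config, encoder_state, head_state, meta).
    """
    with np.load(path) as npz:
        header = json.loads(bytes(npz["__header__"]).decode())
        if header.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ConfigurationError(
                f"unsupported checkpoint format {header.get('format_version')}"
            )
        config = EncoderConfig(**header["config"])
        if expect_config is not None and config != expect_config:
            raise ConfigurationError(
                f"checkpoint config {config} does not match requested "
                f"{expect_config}"
            )
        enc, head = {}, {}
        for key in npz.files:
            if key.startswith("encoder/"):
                enc[key[len("encoder/"):]] = npz[key]
            elif key.startswith("head/"):
                head[key[len("head/"):]] = npz[key]
    return config, enc, (head or None), header.get("meta", {})


def load_encoder(path, expect_config: EncoderConfig | None = None):
    """Convenience: instantiate a frozen encoder from a checkpoint."""
    config, enc_state, _, _ = load_checkpoint(path, expect_config)
    encoder = GeometricEncoder(config)
    encoder.load_state_dict(enc_state)
    return encoder
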