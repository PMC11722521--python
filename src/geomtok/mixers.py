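"""Learnable heads over token arrays.

Three families of token combiners feed a task MLP:

* pooling — sum/mean over tokens (no token interactions);
* SubMixer — an MLP-mixer alternating token-mixing and channel-mixing
  blocks over the fixed token grid;
* SubFormer — a transformer over the token sequence with an extra global
  token encoding the pairwise distances between per-token anchor atoms
  (e.g. Cα); its head-averaged attention maps are exposed for
  interpretation.

Optionally, rotation-invariant functions of the token vector channels
(norms, scalar-gated) are injected into the scalar channels first
("GVP enrichment"), so equivariant information reaches the mixer while
task outputs stay invariant.  Downstream heads consume scalar channels
only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, no_grad
from .errors import ConfigurationError, InputError
from .nn import LayerNorm, Linear, MLP, Module, Parameter

__all__ = ["MixerConfig", "MixerModel", "build_mixer", "pairwise_distances"]

_KINDS = ("pool", "submixer", "subformer", "submixer_gvp", "subformer_gvp")


@dataclass(frozen=True)
class MixerConfig:
    """Architecture of a token-mixer head.

    kind: one of pool | submixer | subformer | submixer_gvp | subformer_gvp.
    depth: mixer/transformer blocks.
    model_dim: working width after input projection.
    heads: attention heads (subformer only; model_dim % heads == 0).
    expansion: widening factor of the mixing MLPs.
    output_dim: task output dimension d_o.
    positional: learned per-token positional embeddings (token order
        matters for polymers; can be disabled to make the subformer
        permutation-equivariant).
    global_token: subformer prepends a distance-encoding global token;
        if disabled a learned start token is used instead.
    softmax_output: normalize task outputs to a probability simplex
        (the classic choice for state-membership features).
    """

    kind: str = "submixer"
    depth: int = 2
    model_dim: int = 64
    heads: int = 4
    expansion: float = 2.0
    output_dim: int = 2
    head_hidden: int = 64
    positional: bool = True
    global_token: bool = True
    softmax_output: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown mixer kind {self.kind!r}")
        if self.kind.startswith("subformer") and self.model_dim % self.heads:
            raise ConfigurationError("model_dim must be divisible by heads")
        if self.output_dim < 1:
            raise ConfigurationError("output_dim must be >= 1")


def pairwise_distances(anchor_coords: np.ndarray) -> np.ndarray:
    """Upper-triangular pairwise distances of per-token anchor atoms.

    anchor_coords: [M, 3] or [B, M, 3] → [P] or [B, P], P = M(M−1)/2.
    Rigid-motion invariant by construction.
    """
    c = np.asarray(anchor_coords, dtype=np.float64)
    single = c.ndim == 2
    if single:
        c = c[None]
    M = c.shape[1]
    if M < 2:
        raise InputError("global token needs at least 2 anchors")
    iu, ju = np.triu_indices(M, k=1)
    d = np.sqrt(((c[:, iu] - c[:, ju]) ** 2).sum(-1))
    return d[0] if single else d


class _GlobalTokenEncoder(Module):
    """Distances → model_dim vector via standardization + 2-layer MLP.

    Raw distances are unbounded, which destabilizes attention logits, so
    they are standardized by training-set mean/std (``fit``)."""

    def __init__(self, n_dists: int, model_dim: int, rng):
        self.mlp = MLP([n_dists, model_dim, model_dim], rng)
        self._mean = np.zeros(n_dists)
        self._std = np.ones(n_dists)

    def fit(self, dists: np.ndarray) -> None:
        self._mean = dists.mean(axis=0)
        self._std = np.maximum(dists.std(axis=0), 1e-8)

    def forward(self, dists: np.ndarray) -> Tensor:
        z = (np.atleast_2d(dists) - self._mean) / self._std
        return self.mlp(Tensor(z))


class _GVPEnrich(Module):
    """Inject invariant functions of vector channels into scalars.

    Channel-mixed vector norms are gated by scalar-derived sigmoids and
    concatenated with the scalars; an MLP maps back to the scalar width.
    """

    def __init__(self, d: int, rng):
        self.vec_mix = Linear(d, d, rng, bias=False)
        self.gate = Linear(d, d, rng)
        self.out = MLP([2 * d, d, d], rng)

    def forward(self, scalars: Tensor, vectors: Tensor) -> Tensor:
        vm = vectors @ self.vec_mix.weight
        norms = ((vm * vm).sum(axis=-2) + 1e-12).sqrt()
        gated = norms * self.gate(scalars).sigmoid()
        return self.out(concat([scalars, gated], axis=-1))


class _MixerBlock(Module):
    def __init__(self, n_tokens: int, dim: int, expansion: float, rng):
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.token_mlp = MLP([n_tokens, int(expansion * n_tokens), n_tokens], rng)
        self.channel_mlp = MLP([dim, int(expansion * dim), dim], rng)

    def forward(self, x: Tensor) -> Tensor:
        # token mixing operates across the token axis
        y = self.norm1(x).swapaxes(-1, -2)
        x = x + self.token_mlp(y).swapaxes(-1, -2)
        return x + self.channel_mlp(self.norm2(x))


class _AttentionBlock(Module):
    def __init__(self, dim: int, heads: int, expansion: float, rng):
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.wq = Linear(dim, dim, rng, bias=False)
        self.wk = Linear(dim, dim, rng, bias=False)
        self.wv = Linear(dim, dim, rng, bias=False)
        self.wo = Linear(dim, dim, rng, bias=False)
        self.mlp = MLP([dim, int(expansion * dim), dim], rng)
        self._heads = heads
        self._dh = dim // heads

    def forward(self, x: Tensor):
        B, L, D = x.shape
        H, dh = self._heads, self._dh
        h = self.norm1(x)

        def split(t):
            return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(h)), split(self.wk(h)), split(self.wv(h))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = logits.softmax(axis=-1)                      # [B, H, L, L]
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        x = x + self.wo(out)
        x = x + self.mlp(self.norm2(x))
        return x, attn.data.mean(axis=1)                    # head-averaged


class MixerModel(Module):
    """Token mixer + task head.

    forward(scalars [B, M, d_in], vectors [B, M, 3, d_in] for *_gvp,
    global_features [B, P] pairwise anchor distances for the subformer
    global token) → task outputs [B, output_dim].

    After a subformer forward, ``last_attention`` holds the per-layer
    head-averaged (M+1)×(M+1) attention maps.
    """

    def __init__(self, cfg: MixerConfig, input_dim: int, n_tokens: int,
                 n_global_dists: int | None = None):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self._n_tokens = n_tokens
        self.proj = Linear(input_dim, cfg.model_dim, rng)
        self.gvp = _GVPEnrich(input_dim, rng) if cfg.kind.endswith("_gvp") else None
        kind = cfg.kind.split("_")[0]
        self._base = kind
        D = cfg.model_dim
        if kind == "submixer":
            self.blocks = [_MixerBlock(n_tokens, D, cfg.expansion, rng)
                           for _ in range(cfg.depth)]
        elif kind == "subformer":
            self.blocks = [_AttentionBlock(D, cfg.heads, cfg.expansion, rng)
                           for _ in range(cfg.depth)]
            if cfg.global_token:
                n_global_dists = n_global_dists or n_tokens * (n_tokens - 1) // 2
                self.global_encoder = _GlobalTokenEncoder(n_global_dists, D, rng)
            else:
                self.cls = Parameter(rng.normal(0.0, 0.02, size=(1, 1, D)))
        else:
            self.blocks = []
        seq = n_tokens + (1 if kind == "subformer" else 0)
        if cfg.positional and kind in ("submixer", "subformer"):
            self.pos = Parameter(rng.normal(0.0, 0.02, size=(1, seq, D)))
        else:
            self.pos = None
        self.final_norm = LayerNorm(D) if kind != "pool" else None
        self.head = MLP([D, cfg.head_hidden, cfg.output_dim], rng)
        self.last_attention: list[np.ndarray] = []

    # -- pieces ---------------------------------------------------------------
    def make_global_token(self, anchor_coords: np.ndarray) -> np.ndarray:
        """Global token for one frame from anchor coordinates [M, 3]."""
        if self._base != "subformer" or not self.cfg.global_token:
            raise ConfigurationError("model has no global token encoder")
        d = pairwise_distances(anchor_coords)
        with no_grad():
            return self.global_encoder(d[None]).data[0]

    def mix(self, scalars, vectors=None, global_features=None) -> Tensor:
        """Token combination up to (not including) the task head."""
        x = scalars if isinstance(scalars, Tensor) else Tensor(scalars)
        if x.ndim != 3:
            raise InputError("scalars must be [B, M, d]")
        if x.shape[1] != self._n_tokens:
            raise ConfigurationError(
                f"model trained for M={self._n_tokens} tokens, got {x.shape[1]}"
            )
        if self.gvp is not None:
            if vectors is None:
                raise ConfigurationError("gvp-enriched mixer needs vector channels")
            v = vectors if isinstance(vectors, Tensor) else Tensor(vectors)
            x = self.gvp(x, v)
        x = self.proj(x)
        self.last_attention = []
        if self._base == "pool":
            return x.sum(axis=1)
        if self._base == "subformer":
            B = x.shape[0]
            if self.cfg.global_token:
                if global_features is None:
                    raise InputError(
                        "subformer configured with a global token requires "
                        "global_features (pairwise anchor distances)"
                    )
                g = self.global_encoder(global_features)
                g = g.reshape(g.shape[0], 1, g.shape[1])
            else:
                g = self.cls * Tensor(np.ones((B, 1, 1)))
            x = concat([g, x], axis=1)
        if self.pos is not None:
            x = x + self.pos
        if self._base == "submixer":
            for blk in self.blocks:
                x = blk(x)
            return self.final_norm(x).mean(axis=1)
        for blk in self.blocks:
            x, amap = blk(x)
            self.last_attention.append(amap)
        return self.final_norm(x)[:, 0, :]

    def forward(self, scalars, vectors=None, global_features=None) -> Tensor:
        feats = self.mix(scalars, vectors, global_features)
        out = self.head(feats)
        if self.cfg.softmax_output:
            out = out.softmax(axis=-1)
        return out

    def predict(self, scalars, vectors=None, global_features=None,
                batch_size: int = 4096) -> np.ndarray:
        """Inference in batches; deterministic."""
        outs = []
        n = len(scalars)
        with no_grad():
            for s in range(0, n, batch_size):
                outs.append(self.forward(
                    np.asarray(scalars[s:s + batch_size], dtype=np.float64),
                    None if vectors is None else
                    np.asarray(vectors[s:s + batch_size], dtype=np.float64),
                    None if global_features is None else
                    global_features[s:s + batch_size],
                ).data)
        return np.concatenate(outs, axis=0)


def build_mixer(cfg: MixerConfig, input_dim: int, n_tokens: int,
                global_dists: np.ndarray | None = None) -> MixerModel:
    """Construct a mixer; if training-set anchor distances are given the
    global-token standardizer is fit to them."""
    n_gd = None if global_dists is None else global_dists.shape[-1]
    model = MixerModel(cfg, input_dim, n_tokens, n_gd)
    if global_dists is not None and getattr(model, "global_encoder", None):
        model.global_encoder.fit(np.atleast_2d(global_dists))
    return model
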