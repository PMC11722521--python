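"""State Predictive Information Bottleneck (SPIB) and Markov state models.

SPIB learns metastable states by predicting the state label a trajectory
will carry a lag time τ ahead from the features now.  A Gaussian encoder
maps features x to a latent z ~ N(μ(x), Σ(x)) (diagonal Σ); a
categorical decoder q(s|z) predicts the future label; the objective

    E[ln q(s_τ | z)] − β · E[ln p(z|x) − ln r(z)]

trades prediction accuracy against latent complexity, with a
mixture-of-posteriors prior r(z) = Σᵢ ωᵢ p(z|uᵢ) / Σᵢ ωᵢ over learned
pseudo-inputs uᵢ.  Labels start from k-means clusters and are refreshed
during training by s ← argmax_s q(s | μ(x)); unpredictable fine-grained
clusters merge, so the number of populated labels decays toward the
number of metastable states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .autodiff import Tensor, no_grad
from .errors import InputError, TrainingError
from .featurize import FeatureStore
from .nn import Adam, MLP, Module, Parameter

__all__ = ["SpibConfig", "StateLabels", "SpibModel", "init_labels",
           "train_spib", "SpibResult", "build_msm"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class SpibConfig:
    """SPIB hyperparameters.

    beta controls state merging: larger β compresses the latent space
    harder and merges states more aggressively.  refresh_interval is the
    number of gradient steps between label refreshes; it must be long
    enough for the decoder to converge between refreshes — relabeling
    with an underconverged decoder assigns near-arbitrary argmax labels
    and merges states irreversibly.
    """

    latent_dim: int = 2
    beta: float = 0.01
    lag: int = 1
    init_k: int = 100
    refresh_interval: int = 1000
    n_pseudo: int = 10
    batch_size: int = 1000
    hidden: int = 64
    learning_rate: float = 2e-3
    n_steps: int = 4000
    seed: int = 0

    def __post_init__(self):
        if self.beta < 0:
            raise InputError("beta must be >= 0")
        if min(self.latent_dim, self.lag, self.init_k, self.n_pseudo) < 1:
            raise InputError("latent_dim, lag, init_k, n_pseudo must be >= 1")


@dataclass
class StateLabels:
    """Per-frame integer labels in [0, init_k)."""

    labels: np.ndarray

    @property
    def populated(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def populated_count(self) -> int:
        return len(self.populated)


def init_labels(cv_series: np.ndarray, k: int,
                rng: np.random.Generator | int = 0) -> StateLabels:
    """k-means clustering of a CV time series into k initial labels."""
    cv = np.asarray(cv_series, dtype=np.float64)
    if cv.ndim == 1:
        cv = cv[:, None]
    if cv.shape[0] < k:
        raise InputError(f"need at least k={k} frames, got {cv.shape[0]}")
    seed = rng if isinstance(rng, (int, np.integer)) \
        else int(rng.integers(2 ** 31))
    km = KMeans(n_clusters=k, random_state=int(seed), n_init=10)
    return StateLabels(km.fit_predict(cv).astype(np.intp))


class SpibModel(Module):
    """Gaussian encoder + categorical decoder + VampPrior."""

    def __init__(self, input_dim: int, cfg: SpibConfig,
                 pseudo_init: np.ndarray | None = None):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.enc = MLP([input_dim, cfg.hidden, 2 * cfg.latent_dim], rng)
        self.dec = MLP([cfg.latent_dim, cfg.hidden, cfg.init_k], rng)
        if pseudo_init is None:
            pseudo_init = rng.normal(size=(cfg.n_pseudo, input_dim))
        self.pseudo = Parameter(np.asarray(pseudo_init, dtype=np.float64))
        self.log_omega = Parameter(np.zeros(cfg.n_pseudo))

    # -- pieces ---------------------------------------------------------------
    def posterior(self, x: Tensor):
        """μ(x), log σ²(x) of the Gaussian posterior (diagonal Σ)."""
        h = self.enc(x)
        L = self.cfg.latent_dim
        mu, logvar = h[:, :L], h[:, L:]
        # bounded log-variance, biased small at init so the latent starts
        # informative (a wide posterior would let the decoder ignore z)
        logvar = logvar.tanh() * 4.0 - 2.0
        return mu, logvar

    def encode_latent(self, x, rng: np.random.Generator):
        """Reparameterized sample: z = μ + σ·ε, ε ~ N(0, I)."""
        x = x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x))
        mu, logvar = self.posterior(x)
        eps = rng.normal(size=mu.shape)
        z = mu + (logvar * 0.5).exp() * Tensor(eps)
        return z, (mu, logvar)

    def decode_state(self, z) -> Tensor:
        """q(s|z): probabilities over the init_k labels (rows sum to 1)."""
        z = z if isinstance(z, Tensor) else Tensor(np.atleast_2d(z))
        return self.dec(z).softmax(axis=-1)

    def _component_logpdf(self, z: Tensor) -> Tensor:
        """log N(z; μ(uᵢ), Σ(uᵢ)) for each pseudo-input: [B, n_pseudo]."""
        mu_u, logvar_u = self.posterior(self.pseudo)
        B, L = z.shape
        K = mu_u.shape[0]
        zb = z.reshape(B, 1, L)
        mub = mu_u.reshape(1, K, L)
        lvb = logvar_u.reshape(1, K, L)
        diff = zb - mub
        return ((diff * diff) * (-lvb).exp() + lvb + _LOG2PI).sum(axis=-1) * -0.5

    def log_prior(self, z: Tensor) -> Tensor:
        """ln r(z) under the mixture-of-posteriors prior."""
        comp = self._component_logpdf(z)
        logw = self.log_omega.log_softmax(axis=-1)
        x = comp + logw.reshape(1, -1)
        m = Tensor(x.data.max(axis=-1, keepdims=True))
        return ((x - m).exp().sum(axis=-1, keepdims=True)).log() + m

    def vamp_prior_density(self, z) -> np.ndarray:
        z = z if isinstance(z, Tensor) else Tensor(np.atleast_2d(z))
        with no_grad():
            return np.exp(self.log_prior(z).data[:, 0])

    def loss(self, x: np.ndarray, labels_tau: np.ndarray,
             rng: np.random.Generator) -> Tensor:
        """Negative SPIB objective (Monte Carlo, one z sample per datum)."""
        xt = Tensor(np.asarray(x, dtype=np.float64))
        z, (mu, logvar) = self.encode_latent(xt, rng)
        logq = self.dec(z).log_softmax(axis=-1)
        idx = (np.arange(len(labels_tau)), np.asarray(labels_tau, dtype=np.intp))
        pred_term = logq[idx].mean()
        # ln p(z|x) at the sampled z
        diff = z - mu
        logp = (((diff * diff) * (-logvar).exp() + logvar + _LOG2PI)
                .sum(axis=-1) * -0.5)
        logr = self.log_prior(z).reshape(logp.shape)
        kl_term = (logp - logr).mean()
        return -(pred_term - self.cfg.beta * kl_term)

    def refine_labels(self, x: np.ndarray, batch_size: int = 8192) -> StateLabels:
        """Deterministic relabeling s = argmax q(s | μ(x)); ties broken by
        the lowest label index."""
        out = []
        with no_grad():
            for s in range(0, len(x), batch_size):
                mu, _ = self.posterior(Tensor(np.asarray(
                    x[s:s + batch_size], dtype=np.float64)))
                probs = self.decode_state(mu)
                out.append(np.argmax(probs.data, axis=-1))
        return StateLabels(np.concatenate(out).astype(np.intp))


@dataclass
class SpibResult:
    model: SpibModel
    labels: StateLabels
    populated_trace: list = field(default_factory=list)  # (step, count)
    loss_history: list = field(default_factory=list)

    @property
    def final_populated_count(self) -> int:
        return self.labels.populated_count


def _as_matrix(store) -> np.ndarray:
    if isinstance(store, FeatureStore):
        T = store.n_frames
        return np.asarray(store.scalars, dtype=np.float64).reshape(T, -1)
    x = np.asarray(store, dtype=np.float64)
    return x.reshape(len(x), -1)


def train_spib(store, cfg: SpibConfig, split,
               initial_labels: StateLabels | None = None,
               backbone=None) -> SpibResult:
    """Train SPIB on token features or a CV series.

    ``store`` may be a FeatureStore (token scalars are flattened per
    frame, or passed through ``backbone.mix`` if a mixer is given) or a
    plain [T, p] array such as VAMPnet CVs.  ``split`` = (train_idx,
    val_idx) temporal split; training pairs (t, t+τ) stay in the train
    range.  Labels are refreshed by the decoder-argmax rule every
    ``refresh_interval`` steps and the populated-state count is recorded
    at every refresh.
    """
    x = _as_matrix(store)
    if backbone is not None:
        feats = []
        with no_grad():
            scal = np.asarray(store.scalars, dtype=np.float64)
            for s in range(0, len(scal), 4096):
                feats.append(backbone.mix(scal[s:s + 4096]).data)
        x = np.concatenate(feats)
    T = x.shape[0]
    rng = np.random.default_rng(cfg.seed)
    train_idx, _ = (np.asarray(s, dtype=np.intp) for s in split)

    if initial_labels is None:
        initial_labels = init_labels(x, cfg.init_k, rng)
    labels = np.asarray(initial_labels.labels, dtype=np.intp).copy()
    if labels.shape[0] != T:
        raise InputError("initial labels must cover every frame")

    mask = np.zeros(T, dtype=bool)
    mask[train_idx] = True
    cand = np.arange(T - cfg.lag)
    starts = cand[mask[cand] & mask[cand + cfg.lag]]
    if len(starts) == 0:
        raise InputError(f"no training pairs at lag {cfg.lag}")

    pseudo_init = x[rng.choice(train_idx, size=cfg.n_pseudo, replace=False)]
    model = SpibModel(x.shape[1], cfg, pseudo_init)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    refresh = cfg.refresh_interval

    result = SpibResult(model, StateLabels(labels))
    result.populated_trace.append((0, len(np.unique(labels))))
    for step in range(1, cfg.n_steps + 1):
        t0 = rng.choice(starts, size=min(cfg.batch_size, len(starts)),
                        replace=True)
        loss = model.loss(x[t0], labels[t0 + cfg.lag], rng)
        if not np.isfinite(loss.item()):
            raise TrainingError("SPIB loss diverged", log=result.loss_history)
        opt.zero_grad()
        loss.backward()
        opt.step()
        result.loss_history.append((step, loss.item()))
        if step % refresh == 0:
            labels = model.refine_labels(x).labels
            result.populated_trace.append((step, len(np.unique(labels))))
    result.labels = StateLabels(model.refine_labels(x).labels)
    return result


def build_msm(labels: StateLabels | np.ndarray, lag: int):
    """Row-stochastic transition matrix over populated states at ``lag``.

    Returns (P_hat [K, K], occupancy [K], state_ids [K]) where state_ids
    maps rows back to the original label values.  A populated state with
    no outgoing transition at this lag gets an imputed self-loop (with a
    warning)."""
    lab = labels.labels if isinstance(labels, StateLabels) else \
        np.asarray(labels, dtype=np.intp)
    T = len(lab)
    if T <= lag:
        raise InputError("need more frames than the lag")
    state_ids, dense = np.unique(lab, return_inverse=True)
    K = len(state_ids)
    counts = np.zeros((K, K))
    np.add.at(counts, (dense[:-lag], dense[lag:]), 1.0)
    rowsum = counts.sum(axis=1)
    empty = rowsum == 0
    if np.any(empty):
        warnings.warn(
            f"states {state_ids[empty]} have no outgoing counts at lag "
            f"{lag}; imputing self-loops"
        )
        counts[empty, empty] = 1.0
        rowsum = counts.sum(axis=1)
    P = counts / rowsum[:, None]
    occupancy = np.bincount(dense, minlength=K) / T
    return P, occupancy, state_ids
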