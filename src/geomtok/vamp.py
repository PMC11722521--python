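"""VAMP-2 scoring and VAMPnet training over token features.

The variational approach for Markov processes (VAMP) states that the
feature functions χ maximizing

    ‖C00^{-1/2} C0τ Cττ^{-1/2}‖²_F

(the VAMP-2 score, with C00/C0τ/Cττ the instantaneous and time-lagged
feature correlation matrices at lag τ) span the slowest decorrelating
modes of the dynamics.  Here χ is a token mixer + MLP head applied to
frozen encoder tokens; one shared network provides both the t and t+τ
lobes.  Training maximizes the score by gradient ascent on randomly
drawn lagged frame pairs, with dual-patience early stopping: halt when
the training score has not improved for ``train_patience`` batches or
the validation score has not improved for ``val_patience`` consecutive
evaluations (validation is scored every ``val_every`` steps).

Large batches matter: the score inverts the empirical correlation
matrices, which are ill-conditioned for small batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, no_grad
from .errors import ConfigurationError, InputError, NumericalError
from .featurize import FeatureStore
from .mixers import MixerConfig, MixerModel, build_mixer
from .nn import Adam

__all__ = ["LaggedPairs", "CorrelationTriple", "VampTrainConfig",
           "sample_lagged_pairs", "correlation_matrices", "inv_sqrt",
           "vamp2_score", "train_vampnet", "evaluate_cvs", "VampResult"]


@dataclass
class LaggedPairs:
    """Frame-index pairs (t, t+τ) in global frame numbering; pairs never
    span trajectory boundaries."""

    t0: np.ndarray
    t1: np.ndarray
    lag: int


def sample_lagged_pairs(n_frames_per_traj, tau: int, batch: int,
                        rng: np.random.Generator,
                        admissible: np.ndarray | None = None) -> LaggedPairs:
    """Uniformly sample ``batch`` pairs spaced by exactly ``tau`` frames.

    ``admissible`` optionally restricts the candidate start frames (in
    global numbering) — used to honor train/validation splits.
    """
    if tau < 0:
        raise InputError("tau must be >= 0")
    lengths = np.atleast_1d(np.asarray(n_frames_per_traj, dtype=np.intp))
    if np.any(lengths <= tau):
        raise InputError(f"every trajectory must be longer than tau={tau}")
    starts = []
    offset = 0
    for L in lengths:
        starts.append(offset + np.arange(L - tau))
        offset += L
    starts = np.concatenate(starts)
    if admissible is not None:
        admissible = np.asarray(admissible, dtype=np.intp)
        starts = starts[np.isin(starts, admissible)
                        & np.isin(starts + tau, admissible)]
    if len(starts) == 0:
        raise InputError("no admissible lagged pairs")
    t0 = rng.choice(starts, size=batch, replace=True)
    return LaggedPairs(t0, t0 + tau, tau)


@dataclass
class CorrelationTriple:
    C00: np.ndarray
    C0t: np.ndarray
    Ctt: np.ndarray


def correlation_matrices(A: np.ndarray, B: np.ndarray,
                         center: bool = True) -> CorrelationTriple:
    """Empirical C00 = AᵀA/n, C0τ = AᵀB/n, Cττ = BᵀB/n with optional
    column-mean centering of each block."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape != B.shape or A.ndim != 2:
        raise InputError("A and B must be matching [n, d] arrays")
    n = A.shape[0]
    if center:
        if n < 2:
            raise InputError("centering requires n >= 2")
        A = A - A.mean(axis=0)
        B = B - B.mean(axis=0)
    return CorrelationTriple(A.T @ A / n, A.T @ B / n, B.T @ B / n)


def inv_sqrt(S: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Regularized S^{-1/2}: eigenvalues floored at eps·λ_max."""
    S = np.asarray(S, dtype=np.float64)
    if not np.allclose(S, S.T, atol=1e-8 * max(1.0, np.abs(S).max())):
        raise InputError("matrix is not symmetric")
    lam, U = np.linalg.eigh(0.5 * (S + S.T))
    floor = eps * max(lam.max(), np.finfo(float).tiny)
    lam = np.maximum(lam, floor)
    return (U * lam ** -0.5) @ U.T


def vamp2_score(triple: CorrelationTriple, eps: float = 1e-6) -> float:
    """Squared Frobenius norm of the whitened time-lagged correlation."""
    K = inv_sqrt(triple.C00, eps) @ triple.C0t @ inv_sqrt(triple.Ctt, eps)
    score = float((K ** 2).sum())
    if not np.isfinite(score):
        c00, ctt = np.linalg.cond(triple.C00), np.linalg.cond(triple.Ctt)
        raise NumericalError(
            f"non-finite VAMP-2 score (cond C00={c00:.2e}, Cττ={ctt:.2e})"
        )
    return score


def _vamp2_loss(chi0: Tensor, chit: Tensor, center: bool, eps: float) -> Tensor:
    """Differentiable negative VAMP-2 via the trace identity
    tr(C00⁻¹ C0τ Cττ⁻¹ C0τᵀ) with ridge regularization."""
    n = chi0.shape[0]
    if center:
        chi0 = chi0 - chi0.mean(axis=0, keepdims=True)
        chit = chit - chit.mean(axis=0, keepdims=True)
    scale = 1.0 / n
    C00 = (chi0.transpose() @ chi0) * scale
    C0t = (chi0.transpose() @ chit) * scale
    Ctt = (chit.transpose() @ chit) * scale
    d = C00.shape[0]
    ridge0 = eps * max(float(np.trace(C00.data)) / d, 1e-12)
    ridget = eps * max(float(np.trace(Ctt.data)) / d, 1e-12)
    inv00 = (C00 + Tensor(ridge0 * np.eye(d))).inv()
    invtt = (Ctt + Tensor(ridget * np.eye(d))).inv()
    score = ((inv00 @ C0t) * (C0t @ invtt.transpose())).sum()
    return -score


@dataclass(frozen=True)
class VampTrainConfig:
    """Training protocol for a VAMPnet head.

    batch_size below ~1000 risks ill-conditioned correlation matrices; a
    warning is attached rather than an error.  The training-patience
    default follows the main early-stopping rule (500 batches); the
    alternative 1000-batch rule used for timing runs is available by
    configuration.
    """

    output_dim: int = 2
    lag: int = 1
    batch_size: int = 5000
    val_every: int = 10
    train_patience: int = 500
    val_patience: int = 10
    learning_rate: float = 3e-4
    eps: float = 1e-6
    center: bool = True
    max_steps: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.lag < 1:
            raise InputError("lag must be >= 1")
        if self.batch_size < 1:
            raise InputError("batch_size must be >= 1")


@dataclass
class VampResult:
    model: MixerModel
    history: list = field(default_factory=list)   # (step, train, val|None)
    best_val_score: float = -np.inf               # best sampled-batch score
    final_val_score: float = np.nan               # best model, full val set
    best_step: int = -1
    stopped_by: str = ""

    @property
    def score_trace(self) -> np.ndarray:
        return np.array([(s, tr, np.nan if v is None else v)
                         for s, tr, v in self.history])


def _as_features(store):
    if isinstance(store, FeatureStore):
        return (np.asarray(store.scalars, dtype=np.float64),
                np.asarray(store.vectors, dtype=np.float64))
    return np.asarray(store, dtype=np.float64), None


def train_vampnet(store, mixer_cfg: MixerConfig, cfg: VampTrainConfig,
                  split, global_features: np.ndarray | None = None,
                  ) -> VampResult:
    """Maximize the VAMP-2 score of a mixer head over token features.

    ``split`` is a (train_indices, val_indices) pair of frame index
    arrays (a temporal split); both members of every sampled pair stay
    within their set.  Returns the best-validation model and the full
    train/validation score trace.
    """
    scalars, vectors = _as_features(store)
    T = scalars.shape[0]
    train_idx, val_idx = (np.asarray(s, dtype=np.intp) for s in split)
    if np.intersect1d(train_idx, val_idx).size:
        raise InputError("train and validation indices overlap")
    rng = np.random.default_rng(cfg.seed)

    mask_train = np.zeros(T, dtype=bool)
    mask_train[train_idx] = True
    mask_val = np.zeros(T, dtype=bool)
    mask_val[val_idx] = True
    tau = cfg.lag
    cand = np.arange(T - tau)
    train_starts = cand[mask_train[cand] & mask_train[cand + tau]]
    val_starts = cand[mask_val[cand] & mask_val[cand + tau]]
    if len(train_starts) == 0 or len(val_starts) == 0:
        raise InputError(f"no admissible pairs at lag {tau} within the split")

    model = build_mixer(
        mixer_cfg, scalars.shape[-1], scalars.shape[1],
        None if global_features is None else global_features[train_idx],
    )
    opt = Adam(model.parameters(), lr=cfg.learning_rate)

    def batch_inputs(t_idx):
        gf = None if global_features is None else global_features[t_idx]
        vec = None if vectors is None or model.gvp is None else vectors[t_idx]
        return scalars[t_idx], vec, gf

    def val_score() -> float:
        t0 = rng.choice(val_starts, size=min(cfg.batch_size, len(val_starts)),
                        replace=True)
        with no_grad():
            chi0 = model.forward(*batch_inputs(t0))
            chit = model.forward(*batch_inputs(t0 + tau))
        triple = correlation_matrices(chi0.data, chit.data, center=cfg.center)
        return vamp2_score(triple, cfg.eps)

    result = VampResult(model)
    best_train = -np.inf
    since_train_improve = 0
    since_val_improve = 0
    best_state = model.state_dict()

    for step in range(1, cfg.max_steps + 1):
        t0 = rng.choice(train_starts, size=min(cfg.batch_size,
                                               len(train_starts)), replace=True)
        chi0 = model.forward(*batch_inputs(t0))
        chit = model.forward(*batch_inputs(t0 + tau))
        loss = _vamp2_loss(chi0, chit, cfg.center, cfg.eps)
        if not np.isfinite(loss.item()):
            raise NumericalError(
                "VAMP-2 loss became non-finite while inverting correlation "
                "matrices; increase batch_size (>= 1000 recommended) or eps"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        train_score = -loss.item()

        if train_score > best_train + 1e-12:
            best_train = train_score
            since_train_improve = 0
        else:
            since_train_improve += 1

        vscore = None
        if step % cfg.val_every == 0:
            vscore = val_score()
            if vscore > result.best_val_score + 1e-12:
                result.best_val_score = vscore
                result.best_step = step
                best_state = model.state_dict()
                since_val_improve = 0
            else:
                since_val_improve += 1
        result.history.append((step, train_score, vscore))

        if since_train_improve >= cfg.train_patience:
            result.stopped_by = "train_patience"
            break
        if since_val_improve >= cfg.val_patience:
            result.stopped_by = "val_patience"
            break
    else:
        result.stopped_by = "max_steps"

    model.load_state_dict(best_state)
    # report the best checkpoint's score over the whole validation set:
    # scoring on sampled batches and keeping the maximum selects upward
    # noise, so the headline number uses every admissible pair once
    t0 = val_starts if len(val_starts) <= 20_000 else \
        val_starts[np.linspace(0, len(val_starts) - 1, 20_000).astype(np.intp)]
    with no_grad():
        chi0 = model.forward(*batch_inputs(t0))
        chit = model.forward(*batch_inputs(t0 + tau))
    result.final_val_score = vamp2_score(
        correlation_matrices(chi0.data, chit.data, center=cfg.center), cfg.eps)
    return result


def evaluate_cvs(model: MixerModel, store,
                 global_features: np.ndarray | None = None,
                 batch_size: int = 4096) -> np.ndarray:
    """Per-frame CV values [T, d_o] of a trained VAMPnet (deterministic)."""
    scalars, vectors = _as_features(store)
    if model.gvp is None:
        vectors = None
    return model.predict(scalars, vectors, global_features, batch_size)
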