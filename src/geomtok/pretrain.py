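"""Self-supervised pretraining of the encoder by coordinate denoising.

Conformer coordinates are corrupted with isotropic Gaussian noise and the
encoder plus a gated equivariant head are trained to predict the added
displacements (normalized to zero mean and unit variance over the
training split).  The mean squared error against normalized targets has
a natural baseline of 1.0 — the loss of always predicting zero — so any
validation MSE below 1 means the network has learned geometry.

Pretraining is a one-time step: downstream modules consume the frozen
checkpoint and never update encoder parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .encoder import (EncoderConfig, GatedEquivariantHead, GeometricEncoder,
                      save_checkpoint)
from .errors import InputError, TrainingError
from .nn import Adam

__all__ = ["DenoiseConfig", "NoiseSample", "corrupt", "denoise_loss",
           "train_denoiser", "DenoiseResult"]


@dataclass(frozen=True)
class DenoiseConfig:
    sigma: float = 0.2          # noise scale, Å
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    val_fraction: float = 0.1   # conformers held out for validation
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise InputError("sigma must be >= 0")
        if not 0.0 < self.val_fraction < 1.0:
            raise InputError("val_fraction must be in (0, 1)")


@dataclass
class NoiseSample:
    clean: np.ndarray
    noisy: np.ndarray
    target: np.ndarray   # displacements, normalized if stats supplied


def corrupt(coords: np.ndarray, sigma: float, rng: np.random.Generator,
            norm: tuple[float, float] = (0.0, 1.0)) -> NoiseSample:
    """Add i.i.d. Normal(0, σ²) displacements per coordinate component.

    ``norm`` = (mean, std) of the dataset normalization applied to the
    raw displacements to form the regression target.
    """
    if sigma < 0:
        raise InputError("sigma must be >= 0")
    coords = np.asarray(coords, dtype=np.float64)
    raw = rng.normal(0.0, sigma, size=coords.shape) if sigma > 0 \
        else np.zeros_like(coords)
    mean, std = norm
    return NoiseSample(coords, coords + raw, (raw - mean) / std)


def denoise_loss(pred: np.ndarray, target: np.ndarray) -> float:
    if np.shape(pred) != np.shape(target):
        raise InputError(f"shape mismatch {np.shape(pred)} vs {np.shape(target)}")
    return float(np.mean((np.asarray(pred) - np.asarray(target)) ** 2))


@dataclass
class DenoiseResult:
    encoder: GeometricEncoder        # loaded with the best-validation params
    head: GatedEquivariantHead
    log: list                        # (epoch, train_mse, val_mse)
    best_epoch: int
    best_val_mse: float
    norm_mean: float
    norm_std: float

    def save(self, path) -> None:
        save_checkpoint(
            path, self.encoder.config, self.encoder.state_dict(),
            head_state=self.head.state_dict(),
            meta={"best_epoch": self.best_epoch,
                  "best_val_mse": self.best_val_mse,
                  "norm_mean": self.norm_mean, "norm_std": self.norm_std},
        )


def train_denoiser(coords: np.ndarray, atom_numbers: np.ndarray,
                   encoder_cfg: EncoderConfig, cfg: DenoiseConfig,
                   ) -> DenoiseResult:
    """Train encoder + gated head to predict added displacements.

    ``coords``: conformer dataset [n, N, 3] sharing one topology.  The
    corruption is drawn once per run (fixed-noise dataset); displacement
    normalization statistics are scalars computed on the training split
    only.  The checkpoint returned is the epoch with the lowest
    validation MSE.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 3 or coords.shape[0] == 0:
        raise InputError("dataset must be non-empty [n, N, 3]")
    n = coords.shape[0]
    rng = np.random.default_rng(cfg.seed)

    # validation conformers drawn at random, disjoint from training
    n_val = max(1, int(round(cfg.val_fraction * n)))
    if n_val >= n:
        raise InputError("validation split leaves no training data")
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    raw = rng.normal(0.0, cfg.sigma, size=coords.shape)
    mean = float(raw[train_idx].mean())
    std = float(raw[train_idx].std())
    if std == 0.0:
        std = 1.0
    noisy = coords + raw
    targets = (raw - mean) / std

    encoder = GeometricEncoder(encoder_cfg)
    head = GatedEquivariantHead(encoder_cfg.d, seed=encoder_cfg.seed + 1)
    params = encoder.parameters() + head.parameters()
    opt = Adam(params, lr=cfg.learning_rate)

    def forward_mse(batch_noisy, batch_targets, train: bool):
        x, v = encoder.forward_trainable(batch_noisy, atom_numbers)
        pred = head(x, v)
        diff = pred - Tensor(batch_targets.reshape(-1, 3))
        loss = (diff * diff).mean()
        if train:
            opt.zero_grad()
            loss.backward()
            opt.step()
        return loss.item()

    log = []
    best = (np.inf, None, None, -1)
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        train_losses = []
        for s in range(0, len(order), cfg.batch_size):
            b = order[s:s + cfg.batch_size]
            train_losses.append(forward_mse(noisy[b], targets[b], train=True))
        from .autodiff import no_grad
        with no_grad():
            val_losses = [
                forward_mse(noisy[val_idx[s:s + cfg.batch_size]],
                            targets[val_idx[s:s + cfg.batch_size]], train=False)
                for s in range(0, n_val, cfg.batch_size)
            ]
        train_mse = float(np.mean(train_losses))
        val_mse = float(np.mean(val_losses))
        if not (np.isfinite(train_mse) and np.isfinite(val_mse)):
            raise TrainingError("denoising loss diverged", log=log)
        log.append((epoch, train_mse, val_mse))
        if val_mse < best[0]:
            best = (val_mse, encoder.state_dict(), head.state_dict(), epoch)

    best_val, enc_state, head_state, best_epoch = best
    encoder.load_state_dict(enc_state)
    head.load_state_dict(head_state)
    return DenoiseResult(encoder, head, log, best_epoch, best_val, mean, std)
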