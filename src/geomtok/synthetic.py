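"""Synthetic benchmark systems with known ground truth.

These generators provide the test bed for the whole pipeline:

* finite-state Markov chains whose transfer-operator eigenvalues are the
  analytic oracle for the VAMP-2 score;
* 2-D overdamped Langevin dynamics on double- and triple-well potentials
  with known slow coordinates and metastable basins;
* small chain-molecule conformer templates so that discrete states or
  continuous 2-D paths can be embedded as all-atom coordinate
  trajectories, letting the encoder → tokens → mixer → head pipeline run
  on data whose slow modes are known exactly;
* the temporal train/validation split (first half trains, second half
  validates — never a random split, which leaks information between
  time-correlated frames).

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InputError, NumericalError

__all__ = [
    "MarkovChainSpec",
    "LangevinSpec",
    "ConformerTemplateSet",
    "three_state_chain",
    "two_state_chain",
    "simulate_markov_chain",
    "potential_energy",
    "potential_gradient",
    "simulate_langevin_2d",
    "make_template_set",
    "gen_toy_conformers",
    "embed_states_as_conformers",
    "temporal_split",
    "kabsch_rmsd",
]


# -- finite-state chains ------------------------------------------------------

@dataclass(frozen=True)
class MarkovChainSpec:
    """Row-stochastic transition matrix with derived spectral quantities."""

    P: np.ndarray

    def __post_init__(self):
        P = np.asarray(self.P, dtype=np.float64)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise InputError("P must be square")
        if np.any(P < -1e-12) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
            raise InputError("P must be row-stochastic")
        object.__setattr__(self, "P", P)

    @property
    def n_states(self) -> int:
        return self.P.shape[0]

    @property
    def stationary(self) -> np.ndarray:
        """Left Perron eigenvector, normalized to a distribution."""
        w, vl = np.linalg.eig(self.P.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(vl[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    @property
    def eigenvalues(self) -> np.ndarray:
        """Transfer-operator eigenvalues, sorted by decreasing magnitude."""
        w = np.linalg.eigvals(self.P)
        return w[np.argsort(-np.abs(w))]

    def vamp2_oracle(self, k: int | None = None) -> float:
        """Sum of the squared top-k transfer-operator eigenvalues — the
        VAMP-2 score of uncentered one-hot features at stationarity
        (for reversible chains singular values equal |eigenvalues|)."""
        lam = np.abs(self.eigenvalues)
        if k is not None:
            lam = lam[:k]
        return float((lam ** 2).sum())


def two_state_chain() -> MarkovChainSpec:
    """Eigenvalues {1, 0.7}; stationary distribution (2/3, 1/3)."""
    return MarkovChainSpec(np.array([[0.9, 0.1], [0.2, 0.8]]))


def three_state_chain() -> MarkovChainSpec:
    """Reversible chain with uniform stationary distribution and
    transfer-operator eigenvalues exactly {1, 0.9, 0.7}.

    Constructed spectrally: P = (1/3)·J + 0.9·u₂u₂ᵀ + 0.7·u₃u₃ᵀ with
    u₂ = (1,−1,0)/√2 and u₃ = (1,1,−2)/√6.
    """
    u2 = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
    u3 = np.array([1.0, 1.0, -2.0]) / np.sqrt(6)
    P = np.full((3, 3), 1.0 / 3.0) + 0.9 * np.outer(u2, u2) + 0.7 * np.outer(u3, u3)
    P[np.abs(P) < 1e-15] = 0.0
    return MarkovChainSpec(P)


def simulate_markov_chain(spec: MarkovChainSpec, T: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Sample a length-T state sequence starting from stationarity."""
    if T < 1:
        raise InputError("T must be >= 1")
    K = spec.n_states
    cdf = np.cumsum(spec.P, axis=1)
    states = np.empty(T, dtype=np.intp)
    states[0] = rng.choice(K, p=spec.stationary)
    u = rng.random(T)
    for t in range(1, T):
        states[t] = np.searchsorted(cdf[states[t - 1]], u[t])
    return states


# -- 2-D Langevin dynamics ----------------------------------------------------

@dataclass(frozen=True)
class LangevinSpec:
    """Overdamped Langevin dynamics on a named 2-D potential.

    potential: "double_well" (quartic in x, harmonic in y; minima at
        x = ±1, barrier ``barrier`` in kT at kT=1, optional linear
        ``tilt``·x) or "triple_well" (sextic u²(u²−1)² with u = x/2:
        minima at x ∈ {−2, 0, 2}, equal depths, barrier ``barrier``;
        the widened wells keep curvatures moderate so the default time
        step integrates stably).
    kT: thermal energy (sets noise amplitude).
    friction: γ in dr = −∇V dt/γ + √(2 kT dt/γ) dW.
    dt: integration step; n_steps: total steps; stride: saved every
    ``stride`` steps; x0: initial position.
    """

    potential: str = "double_well"
    kT: float = 1.0
    friction: float = 1.0
    dt: float = 0.005
    n_steps: int = 100_000
    stride: int = 10
    barrier: float = 3.0
    tilt: float = 0.0
    y_stiffness: float = 2.0
    x0: tuple = (1.0, 0.0)


def potential_energy(spec: LangevinSpec, xy: np.ndarray) -> np.ndarray:
    xy = np.asarray(xy, dtype=np.float64)
    x, y = xy[..., 0], xy[..., 1]
    if spec.potential == "double_well":
        return spec.barrier * (x ** 2 - 1.0) ** 2 + spec.tilt * x \
            + 0.5 * spec.y_stiffness * y ** 2
    if spec.potential == "triple_well":
        # u²(u²−1)², u = x/2: equal-depth minima at −2, 0, 2; the factor
        # 27/4 normalizes the barrier height to ``barrier``
        h = spec.barrier * 27.0 / 4.0
        u = x / 2.0
        return h * u ** 2 * (u ** 2 - 1.0) ** 2 + spec.tilt * x \
            + 0.5 * spec.y_stiffness * y ** 2
    raise InputError(f"unknown potential {spec.potential!r}")


def potential_gradient(spec: LangevinSpec, xy: np.ndarray) -> np.ndarray:
    xy = np.asarray(xy, dtype=np.float64)
    x, y = xy[..., 0], xy[..., 1]
    if spec.potential == "double_well":
        gx = 4.0 * spec.barrier * x * (x ** 2 - 1.0) + spec.tilt
    elif spec.potential == "triple_well":
        h = spec.barrier * 27.0 / 4.0
        u = x / 2.0
        gx = h * u * (u ** 2 - 1.0) * (3.0 * u ** 2 - 1.0) + spec.tilt
    else:
        raise InputError(f"unknown potential {spec.potential!r}")
    gy = spec.y_stiffness * y
    return np.stack([gx, gy], axis=-1)


def simulate_langevin_2d(spec: LangevinSpec, rng: np.random.Generator,
                         bound: float = 1e3) -> np.ndarray:
    """Euler–Maruyama integration; returns positions [T, 2] where
    T = n_steps // stride."""
    r = np.asarray(spec.x0, dtype=np.float64).copy()
    amp = np.sqrt(2.0 * spec.kT * spec.dt / spec.friction)
    noise = rng.normal(size=(spec.n_steps, 2))
    n_out = spec.n_steps // spec.stride
    out = np.empty((n_out, 2))
    k = 0
    for step in range(spec.n_steps):
        r = r - potential_gradient(spec, r) * (spec.dt / spec.friction) \
            + amp * noise[step]
        if not np.all(np.abs(r) < bound):
            raise NumericalError(
                f"Langevin integration diverged at step {step}; reduce dt"
            )
        if (step + 1) % spec.stride == 0:
            out[k] = r
            k += 1
    return out


# -- conformer templates ------------------------------------------------------

@dataclass
class ConformerTemplateSet:
    """K template geometries sharing one bonded chain topology.

    Residues are 4-atom units (N, C, C, O) chained head-to-tail with
    1.5 Å bonds; templates must be mutually distinguishable
    (pairwise aligned RMSD > 5 × jitter).
    """

    templates: np.ndarray        # [K, N, 3] Å
    atom_numbers: np.ndarray     # [N]
    residue_ids: np.ndarray      # [N] 0-based residue index per atom
    bonds: list = field(default_factory=list)   # [(i, j), ...]
    jitter: float = 0.03         # Å, clipped at 2σ to preserve bonds

    @property
    def n_states(self) -> int:
        return self.templates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.templates.shape[1]

    @property
    def n_residues(self) -> int:
        return int(self.residue_ids.max()) + 1


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal rigid alignment (Kabsch via SciPy)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a, b)
    return float(np.sqrt(((a - rot.apply(b)) ** 2).sum(axis=1).mean()))


def _random_chain(n_atoms: int, rng: np.random.Generator,
                  bond_length: float = 1.5) -> np.ndarray:
    """Self-avoiding-ish random walk with fixed bond length."""
    pos = np.zeros((n_atoms, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, n_atoms):
        for _ in range(50):
            perturb = direction + 0.8 * rng.normal(size=3)
            perturb /= np.linalg.norm(perturb)
            candidate = pos[i - 1] + bond_length * perturb
            if i < 2 or np.min(
                np.linalg.norm(pos[: i - 1] - candidate, axis=1)
            ) > 1.2 * bond_length:
                break
        pos[i] = candidate
        direction = perturb
    return pos


def make_template_set(n_states: int, n_residues: int = 3,
                      seed: int = 0, jitter: float = 0.03,
                      max_tries: int = 200) -> ConformerTemplateSet:
    """Draw chain-molecule templates until all pairs are separable
    (aligned RMSD > 5 × jitter)."""
    rng = np.random.default_rng(seed)
    n_atoms = 4 * n_residues
    atom_numbers = np.tile([7, 6, 6, 8], n_residues)
    residue_ids = np.repeat(np.arange(n_residues), 4)
    bonds = [(i, i + 1) for i in range(n_atoms - 1)]
    templates = [_random_chain(n_atoms, rng)]
    tries = 0
    while len(templates) < n_states:
        cand = _random_chain(n_atoms, rng)
        if all(kabsch_rmsd(cand, t) > 5.0 * jitter for t in templates):
            templates.append(cand)
        tries += 1
        if tries > max_tries:
            raise NumericalError("could not draw distinguishable templates")
    return ConformerTemplateSet(
        np.stack(templates), atom_numbers, residue_ids, bonds, jitter
    )


def _clipped_jitter(shape, sigma: float, rng: np.random.Generator):
    """Gaussian perturbation clipped at ±2σ so bonded distances stay
    within 10% of the template values."""
    return np.clip(rng.normal(0.0, sigma, size=shape), -2 * sigma, 2 * sigma)


def gen_toy_conformers(n: int, templates: ConformerTemplateSet,
                       rng: np.random.Generator):
    """Conformer dataset for denoising pretraining: random templates plus
    bond-preserving perturbations.  Returns (coords [n, N, 3], state ids).
    """
    if n < 1:
        raise InputError("n must be >= 1")
    which = rng.integers(0, templates.n_states, size=n)
    coords = templates.templates[which] + _clipped_jitter(
        (n, templates.n_atoms, 3), templates.jitter, rng
    )
    return coords, which


def embed_states_as_conformers(path: np.ndarray,
                               templates: ConformerTemplateSet,
                               rng: np.random.Generator,
                               random_rotation: bool = False):
    """Render a hidden dynamical path as an all-atom trajectory.

    Discrete path (ints [T]): frame t = template[path[t]] + jitter; the
    template count must equal the number of states.

    Continuous path (floats [T, 2]): coordinates are min-max normalized
    and frames interpolate template 0 → 1 along the first coordinate and
    0 → 2 along the second (three templates are the interpolation
    anchors), plus jitter.

    Returns (frames [T, N, 3], ground_truth dict with the hidden path).
    """
    path = np.asarray(path)
    K, N = templates.n_states, templates.n_atoms
    if path.ndim == 1 and np.issubdtype(path.dtype, np.integer):
        if path.max(initial=0) >= K:
            raise InputError(
                f"path references state {path.max()} but only {K} templates"
            )
        frames = templates.templates[path].copy()
        truth = {"kind": "discrete", "labels": path.copy()}
    elif path.ndim == 2 and path.shape[1] == 2:
        if K < 3:
            raise InputError("continuous embedding needs 3 anchor templates")
        lo, hi = path.min(axis=0), path.max(axis=0)
        uv = (path - lo) / np.maximum(hi - lo, 1e-12)
        base, ax, ay = templates.templates[:3]
        frames = base[None] \
            + uv[:, 0, None, None] * (ax - base)[None] \
            + uv[:, 1, None, None] * (ay - base)[None]
        truth = {"kind": "continuous", "positions": path.copy()}
    else:
        raise InputError("path must be int [T] or float [T, 2]")
    frames += _clipped_jitter(frames.shape, templates.jitter, rng)
    if random_rotation:
        rots = Rotation.random(len(frames), random_state=np.random.RandomState(
            int(rng.integers(2 ** 31))))
        frames = np.einsum("tij,tnj->tni", rots.as_matrix(), frames)
    return frames, truth


# -- temporal split -----------------------------------------------------------

def temporal_split(T: int, train_fraction: float = 0.5, n_segments: int = 1,
                   rng: np.random.Generator | None = None):
    """Temporal train/validation split.

    The second half of the trajectory is always the validation set.  The
    training set is drawn from the first half only: with one segment it
    is simply the first ``train_fraction·T`` frames; with ``n_segments``
    > 1 the first half is cut into equal segments and whole segments are
    drawn at random until the requested fraction is reached.
    """
    if not 0.0 < train_fraction <= 0.5:
        raise InputError(
            "train_fraction must be in (0, 0.5]: the validation half is "
            "held out and never used for training"
        )
    if n_segments < 1:
        raise InputError("n_segments must be >= 1")
    half = T // 2
    val_idx = np.arange(half, T)
    if n_segments == 1:
        n_train = int(round(train_fraction * T))
        if n_train == 0:
            raise InputError("train_fraction selects zero frames")
        return np.arange(n_train), val_idx
    seg_len = half // n_segments
    if seg_len == 0:
        raise InputError(
            f"cannot cut the first half ({half} frames) into {n_segments} "
            "segments"
        )
    n_sel = int(round(train_fraction * T / seg_len))
    n_sel = max(1, min(n_sel, n_segments))
    if rng is None:
        rng = np.random.default_rng(0)
    chosen = np.sort(rng.choice(n_segments, size=n_sel, replace=False))
    train_idx = np.concatenate(
        [np.arange(s * seg_len, (s + 1) * seg_len) for s in chosen]
    )
    return train_idx, val_idx
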