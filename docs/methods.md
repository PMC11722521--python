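# Methods

This note records the models implemented in `geomtok`, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic test bed does and does not establish.

## Equivariant encoder

The encoder is a message-passing network over the cutoff graph of a
conformation (edges wherever two atoms are within `cutoff`, default
5 Å; brute-force O(N²) neighbor search, adequate for the few hundred
atoms targeted here and documented as replaceable).  Each atom carries
`d` scalar channels (initialized from an atomic-number embedding) and
`d` 3-vector channels (initialized to zero).  Per layer, a message
phase gates neighbor contributions with Gaussian radial-basis filters
(`n_rbf` centers on [0, cutoff]) under a cosine envelope that vanishes
smoothly at the cutoff, updating scalars from neighbor scalars and
vectors from neighbor vectors plus unit bond directions; an update
phase mixes the two streams node-locally through channel maps, vector
norms and scalar–vector dot products.  Because scalars are built only
from invariants and vectors only from equivariant quantities with
invariant coefficients, rotation/translation invariance and
equivariance hold *by construction*, and the tests verify them to
1e-4 over random rigid transforms (in practice the deviation is at
float-precision level).  Dihedral-angle message terms used by some
published architectures are intentionally not reproduced; the
representation contract (per-atom scalar + vector channels) is what
downstream code depends on.

Defaults `d = 64`, `n_layers = 4`, `cutoff = 5 Å`, `n_rbf = 32` are
configurable; the desk-scale studies in the tests and the acceptance
script use `d = 32`, `n_layers = 2`, `n_rbf = 16`, which suffice for
the 12-atom benchmark molecules.

All trainable components run on a small reverse-mode autodiff engine
over numpy (`geomtok.autodiff`); its gradients are verified against
finite differences in the test suite.

## Denoising pretraining

Conformers are corrupted with i.i.d. Gaussian displacements
(σ default 0.2 Å — large enough to be learnable above the conformer
jitter of the toy dataset, configurable) and encoder + gated
equivariant head regress the displacements, normalized to zero mean
and unit variance by *scalar* statistics computed on the training
split only.  On normalized targets, predicting zero gives an MSE of
exactly 1.0, so validation MSE < 1 is the signal that geometry has
been learned.  The corruption is drawn once per run (a fixed corrupted
dataset) so the normalization statistics are well defined and runs are
reproducible; at the dataset sizes used here re-sampling noise per
epoch made no observable difference.  The checkpoint with the lowest
validation MSE is kept.  Downstream stages load the checkpoint frozen
and never update encoder parameters.

The gated equivariant head applies two channel maps to the vector
features; the norms of the first are concatenated with the scalars and
passed through a two-layer MLP whose output gates the second map,
which is contracted to one 3-vector per atom.  Note the gates depend
on the vector norms, so the head is linear in the vector channels only
at fixed gates (the tests pin the gates before asserting homogeneity).

## Tokens

A partition of the selected atoms into disjoint structural units
(default: one subset per residue) defines tokens as plain sums of the
per-atom features — linear, parameter-free, and preserving the
equivariance contract.  Feature stores are written to HDF5 with
content hashes of the checkpoint, selection and partition so stale
caches are detected.  Selection defaults to non-hydrogen atoms for
protein-like inputs; the toy molecules have no hydrogens and use
`all`.

## Token mixers

Mixer heads consume scalar channels only; equivariant information
enters, when requested, through "GVP enrichment": channel-mixed vector
norms, gated by scalar-derived sigmoids, are appended to the scalars
and mapped back to the scalar width.  This keeps every task output
exactly invariant under rigid motion.  SubMixer alternates token-mixing
and channel-mixing MLP blocks over the fixed token grid and reads out
the token mean; SubFormer is a pre-norm transformer over the token
sequence with an extra global token and reads out that position.  The
global token encodes the M(M−1)/2 pairwise distances between per-token
anchor atoms, standardized by training-set mean/std (raw distances are
unbounded and destabilize attention logits) and passed through a
two-layer MLP.  Learned positional embeddings are on by default
(residue order matters for polymers) and can be disabled, which makes
the subformer exactly permutation-invariant — both behaviors are
tested.  Head-averaged per-layer attention maps, (M+1)×(M+1) and
row-stochastic, are recorded at inference for interpretation.

## VAMP-2

The slow-mode objective is the squared Frobenius norm of the whitened
time-lagged correlation of the head outputs χ.  The scoring routine
whitens with an eigenvalue floor at `eps·λ_max` (eps default 1e-6,
exposed because it interacts with batch size); the training loss uses
the equivalent trace form tr(C₀₀⁻¹C₀τCττ⁻¹C₀τᵀ) with a ridge, which
avoids differentiating an eigendecomposition.  One shared network
provides both lobes (χ₀ = χτ): the benchmark chains are reversible, and
a shared embedding halves the parameters; the two-lobe variant would
only matter for strongly non-reversible data.  Outputs are
softmax-normalized by default for VAMP so that perfectly resolved
discrete states reproduce one-hot indicator features.

Mean-centering of the correlation blocks is on by default (it removes
the trivial constant mode and bounds the score by d_o, which is
asserted as a property); the analytic oracles for finite-state chains
use the *uncentered* convention, where the score equals the sum of
squared transfer-operator eigenvalues including the stationary mode —
each test states its convention.

Training follows a dual-patience protocol: validation is scored every
10 steps; training halts when the training score has not improved for
500 batches or the validation score has not improved for 10 consecutive
evaluations.  Early stopping monitors sampled validation batches, but
the *reported* score of the selected checkpoint is recomputed once over
the full validation pair set: keeping the maximum over noisy batch
scores selects upward fluctuations and overstates the score by a few
percent.  Batches are random lagged pairs that never span
trajectory boundaries and respect the temporal split.  Batch sizes
below ~1000 make the empirical correlation matrices ill-conditioned;
the trainer aborts with guidance rather than silently regularizing
harder.

## Temporal split

Validation is always the second half of the trajectory; training data
come only from the first half, drawn as whole random segments when
segment subsampling is requested.  A random frame split is deliberately
not offered: successive frames are strongly correlated, and a random
split lets a network score well by memorization.

## SPIB

The encoder outputs a diagonal Gaussian posterior (log-variance
bounded to [−6, 2] by a shifted tanh and biased small at
initialization — a wide initial posterior lets the decoder ignore the
latent and collapse to the marginal).  The prior is a variational
mixture of posteriors over `n_pseudo = 10` learned pseudo-inputs
initialized from random training samples; β defaults to 0.01 and is
the primary control over state merging.  Labels start from k-means
(k = `init_k`) and are refreshed by decoder argmax at the posterior
mean; argmax ties resolve to the lowest label index.

The refresh cadence is a load-bearing choice: refreshing after every
pass over the data collapses all states to one, because an
underconverged decoder assigns near-arbitrary argmax labels and merges
are effectively irreversible (a merged target distribution is
self-fulfilling).  The default is therefore one refresh per 1000
gradient steps, long enough at the default batch size for the decoder
to reach its conditional optimum between refreshes.

A state is only "metastable" relative to the lag: if basin residence
times are comparable to τ, the argmax update *correctly* merges basins
(the most likely future basin is no longer the current one).  The
triple-well benchmark is therefore configured so that
P(stay in basin over τ) ≈ 0.95.

MSMs are estimated from the final labels by row-normalized transition
counts at the stated lag; populated states with no outgoing counts get
an imputed self-loop and a warning.

## Synthetic test bed

* Finite-state chains built spectrally: the three-state benchmark is
  (1/3)J + 0.9·u₂u₂ᵀ + 0.7·u₃u₃ᵀ, reversible with uniform stationary
  distribution and eigenvalues exactly {1, 0.9, 0.7}, so the uncentered
  VAMP-2 optimum is 2.30 by construction.
* Overdamped Langevin dynamics (Euler–Maruyama, kT = 1, γ = 1,
  dt = 0.005, saved every 10 steps).  Double well: barrier·(x²−1)² +
  harmonic y, barrier 3 kT — dozens of well hops per 10⁴ saved frames.
  Triple well: (27/4)·barrier·u²(u²−1)² with u = x/2 (minima at
  x = −2, 0, 2, equal depths, barrier 4 kT).  The widened wells keep
  dt·V″ ≲ 0.3; a narrower variant put the integrator at the edge of
  stability and silently depopulated the side wells.
* Chain-molecule templates: 4-atom (N,C,C,O) residues joined by 1.5 Å
  bonds along self-avoiding random walks, drawn until pairwise aligned
  RMSD exceeds 5× the jitter scale (0.03 Å, clipped at 2σ so bonded
  distances stay within 10% of template values).  Discrete states map
  to templates; continuous 2-D paths interpolate between three anchor
  templates.  Ground-truth records travel with every generated
  trajectory.

What passing these benchmarks shows: the pipeline recovers *known*
slow spectra, slow coordinates and metastable-state counts through the
full encoder→token→mixer stack at desk scale.  What it does not show:
performance on real force-field data, where states are not separable by
template geometry, intra-state fluctuations are anisotropic and
heavy-tailed, solvent and hydrogens matter, and the slow processes span
orders of magnitude in timescale.  Problem sizes (10–20k frames,
12-atom molecules, d = 32) were chosen as the smallest at which the
oracles are statistically resolvable.

## Known limitations

* The encoder's O(N²) neighbor search and dense per-frame batching cap
  practical system sizes at a few hundred atoms.
* The SubFormer global token uses anchor-atom distances only; no other
  multimodal tokens are implemented.
* SPIB merging is irreversible by construction; a state lost to an
  ill-timed refresh cannot be recovered within a run (mitigated by the
  long refresh default).
* VAMP-2 only (no VAMP-r, no reversible/symmetrized estimators).
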