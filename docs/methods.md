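# Methods

This note records the modelling choices, numerical conventions, and known
limitations of `gcdiff`.

## Diffusion process

The joint state is `z = [z^(x), z^(h)]` with coordinates on the zero
center-of-mass (CoM) subspace and features a flat block of
`[one-hot × 0.25, charge × 0.1]` (the feature scalings follow the common
processing convention for these benchmarks; both factors are config
constants in `gcdiff.mol`). Keeping coordinates mean-free makes the
coordinate Gaussians well-defined on a 3(N−1)-dimensional subspace and
the model likelihood translation invariant; every operation that touches
coordinates (noise draws, reverse steps, network outputs) re-projects
onto the subspace, and the sampling loop asserts this per step in tests.

Schedules are variance preserving, `α_t² + σ_t² = 1`. The default is the
polynomial schedule `α_t² ∝ (1 − (t/T)²)²` with stepwise-ratio clipping
and an endpoint precision clamp of 1e−5 (so α never hits 0 or 1
exactly); a squared-cosine alternative is provided. Default `T = 1000`
for full-scale presets; the toy experiments use `T = 500`.

Transition identities: `α_{t|s} = α_t/α_s` and
`σ_{t|s}² = σ_t² − α_{t|s}² σ_s²`. The square on `α_{t|s}` is required
for Gaussian self-consistency (composing 0→s→t reproduces the 0→t
marginal exactly); the test suite verifies this by Monte-Carlo
composition. Because of the precision clamp, `α_0` is slightly below 1,
so all "relative to data" quantities consistently use the (t|0)
transition coefficients; in particular `predict_clean` inverts the
closed-form forward draw at machine precision, and the denoising
posterior uses the (s|0)/(t|0) widths, which a 1-D numerical Bayes
oracle confirms to 1e−6.

The final reverse step (t = 1 → 0) decodes from the predicted clean
state without added noise: atom type by argmax over the one-hot block,
charge by rounding the unscaled charge channel (clamped to ±3, outside
which no formal charge occurs in this chemistry). Whether noise should
be added at the last step is a genuinely open choice; mean decoding is
the stabler reading and is what we implement.

## Denoising network

The network keeps per-node invariant scalars (width 256 by default) and
equivariant vector channels (64 by default; the desk-scale presets use
64/8), with 9 message-passing layers by default (4 at desk scale). Per
directed edge of the fully-connected molecular graph a local frame
`a = (xᵢ−xⱼ)/‖·‖`, `b = (xᵢ×xⱼ)/‖·‖`, `c = a×b` is built from the
*centered* noisy coordinates. Degenerate geometries (coincident points,
or `xᵢ ∥ xⱼ`, which always happens for centered two-atom molecules) fall
back to a zero frame with a degeneracy flag so scalarized features are
zeros, never NaN.

Messages concatenate both endpoint scalars, a radial-basis embedding of
the edge length, and frame projections of both endpoints' vector
channels, normalized by `1/(1 + d)` to keep projections of
position-valued vectors O(1) across molecule sizes. Message and node
MLPs are two-layer with SiLU; node scalars get residual updates followed
by LayerNorm. Vector channels are updated only through linear
combinations of frame axes and neighbor vector channels with
invariant coefficients, which preserves rotation equivariance exactly
(float64 residuals around 1e−12 in tests). Scalar message attention
(SMA) is a learned sigmoid gate per directed edge multiplying the whole
message; `use_sma=False` fixes the gate path off, reproducing the
no-attention ablation.

Parity: under reflection, `b` is a pseudovector and flips sign while `a`
and `c` transform as polar vectors, so exactly the b-projection of a
polar vector changes sign. That single sign flip is what makes the
network chirality-aware; with `use_frames=False` only the `a` axis is
used and the network is exactly reflection invariant (both directions
are tested on the chiral fixture).

Time enters as `t/T` appended to the node scalars; a conditional model
appends one standardized property value per node. Output heads are
zero-initialized by default so an untrained model predicts ε̂ = 0
(stabilizing early training); geometry probes that need a generic
function use random heads scaled by 0.1.

The network and its training loop run on a compact reverse-mode
automatic-differentiation engine over NumPy arrays
(`gcdiff.autodiff`) — float64 throughout, with exactly the op set the
architecture needs; gradients are verified against central finite
differences in the test suite.

## Likelihood

`nll` returns the variational bound on −log p(x, h, N): the size term
−log p(N) from the empirical size distribution, a prior KL at T
(coordinate part on 3(N−1) dimensions), diffusion terms
`½ (SNR(t−1)/SNR(t) − 1) ‖ε − ε̂‖²` for t = 2..T (uniform Monte-Carlo
over t by default, full sum behind a flag), and a reconstruction term at
t = 0 using a Gaussian for coordinates and discretized Gaussians for the
one-hot and integer-charge channels.

Monte-Carlo noise is drawn in an equivariantly canonicalized molecular
frame (gyration-tensor principal axes, ordered by eigenvalue, signs
fixed by third moments, handedness by the cross product). An orthogonal
transform of i.i.d. Gaussian noise is still i.i.d. Gaussian, so the
estimator is unbiased — but the draw now co-rotates with the molecule,
making the finite-sample estimate *exactly* rotation invariant rather
than only invariant in expectation. Degenerate canonical frames
(symmetric point clouds) fall back to the identity; generic molecules,
including all jittered fixtures, are unaffected.

## Conditioning and optimization

Conditional models standardize the property with training-set mean/std
and broadcast it to every node. Molecule optimization re-uses a trained
conditional model without retraining: the input is encoded as z_0,
forward-noised to t = n_opt_steps (default 100; 250 as the alternative
preset), and reverse-diffused to 0 under the target condition. Noising
the input (rather than inserting it raw at t) matches the diffusion
prior's assumptions at t; raw insertion is available behind a flag for
comparison. Atom count is preserved; composition and geometry may
change. Time-scaled generation runs the reverse chain on a uniform
stride-⌈T/n⌉ grid (uniform in step index; a uniform-in-α grid would be a
one-line change), producing deliberately under-refined molecules that
serve as optimization starting material.

## Metrics

Bond orders: a pair at distance d (converted to pm) gets the highest
order whose reference length + margin exceeds d; margins are 10/5/3 pm
for single/double/triple. Reference lengths are standard experimental
equilibrium values for the light-element pairs plus common heteroatom
pairs; pairs absent from the table are treated as non-bonded (logged
once). Valency tables are charge-aware by default (e.g. N⁺ = 4, O⁻ = 1)
with a charge-blind variant available. Validity sanitizes the inferred
bond graph with RDKit and canonicalizes the largest fragment's SMILES;
novelty is string equality against an identically canonicalized
reference set, computed over the valid-and-unique subset. The energy
ratio embeds 50 ETKDGv3 conformers of the same graph and divides the
input conformation's UFF energy by their mean; ratios above 7 are
flagged as unlikely geometries. This operation needs RDKit's force
field and embedder at call time and is not on any training path.

## Synthetic fixtures

The generator emulates small rigid molecules: four templates (tetrahedral
methane-like, bent water-like, linear hydrogen-cyanide-like with a triple
bond, and a chiral five-atom scaffold whose mirror image is 1.2 Å RMSD
away under the best proper-rotation alignment), uniformly mixed, with
per-coordinate Gaussian jitter (default 0.05 Å), uniform random
rotations, and re-centering. Properties (radius of gyration as the
size-like conditioning target, a pseudo-charge dipole norm) are evaluated
on the jittered geometry so conditional models see a continuum of values.

The toy bond table restricts the real table to template pairs but widens
margins to 25 pm (single) / 12 pm (triple): with 0.05 Å jitter a bond
length fluctuates with ≈7 pm standard deviation, so the real 10/5/3 pm
margins would misclassify ≈8% of C–H bonds — the widened margins keep
the fixture set ≥95% molecule-stable by design, which was computed from
that noise budget before any experiments were run. Toy valencies accept
the valences realized in the templates (N: 1 or 3; O: 1 or 2). The toy
table is test-only; real data is always scored with the real table.

What the fixtures do **not** emulate: chemical diversity (four graphs
only, so uniqueness is intentionally tiny), conformational flexibility,
aromaticity, charged species, and size ranges beyond 3–5 atoms. Passing
the recovery tests therefore demonstrates that the diffusion/denoiser
machinery learns and reproduces 3D geometry and composition — not that
the model generalizes across chemical space; that claim needs the
full-scale datasets.

## Desk-scale presets and problem sizes

The shipped experiments are sized for a single CPU: 2,000 training
molecules, 4-layer/64-dim denoiser, T = 500, 100 epochs of Adam at
lr 1e−3 and batch 64 (loss plateaus near 0.044 after ~30 epochs; the
extra epochs buy composition accuracy), 500 generated samples for the
recovery measurements, 200 paired molecules (0.15 Å jitter) for the
optimization experiment, and three condition targets × 50 samples for
the conditioning-response curve. Full-scale presets (9 layers,
256/64/32/16 widths, T = 1000) are the config defaults but require
GPU-scale budgets and the published processed datasets.

## Known limitations

- Fully-connected topology costs O(N²) edges per molecule; a distance
  cutoff is exposed in config for large N but is not used in any shipped
  experiment.
- The NLL's reconstruction term assumes the discretized-Gaussian decoder;
  other decoders would shift absolute NLL values (comparisons across
  models trained in this package remain consistent).
- `aligned_rmsd` alternates Hungarian matching and Kabsch alignment from
  several random restarts; exact for the small rigid templates, heuristic
  for large flexible molecules.
- Optimization preserves atom count but not atom identities; this is the
  intended behavior for composition-level refinement.
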