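# gcdiff

Geometry-complete SE(3)-equivariant denoising diffusion for 3D molecules:
joint generation of atom coordinates, atom types, and formal charges, with
a chirality-aware local-frame denoising network, property-conditional
generation, diffusion-based molecule optimization, and a valency-based
molecule-quality metric suite.

## Who this is for

Researchers in generative chemistry who want a CPU-friendly, fully
inspectable implementation of equivariant molecular diffusion: every
component — the variance-preserving schedule, the zero-center-of-mass
coordinate diffusion, the frame-based denoiser, the stability metrics —
is plain NumPy/SciPy/RDKit and unit-tested against independent oracles.

## The model

A molecule is `M = [X, H]`: coordinates `X ∈ R^{N×3}` (Å, kept on the
zero center-of-mass subspace `Σᵢ xᵢ = 0`) and per-atom features `H`
(one-hot element over {H, C, N, O, F} plus an integer charge, diffused as
scaled continuous channels). The forward process is variance preserving,

    q(z_t | z_{t-1}) = N_xh(z_t | α_t z_{t-1}, σ_t² I),   α_t² + σ_t² = 1,

with closed-form marginals `q(z_t | z_0) = N(α_{t|0} z_0, σ_{t|0}² I)`
where `α_{t|s} = α_t/α_s` and `σ_{t|s}² = σ_t² − α_{t|s}² σ_s²`. The
reverse process is ε-parametrized: a denoising network Φ predicts the
injected noise `ε̂ = [ε̂^(x), ε̂^(h)]`, the clean state is recovered as
`z̃_0 = z_t/α_t − ε̂ σ_t/α_t`, and each step samples the exact Gaussian
posterior `q(z_s | z_t, z̃_0)`. Training minimizes `½ w(t) ‖ε − ε̂‖²`
with `w(t) = 1`.

Φ carries separate scalar (invariant) and vector (equivariant) feature
channels. Per directed edge (i, j) a local frame

    a = (xᵢ−xⱼ)/‖xᵢ−xⱼ‖,  b = (xᵢ×xⱼ)/‖xᵢ×xⱼ‖,  c = a × b

spans all of 3D ("geometry complete"); vector channels are scalarized by
projection onto (a, b, c) before entering message MLPs, and vector
updates are linear combinations of existing vectors and frame axes, so
rotation equivariance holds by construction while the cross-product axis
makes the network sensitive to chirality. Each edge message passes
through a learned sigmoid gate (scalar message attention). Both
ingredients can be ablated via config flags (`use_frames`, `use_sma`).

Generated molecules are scored by inferring bonds from inter-atomic
distances against reference bond-length tables, then checking that each
atom's summed bond orders hit its allowed valence (atom stability, AS),
that all atoms do (molecule stability, MS), RDKit sanitization of the
bond graph (validity), uniqueness/novelty of canonical SMILES, and a
UFF/ETKDGv3 conformer energy ratio (values above 7 flag unlikely
geometries).

## Worked example

```python
import numpy as np
from gcdiff import GCDM, DenoiserConfig, make_schedule
from gcdiff.fixtures import sample_dataset, toy_bond_table
from gcdiff.metrics import batch_report

data = sample_dataset(n=2000, rng=np.random.default_rng(0))
cfg = DenoiserConfig(n_layers=4, node_scalar_dim=64, node_vector_channels=8,
                     edge_scalar_dim=16, edge_vector_channels=8)
model = GCDM(cfg, schedule=make_schedule("polynomial", 500), seed=0)
result = model.fit(data, epochs=100, batch_size=64, seed=0)
print(result.summary())
mols = model.sample(500, np.random.default_rng(10))
print(batch_report(mols, toy_bond_table()))
```

prints (numbers from this exact run):

```
GCDM fit summary
================
training molecules : 2000
epochs             : 100
denoiser           : 4 layers, 64/8 node dims
schedule           : polynomial, T=500
conditional        : no
first-epoch loss   : 0.249148
final loss         : 0.043557
{'n_molecules': 500, 'n_atoms': 2002,
 'atom_stability_pct': 98.4, 'molecule_stability_pct': 96.4,
 'validity_pct': 98.6, 'valid_and_unique_pct': 2.2}
```

The falling ε-matching loss shows the denoiser learning the template
geometry; 96.4% of the 500 generated molecules are fully stable under
the fixture bond table, and 92% reproduce a template's exact element
composition with a median aligned RMSD of about 0.07 Å to the ideal
geometry. (Valid-and-unique is intentionally tiny here — the fixture
world only contains four distinct molecules.)

The same workflow is available from the shell:

```bash
gcdiff fixtures --out data/ --n 2000 --jitter 0.05 --seed 0
gcdiff train --data data/ --out ckpt.npz --epochs 100 -T 500
gcdiff sample --checkpoint ckpt.npz --n 500 --out samples.xyz \
              --bond-table toy --report report.json
gcdiff train --data data/ --out cond.npz --condition radius_of_gyration
gcdiff optimize --checkpoint cond.npz --input samples.xyz \
                --target-value 1.0 --steps 100 --out optimized.sdf
gcdiff evaluate --input optimized.sdf --bond-table toy
```

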