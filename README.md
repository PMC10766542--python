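# reallife

Regularized streamline pruning and connectome evaluation for diffusion MRI.

Tractography produces far more candidate streamlines ("fibers") than the
diffusion signal supports: many are redundant copies of the same pathway and
some are outright spurious. This package evaluates a candidate connectome
against the measured signal by solving a regularized non-negative
least-squares problem over a memory-efficient sparse forward model, assigning
each fiber a weight and pruning the zero-weight ones — and ships the
evaluation machinery around that core: synthetic phantoms with known ground
truth, duplicate-fiber uniqueness scoring, cross-validated fit-quality
protocols, test–retest reliability statistics for region-level connectivity,
and an SVR-RFE pipeline for predicting behavioral scores from connection
features. It is aimed at researchers developing or benchmarking connectome
evaluation methods who need every stage testable without any data downloads.

## The model

The demeaned diffusion signal is modeled as a non-negative combination of
fiber contributions, `b ≈ M w` with `w ≥ 0`, where `M` is held in sparse
Tucker-decomposed form `M = Φ ×₁ D ×₂ S₀`: a voxel-sorted sparse coefficient
tensor `Φ` (voxel × orientation atom × fiber), a demeaned stick-kernel
orientation dictionary `D` (`N_θ × N_a`), and the per-voxel baseline `S₀`.
Weights minimize

    ½‖b − Mw‖² + λ‖w‖₁,   w ≥ 0

(λ = 0 recovers the unregularized fit; the L1 penalty induces extra sparsity
and removes redundant fibers) via a subspace Barzilai–Borwein projected
gradient iteration, `w⁽ⁱ⁺¹⁾ = [w⁽ⁱ⁾ − α⁽ⁱ⁾∇g(w⁽ⁱ⁾)]⁺`, with alternating
spectral step sizes and a windowed convergence criterion
`|O(t) − O(t−10)| < Δ·O(t₀)`. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from reallife import (SolverConfig, build_dictionary, build_sparse_model,
                      make_phantom, prune, solve)
from reallife.phantom import two_bundle_spec

# two crossing bundles (20 true fibers), 5 spurious decoys, 1% noise
vol, connectome, w_true = make_phantom(
    two_bundle_spec(n_spurious=5, noise_sigma=0.01, seed=7)
)
dictionary = build_dictionary(vol.scheme)
model = build_sparse_model(connectome, vol, dictionary)
print(f"encoded {model.n_fibers} fibers over {model.n_voxels} voxels "
      f"({model.coeff.size} tensor entries)")

cfg = SolverConfig(regularization="l1", lam=0.01, max_iters=2000, delta=1e-9)
w, trace = solve(model, cfg)
result = prune(connectome, w)
print(f"solver {trace.reason} after {trace.n_iters} iterations")
print(f"{len(result.retained)} of {len(connectome)} fibers retained")
print(f"correlation with ground truth: {np.corrcoef(w, w_true)[0, 1]:.3f}")
```

prints

```
encoded 25 fibers over 151 voxels (212 tensor entries)
solver converged after 20 iterations
22 of 25 fibers retained
correlation with ground truth: 0.999
```

The fitted weights track the planted ground truth almost perfectly (r =
0.999) and the pruned connectome drops most of the decoys while keeping every
true fiber — on a noise-free phantom the recovery is exact to solver
precision.

## Command line

The same pipeline is exposed as a thin CLI:

```bash
reallife simulate --spec phantom.yaml --seed 3 --out phantom/
reallife encode --dwi phantom/ --tck phantom/connectome.tck --out model.h5
reallife solve --model model.h5 --reg l1 --lam 0.01 --out weights.csv
reallife evaluate --dwi phantom/ --tck phantom/connectome.tck \
    --perturb jitter --out duplicates.json
reallife reliability --visit1 v1.csv --visit2 v2.csv --out reliability.csv
reallife rfe --features features.csv --scores scores.csv --out rfe.json
```

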