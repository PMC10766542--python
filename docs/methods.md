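# Methods

## The forward model

A candidate connectome is a set of `N_f` streamlines (fibers) traced through a
diffusion-weighted volume. The demeaned diffusion signal — per voxel, the
measured intensity along each of `N_θ` gradient directions minus its mean over
directions — is modeled as a non-negative combination of per-fiber signal
contributions:

    b ≈ M w,   w ≥ 0,

where `b` stacks the demeaned signal of the `N_v` voxels the connectome
traverses and `M` is never formed densely. Instead it is factored (sparse
Tucker decomposition) as `M = Φ ×₁ D ×₂ S₀`:

- `D` (`N_θ × N_a`) is an orientation dictionary: column `a` holds the
  demeaned stick-kernel response of a canonical orientation `u_a`,
  `exp(−b_i[(d_ax − d_rad)(g_i·u_a)² + d_rad])` minus its mean over
  directions. Defaults: `N_a = 96` atoms on a deterministic Fibonacci-spiral
  tessellation of the upper hemisphere (antipodally unique and well-spread for
  any atom count), axial diffusivity `d_ax = 1e-3 mm²/s`, radial `d_rad = 0`.
  The stick kernel is the simplest axially symmetric single-fiber response;
  multi-compartment kernels are out of scope.
- `Φ` is a sparse third-order tensor in COO form, sorted along the voxel
  dimension. Each streamline is resampled at `step_mm` (default half the voxel
  size) and every inter-node segment contributes one entry
  `(voxel of its midpoint, nearest atom to its direction, fiber index,
  coefficient)`. Coefficients are segment lengths in mm, so a fiber's
  contribution to a voxel scales with its path length there and is invariant
  to resampling resolution; duplicate `(v, a, f)` triplets are summed.
  (The strictly binary variant of `Φ` can be emulated by quantizing
  coefficients, but length weighting is the package default because it makes
  the noise-free phantom round-trip exact at any step size.)
- `S₀(v)` is the baseline (b=0) intensity, averaged over the acquisition's
  b=0 volumes.

The voxel sorting is what makes the two work-horse products cheap and
streamable: `Mx` accumulates `S₀(v)·x_f·coeff·D[:,a]` one voxel run at a
time (entries with `x_f = 0` are skipped outright, which is where sparse
weight vectors pay off), and `MᵀY` reduces inner products of `D` columns with
per-voxel signal blocks. Both are implemented as vectorized scatter/gather
operations and are tested against an explicitly densified `M` and for
adjointness (`⟨Mx, y⟩ = ⟨x, Mᵀy⟩`).

## The solver

Weights solve

    min_{w ≥ 0} ½‖b − Mw‖² + λ P(w)

with `P` absent, `‖w‖₁` (the regularized variant that induces extra sparsity
and prunes redundant fibers), or an L2 penalty. The optimizer is a subspace
Barzilai–Borwein projected-gradient iteration:

    w⁽ⁱ⁺¹⁾ = [w⁽ⁱ⁾ − α⁽ⁱ⁾ ∇g(w⁽ⁱ⁾)]⁺,  ∇g(w) = Mᵀ(Mw − b) + λ∇P,

whose step size alternates between two spectral ratios computed from the
gradient projected onto the feasible directions `g̃` (components pushing an
at-bound zero weight negative are zeroed): odd iterations use
`⟨g̃,g̃⟩/⟨Mg̃,Mg̃⟩`, even iterations `⟨Mg̃,Mg̃⟩/⟨MᵀMg̃,MᵀMg̃⟩`. Iteration 1
counts as odd; the initial iterate is `w⁰ = 0`, so the first step is steepest
descent on the active set. Convergence is declared when
`|O(t) − O(t−window)| < Δ·O(t₀)` with defaults `Δ = 0.001`, `window = 10`,
`max_iters = 500`; the absolute value guards against the non-monotone
objective of BB iterations. Vanishing spectral denominators terminate the
solve with reason "stationary" rather than erroring (the projected gradient is
null there). Tests tighten `Δ` to 1e-9–1e-12 where oracle-level accuracy is
needed; at those settings the final objective matches scipy's Lawson–Hanson
active-set solution to ~1e-11 relative on random instances.

One printed-form subtlety: the L2 penalty is conventionally written `λ‖w‖₂`
with gradient `+λw`, which are not a consistent pair. `objective()` reproduces
the printed penalty by default; the solver's trace uses `½λ‖w‖₂²` so the
traced objective and the gradient agree. Both forms are exposed via the
`consistent_l2` flag.

`calibrate_lambda` matches the summed weights (L1 norm) of an L1-regularized
fit on a larger candidate pool to an unregularized reference fit over a
log-spaced grid (default span `[1e-8, 1]`), returning the grid value
minimizing the norm mismatch; ties go to the smaller λ.

## The synthetic phantom

`phantom.make_phantom` lays curved fiber bundles (quadratic Bézier
centerlines, sunflower-packed parallel offsets across the bundle
cross-section) plus spurious decoy streamlines (random smooth paths through
the signal-bearing volume, so they are non-trivially prunable) on a small
voxel grid, then synthesizes the signal through the same forward model the
encoder builds: `signal = baseline + M w_true (+ noise)`. Because the
baseline is constant across directions it demeans away, and a noise-free
phantom satisfies `demeaned signal = M w_true` to machine precision — the
round-trip that anchors the encoder tests.

Design choices that matter:

- **Geometry is seed-independent.** Streamline geometry derives from a fixed
  internal generator; the phantom's `seed` drives only measurement noise.
  Two phantoms differing only in seed share a connectome exactly, which is
  what the replicate-visit protocols (overfitting, consistency) require.
- **The standard test-bed** (`two_bundle_spec`) is two interdigitating
  bundles of 10 fibers each on a 10×10×10 grid of 2 mm voxels, bundle
  cross-section radius 4 mm. The spread matters: fibers packed much tighter
  than a voxel produce near-duplicate columns of `M` and the weights stop
  being identifiable (that degeneracy is precisely what the duplicate-fiber
  experiment exploits deliberately). At these settings `cond(M) ≈ 2` and both
  SBB-NNLS and the active-set oracle recover `w_true` essentially exactly.
- **Unit baseline.** The test-bed sets `S₀ = 1` so the data term and L1
  penalties in the conventional `[1e-8, 1]` grid are commensurate; with
  scanner-scale intensities the same grid would be inert and λ would simply
  need rescaling.
- **Noise** is additive Gaussian per diffusion-weighted intensity with
  standard deviation `noise_sigma·S₀` (Rician available behind
  `noise_model="rician"`). Default true weights are an auto-scaled ramp that
  keeps the modeled deviation inside the positive-signal envelope.
- **Perturbations.** `jitter_connectome` displaces `round(f·n)` nodes per
  streamline (default 10%), multiplying each coordinate by `1 + u`,
  `u ~ U(−a, a)` with default amplitude 1e-4 (±0.01% of the coordinate
  value — the multiplicative reading of a relative jitter; a per-node vector
  displacement would be the alternative). `trim_connectome` removes
  `floor(f·n)` nodes from each terminus (default 5%), leaving streamlines
  that would drop below two nodes unchanged.

What the phantom does *not* emulate: scanner artifacts (eddy currents,
ghosting, susceptibility), partial-volume and crossing-fiber complexity
beyond what two bundles provide, multi-shell acquisitions, or realistic
whole-brain geometry. Passing tests demonstrate algorithmic correctness and
direction-of-effect on controlled synthetic data, not performance on real
acquisitions.

## Evaluation protocols

- **Duplicate-fiber uniqueness.** The connectome is duplicated (exactly, or
  with jitter/trim perturbations), concatenated, encoded and solved; copy
  pairs `(i, i + N_f)` are scored with `ζ = |w₁ − w₂|/(w₁ + w₂)` ∈ [0, 1].
  Both-zero pairs are excluded and reported separately (the index is
  undefined there). Exact duplicates produce identical columns of `M`, the
  gradient flow cannot break the tie, and every defined pair has ζ = 0
  bitwise; L1 regularization raises mean ζ on jittered pairs (it prefers
  dropping one copy).
- **Voxel-wise r.m.s.e.** between two demeaned signals, per masked voxel over
  directions. A direction-constant offset demeans away by construction.
- **Overfitting protocol:** fit on acquisition D1 under two solver configs,
  cross-validate both predictions against an independent acquisition D2,
  report per-voxel r.m.s.e. maps and their difference. On the spurious-rich
  test-bed (20 decoys, 5% noise) the L1 fit generalizes no worse on the
  median voxel; with few decoys the effect vanishes into noise.
- **Consistency protocol:** cross-fit two connectomes on swapped
  acquisitions, keep each solution's top-half fibers — threshold at the
  median of the *nonzero* weights, kept at-or-above (including zeros would
  make the filter a no-op on sparse solutions) — and compare the two
  predictions voxel-wise.

## Reliability statistics

Connection strengths (fiber counts or summed weights between region pairs;
labels 1..R left hemisphere, R+1..2R right; inter-hemispheric streamlines
excluded and counted) are vectorized as the strict upper triangles of the two
hemispheric matrices — 2·C(34,2) = 1,122 features for the standard 34-region
parcellation — and filtered to the top half by mean strength (561 features,
floor(n/2), ties to the lower index).

For a two-visit cohort, `V_w` averages `|c₁−c₂|/(c₁+c₂)` within participants
and `V_b` over all *ordered* participant pairs `(l, m)`, `l ≠ m`, pairing
visit 1 of `l` with visit 2 of `m` (the formula's asymmetric pairing;
unordered averaging would double-count). Both-zero pairs are excluded and
counted. Reliability is `φ = V_b/(V_b + V_w)`; changes against an unpruned
baseline place each connection on the (ΔV_w, ΔV_b) plane, with
high-reliability = strictly (ΔV_b > 0, ΔV_w < 0), low-reliability the
opposite, boundaries in neither; a one-sided binomial test (p = 0.5) compares
the high and low counts.

The retest cohort generator needs one non-obvious design decision. If the two
visits carry *independent* noise, then for any exchangeable cohort the
between-participant pairs contain the same two independent noise draws plus
the trait spread, so `E[V_b] ≥ E[V_w]` always and φ can approach but never
fall below 0.5 — no parameter setting would exercise the unreliable regime.
The generator therefore plants within-participant variability as a symmetric
session-state excursion: on the log scale, visit 1 sits at `trait + d` and
visit 2 at `trait − d` with `d ~ N(0, within_sd)` per participant and
connection. `within_sd` then directly controls the planted visit-to-visit
variability while each visit's marginal stays symmetric, and the two regimes
behave as intended: trait spread ≫ state noise gives mean φ well above 0.5,
the reverse gives mean φ below 0.5, and `within_sd = 0` gives `V_w = 0` and
φ = 1 exactly.

## Structure–behavior prediction (SVR-RFE)

A linear support-vector regressor (epsilon-insensitive loss; scikit-learn's
`LinearSVR`, with a closed-form ridge backend as the fast pluggable
alternative) predicts a z-scored behavioral score from connection features
inside a two-stage nested cross-validation: N outer folds (default 10); per
outer fold, K inner folds (default 5) fit the model and predict the held-out
outer test fold; coefficients and test-fold correlations are averaged over
the K fits; the bottom `max(1, floor(0.10·n))` features by average
coefficient magnitude are discarded (ranking by |mean β|) and the loop
repeats until no features remain. The feature set maximizing the averaged
test correlation wins the fold. Features are standardized on the outer
training fold only; elimination never sees test data, but the *selection* of
the winning set does use test-fold correlations — an optimistic bias the
procedure inherits by design and which the permutation test is there to
expose. Reported per score: the selection frequency of every feature, the
final selected set (frequency ≥ 0.5 across outer folds and runs), averaged
coefficients, and the accuracy `r` — the percentage-bend correlation between
observed scores and run-averaged held-out predictions, with its
t-approximation p. For combined feature blocks the proportion of selected
features per block is reported and sums to one.

Control analyses:

- **Permutation test.** Participant labels are shuffled `n_perm` times
  (default 100) and a reduced RFE (one run) is re-fit per shuffle; p is the
  plain proportion of null accuracies exceeding the observed one (a smoothed
  `(k+1)/(n+1)` variant is available behind a flag). The observed statistic
  is the reported pooled accuracy; each null draw is the cheap fold-averaged
  accuracy, which carries the full selection bias.
- **Head-motion regression.** Each score is replaced by its OLS residual
  against the six motion parameters plus intercept (pseudo-inverse with a
  warning if rank-deficient); residuals are exactly orthogonal to the motion
  columns.
- **Minimally correlated scores.** A greedy-random search: seed a random pair
  with |r| < 0.1, grow one score at a time among candidates with |r| < 0.01
  against all members, repeat 100 times, keep the subset with the least
  maximum absolute mutual correlation.

The percentage-bend correlation (bend constant 0.2) is authored in-package
and cross-checked in the tests against pingouin's independent implementation.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data sized
for a single CPU: the two-bundle phantom (10³ voxels, 32 directions, 20–45
fibers), 100 random solver instances of at most ~60 signal rows and 8 fibers,
retest cohorts of 6 participants × 40 connections, and RFE cohorts of 200
participants × 100 features with 2 runs for the planted-signal experiment and
9 label-shuffled replicates × 40 permutations (ridge backend) for the null.
These sizes were chosen so that every stochastic direction check is
well-powered at its threshold while the full pipeline remains quick to
re-run; the statistical behavior they probe does not depend on scale.

Numerical conventions: voxel linear index `i + X·(j + Y·k)`, 0-based, with
the affine mapping voxel centers to mm; COO entries kept stably sorted by
voxel; `round-half-up` for the jitter node count, `floor` for trim and
elimination counts; strict inequality for pruning thresholds (`w > threshold`)
so a threshold at `max(w)` empties the connectome.

## Known limitations

- The stick-kernel dictionary is a stand-in for richer single-fiber response
  estimates; its diffusivities are configurable but not fitted.
- The GPU-oriented voxel-sorted kernels are implemented as CPU-equivalent
  vectorized computations; no actual GPU code or wall-clock speedup claims.
- Comparative statements about regularized versus unregularized pruning
  (overfitting, consistency, tie-breaking) are established on the packaged
  synthetic suite only and say nothing quantitative about real acquisitions.
- The L2 mode follows the printed gradient (`+λw`) as discussed above.
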