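# Methods

## Model

For nonnegative spectra `X ∈ R≥0^{M×N}` on a 2-D pixel grid the package
factorizes `X ≈ UV` with `U ∈ R≥0^{M×K}` (memberships), `V ∈ R≥0^{K×N}`
(characteristic spectra), encouraging row-clustering structure through an
orthogonality penalty on `U` and spatial coherence through the isotropic
total variation of each membership column.  The hard clustering assigns
each spectrum to the column of its row maximum in `U`; exact ties are
broken uniformly at random with the replicate seed (all-zero rows are full
ties).

Assumptions: the noise model behind the Frobenius discrepancy is additive
Gaussian; the number of clusters K is known a priori; spectra belonging to
the same class are spatially contiguous except for pixel-level
contamination.

## Grid and TV discretization

The neighborhood of pixel `(i, j)` is the forward stencil
`N_(i,j) = {(i+1, j), (i, j+1)}` restricted to occupied pixels, giving a
one-sided estimate of both gradient components; the adjoint neighborhood
is the exact transpose relation.  On irregular masks, neighbors outside
the mask are dropped and the corresponding TV summands simply disappear —
no imputation.  Pixels without neighbors in either direction contribute
`ε_TV` (smoothed) or 0 (unsmoothed) to the TV value and are untouched by
the proximal operator.

The smoothed TV `Σ_{m,k} sqrt(ε² + Σ_{m̃∈N_m}(U_mk − U_m̃k)²)` is used by
the multiplicative solvers (which need differentiability); the PALM family
uses the unsmoothed seminorm through its proximal operator.  The TV
gradient used by the second multiplicative solver is the discretization
`div(∇U/‖∇U‖_ε)` with forward differences for `∇` and the negative
transpose (adjoint) for `div`; this equals exactly minus the gradient of
the smoothed TV, each column sums to zero (discrete divergence theorem
with zero-flux boundary), and it may be negative.

## TV proximal operator

`prox_{τ‖·‖TV}(x) = argmin_y ½‖y−x‖² + τ‖y‖_TV` is evaluated column-wise
by fast gradient projection — FISTA on the dual problem
`min_p ½‖x − Dᵀp‖²` over the product of per-pixel Euclidean balls
`‖p_(m)‖₂ ≤ τ` — with fixed step `1/8` (a Gershgorin bound on `‖D‖²` for
the 4-neighbor stencil), standard Nesterov momentum, no restart and no
early-exit tolerance: a fixed iteration count makes the operator
deterministic.  Caps: 100 iterations in the separated workflow, 5 inside
each PALM iteration.  Correctness is checked in the tests against an
independent bounded-least-squares solution of the dual on 1-D chains
(agreement to ~1e-12 at convergence).

## Solvers

**mul1** minimizes `½‖X−UV‖² + σ₁/2‖I−WᵀU‖² + σ₂/2‖W−U‖² +
τ/2·TV_ε(U)`; the auxiliary variable `W` removes the quartic orthogonality
term so a quadratic majorizer exists.  One sweep multiplies U, V, W by
nonnegative ratios built from the MM weight matrices

    P_mk = |N_m|/|∇_mk U| + Σ_{m̃∈N̄_m} 1/|∇_m̃k U|,
    Z_mk = (1/P_mk)[ (1/|∇_mk U|) Σ_{m̃∈N_m}(U_mk+U_m̃k)/2
                     + Σ_{m̃∈N̄_m}(U_mk+U_m̃k)/(2|∇_m̃k U|) ],

with isolated pixels assigned `P = Z = 0` (their TV contribution is
absent).  The MM construction guarantees a monotone cost decrease, which
the tests assert at 1e-10 relative slack over 300 study-scale sweeps.
When `σ₁ = σ₂ = 0` the W update is skipped (W decouples entirely).

**mul2** minimizes `½‖X−UV‖² + σ₁/4‖I−UᵀU‖² + τ·TV_ε(U)` without an
auxiliary variable; the U update injects `τ·div(∇U/‖∇U‖_ε)` into the
numerator of the multiplicative ratio (the gradient-descent step-size
matrix is absorbed by the standard multiplicative choice `Γ = U ⊘
denominator`).  The numerator can be negative, so the subsequent
positivity projection is essential, and no descent guarantee exists (the
logged objective is the `σ₁/4`-weighted one).

**palm / ipalm / spring** minimize `F(U,V,W) + τ‖U‖_TV` with
`F = ½‖X−UV‖² + σ₁/2‖I−WᵀU‖² + σ₂/2‖W−U‖²`.  Partial gradients:

    ∇_U F = (UV−X)Vᵀ + σ₁ W(WᵀU−I) + σ₂(U−W)
    ∇_V F = Uᵀ(UV−X)
    ∇_W F = σ₁ U(UᵀW−I) + σ₂(W−U)

Step sizes are `η = 1/L̂` with Lipschitz moduli `L_U = λmax(VVᵀ) +
σ₁λmax(WWᵀ) + σ₂`, `L_V = λmax(UᵀU)`, `L_W = σ₁λmax(UᵀU) + σ₂`,
estimated by 20 power iterations on the K×K Gram matrices with a seeded
random start vector, recomputed every outer iteration, and clipped to
`[1e-8, 1e3]`.  The U block applies the TV prox with effective weight
`τ·η_U`, itself clipped at `10τ` to keep the spatial step bounded when the
curvature estimate is small; V and W take projected gradient steps.
Updates use the freshest iterates (U, then V, then W).

`ipalm` evaluates each block's gradient at the extrapolated point
`Y + β(Y − Y_prev)` with `β = min((i−1)/(i+2), 0.45)`.  The cap is a
deliberate design choice: with unscaled `1/L` steps the nonconvex
inertial-PALM admissibility condition requires `β < 1/2`, and an uncapped
Nesterov ramp demonstrably destabilizes late iterations on the phantom
(clustering quality degrades as β → 1).

`spring` replaces the U/V gradients by SGD estimates over a seeded
per-epoch partition of the channel indices into `sr` disjoint blocks
(default `sr = 5`); the splitting assigns `1/N` of the orthogonality terms
to each channel, so the block estimates sum exactly to the full gradient
over one epoch.  The W update always uses the full gradient (cheap, since
K ≪ N).  With `sr = 1` the method is per-iterate identical to `palm`
under a shared seed — asserted to 1e-8 in the tests.

Iteration caps (no other stopping rule, for determinism): 500 sweeps for
mul1/mul2 and the separated engines, 300 iterations for palm/ipalm, 100
epochs for spring.

### Numerical safeguards

All matrices are clipped element-wise to `[1e-16, 1e35]` after ingestion,
after initialization, and after every multiplicative update — the lower
bound prevents zero locking of multiplicative rules, the upper bound
overflow.  Non-finite entries appearing in an update abort the run with a
diagnostic naming the offending matrix.  A power iteration on a zero
matrix yields the upper step clip.  Empty K-means clusters are relocated
by scikit-learn's built-in strategy.

## Separated engines

`kmeans` delegates to scikit-learn's Lloyd algorithm (k-means++ seeding,
single start).  `choi` uses the alternating multiplicative orthogonal
updates `U ← U ∘ (XVᵀ) ⊘ (UVXᵀU)`, `ding` the square-root form
`U ← U ∘ sqrt((XVᵀ) ⊘ (UUᵀXVᵀ))`; both share the plain multiplicative V
rule.  `kimura` and `li` are HALS schemes (column-wise on U, row-wise on
V): `kimura` enforces orthogonality by subtracting cross-column
projections after each least-squares column update, `li` by an additive
penalty `λ·Σ_{l≠k}U_l` (default λ = 0.5) in the column subproblem;
negative intermediates are projected to zero, and a collapsed column is
re-seeded from the positive part of the residual.  Note that per-sweep
descent of `‖X−UV‖_F` holds for the multiplicative engines only from a
feasible (orthonormal-membership) initialization; from an unconstrained
SVD initialization the error necessarily rises while the iterates approach
the orthogonality constraint set.

The TV post-processing applies the prox column-wise to the engine's U and
projects negative entries to zero; both pre- and post-TV hard clusterings
are retained.

## Initialization

`svd`: a nonnegative-double-SVD variant — per leading singular triplet the
sign pair (positive or negative parts) with the larger contribution is
kept, scaled by the singular value; degenerate components fall back to
flat positive vectors.  Deterministic.  `kmeans++`: seed spectra via
k-means++, one Lloyd refinement, binary memberships.  Both normalize U to
unit columns (absorbing the scale into V) so `UᵀU` starts near the
identity, then clip to strict positivity.  Defaults: `kmeans++` for the
`kmeans` and `ding` engines, `svd` everywhere else (and for all combined
solvers), overridable.

## Hyperparameter defaults

σ₁ = σ₂ = 1 and per-method TV weights (mul1: 50, mul2: 10, palm/ipalm:
500, spring: 50; post-TV weights kmeans 0.2, choi/ding 0.05, kimura 0.02,
li 0.05) were selected by a one-off grid search on the default phantom for
the best median van Dongen criterion and stability — the same protocol a
practitioner applies per dataset.  The wide spread of the PALM-family τ is
expected: the prox enters with effective weight `τ·η_U` and `η_U ~ 1/λmax(VVᵀ)`
is of order 1e-4 at this data scale, while the separated prox acts
directly on unit-scale membership columns.  ε_TV = 1e-2 balances
smoothing bias against the curvature of the MM weights.

## Synthetic phantom

`make_phantom` emulates an annotated MALDI acquisition at desk scale:
40×40 pixels, K = 6 spatially connected regions grown by seeded
multi-source randomized BFS (one region weighted down to ≈2% of pixels,
mirroring a strongly underrepresented cell class), N = 120 channels with
per-class disjoint dominant channel blocks on a shared random baseline,
additive truncated-Gaussian noise scaled to a target signal-to-noise
Frobenius ratio (default 3; a Poisson-like option exists), and — crucial
for realism — 10% of pixels contaminated by convex mixing with another
class's signature (weight U(0.3, 0.8)), standing in for matrix-application
artifacts and partial-volume effects.  Without contamination,
channel-i.i.d. noise averages out over N and a purely feature-space
clustering is already perfect, which real acquisitions are not.
`snr = inf` disables every perturbation (`X = U*V*` exactly).
`class_imbalance` further shrinks the minority region by
connectivity-preserving boundary erosion.

What the phantom does **not** emulate: realistic peak shapes, isotope
envelopes, m/z-correlated baselines, spatially correlated noise, and
within-class biological gradients.  Passing tests therefore demonstrate
correct optimization and the genuine benefit of spatial regularization
under pixel-level spectral corruption; they do not certify performance on
real spectra, where preprocessing (binning, baseline removal) and
hyperparameter re-tuning are required.

## Problem sizes and replication

The evaluation protocol runs each method over seeded replicates (CLI
default 30, matching common practice; the bundled acceptance script uses 5
and the heavier integration test 10 to keep a desk-scale footprint) on the
1600-pixel default phantom; per-replicate wall time is recorded but never
asserted.  Reported values are medians across replicates.  With the
deterministic SVD initialization, replicate variance for mul1/mul2/palm/
ipalm collapses to tie-break noise; k-means++-seeded engines and spring
vary through their seeds.

## Known limitations

* Orthogonality in the combined solvers is enforced only via penalties;
  the factor scale drifts (the model fixes only the product UV), so
  orthogonality residuals are meaningful only after column normalization.
* mul2 has no descent guarantee and can oscillate for large τ.
* The stochastic solver's gradient estimator is plain SGD; variance-
  reduced estimators (SAGA/SARAH) are not implemented.
* 3-D grids, anisotropic/higher-order TV, and automatic selection of K or
  of the regularization weights are out of scope.
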