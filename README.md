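# onmftv — spatially coherent clustering via TV-regularized orthogonal NMF

Hyperspectral measurements — mass-spectrometry imaging (MALDI-MSI), Earth
remote sensing, and related modalities — attach a full spectrum to every
pixel of a 2-D grid, and their ground-truth tissue or land-cover classes
form spatially coherent regions.  Classical cluster analysis works in
feature space only, so pixel-level spectral noise produces speckled,
incoherent label maps.  `onmftv` clusters such data by **orthogonal
nonnegative matrix factorization (ONMF) with total-variation (TV)
regularization of the cluster membership matrix**, which pulls isolated
misassignments toward their spatial neighborhood while preserving region
edges.

## The model

Given a nonnegative data matrix `X ∈ R^{M×N}` (M spectra on a pixel grid,
N channels) and K clusters, ONMF seeks nonnegative factors `U ∈ R^{M×K}`
(cluster memberships) and `V ∈ R^{K×N}` (characteristic spectra) with
`X ≈ UV` and `UᵀU ≈ I`; with binary row-orthogonal `U` this is exactly
K-means (`‖X − UV‖_F²` = within-cluster sum of squares).  Spatial coherence
enters through the isotropic total variation of each membership column,

    TV(U) = Σ_k Σ_m sqrt(ε² + Σ_{m̃ ∈ N_m} (U_mk − U_m̃k)²),

with the forward-difference neighborhood `N_(i,j) = {(i+1,j), (i,j+1)}`
restricted to the occupied (annotated) pixels of an arbitrary mask.

Two families of methods are provided:

* **Separated** (`SeparatedONMFTV`): run a classical ONMF engine
  (`kmeans`, the multiplicative `choi` / `ding` rules, or the HALS
  variants `kimura` / `li`), then denoise `U` column-wise with the TV
  proximal operator (dual FISTA) and re-project to the nonnegative orthant.
* **Combined** (`CombinedONMFTV`): minimize reconstruction +
  orthogonality penalty + TV jointly, by one of five solvers —
  `mul1` (majorize–minimization multiplicative updates with auxiliary
  variable `W`, provably monotone), `mul2` (multiplicative update with the
  TV divergence direction), and the proximal-alternating-linearized family
  `palm`, `ipalm` (momentum), `spring` (stochastic mini-batch gradients),
  all with power-iteration Lipschitz step sizes.

Clusterings are scored against ground truth with the external validation
measures entropy, normalized variation of information (VI_n) and the
normalized van Dongen criterion (VD_n); all three are 0 for a perfect
partition, and lower is better.

Because typical annotated MALDI datasets are not redistributable, the
package ships a phantom generator (`make_phantom`) producing spatially
connected label regions, per-class spectral signatures, a strongly
underrepresented minority class, nonnegative noise with pixel-level
spectral contamination, and optional annotation holes.

## Worked example

```python
from onmftv import CombinedONMFTV, SeparatedONMFTV, make_phantom, evaluate_clustering

phantom = make_phantom(seed=0)          # 40x40 grid, K=6, N=120, moderate noise

model = CombinedONMFTV(n_clusters=6, solver="palm", random_state=1)
model.fit(phantom.data)                 # or .fit(X, coords=...) on raw arrays
print(evaluate_clustering(model.labels_, phantom.labels, n_clusters=6))

baseline = SeparatedONMFTV(n_clusters=6, engine="kmeans", random_state=1)
baseline.fit(phantom.data)
pre = evaluate_clustering(baseline.labels_pre_tv_, phantom.labels, n_clusters=6)
post = evaluate_clustering(baseline.labels_, phantom.labels, n_clusters=6)
print(pre["vd_n"], "->", post["vd_n"])
```

prints

```
{'entropy': 0.0431, 'vi_n': 0.0266, 'vd_n': 0.0095, 'K_used': 6}
0.0698 -> 0.0071
```

i.e. the joint PALM solver recovers the six regions almost perfectly
(VD_n ≈ 0.01), and for the two-stage baseline the TV denoising step cuts
the K-means van Dongen criterion roughly tenfold (0.070 → 0.007) by
cleaning up isolated misassigned pixels.  The estimators follow
scikit-learn conventions (`fit`, `fit_predict`, `labels_`, `get_params`),
and fitted factors are available as `U_`, `V_` (and `W_`).

A command-line interface covers the same workflow:

```
onmftv simulate --out phantom/ --seed 0
onmftv run --method palm -K 6 --data phantom/X.csv --coords phantom/coords.csv \
           --labels phantom/labels.csv --seed 1 --out run/
onmftv replicates --method kmeans -K 6 --n-replicates 30 ... --out reps/
onmftv evaluate --pred run/labels.csv --truth phantom/labels.csv
```

Every run writes a manifest (all parameters, seed, library versions);
deterministic configurations reproduce bit-identically from it.

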