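# Methods

## Model

Given a source volume `I_s` and a target volume `I_t` of identical shape,
the flow `u` maps source coordinates into the target: the brightness-
constancy residual is `I_s(x) − I_t(x + u(x))`. Instead of one unknown
vector per voxel, the foreground is partitioned into super-voxels and a
single translation `u_i` is carried by each region `R_i` — a compromise
between a global affine model (too rigid for variable cell dynamics) and
per-voxel flow (underdetermined on textureless objects). The energy is

```
E(u) = Σ_{i∈S} Σ_{x∈R_i} ρ_D( I_s(x) − I_t(x + u_i) )
     + α · V̄ · Σ_{(i,j)∈E} λ_ij ρ_S( ‖u_i − u_j‖ )
```

where `S` is the region set, `E` the edge set of the partition graph,
`V̄` the mean region size (voxels) and `ρ_D`, `ρ_S` Huber penalties. The
smoothness argument is the Euclidean norm of the translation difference
in isotropic units (voxel offsets multiplied by the per-axis scale
normalized so the finest-sampled axis has unit scale), so anisotropic
sampling does not bias the regularizer.

Edges connect regions whose centers of mass are within `d_max` isotropic
voxels — deliberately including non-adjacent regions, because coherently
moving cells are usually separated by background. Edge weights

```
λ_ij = λ0 · exp(−d_ij / d_max) · min(|R_i|, |R_j|) / V̄
```

decrease with centroid distance and grow with the smaller region's voxel
count. The exact functional form is a package choice (the qualitative
contract — distance-decreasing, size-increasing, one `d_max`-controlled
scale — is what matters); it is isolated behind a single pluggable
function so alternatives are one-line swaps.

### Term balance

The data term scales with region voxel counts; `λ_ij` is normalized by
`V̄`, so a per-edge weight is O(1). Multiplying the smoothness sum by `V̄`
restores balance for *any* partition granularity: both terms then scale
with voxel counts, and the degenerate voxel partition (every region one
voxel, `V̄ = 1`, face-adjacency edges) reduces exactly to the classical
robust voxel-wise energy. Without this factor the regularizer contributes
on the order of 1% of the energy at the default `α = 1` and the MRF is
effectively inert.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `d_max` | 25 | isotropic voxels | neighborhood radius; slightly above the typical nearest-neighbor distance of adjacent nuclei, so neighbors exchange motion information without coupling unrelated structures |
| `levels` | 3 | — | Gaussian-pyramid depth; at least two levels are needed to escape local minima for displacements beyond the object radius |
| `step` | 5 | voxels | nominal SLIC super-voxel spacing; regions below `step^d/8` voxels are absorbed (tiny regions carry too little signal) |
| `slic_compactness` | 10 | — | SLIC intensity-vs-space trade-off on the internal [0, 255] intensity normalization |
| `huber_data` (`ρ_D` δ) | 5 | intensity units ([0, 255]) | residuals beyond δ are penalized linearly — intensity values are well preserved between frames, larger deviations are outliers |
| `huber_smooth` (`ρ_S` δ) | 1 | voxel | translation differences beyond 1 voxel cost linearly, allowing motion discontinuities between regions with genuinely different dynamics |
| `alpha` | 1.0 | — | global smoothness multiplier (the absolute term scaling of the reference formulation is not recoverable; with the `V̄` balance above, 1.0 makes the two terms comparable) |
| `sigma` | 1.0 | voxels | Gaussian pre-smoothing to stabilize image gradients |
| `threshold` | `"otsu"` | — | automatic foreground threshold, two-pass Otsu (below) |
| `min_component` | 27 | voxels | smallest surviving foreground component (a 3×3×3 speck) |
| `max_iter` | 200 | — | L-BFGS iteration cap per level (memory 10, gradient tolerance `1e-5·√n`) |

Both volumes are first mapped by one shared affine transform to [0, 255],
so the Huber scales are meaningful regardless of source bit depth.

## Numerical choices

* **Interpolation and gradients.** `I_t(x + u_i)` is sampled by
  multilinear interpolation with clamp-to-edge behaviour outside the
  grid. The data-term gradient is the *exact* analytic derivative of
  that interpolant — the per-cell first difference interpolated along
  the remaining axes, and zero along any clamped axis. The widely used
  alternative (sampling a five-point-stencil gradient field, available
  here as `gradient_5pt` / `grad_mode="fivepoint"`) is smoother but is
  not the derivative of the sampled energy; the exact form keeps the
  analytic gradient consistent with finite differences to near machine
  precision, which quasi-Newton line searches rely on and which the test
  suite verifies at 1e-4.
* **Huber under L-BFGS.** The Huber penalty has a discontinuous second
  derivative but is C¹ and convex; quasi-Newton methods are known to
  converge on it in practice. A level solve that fails to descend
  returns its starting point with a warning rather than raising.
* **Smoothness at Δu = 0.** The gradient of `ρ_S(‖Δu‖)` has a 0/0 at
  `Δu = 0`; it is defined as 0 (the true subgradient there).
* **Pyramid.** Factor 2 per axis, skipping axes of length ≤ 4 (thin
  anisotropic Z stacks); the level count is clamped with a warning when
  no axis can be halved. Volumes are Gaussian-antialiased before
  striding; the mask is downsampled by an any-foreground rule; labels by
  majority vote among foreground children (ties toward the larger id,
  deterministically), so one global region id set spans all levels.
  Super-voxels are computed once at the finest level and propagated
  down, never recomputed.
* **Level transfer.** Region translations are carried by id and
  multiplied by the per-axis factor — no vector-field interpolation is
  needed because unknowns live on regions. A region absent at the
  coarser level is re-initialized from the mean translation of its graph
  neighbors that were present there, else zero.
* **Coarse-level geometry.** Coarse centroids are expressed in
  finest-level isotropic units (coarse index × accumulated factor ×
  normalized scale) and `d_max` is held constant, which is equivalent to
  dividing `d_max` by the pyramid factor when all axes are downsampled
  and remains correct when thin axes are skipped.
* **Degenerate inputs.** An empty foreground yields an all-invalid zero
  flow; an empty partition yields an empty graph; `d_max → 0` removes
  all edges and the solver degenerates to independent per-region
  matching.

## Foreground mask

The automatic threshold is two-pass Otsu on the pre-smoothed volume:
with 80–95% background the first Otsu pass is dominated by the huge
background class and lands inside the dim blob skirts; re-running Otsu on
the voxels above the first cut gives the conservative mask this method
wants (~10% foreground on the default synthetic embryo). Numeric
thresholds and externally produced masks (any nonzero-is-foreground
TIFF) are accepted unchanged; components below `min_component` voxels
are removed.

## Synthetic data

The simulator emulates nuclei-labelled light-sheet recordings:

* **Geometry.** Nuclei are placed by rejection sampling with a minimum
  pairwise separation (default 2 radii; the division fixture uses 1.7,
  touching as in a syncytial blastoderm), with per-nucleus radii drawn
  from a clipped normal.
* **Appearance.** Each nucleus is a *flat-top* super-Gaussian blob
  `exp(−(d²/2σ²)²)` with half-maximum at its radius: a nearly uniform,
  textureless interior with a steep falloff — a plain Gaussian would put
  informative intensity gradient at every voxel and make even voxel-wise
  matching trivial, misrepresenting the data this method exists for.
  Blobs are rendered on an anisotropic grid, blurred by a Gaussian PSF,
  and Gaussian read noise is added. SNR is defined as the typical
  blurred single-blob peak amplitude over the noise standard deviation
  (the image maximum would overstate it where tails overlap).
* **Motion.** `linear` = shared drift `+` optional smooth speed gradient
  along Y (`speed_variation`: same direction, different speeds, as cell
  groups in an embryo) `+` per-nucleus Gaussian jitter; `brownian` =
  i.i.d. Gaussian steps; `division` = a fraction of nuclei replaced by
  two daughters displaced `±separation/2` along a random direction,
  mother→daughter correspondences recorded; `mixed` combines them.
  Photobleaching multiplies frame-2 amplitudes.
* **Truth.** Half-max masks per frame, exact per-nucleus displacements
  (recorded from the drawn motion, not reconstructed from rounded
  centers). For scoring, each division daughter becomes an independent
  ground-truth entry carrying the mother's source-frame mask and the
  mother-to-daughter displacement, so a single translation can match at
  most one daughter — deliberately the hard case.

What the simulator does **not** model: optics-accurate PSFs, chromatin
texture, intensity inhomogeneity across the field, nucleus deformation,
and tissue-scale morphodynamics. Passing tests therefore demonstrate the
solver's correctness and the claimed qualitative behaviours on
controlled data, not segmentation-grade accuracy on real embryos.

### Fixture conditions

* **embryo-small** (default config): 128×128×32 voxels at normalized
  scale (2, 1, 1), 110 nuclei of radius 6 ± 0.5 isotropic units, SNR 10
  — ~90% background, matching the sparsity of real recordings, and small
  enough that a full estimate runs in well under a minute on one CPU.
* **division** fixture: 128×128×32, 60 touching nuclei of radius 8 ±
  0.6, drift (1, 6, −5) voxels with a ±50% speed gradient and unit
  jitter, 30% synchronous divisions with daughter separation equal to
  the nucleus diameter, SNR 2.5. This is the adverse regime in which the
  modeling choices separate: displacements beyond the single-level
  capture range (the pyramid matters), nuclei still resolvable at the
  coarsest level, dense packing and low SNR (region size matters). The
  comparison margins between the full model and the fine-grid ablation
  are modest (a few 1e-3 to 1e-2 of AUC) and seed-dependent in sign only
  rarely; the orderings against voxel-based and single-level variants
  are robust.

## Evaluation protocol

Per nucleus, the estimated displacement is the mean flow over its mask
(invalid voxels excluded; an uncovered nucleus scores zero flow and is
flagged), compared with the true centroid displacement by Euclidean EE
in isotropic units. Reports give EE percentiles (90/95/99/100, linear
interpolation), the per-nucleus EE normalized by the equivalent diameter
`(6V/π)^(1/3)` (2D: `2(V/π)^(1/2)`), quality bands (good < 0.5, bad
> 1.0), and the AUC of the cumulative normalized-EE distribution on
`[0, x_max]`, `x_max = 2` by default (the integration range is a package
choice; it covers the bad band with margin and is configurable). The
ECDF integral is computed in closed form, `mean(max(0, x_max − e))/x_max`
— exact, not a quadrature.

## Known limitations

* One translation per super-voxel cannot represent rotation or shear
  within a region; dividing mothers whose daughters separate can match
  at most one daughter.
* The smoothness term couples everything within `d_max`; strongly
  incoherent motion inside that radius (colliding daughters from
  different mothers) can pull a nucleus to the wrong target. A locally
  reduced `d_max` would help; only a global value is exposed.
* Clamp-to-edge sampling makes the energy insensitive to motion that
  pushes regions outside the volume; flow near the faces is accordingly
  less reliable.
* The solver is single-threaded NumPy; volumes are processed in memory
  (one pair at a time), not out-of-core.
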