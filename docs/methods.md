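# Methods

## Model and assumptions

`icextract` treats intracranial cavity (IC) extraction as binary label
fusion over a template library. The operating assumptions are:

- subject and templates are linearly registered to one 1 mm isotropic
  grid (no resampling is performed; grid mismatches are errors);
- images are denoised and bias-corrected upstream;
- subject and templates share one intensity scale — either normalized
  upstream or via the tissue-based normalization below;
- the IC is a single connected structure whose local intensity patterns
  are represented somewhere in the library. Patterns absent from the
  library cannot be labeled correctly; enlarging the library (including
  by midsagittal flipping, which doubles it) is the intended remedy.

The vote at voxel `x_i` is the weighted mean of candidate-center labels
over the search windows of the `N` selected templates; a vote of 0.5 or
more maps to label 1. Weights combine three ingredients:

1. **Patch distance** `d² = ‖P(x_i) − P(x_{s,j})‖² / |P|` — squared L2,
   normalized by patch size.
2. **Adaptive bandwidth** `h(x_i) = λ · min d² + ε`, the minimum taken
   over all candidates of the target voxel. A near-perfect match makes
   `h` tiny, so the weight field becomes sharply selective; `λ = 0.1`
   by default, `ε = 1e-6` for numerical stability.
3. **Spatial proximity** `exp(−‖x_i − x_j‖ / σ_d)` between patch
   centers, in mm, with `σ_d = 8 mm`: after linear registration,
   spatially closer candidates are more likely to carry the right
   label. The spatial distance enters unsquared.

The bilateral weight is `exp(−(spatial/σ_d + d²/h))`; the classical
baseline (`--baseline`) is `exp(−d²/h²)` with no spatial term. Both are
gated by a structural-similarity preselection
`ss = (2μ₁μ₂/(μ₁²+μ₂²)) · (2σ₁σ₂/(σ₁²+σ₂²)) ≥ 0.97`; the gate avoids
computing exponential weights for clearly dissimilar patches. Degenerate
moments are defined by continuity: a ratio term is 1 when both moments
vanish and 0 when exactly one does.

**Blockwise voting.** One weight per candidate labels the candidate's
whole `(2b+1)³` block (default `b = 1`); per-voxel numerator and weight
mass accumulate over all covering blocks and the vote is their ratio
(overcomplete averaging). Block centers sit every `block_spacing` voxels
per axis (default 2), with a tail center appended only when the last
regular block does not reach the axis end — on even-length axes at
spacing 2 this yields exactly 1/8 of the spacing-1 evaluation sites.
With `b = 0` and spacing 1 the scheme reduces exactly to voxelwise
fusion (verified bit-for-bit in the tests).

**Zero-mass fallback.** If no candidate of a target center survives the
gate, its uncovered voxels receive the majority label of the candidate
centers (ties → 0) and are flagged in `VoteVolume.fallback`. This is a
deterministic convention for a case the weight model leaves undefined.

**Boundary handling.** Target patches are clipped at the image border;
candidate locations are restricted to positions where every clipped
target offset is in-bounds, so compared patches always have equal
length; label blocks are clipped to in-bounds voxels at both ends. No
padding intensities are invented.

## Multiresolution pipeline

`segment()` runs a [4, 2, 1] downsampling pyramid:

1. Intensities are block-averaged per level; masks are block-averaged
   and thresholded at 0.5 (ties → 1).
2. Templates are preselected once, at the coarsest scale, by mean
   squared intensity difference over the union of template masks,
   ascending with index tie-break. Only `N` (default 30) templates
   enter fusion.
3. Coarsest level: blockwise fusion over the union of the selected
   template masks dilated by the boundary-band width.
4. Each finer level: the previous mask is upsampled (nearest neighbor)
   and fusion re-runs only inside a Chebyshev band of ±2 voxels around
   its boundary; labels outside the band are frozen. This bounds cost
   and confines re-estimation to the uncertain boundary shell.
5. The full-resolution mask yields `icv_ml = count × voxel volume /
   1000`.

The per-level patch radii [1, 1, 1] and search radii [4, 3, 2]
(coarse→fine) are this package's own defaults — the multiresolution
schedule for this family of methods is not standardized — and are fully
configurable, as are all parameters, via a YAML/JSON config mirroring
`FusionConfig` field-for-field.

The pipeline contains no random number draws: identical inputs and
configuration give bit-identical masks. The `seed` field is recorded in
provenance and drives only synthetic data generation.

## Intensity normalization

Robust CSF/GM/WM means are estimated inside a region of interest
(default: the library's majority mask, a stand-in for a standard-space
brain mask) by alternating nearest-mean assignment with trimmed-mean
updates: each class mean is recomputed after discarding the 20 % of its
voxels farthest from the current mean, which suppresses partial-volume
voxels lying between tissue modes. Initialization is at the
10th/50th/90th ROI intensity percentiles; convergence when every mean
moves < 0.01; at most 100 iterations. The exact trimming rule of the
original robust estimator this emulates is not publicly specified, so
this scheme is a documented stand-in chosen for determinism and
simplicity.

The piecewise-linear map then anchors (0, CSF, GM, WM) at
(0, 50, 150, 250); the last segment's slope extends above the WM anchor
and output is clamped at 0 below. On a noiseless three-class volume the
re-estimated means hit the anchors exactly; with Gaussian noise σ = 5
the mapped class means stay within 1 unit (the residual bias comes from
slope changes at the anchors acting on symmetric noise).

## Synthetic phantoms

The generator emulates a desk-scale template library: nested ellipsoids
(skull shell, outer CSF, GM shell, WM core, CSF ventricles) on a 64³
1 mm grid, tissue intensities already on the normalized scale
(background 10, skull 40, CSF 50, GM 150, WM 250), additive Gaussian
noise (default σ = 5), and a smooth random displacement field (sum of
three low-frequency sinusoids per axis, amplitude-capped at 2 voxels,
seeded) applied identically to labels and intensities. Library
templates additionally jitter the three IC tissue means (σ = 5 units).
Masks are derived from the deformed labels, so ground truth is exact
and bit-reproducible from (spec, seed).

What the phantoms do **not** model: Rician noise statistics, bias
fields, partial-volume averaging at tissue interfaces, true cortical
folding geometry, and registration error beyond smooth low-frequency
deformation. Passing phantom tests therefore demonstrates correctness
of the fusion machinery and pipeline plumbing — not clinical-grade
accuracy on real heads, which depends on library quality and
preprocessing.

Problem sizes used in the test suite — 64³ leave-one-out over 10
phantoms with N = 9, 32³ libraries elsewhere — were chosen to keep the
full suite in the low minutes on one CPU while still exercising every
pipeline stage at multiple scales.

## Numerical choices and edge cases

- All fusion arithmetic is float64 with fixed loop order; results are
  deterministic across runs.
- Vote threshold is inclusive at 0.5 (`v ≥ 0.5 → 1`).
- Mask downsampling ties (block mean exactly 0.5) round to 1, matching
  the vote convention.
- Template-selection ties break toward the lower library index.
- `dice(empty, empty) = 1` by the continuity convention; `overlap()`
  refuses an empty reference because sensitivity is then undefined.
- Percent volume difference uses the symmetrized denominator
  `(v1+v2)/2` by default; a reference-anchored variant is available.

## Known limitations

- Binary labels only; no multi-class fusion.
- No registration or bias correction: inputs must be preprocessed.
- The blockwise denominator is per-voxel accumulated weight mass over
  covering blocks; other overcomplete-averaging conventions exist, but
  this one reduces exactly to the voxelwise formula in the degenerate
  case, which is the property the tests pin down.
- Single-threaded kernel; a 64³ phantom segments in seconds, a full
  181×217×181 head in MNI space in minutes.
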