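# icextract

Multi-template, nonlocal patch-based extraction of the intracranial
cavity (IC) from T1-weighted brain MRI.

Regional brain volumes are routinely normalized by the intracranial
cavity volume (ICV) to remove head-size effects, so an accurate and
reproducible IC mask matters for almost every downstream morphometric
analysis. `icextract` segments the IC by label fusion against a library
of pre-labeled templates: the subject and the templates are assumed
linearly registered to a common 1 mm isotropic space and intensity
normalized, and each subject voxel receives a soft vote computed from
similar intensity patches found across the best-matching templates.

## Method

For a voxel `x_i`, candidate patches `P(x_{s,j})` are drawn from a search
window `V_i` around the corresponding location in each of the `N`
preselected templates, and the fused vote is the weighted label average

    v(x_i) = Σ_s Σ_{j∈V_i} w(x_i, x_{s,j}) l_{s,j} / Σ_s Σ_j w(x_i, x_{s,j})

with final label `L(x_i) = 1` iff `v(x_i) ≥ 0.5`. The weight is
*bilateral* — it combines patch intensity distance with spatial proximity
of the patch centers, which is informative because all images share one
registered space:

    w = exp(−(‖x_i − x_j‖ / σ_d + ‖P(x_i) − P(x_{s,j})‖² / h(x_i)))

where `‖·‖²` is the squared L2 patch distance normalized by patch size,
`σ_d = 8 mm`, and the bandwidth adapts per voxel to the best match,
`h(x_i) = λ·min_{s,j} ‖P(x_i) − P(x_{s,j})‖² + ε` with `λ = 0.1`.
Candidates are preselected by a cheap structural-similarity score on
patch means and standard deviations (gate 0.97), and a classical
intensity-only weight `exp(−d²/h²)` is available as an ablation baseline.

Votes are cast *blockwise*: one weight labels the candidate's whole
3×3×3 block, blocks are placed every 2 voxels, and each voxel's vote is
the overcomplete average over all covering blocks — an intrinsic
regularization that also cuts weight evaluations by 2³ = 8. The whole
scheme runs coarse-to-fine on a [4, 2, 1] mm pyramid, re-estimating only
a narrow band around the upsampled boundary at each finer level.

The package also provides tissue-based intensity normalization (robust
CSF/GM/WM mean estimation and a piecewise-linear map anchoring them at
50/150/250), library utilities (validation, midsagittal flip
augmentation), overlap/volume metrics, and a synthetic 3-tissue head
phantom generator with exact ground-truth masks, so the entire pipeline
is testable without any external data.

## Worked example

Simulate a 6-phantom template library and one held-out subject, segment
it, and score the result against its ground-truth mask:

```sh
icextract simulate --n 6 --seed 42 --out-dir library --grid-size 64
icextract simulate --n 1 --seed 99 --out-dir subject --grid-size 64
icextract extract --subject subject/phantom_000.nii.gz \
                  --library library/library.json \
                  --out mask.nii.gz --n-templates 5 --seed 42
icextract evaluate mask.nii.gz subject/phantom_000_mask.nii.gz
```

which prints

```
ICV_ml  45.633
tag,dice,sensitivity,specificity,volume_a_ml,volume_b_ml,pct_volume_diff,error
pair0,0.9898...,0.9880...,0.9982...,45.633,45.798,0.3609...
```

The estimated intracranial volume is 45.633 mL (these desk-scale
phantoms are ~64³ voxels; a real head in MNI space yields ~1300–1700 mL),
overlapping the ground truth with Dice 0.990 and a test volume error of
0.36 %. Every `extract`/`simulate` run writes a JSON manifest recording
the exact configuration and seed, and repeated runs are bit-identical.

Library API equivalent:

```python
import icextract as ic

lib = ic.make_library(ic.PhantomSpec(seed=42), n=6)
subject, truth = lib[0][0], lib[0][1]
result = ic.segment(subject, lib, ic.FusionConfig(n_templates=5))
print(result.icv_ml, ic.dice(result.mask, truth))
```

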