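# roifuse

Multimodal atlas-ROI feature fusion for 3D neuroimage classification,
with a brain-phantom simulator for end-to-end testing.

## The problem

Dementia staging from neuroimaging (normal controls NC, stable and
progressive mild cognitive impairment sMCI/pMCI, Alzheimer's disease
AD) classically follows one of two routes: learn directly from the
registered 3D volumes (MRI, FDG-PET) with a convolutional network, or
reduce each volume to a handful of per-region scalars defined by the
AAL atlas — gray-matter volume per region normalized to intracranial
volume for MRI, mean tracer uptake per region for PET — and feed those
to a conventional classifier. Each route discards what the other
keeps.

`roifuse` implements an architecture that uses both at once. The ROI
scalars are *painted back into image space*: every voxel of region *r*
receives that region's scalar, producing a piecewise-constant
"synthetic image" aligned with the original volume. Per modality, a
CNN processes the original volume while a convolutional auto-encoder
(CAE) processes the synthetic one; after each of the three convolution
stages the two branches exchange feature maps by channel
concatenation. The CAE decoder is trained to reconstruct the synthetic
image restricted to the 32 AAL regions most strongly associated with
AD (hippocampus, amygdala, posterior cingulate, temporal and parietal
cortex, ...), which steers the shared representation toward those
regions. Flattened features from all modalities are fused by a small
fully connected head with softmax output.

## Model

Per modality m ∈ {MRI, PET}, with original volume x and synthetic
volume x_syn:

- encoder latent: z = f(x_syn), z ∈ R^Z
- reconstruction: x̂ = g(f(x_syn)), trained against the 32-ROI-masked
  synthetic image t with MSE: L_rec = mean_v (x̂_v − t_v)²
- classification: two-class cross-entropy L_cls = −log p(y) on the
  softmax output of the fusion head
- joint objective: L = λ_cls · L_cls + λ_rec · Σ_m L_rec,m
  (λ_cls = λ_rec = 1 by default), optimized end to end with Adam.

Each convolution stage is conv → ReLU → batch norm → 2× max-pool, three
stages per branch; cross-branch concatenation is bidirectional by
default and severable for ablations (`cross_mode="none"`,
`use_cae=False`).

Evaluation uses stratified k-fold cross-validation over three binary
tasks (NC vs AD, MCI vs NC with MCI = sMCI ∪ pMCI, pMCI vs sMCI) and
reports ACC, SEN, SPE, PRE, F1 (from confusion counts) and AUC (rank
statistic, ties ½) as mean ± SD over folds and repeats.

Because clinical volumes cannot ship with a test suite, the `phantom`
module generates template-space stand-ins: a Voronoi parcellation of
an ellipsoidal brain mask (116 regions by default, mirroring AAL), and
per-subject paired pseudo-MRI/pseudo-PET volumes in which the disease
class reduces signal inside the 32 AD regions with additive Gaussian
noise. A real AAL label map in NIfTI form loads through the same
`AtlasLabelMap` reader.

The network stack (3D convolution, batch norm, pooling, autodiff, Adam)
is implemented directly on NumPy with BLAS-backed matmuls; it is small,
deterministic, and fast enough for phantom-scale volumes on one CPU
core. Gradients are verified against finite differences in the tests.

## Worked example

```python
import roifuse as rf

atlas = rf.make_toy_atlas((32, 32, 32), n_regions=116, seed=0)
effects = rf.EffectSpec(noise_sd=0.1)          # 30% reduction in the 32 AD ROIs
ad = rf.simulate_subject(atlas, "AD", effects, seed=1)
nc = rf.simulate_subject(atlas, "NC", effects, seed=2)

pet_ad = rf.pet_roi_means(ad.pet_volume, atlas)
pet_nc = rf.pet_roi_means(nc.pet_volume, atlas)
print(f"Hippocampus_L (ROI 37) PET mean:  AD {pet_ad.values[37]:.3f}   NC {pet_nc.values[37]:.3f}")
print(f"unaffected   (ROI  1) PET mean:  AD {pet_ad.values[1]:.3f}   NC {pet_nc.values[1]:.3f}")

rois = rf.ad_roi_indices()                     # the 32 AD-related AAL regions
syn = rf.paint_synthetic_image(pet_ad, atlas, rois.indices)
print(f"synthetic PET image: nonzero voxels {int((syn != 0).sum())} "
      f"of {int(atlas.brain_mask.sum())} brain voxels")
```

prints

```
Hippocampus_L (ROI 37) PET mean:  AD 0.701   NC 0.994
unaffected   (ROI  1) PET mean:  AD 1.009   NC 0.981
synthetic PET image: nonzero voxels 3355 of 12568 brain voxels
```

The AD subject's hippocampal uptake sits near 0.7 (baseline 1.0 minus
the 30% class effect) while an unaffected region stays near baseline;
the painted synthetic image carries those scalars only inside the
32-ROI mask.

The same pipeline is scriptable from the shell:

```sh
roifuse simulate --shape 32 32 32 --n-regions 116 \
    --n-per-class NC=20 --n-per-class AD=20 --seed 0 --out-dir cohort/
roifuse extract --manifest cohort/manifest.tsv --atlas cohort/atlas.nii.gz \
    --out cohort/features.csv
roifuse train --manifest cohort/manifest.tsv --atlas cohort/atlas.nii.gz \
    --task NC_vs_AD --seed 0 --out-dir run/
roifuse evaluate --results-dir run/
```

## Layout

- `roifuse.phantom` — atlas + cohort simulation, NIfTI/TSV I/O
- `roifuse.features` — ROI feature extraction, synthetic-image painting,
  the 32-region AD ROI table
- `roifuse.network` — autodiff tape, layers, the dual-branch model,
  losses, training loop
- `roifuse.evaluation` — stratified k-fold experiments and metrics
- `roifuse.cli` — the `roifuse` command

See `docs/methods.md` for modeling assumptions, parameter defaults and
limitations.
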