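# Methods

## Scope and data model

`roifuse` operates entirely in template space: every volume (subject
MRI, subject PET, GM probability map, atlas label map) shares one
voxel grid, and region membership is a pure label lookup. The heavy
preprocessing that produces such data in practice — bias correction,
skull stripping, MNI registration, tissue segmentation — is upstream
of this package and is emulated, not implemented: the phantom module
generates volumes that are already registered and masked.

## ROI features

Two scalars summarize each atlas region per subject:

- **GM volume fraction** (MRI modality): sum of the GM map over the
  region's voxels divided by intracranial volume (ICV). ICV is not
  observable in the phantoms (there are no WM/CSF compartments), so
  the default ICV proxy is total GM mass over the brain mask, which
  makes the fractions sum to one; an externally computed GM+WM+CSF
  volume can be passed instead (`icv=` argument). Either way the
  contract is a unitless fraction in [0, 1], invariant to global
  rescaling of the GM map.
- **PET ROI mean** (PET modality): arithmetic mean of the PET volume
  over the region. By default the mean runs over the full region; a
  GM-masked variant (`gm_mask=` argument) restricts it to voxels with
  positive GM, since the field is not consistent about which is meant.

Painting writes a feature vector back to image space by hard label
assignment — every voxel of region r gets value_r, background 0. No
partial-volume weighting is applied; synthetic images are
intentionally piecewise constant. Painting is linear in the features
and exactly invertible by the PET ROI mean, properties the tests
exploit.

The 32-region AD ROI table (posterior cingulate, hippocampus,
parahippocampus, amygdala, occipital, fusiform, parietal, precuneus,
temporal regions; AAL indices 35–42, 49–56, 59–62, 67–68, 81–90) is a
package constant with names, used both as the default reconstruction
mask and as the default set of affected regions in the phantom
generator.

## Phantom generator

The generator emulates the *structure* the method assumes, not the
appearance of clinical data:

- **Atlas**: nearest-seed (Voronoi) parcellation of an axis-aligned
  ellipsoid (semi-axes 0.45 of each grid dimension) into n nonempty
  regions; seeds are distinct mask voxels drawn per RNG seed, so every
  region contains at least its seed voxel. Default 116 regions on a
  32³ grid (~12.6k brain voxels, ~100 voxels per region).
- **Subjects**: region r has baseline mean 1.0 (arbitrary units;
  nothing downstream depends on absolute intensity scale). A
  subject of class c gets baseline·(1 − reduction_c) in affected
  regions, plus i.i.d. Gaussian voxel noise, exactly zero outside the
  brain mask. Default reductions 0 / 0.10 / 0.20 / 0.30 for
  NC / sMCI / pMCI / AD in both modalities — a monotone severity
  gradient with a strong, cleanly planted AD effect — and noise SD
  0.1, i.e. a 3:1 effect-to-noise ratio at the voxel level for NC vs
  AD. The GM map is the pseudo-MRI scaled by the maximum baseline and
  clipped to [0, 1], a tissue-probability-like stand-in that avoids
  simulating segmentation.
- **Determinism**: everything is a pure function of (parameters,
  seed); per-subject seeds derive from the master seed and subject
  index through `numpy.random.SeedSequence`, so regeneration is
  bit-identical and order-independent.

What the phantoms deliberately lack: anatomy, intensity
nonuniformity, registration error, partial-volume effects, correlated
noise, scanner physics. Tests passing on phantoms therefore
demonstrate that the pipeline is wired correctly and can recover a
planted regional effect — not that any particular accuracy transfers
to clinical data.

## Network

Per modality, two three-stage convolutional encoders run in parallel:
the CNN branch on the original volume, the CAE encoder on the
full-parcellation synthetic image. Each stage is conv(k=3, 'same') →
ReLU → batch norm → 2×2×2 max-pool, in that order (the ReLU-then-norm
order is unusual by current convention but is the documented design
here). After every stage the two branches' maps are concatenated along
channels and fed to the next stage of both branches (`bidirectional`);
asymmetric wiring (`cae_to_cnn`, `cnn_to_cae`) and a severed mode
(`none`) are selectable, and `use_cae=False` removes the CAE branch
entirely for the CNN-only ablation.

The CAE bottleneck is a fully connected map from the flattened final
encoder stage to a latent z (Z = 128 by default); the decoder mirrors
the encoder with three (nearest-neighbour upsample → conv) stages and
consumes only z — cross-branch features do not enter the decoder. Its
target is the synthetic image masked to the 32 AD regions, scored by
MSE. The classifier consumes the flattened final concatenated maps of
every modality, applies dropout (rate 0.5) and a two-layer FC head
with softmax over the two classes; "binary cross-entropy" is
implemented as two-class cross-entropy on that head, which is the same
function. The joint loss is λ_cls·CE + λ_rec·Σ_m MSE_m with both
weights 1 by default; the reconstruction and classification terms are
optimized in a single stage.

Weight initialization defaults to He fan-in scaling. A literal
N(0, 1) initialization is available (`init="unit_normal"`) for
fidelity to the original description, but unit-SD weights make deep
3D stacks explode numerically, so it is opt-in.

### The NumPy backend

The network runs on a small reverse-mode autodiff tape written
directly on NumPy (float32 throughout). 3D convolution is im2col with
a single BLAS gemm per layer; the column matrix is cached for the
backward pass unless it exceeds 128 MiB, in which case it is rebuilt.
This backend exists because the model is small enough not to need a
GPU framework, and it keeps the dependency set to the scientific
Python base. Every op's gradient is checked against central finite
differences in the test suite, and the convolution forward pass
against `scipy.ndimage.correlate`.

## Training and evaluation

Optimization is Adam. Two named settings:

- **desk scale** (package defaults): lr 2·10⁻³, 10 epochs, batch 16,
  k = 5 folds, 3 repeats, batch-norm momentum 0.5, and network inputs
  block-averaged by 2 (so 32³ phantoms are processed at 16³). These
  are sized for single-core CPUs: one cross-validated NC-vs-AD
  experiment on a 40-subject cohort takes ~2.5 minutes. The high BN
  momentum compensates for the short schedule (few optimizer steps
  must still converge the running statistics used at evaluation); the
  raised learning rate does the same for the weights.
- **reference scale**: the original large-data settings — lr 10⁻⁴, 100
  epochs, batch 30, k = 10, 10 repeats — remain expressible through
  `TrainConfig`/`ExperimentConfig`; nothing in the code is specialized
  to the desk values.

Feature extraction, painting and reconstruction targets are
per-subject computations from that subject's own volumes, so k-fold
evaluation cannot leak test information into training; folds are
stratified by class, disjoint and exhaustive, with per-class sizes
differing by at most one. By default fold assignment is re-randomized
every repeat (`refold_each_repeat=False` keeps folds fixed and varies
only initialization and shuffling). The MCI group for MCI vs NC pools
sMCI and pMCI. Subjects must have both modalities; there is no
missing-modality path.

Metrics come from confusion counts: ACC, SEN, SPE, PRE, F1, plus AUC
as the Mann–Whitney rank statistic with ties counted ½. A metric whose
denominator is zero (e.g. sensitivity of a fold with no positives) is
reported as an explicit undefined marker and excluded from mean/SD
summaries with a logged count — never coerced to zero. Summaries are
mean ± SD over all folds of all repeats, recomputable from the stored
per-fold values. No hypothesis testing or multiplicity correction is
applied; the pipeline reports raw metrics.

## Numerical notes and edge cases

- Zero ICV (empty GM map) and shape mismatches raise immediately.
- Parcellation ties in the Voronoi assignment resolve by KD-tree
  order, deterministically per seed; an atlas whose ellipsoid mask has
  fewer voxels than regions is an error, never a silent shrink.
- Probability clipping at 10⁻¹² guards the cross-entropy log.
- Max-pool gradients split evenly among tied maxima.
- Training splits are validated (both classes present) for all folds
  of a repeat before any fold trains.
- With dropout off, evaluation-mode forward passes are bit-reproducible;
  whole-pipeline determinism additionally relies on single-threaded
  BLAS behaving deterministically, which holds in the tested setup.

## Known limitations

- The phantom's class effect is spatially uniform within each affected
  region — exactly the signal the ROI features are designed to detect.
  Realistic within-region gradients would weaken the synthetic-image
  branch relative to the CNN branch in ways these tests do not probe.
- The GM "map" is derived from the pseudo-MRI rather than an
  independent tissue model, so MRI and GM features are perfectly
  coupled in phantoms.
- The decoder's reconstruction quality is only constrained through the
  joint loss; no separate reconstruction-quality acceptance exists.
- Single-stage joint training with equal loss weights is a choice, not
  a tuned optimum; the weights are exposed (`LossWeights`).
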