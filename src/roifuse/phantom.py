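"""Template-space brain phantoms for the ROI-fusion pipeline.

Real use of the pipeline assumes MRI/PET volumes that have been
skull-stripped, registered to the MNI template and parcellated with the
AAL atlas (116 regions). This module generates stand-ins with the same
structure: an ellipsoidal "brain" mask parcellated into nearest-seed
(Voronoi) regions, and per-subject paired pseudo-MRI / pseudo-PET
volumes in which a disease class reduces signal inside a chosen set of
regions (by default the 32 AD-related AAL regions) on top of additive
Gaussian voxel noise. All generation is a pure function of
(parameters, seed).
"""

from __future__ import annotations

import dataclasses
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

CLASSES = ("NC", "sMCI", "pMCI", "AD")

#: default per-class fractional signal reduction in affected regions
DEFAULT_GM_REDUCTION = {"NC": 0.0, "sMCI": 0.10, "pMCI": 0.20, "AD": 0.30}
DEFAULT_PET_REDUCTION = {"NC": 0.0, "sMCI": 0.10, "pMCI": 0.20, "AD": 0.30}
DEFAULT_NOISE_SD = 0.1
DEFAULT_BASELINE = 1.0


@dataclasses.dataclass(frozen=True)
class AtlasLabelMap:
    """Integer parcellation: voxel -> region index, 0 = background."""

    labels: np.ndarray
    name_table: Mapping[int, str]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3 or not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be a 3D integer array")
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def region_index_set(self) -> list[int]:
        return sorted(self.name_table)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def validate(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        declared = set(self.name_table)
        if present - declared:
            raise ValueError(f"labels contain undeclared regions {sorted(present - declared)}")
        empty = declared - present
        if empty:
            raise ValueError(f"declared regions with zero voxels: {sorted(empty)}")


@dataclasses.dataclass(frozen=True)
class EffectSpec:
    """Class-dependent signal model for the phantom generator.

    Reductions are fractions in [0, 1): a voxel of an affected region r
    gets baseline_r * (1 - reduction) plus N(0, noise_sd) noise.
    `affected_rois=None` means "resolve to the 32 AD-related AAL regions
    at simulation time" (only valid for atlases carrying AAL-style
    indices, i.e. >= 90 regions); smaller toy atlases must name the
    affected set explicitly.
    """

    affected_rois: frozenset[int] | None = None
    gm_reduction_per_class: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GM_REDUCTION))
    pet_reduction_per_class: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PET_REDUCTION))
    noise_sd: float = DEFAULT_NOISE_SD
    baseline_mean_per_region: Mapping[int, float] | float = DEFAULT_BASELINE

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for table in (self.gm_reduction_per_class, self.pet_reduction_per_class):
            for cls, red in table.items():
                if not 0.0 <= red < 1.0:
                    raise ValueError(f"reduction for {cls} must be in [0,1), got {red}")
        if self.affected_rois is not None:
            object.__setattr__(self, "affected_rois", frozenset(self.affected_rois))

    def resolve_affected(self, atlas: AtlasLabelMap) -> frozenset[int]:
        if self.affected_rois is not None:
            return self.affected_rois
        from .features import ad_roi_indices

        if len(atlas.region_index_set) < 90:
            raise ValueError(
                "affected_rois defaults to the 32 AD-related AAL indices, which "
                f"requires an atlas with >= 90 regions; this atlas has "
                f"{len(atlas.region_index_set)}. Pass affected_rois explicitly.")
        return frozenset(ad_roi_indices().indices)

    def baseline(self, region: int) -> float:
        if isinstance(self.baseline_mean_per_region, Mapping):
            return float(self.baseline_mean_per_region[region])
        return float(self.baseline_mean_per_region)


@dataclasses.dataclass(frozen=True)
class PhantomSubject:
    subject_id: str
    class_label: str
    mri_volume: np.ndarray
    pet_volume: np.ndarray
    gm_map: np.ndarray
    seed: int


def ellipsoid_mask(shape: Sequence[int], semiaxis_fraction: float = 0.45) -> np.ndarray:
    """Axis-aligned ellipsoid centred in the grid (the toy 'brain')."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    centre = [(s - 1) / 2.0 for s in shape]
    semi = [max(semiaxis_fraction * s, 0.5) for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    return r2 <= 1.0


def make_toy_atlas(shape: Sequence[int], n_regions: int, seed: int,
                   semiaxis_fraction: float = 0.45) -> AtlasLabelMap:
    """Voronoi parcellation of an ellipsoidal mask into `n_regions` parcels.

    Region seeds are drawn without replacement from mask voxels, so every
    region contains at least its own seed voxel; a census check guards
    against any degenerate draw, with bounded redraws.
    """
    shape = tuple(int(s) for s in shape)
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    mask = ellipsoid_mask(shape, semiaxis_fraction)
    coords = np.argwhere(mask)
    if len(coords) < n_regions:
        raise ValueError(
            f"brain mask has {len(coords)} voxels, cannot host {n_regions} regions")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)
    for _attempt in range(10):
        pick = rng.choice(len(coords), size=n_regions, replace=False)
        tree = cKDTree(coords[pick])
        _, nearest = tree.query(coords)
        labels[tuple(coords.T)] = nearest + 1
        counts = np.bincount(labels.ravel(), minlength=n_regions + 1)
        if (counts[1:] > 0).all():
            break
    else:  # pragma: no cover - unreachable with distinct-voxel seeds
        raise RuntimeError("could not place nonempty regions after 10 attempts")
    names = {r: f"toy_region_{r:03d}" for r in range(1, n_regions + 1)}
    return AtlasLabelMap(labels=labels, name_table=names)


def simulate_subject(atlas: AtlasLabelMap, class_label: str, effects: EffectSpec,
                     seed: int, subject_id: str | None = None) -> PhantomSubject:
    """One subject: paired pseudo-MRI / pseudo-PET volumes plus a GM map.

    Voxels of region r get baseline_r * (1 - reduction_class) when r is
    affected (baseline_r otherwise), plus N(0, noise_sd); background is
    exactly zero. The GM map is the MRI volume scaled by the maximum
    baseline and clipped to [0, 1], a tissue-probability-like stand-in.
    """
    if class_label not in effects.gm_reduction_per_class:
        raise ValueError(
            f"unknown class {class_label!r}; valid: "
            f"{sorted(effects.gm_reduction_per_class)}")
    affected = effects.resolve_affected(atlas)
    rng = np.random.default_rng(seed)
    labels = atlas.labels
    regions = atlas.region_index_set
    max_region = max(regions)

    def painted(reduction: float) -> np.ndarray:
        lut = np.zeros(max_region + 1)
        for r in regions:
            base = effects.baseline(r)
            lut[r] = base * (1.0 - reduction) if r in affected else base
        return lut[labels]

    mask = atlas.brain_mask
    gm_red = effects.gm_reduction_per_class[class_label]
    pet_red = effects.pet_reduction_per_class[class_label]
    mri = painted(gm_red)
    pet = painted(pet_red)
    if effects.noise_sd > 0:
        mri = mri + rng.normal(0.0, effects.noise_sd, labels.shape)
        pet = pet + rng.normal(0.0, effects.noise_sd, labels.shape)
    mri = np.where(mask, mri, 0.0)
    pet = np.where(mask, pet, 0.0)
    max_baseline = max(effects.baseline(r) for r in regions)
    gm_map = np.where(mask, np.clip(mri / max_baseline, 0.0, 1.0), 0.0)
    if subject_id is None:
        subject_id = f"sub-{class_label}-seed{seed}"
    return PhantomSubject(subject_id=subject_id, class_label=class_label,
                          mri_volume=mri, pet_volume=pet, gm_map=gm_map,
                          seed=int(seed))


def subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed, independent of generation order."""
    state = np.random.SeedSequence(entropy=(int(master_seed), int(index)))
    return int(state.generate_state(1)[0] % (2 ** 31))


def simulate_cohort(atlas: AtlasLabelMap, n_per_class: Mapping[str, int],
                    effects: EffectSpec, seed: int
                    ) -> tuple[list[PhantomSubject], pd.DataFrame]:
    """Generate a cohort with the requested per-class counts.

    Returns (subjects, manifest); manifest columns subject_id, class, seed.
    """
    for cls, n in n_per_class.items():
        if n < 0:
            raise ValueError(f"negative count for class {cls}")
    subjects: list[PhantomSubject] = []
    index = 0
    for cls in sorted(n_per_class):
        for i in range(n_per_class[cls]):
            sid = f"sub-{cls}-{i:03d}"
            subjects.append(simulate_subject(
                atlas, cls, effects, seed=subject_seed(seed, index),
                subject_id=sid))
            index += 1
    manifest = pd.DataFrame(
        {"subject_id": [s.subject_id for s in subjects],
         "class": [s.class_label for s in subjects],
         "seed": [s.seed for s in subjects]})
    return subjects, manifest


# ---------------------------------------------------------------------------
# NIfTI / TSV I/O


def _nifti_affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_atlas(atlas: AtlasLabelMap, path: str) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(atlas.labels.astype(np.int32),
                          _nifti_affine(atlas.voxel_size_mm))
    nib.save(img, path)
    names = pd.DataFrame(
        {"index": atlas.region_index_set,
         "name": [atlas.name_table[r] for r in atlas.region_index_set]})
    names.to_csv(_sidecar(path), sep="\t", index=False)


def _sidecar(path: str) -> str:
    base = path
    for ext in (".nii.gz", ".nii"):
        if base.endswith(ext):
            base = base[: -len(ext)]
            break
    return base + "_labels.tsv"


def load_atlas(path: str) -> AtlasLabelMap:
    """Read any integer label-map NIfTI (toy or a real AAL atlas)."""
    import nibabel as nib

    img = nib.load(path)
    labels = np.asarray(img.dataobj).astype(np.int32)
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    sidecar = _sidecar(path)
    if os.path.exists(sidecar):
        tab = pd.read_csv(sidecar, sep="\t")
        names = dict(zip(tab["index"].astype(int), tab["name"].astype(str)))
    else:
        names = {int(r): f"region_{int(r):03d}" for r in np.unique(labels) if r != 0}
    return AtlasLabelMap(labels=labels, name_table=names, voxel_size_mm=voxel)


def save_cohort(subjects: Sequence[PhantomSubject], atlas: AtlasLabelMap,
                out_dir: str) -> pd.DataFrame:
    """Write per-subject volumes as .nii.gz plus a manifest.tsv."""
    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    aff = _nifti_affine(atlas.voxel_size_mm)
    rows = []
    for s in subjects:
        paths = {}
        for kind, vol in (("mri", s.mri_volume), ("pet", s.pet_volume),
                          ("gm", s.gm_map)):
            fname = f"{s.subject_id}_{kind}.nii.gz"
            nib.save(nib.Nifti1Image(vol.astype(np.float32), aff),
                     os.path.join(out_dir, fname))
            paths[kind] = fname  # manifest paths are relative to its folder
        rows.append({"subject_id": s.subject_id, "class": s.class_label,
                     "mri_path": paths["mri"], "pet_path": paths["pet"],
                     "gm_path": paths["gm"], "seed": s.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return manifest


def load_cohort(manifest_path: str) -> list[PhantomSubject]:
    import nibabel as nib

    manifest = pd.read_csv(manifest_path, sep="\t")
    base = os.path.dirname(os.path.abspath(manifest_path))

    def _vol(p):
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        return np.asarray(nib.load(p).dataobj, dtype=np.float64)

    return [PhantomSubject(subject_id=row.subject_id, class_label=row["class"],
                           mri_volume=_vol(row.mri_path),
                           pet_volume=_vol(row.pet_path),
                           gm_map=_vol(row.gm_path), seed=int(row.seed))
            for _, row in manifest.iterrows()]
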