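"""Atlas-ROI feature extraction and synthetic-image painting.

Two scalar features per region: the GM modality carries each region's
gray-matter volume as a fraction of intracranial volume (ICV); the PET
modality carries the mean voxel intensity over the region. "Painting"
writes a feature vector back into image space — every voxel of region r
takes the region's scalar — producing the piecewise-constant synthetic
image the dual-branch network consumes, optionally restricted to the 32
AAL regions most associated with Alzheimer's disease.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phantom import AtlasLabelMap

# The 32 AAL regions most strongly associated with AD (index, name),
# by AAL-116 numbering: posterior cingulate, medial temporal structures,
# occipital, fusiform, parietal, precuneus and lateral temporal cortex.
AD_ROI_TABLE: tuple[tuple[int, str], ...] = (
    (35, "Cingulum_Post_L"), (36, "Cingulum_Post_R"),
    (37, "Hippocampus_L"), (38, "Hippocampus_R"),
    (39, "ParaHippocampal_L"), (40, "ParaHippocampal_R"),
    (41, "Amygdala_L"), (42, "Amygdala_R"),
    (49, "Occipital_Sup_L"), (50, "Occipital_Sup_R"),
    (51, "Occipital_Mid_L"), (52, "Occipital_Mid_R"),
    (53, "Occipital_Inf_L"), (54, "Occipital_Inf_R"),
    (55, "Fusiform_L"), (56, "Fusiform_R"),
    (59, "Parietal_Sup_L"), (60, "Parietal_Sup_R"),
    (61, "Parietal_Inf_L"), (62, "Parietal_Inf_R"),
    (67, "Precuneus_L"), (68, "Precuneus_R"),
    (81, "Temporal_Sup_L"), (82, "Temporal_Sup_R"),
    (83, "Temporal_Pole_Sup_L"), (84, "Temporal_Pole_Sup_R"),
    (85, "Temporal_Mid_L"), (86, "Temporal_Mid_R"),
    (87, "Temporal_Pole_Mid_L"), (88, "Temporal_Pole_Mid_R"),
    (89, "Temporal_Inf_L"), (90, "Temporal_Inf_R"),
)


@dataclasses.dataclass(frozen=True)
class ADROISet:
    """The 32 AD-related AAL regions, ordered by atlas index."""

    indices: tuple[int, ...]
    names: tuple[str, ...]

    def __contains__(self, index: int) -> bool:
        return index in self.indices

    def __len__(self) -> int:
        return len(self.indices)

    def name_of(self, index: int) -> str:
        return self.names[self.indices.index(index)]


def ad_roi_indices() -> ADROISet:
    """Return the 32 AD-related AAL region indices with their names."""
    idx, names = zip(*AD_ROI_TABLE)
    return ADROISet(indices=idx, names=names)


@dataclasses.dataclass(frozen=True)
class ROIFeatureVector:
    """One scalar per atlas region for one subject and modality."""

    subject_id: str
    modality: str  # "MRI" (GM volume fractions) or "PET" (mean intensity)
    values: Mapping[int, float]

    def as_array(self, regions: Sequence[int] | None = None) -> np.ndarray:
        regions = list(self.values) if regions is None else regions
        return np.array([self.values[r] for r in regions], dtype=float)


def _check_grid(volume: np.ndarray, atlas: AtlasLabelMap) -> None:
    if volume.shape != atlas.shape:
        raise ValueError(
            f"volume grid {volume.shape} does not match atlas grid {atlas.shape}")


def gm_roi_volumes(gm_map: np.ndarray, atlas: AtlasLabelMap,
                   subject_id: str = "", icv: float | None = None
                   ) -> ROIFeatureVector:
    """Per-region GM volume normalized to total intracranial volume.

    value_r = (sum of gm_map over voxels of region r) / ICV. By default
    ICV is the total GM mass over the brain mask (the phantoms carry no
    WM/CSF compartments); pass `icv` to use an externally computed
    GM+WM+CSF volume instead. With zero GM on background, the fractions
    sum to 1 under the default ICV.
    """
    gm_map = np.asarray(gm_map, dtype=float)
    _check_grid(gm_map, atlas)
    if (gm_map < 0).any():
        raise ValueError("gm_map must be nonnegative")
    sums = np.bincount(atlas.labels.ravel(), weights=gm_map.ravel(),
                       minlength=max(atlas.region_index_set) + 1)
    if icv is None:
        icv = float(sums[1:].sum())
    if icv <= 0:
        raise ValueError("intracranial volume is zero; degenerate subject")
    values = {r: float(sums[r] / icv) for r in atlas.region_index_set}
    return ROIFeatureVector(subject_id=subject_id, modality="MRI", values=values)


def pet_roi_means(pet_volume: np.ndarray, atlas: AtlasLabelMap,
                  subject_id: str = "", gm_mask: np.ndarray | None = None
                  ) -> ROIFeatureVector:
    """Mean PET intensity over each region.

    `gm_mask` optionally restricts the average to voxels where the mask
    is positive (GM-masked ROI means); the default averages the full
    region.
    """
    pet_volume = np.asarray(pet_volume, dtype=float)
    _check_grid(pet_volume, atlas)
    labels = atlas.labels
    weights = pet_volume
    if gm_mask is not None:
        _check_grid(np.asarray(gm_mask), atlas)
        inside = np.asarray(gm_mask) > 0
        labels = np.where(inside, labels, 0)
    nmax = max(atlas.region_index_set) + 1
    sums = np.bincount(labels.ravel(), weights=weights.ravel(), minlength=nmax)
    counts = np.bincount(labels.ravel(), minlength=nmax)
    values = {}
    for r in atlas.region_index_set:
        if counts[r] == 0:
            raise ValueError(f"region {r} has no voxels under the requested mask")
        values[r] = float(sums[r] / counts[r])
    return ROIFeatureVector(subject_id=subject_id, modality="PET", values=values)


def paint_synthetic_image(features: ROIFeatureVector, atlas: AtlasLabelMap,
                          roi_subset: Iterable[int] | None = None) -> np.ndarray:
    """Write ROI features back into image space.

    Every voxel of region r takes value_r when r is in `roi_subset`
    (default: all atlas regions) and 0 otherwise; background stays 0.
    """
    subset = set(atlas.region_index_set if roi_subset is None else roi_subset)
    missing = [r for r in subset if r not in features.values]
    if missing:
        raise KeyError(f"features missing for regions {sorted(missing)}")
    lut = np.zeros(max(atlas.region_index_set) + 1)
    for r in subset:
        lut[r] = features.values[r]
    return lut[atlas.labels]


def features_to_frame(vectors: Sequence[ROIFeatureVector]) -> pd.DataFrame:
    """Tabulate feature vectors: one row per (subject, modality)."""
    regions = sorted({r for v in vectors for r in v.values})
    rows = []
    for v in vectors:
        row = {"subject_id": v.subject_id, "modality": v.modality}
        row.update({f"roi_{r}": v.values.get(r, np.nan) for r in regions})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_features(frame: pd.DataFrame) -> list[ROIFeatureVector]:
    roi_cols = [c for c in frame.columns if c.startswith("roi_")]
    out = []
    for _, row in frame.iterrows():
        values = {int(c[4:]): float(row[c]) for c in roi_cols
                  if not pd.isna(row[c])}
        out.append(ROIFeatureVector(subject_id=row["subject_id"],
                                    modality=row["modality"], values=values))
    return out
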