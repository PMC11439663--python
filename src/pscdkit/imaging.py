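"""Regional/global amyloid-PET SUVR and WMH lesion quantification.

All volumes are assumed already normalized to one common grid (spatial
normalization itself is out of scope).  SUVR (standardized uptake value
ratio) is a region's mean tracer intensity divided by the mean intensity
of a reference region -- cerebellar gray matter in the florbetaben
workflow this mirrors.  The global SUVR averages four composite cortical
regions (frontal, cingulate, lateral parietal, lateral temporal).  WMH
burden is summarized as lesion voxels as a percentage of brain
parenchymal volume, and across subjects as a voxelwise lesion frequency
map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "LabeledVolume",
    "RegionalSUVR",
    "LesionFrequencyMap",
    "regional_suvr",
    "global_suvr",
    "wmh_volume_fraction",
    "lesion_frequency_map",
]


@dataclass
class LabeledVolume:
    """3-D voxel array (intensity, integer labels, or 0/1 mask) on a shared grid."""

    data: np.ndarray
    voxel_volume_mm3: float = 1.0
    space_tag: str = "common-grid"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel_volume_mm3 must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def to_nifti(self, path: str | Path) -> None:
        edge = self.voxel_volume_mm3 ** (1.0 / 3.0)
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), np.diag([edge] * 3 + [1.0]))
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, space_tag: str = "common-grid") -> "LabeledVolume":
        img = nib.load(str(path))
        vox = float(abs(np.linalg.det(img.affine[:3, :3])))
        return cls(np.asarray(img.dataobj), vox or 1.0, space_tag)


def _check_same_grid(*vols: LabeledVolume) -> None:
    ref = vols[0]
    for v in vols[1:]:
        if v.grid_shape != ref.grid_shape or v.space_tag != ref.space_tag:
            raise ValueError(
                f"volumes are not on the same grid/space: "
                f"{v.grid_shape}/{v.space_tag} vs {ref.grid_shape}/{ref.space_tag}"
            )


@dataclass
class RegionalSUVR:
    per_region: dict[int, float]
    reference_label: int
    global_suvr: float | None = None
    composite_regions: list[list[int]] = field(default_factory=list)


def regional_suvr(
    pet: LabeledVolume, labels: LabeledVolume, reference_label: int
) -> RegionalSUVR:
    """Mean intensity per labeled region divided by the reference mean.

    Empty regions get NaN with a warning; an empty reference is an error.
    The reference region's own SUVR is 1 by construction.
    """
    _check_same_grid(pet, labels)
    lab = np.asarray(labels.data).astype(np.int64)
    pet_data = np.asarray(pet.data, dtype=float)
    region_ids = [int(r) for r in np.unique(lab) if r > 0]
    ref_mask = lab == reference_label
    if not ref_mask.any():
        raise ValueError(f"reference region {reference_label} has no voxels")
    ref_mean = pet_data[ref_mask].mean()
    if ref_mean == 0:
        raise ValueError("reference region mean intensity is zero")
    per: dict[int, float] = {}
    if reference_label not in region_ids:
        region_ids.append(reference_label)
    for r in sorted(region_ids):
        mask = lab == r
        if not mask.any():
            warnings.warn(f"region {r} has no voxels; SUVR recorded as missing")
            per[r] = float("nan")
        else:
            per[r] = float(pet_data[mask].mean() / ref_mean)
    return RegionalSUVR(per, reference_label)


def global_suvr(r: RegionalSUVR, composite_map: dict[str, list[int]]) -> float:
    """Mean of the four composite SUVRs, each the unweighted mean of its regions."""
    if len(composite_map) != 4:
        raise ValueError("composite_map must define exactly 4 composites")
    composite_vals = []
    for name, members in composite_map.items():
        vals = [r.per_region[m] for m in members if m in r.per_region and np.isfinite(r.per_region[m])]
        if not vals:
            raise ValueError(f"composite {name!r}: all member regions missing")
        composite_vals.append(float(np.mean(vals)))
    g = float(np.mean(composite_vals))
    r.global_suvr = g
    r.composite_regions = [list(m) for m in composite_map.values()]
    return g


def wmh_volume_fraction(lesion: LabeledVolume, brain: LabeledVolume) -> float:
    """100 x (lesion-and-brain voxels) / brain voxels, in % of parenchymal volume."""
    _check_same_grid(lesion, brain)
    lesion_mask = np.asarray(lesion.data) > 0
    brain_mask = np.asarray(brain.data) > 0
    n_brain = int(brain_mask.sum())
    if n_brain == 0:
        raise ValueError("brain mask is empty")
    outside = int((lesion_mask & ~brain_mask).sum())
    if outside:
        warnings.warn(f"{outside} lesion voxels fall outside the brain mask; ignored")
    return 100.0 * int((lesion_mask & brain_mask).sum()) / n_brain


@dataclass
class LesionFrequencyMap:
    counts: np.ndarray
    proportion: float
    n_subjects: int


def lesion_frequency_map(
    masks: list[LabeledVolume], brain: LabeledVolume
) -> LesionFrequencyMap:
    """Voxelwise lesion count across subjects and the pooled lesion proportion.

    ``proportion`` is total lesion voxels across subjects over
    n_subjects x brain voxels.
    """
    if not masks:
        raise ValueError("empty mask list")
    _check_same_grid(*masks, brain)
    counts = np.zeros(brain.grid_shape, dtype=np.int32)
    for m in masks:
        counts += (np.asarray(m.data) > 0).astype(np.int32)
    n_brain = int((np.asarray(brain.data) > 0).sum())
    if n_brain == 0:
        raise ValueError("brain mask is empty")
    proportion = float(counts.sum()) / (len(masks) * n_brain)
    return LesionFrequencyMap(counts, proportion, len(masks))
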