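"""Isotropic resampling and sub-lesion mask construction.

Each lesion is analysed over four disjoint sub-regions (the analysis units
of the whole pipeline):

* **tumour** — the contrast-enhancing disease on T1w,
* **edema** — the surrounding T2-FLAIR hyperintensity,
* **tumour-margin** — a morphological ring of configurable width around the
  tumour, excluding tumour and edema,
* **lesion-margin** — a ring of the same width around tumour ∪ edema.

Margins are built by Euclidean-distance-transform thresholding in physical
units, equivalent to dilation with a Euclidean ball of the margin radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage


class Sequence(str, Enum):
    T1W = "T1"
    T2FLAIR = "T2"


class Timepoint(str, Enum):
    BASELINE = "baseline"
    FOLLOWUP = "followup"


@dataclass
class LesionVolume:
    """One co-registered scalar volume of a lesion."""

    image: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    sequence: Sequence
    timepoint: Timepoint

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3:
            raise ValueError("image must be 3D")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("image contains non-finite intensities")


@dataclass
class SubLesionMasks:
    """The four disjoint sub-lesion masks on one grid."""

    tumour: np.ndarray
    edema: np.ndarray
    tumour_margin: np.ndarray
    lesion_margin: np.ndarray
    margin_mm: float
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    #: region names whose mask came out empty (e.g. tumour-margin swallowed
    #: by thick edema); their features are reported missing, not zero
    empty_regions: list[str] = field(default_factory=list)

    def regions(self) -> dict[str, np.ndarray]:
        return {
            "Tumour": self.tumour,
            "Edema": self.edema,
            "Tumour-Margin": self.tumour_margin,
            "Lesion-Margin": self.lesion_margin,
        }


def resample_isotropic(volume: LesionVolume, target_mm: float = 0.5) -> LesionVolume:
    """Linear interpolation of a volume onto an isotropic grid.

    Axes already at the target spacing are left untouched (the clinical
    acquisition is 0.5 mm in-plane; only the slice direction is
    interpolated).
    """
    if target_mm <= 0:
        raise ValueError("target voxel size must be positive")
    if not np.all(np.isfinite(volume.image)):
        raise ValueError("non-finite voxels")
    factors = tuple(v / target_mm for v in volume.voxel_size_mm)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return LesionVolume(
            volume.image.copy(), (target_mm,) * 3, volume.sequence, volume.timepoint
        )
    out = ndimage.zoom(
        np.asarray(volume.image, dtype=np.float64),
        factors,
        order=1,
        mode="nearest",
        grid_mode=True,
    )
    return LesionVolume(out, (target_mm,) * 3, volume.sequence, volume.timepoint)


def resample_mask_isotropic(
    mask: np.ndarray, voxel_size_mm: tuple[float, float, float], target_mm: float = 0.5
) -> np.ndarray:
    """Nearest-neighbour resampling of a binary mask."""
    factors = tuple(v / target_mm for v in voxel_size_mm)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return np.asarray(mask, dtype=bool).copy()
    out = ndimage.zoom(
        np.asarray(mask, dtype=np.uint8), factors, order=0, mode="nearest",
        grid_mode=True,
    )
    return out.astype(bool)


def make_margin_masks(
    tumour: np.ndarray,
    edema: np.ndarray,
    voxel_mm: tuple[float, float, float],
    margin_mm: float = 3.0,
    margin_excludes_edema: bool = True,
) -> SubLesionMasks:
    """Construct the four sub-lesion masks from tumour and edema masks.

    ``tumour_margin`` is the Euclidean-ball dilation of the tumour by
    ``margin_mm``, minus tumour (and minus edema when
    ``margin_excludes_edema``, the default, so the four regions are
    disjoint); ``lesion_margin`` is the dilation of tumour ∪ edema minus
    tumour ∪ edema. Masks reaching the grid border are clipped. Empty
    margins (edema thicker than the margin) are retained and flagged in
    ``empty_regions``.
    """
    tumour = np.asarray(tumour, dtype=bool)
    edema = np.asarray(edema, dtype=bool)
    if not tumour.any():
        raise ValueError("tumour mask is empty")
    if margin_mm <= 0:
        raise ValueError("margin must be positive")
    if margin_mm < min(voxel_mm):
        raise ValueError(
            f"margin {margin_mm} mm is below one voxel "
            f"({min(voxel_mm)} mm); margins thinner than the grid "
            "resolution cannot be represented"
        )
    lesion = tumour | edema
    dist_t = ndimage.distance_transform_edt(~tumour, sampling=voxel_mm)
    dist_l = ndimage.distance_transform_edt(~lesion, sampling=voxel_mm)
    tumour_margin = (dist_t <= margin_mm) & ~tumour
    if margin_excludes_edema:
        tumour_margin &= ~edema
    lesion_margin = (dist_l <= margin_mm) & ~lesion

    masks = SubLesionMasks(
        tumour=tumour,
        edema=edema,
        tumour_margin=tumour_margin,
        lesion_margin=lesion_margin,
        margin_mm=float(margin_mm),
        voxel_size_mm=tuple(float(v) for v in voxel_mm),
    )
    masks.empty_regions = [
        name for name, m in masks.regions().items() if not m.any()
    ]
    return masks
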