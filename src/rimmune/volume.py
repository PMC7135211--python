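"""The unit of radiomic analysis: a 3-D intensity grid with a binary mask."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class VolumeROI:
    """A 3-D scalar volume (HU), a binary tumor mask and voxel spacing.

    Parameters
    ----------
    intensities
        3-D array of CT intensities in Hounsfield units.
    mask
        Boolean array of the same shape; True marks tumor voxels.
    spacing_mm
        Physical voxel size per axis in millimetres, ordered like the
        array axes.
    """

    intensities: np.ndarray
    mask: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        if self.intensities.shape != self.mask.shape:
            raise ValueError(
                f"shape mismatch: intensities {self.intensities.shape} vs mask {self.mask.shape}"
            )
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be three positive values, got {self.spacing_mm}")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if not np.isfinite(self.intensities).all():
            raise ValueError("intensities contain non-finite values")

    @property
    def roi_values(self) -> np.ndarray:
        """Intensities of the in-mask voxels, flattened in C order."""
        return self.intensities[self.mask]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def save(self, image_path: str | Path, mask_path: str | Path) -> None:
        """Write image and mask as NIfTI volumes with spacing in the affine."""
        affine = np.diag(list(self.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.intensities.astype(np.float32), affine), str(image_path))
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), str(mask_path))

    @classmethod
    def load(cls, image_path: str | Path, mask_path: str | Path) -> "VolumeROI":
        img = nib.load(str(image_path))
        msk = nib.load(str(mask_path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            intensities=np.asarray(img.dataobj, dtype=np.float64),
            mask=np.asarray(msk.dataobj) > 0,
            spacing_mm=spacing,
        )
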