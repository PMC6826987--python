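"""Image container shared by every pipeline stage.

An :class:`ImageVolume` is a thin wrapper around a numpy intensity grid
(2D slice or 3D volume) carrying the voxel geometry, the modality tag
(anatomical MRI vs functional PET) and an optional foreground mask.
NIfTI round-tripping goes through nibabel.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "load_nifti", "save_nifti"]

MODALITIES = ("anatomical", "functional")


@dataclasses.dataclass
class ImageVolume:
    """Intensity grid with voxel geometry and modality tag.

    Parameters
    ----------
    data
        Finite real intensity array, 2D or 3D.
    voxel_size
        Physical edge length of a voxel per axis, in mm.
    modality
        ``"anatomical"`` or ``"functional"``.
    mask
        Optional boolean foreground grid of the same shape. ``None``
        means every voxel is foreground.
    """

    data: np.ndarray
    voxel_size: tuple[float, ...] = None
    modality: str = "anatomical"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError("ImageVolume expects a 2D or 3D grid")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if self.voxel_size is None:
            self.voxel_size = (1.0,) * self.data.ndim
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != self.data.ndim:
            raise ValueError("voxel_size length must match dimensionality")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^d."""
        return float(np.prod(self.voxel_size))

    def foreground(self) -> np.ndarray:
        """Boolean foreground grid (all-true when no mask is set)."""
        if self.mask is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.mask

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Copy of this volume with new intensities, same geometry."""
        return ImageVolume(
            data=np.asarray(data, dtype=float),
            voxel_size=self.voxel_size,
            modality=self.modality,
            mask=None if self.mask is None else self.mask.copy(),
        )


def _affine(voxel_size: tuple[float, ...]) -> np.ndarray:
    aff = np.eye(4)
    for i, v in enumerate(voxel_size[:3]):
        aff[i, i] = v
    return aff


def save_nifti(img: ImageVolume | np.ndarray, path: str | Path,
               voxel_size: tuple[float, ...] | None = None) -> None:
    """Write a volume (or raw array) as uncompressed NIfTI."""
    if isinstance(img, ImageVolume):
        data, vs = img.data, img.voxel_size
    else:
        data = np.asarray(img, dtype=float)
        vs = voxel_size or (1.0,) * min(data.ndim, 3)
    nii = nib.Nifti1Image(np.asarray(data), _affine(vs))
    # pin the header fields nibabel would otherwise leave environment-dependent
    nii.header.set_data_dtype(np.float64)
    nib.save(nii, str(path))


def load_nifti(path: str | Path, modality: str = "anatomical") -> ImageVolume:
    """Read a NIfTI file into an :class:`ImageVolume`."""
    nii = nib.load(str(path))
    data = np.asarray(nii.get_fdata(), dtype=float)
    zooms = nii.header.get_zooms()[: data.ndim]
    return ImageVolume(data=data, voxel_size=tuple(zooms), modality=modality)
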