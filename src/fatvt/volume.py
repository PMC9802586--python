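"""Voxel-volume container shared by all imaging-side modules.

A :class:`TissueVolume` is a thin wrapper around a numpy array on a regular
isotropic-or-not voxel grid, carrying the voxel spacing (mm) and the
myocardial mask.  It is the in-memory representation of CT-like attenuation
volumes, LGE-like intensity volumes and integer tissue-label volumes alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

__all__ = ["TissueVolume"]


@dataclass
class TissueVolume:
    """A voxel grid with spacing and an optional myocardial mask.

    Parameters
    ----------
    data:
        Voxel values; float (HU / intensity) or integer labels.
    spacing:
        Voxel edge lengths in mm, one per axis.
    mask:
        Boolean myocardial mask, same shape as ``data``.  ``None`` means
        "everything in-mask".
    """

    data: np.ndarray
    spacing: tuple[float, ...]
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if len(self.spacing) != self.data.ndim:
            raise ValueError(
                f"spacing has {len(self.spacing)} entries for a "
                f"{self.data.ndim}-D volume"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape does not match data shape")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def in_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.mask

    def copy_with(self, data: np.ndarray) -> "TissueVolume":
        return TissueVolume(data=data, spacing=self.spacing,
                            mask=None if self.mask is None else self.mask.copy(),
                            meta=dict(self.meta))

    def voxel_centers(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers.

        ``idx`` is an (n, ndim) integer index array; ``None`` returns all
        in-mask voxel centers.
        """
        if idx is None:
            idx = np.argwhere(self.in_mask())
        return (np.asarray(idx, dtype=float) + 0.5) * np.asarray(self.spacing)

    # -- NIfTI round-trip -------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing) + [1.0][: 4 - self.data.ndim])
        aff4 = np.eye(4)
        aff4[: self.data.ndim, : self.data.ndim] = np.diag(self.spacing)
        return nib.Nifti1Image(np.asarray(self.data), aff4)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, mask: np.ndarray | None = None) -> "TissueVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        return cls(data=data, spacing=spacing, mask=mask)
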