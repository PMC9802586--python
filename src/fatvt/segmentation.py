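"""Tissue classification on CT-like and LGE-like volumes.

CT side: infiltrating adipose tissue (inFAT) is hypoattenuation between
-180 HU and -5 HU, split into dense inFAT (-180 to -50 HU) and
fat--myocardium admixture (-50 to -5 HU).  MRI side: the full-width
half-maximum rule labels voxels above 50% of the in-mask maximum intensity
as dense scar and 35--50% as gray zone.  Volumes convert to mass with a
myocardial density of 1.055 g/cm^3.

Umbrella terms used throughout the package: "inFAT" = dense fat +
admixture; "scar" = dense scar + gray zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .volume import TissueVolume

__all__ = [
    "CtLabel",
    "MriLabel",
    "SegmentationConfig",
    "classify_ct",
    "classify_mri",
    "mass_of",
    "bullseye_breakdown",
    "MYOCARDIAL_DENSITY_G_PER_CM3",
]

MYOCARDIAL_DENSITY_G_PER_CM3 = 1.055


class CtLabel(IntEnum):
    non_injured = 0
    admixture = 1
    dense_fat = 2


class MriLabel(IntEnum):
    non_injured = 0
    gray_zone = 1
    dense_scar = 2


@dataclass
class SegmentationConfig:
    """Thresholds for CT/MRI tissue classification.

    HU boundaries follow the hypoattenuation convention for inFAT; the
    boundary HU of exactly ``dense_fat_upper`` (-50) classifies as dense
    fat, and exactly ``fat_upper`` (-5) is still admixture.  FWHM
    fractions: intensity > ``fwhm_dense_frac`` x max is dense scar;
    [``fwhm_gray_frac``, ``fwhm_dense_frac``] x max (both ends inclusive)
    is gray zone.
    """

    fat_lower: float = -180.0
    dense_fat_upper: float = -50.0
    fat_upper: float = -5.0
    fwhm_dense_frac: float = 0.50
    fwhm_gray_frac: float = 0.35
    density_g_per_cm3: float = MYOCARDIAL_DENSITY_G_PER_CM3

    def __post_init__(self) -> None:
        if not (self.fat_lower < self.dense_fat_upper < self.fat_upper):
            raise ValueError("HU subranges must be ordered and disjoint")
        if not (0.0 < self.fwhm_gray_frac < self.fwhm_dense_frac < 1.0):
            raise ValueError("FWHM fractions must satisfy 0 < gray < dense < 1")


def classify_ct(
    hu: TissueVolume,
    mask: np.ndarray | None = None,
    cfg: SegmentationConfig | None = None,
    artifact_mask: np.ndarray | None = None,
) -> TissueVolume:
    """Label each in-mask voxel by its HU subrange.

    Artifact-flagged voxels are treated as non-injured myocardium,
    mirroring the handling of lead/device artifacts on clinical CT.
    """
    cfg = cfg or SegmentationConfig()
    mask = hu.in_mask() if mask is None else np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty myocardial mask")
    data = np.asarray(hu.data, dtype=float)
    labels = np.zeros(data.shape, dtype=np.int8)
    dense = (data >= cfg.fat_lower) & (data <= cfg.dense_fat_upper)
    admix = (data > cfg.dense_fat_upper) & (data <= cfg.fat_upper)
    labels[dense] = int(CtLabel.dense_fat)
    labels[admix] = int(CtLabel.admixture)
    labels[~mask] = int(CtLabel.non_injured)
    if artifact_mask is not None:
        labels[np.asarray(artifact_mask, dtype=bool)] = int(CtLabel.non_injured)
    return TissueVolume(data=labels, spacing=hu.spacing, mask=mask)


def classify_mri(
    intensity: TissueVolume,
    mask: np.ndarray | None = None,
    cfg: SegmentationConfig | None = None,
    artifact_mask: np.ndarray | None = None,
) -> TissueVolume:
    """Full-width half-maximum scar labelling.

    Thresholds are fractions of the maximal in-mask intensity (after
    artifact exclusion); scaling all intensities by a positive constant
    leaves the labels unchanged.
    """
    cfg = cfg or SegmentationConfig()
    mask = intensity.in_mask() if mask is None else np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty myocardial mask")
    data = np.asarray(intensity.data, dtype=float)
    eff_mask = mask.copy()
    if artifact_mask is not None:
        eff_mask &= ~np.asarray(artifact_mask, dtype=bool)
    vmax = float(data[eff_mask].max()) if eff_mask.any() else 0.0
    if vmax <= 0:
        raise ValueError("in-mask maximum intensity must be positive")
    frac = data / vmax
    labels = np.zeros(data.shape, dtype=np.int8)
    labels[(frac >= cfg.fwhm_gray_frac) & (frac <= cfg.fwhm_dense_frac)] = int(
        MriLabel.gray_zone
    )
    labels[frac > cfg.fwhm_dense_frac] = int(MriLabel.dense_scar)
    labels[~eff_mask] = int(MriLabel.non_injured)
    return TissueVolume(data=labels, spacing=intensity.spacing, mask=mask)


def mass_of(
    label_volume: TissueVolume,
    labels,
    cfg: SegmentationConfig | None = None,
) -> float:
    """Mass in grams of the voxels carrying any of ``labels``.

    mass = count x voxel volume x 1.055 g/cm^3 (1 mm^3 = 1e-3 cm^3).
    """
    cfg = cfg or SegmentationConfig()
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    sel = np.isin(np.asarray(label_volume.data, dtype=int), labels)
    sel &= label_volume.in_mask()
    vol_mm3 = int(sel.sum()) * label_volume.voxel_volume_mm3
    return vol_mm3 * cfg.density_g_per_cm3 * 1e-3


def bullseye_breakdown(
    label_volume: TissueVolume,
    uvc,
    cfg: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Per-anatomical-segment mass of each label (7-segment bullseye).

    ``uvc`` is a :class:`fatvt.geometry.UVCField` on the same grid.  The
    returned frame has one row per segment and one column per label value
    present, in grams; rows sum to the total per-label mass.
    """
    from .geometry import anatomical_segment, SEGMENT_NAMES

    cfg = cfg or SegmentationConfig()
    mask = label_volume.in_mask()
    if uvc is None:
        raise ValueError("UVC field required for bullseye breakdown")
    seg = anatomical_segment(uvc)
    data = np.asarray(label_volume.data, dtype=int)
    voxel_mass = label_volume.voxel_volume_mm3 * cfg.density_g_per_cm3 * 1e-3
    label_values = sorted(int(v) for v in np.unique(data[mask]))
    rows = {}
    for name in SEGMENT_NAMES:
        in_seg = mask & (seg == name)
        rows[name] = {
            lv: float(np.count_nonzero(in_seg & (data == lv))) * voxel_mass
            for lv in label_values
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("segment")
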