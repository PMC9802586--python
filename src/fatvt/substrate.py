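"""Hybrid CT-MRI substrate construction and overlap-region classification.

Combining the CT-side labels (non-injured / admixture / dense fat) with
the MRI-side labels (non-injured / gray zone / dense scar) on a common
grid yields seven hybrid tissue classes.  Combinations mixing a dense,
non-conducting tissue with a heterogeneous one follow a dense-dominance
rule: the insulating component governs downstream electrophysiology, and
the heterogeneous partner is retained as an auxiliary flag for
composition accounting.

Locations are also classified into four mutually exclusive overlap
regions (inFAT_inScar, Scar_noFat, inFAT_noScar, no_remodeling) by the
presence rule: a tissue type is "present" at a point if it occupies at
least 10% of the myocardial volume within a 1-cm radius sphere (a sphere
rather than a surface disc, to account for intramural remodeling).
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .segmentation import CtLabel, MriLabel, SegmentationConfig, mass_of
from .volume import TissueVolume

__all__ = [
    "HybridLabel",
    "OverlapRegion",
    "merge_labels",
    "merge_label_volumes",
    "region_at_point",
    "presence_fraction_maps",
    "overlap_statistics",
    "modality_view",
    "REGION_NAMES",
]


class HybridLabel(IntEnum):
    non_injured = 0
    admixture_only = 1
    gray_zone_only = 2
    fibrofatty = 3
    dense_fat_only = 4
    dense_scar_only = 5
    dense_fat_and_scar = 6


class OverlapRegion(IntEnum):
    no_remodeling = 0
    inFAT_noScar = 1
    Scar_noFat = 2
    inFAT_inScar = 3


REGION_NAMES = [r.name for r in OverlapRegion]

# (CT label, MRI label) -> (hybrid label, auxiliary heterogeneous flag).
# The two dense-dominance rows resolve combinations of a dense tissue on
# one modality with a heterogeneous tissue on the other.
_MERGE_TABLE = {
    (CtLabel.non_injured, MriLabel.non_injured): (HybridLabel.non_injured, None),
    (CtLabel.admixture, MriLabel.non_injured): (HybridLabel.admixture_only, None),
    (CtLabel.non_injured, MriLabel.gray_zone): (HybridLabel.gray_zone_only, None),
    (CtLabel.admixture, MriLabel.gray_zone): (HybridLabel.fibrofatty, None),
    (CtLabel.dense_fat, MriLabel.non_injured): (HybridLabel.dense_fat_only, None),
    (CtLabel.non_injured, MriLabel.dense_scar): (HybridLabel.dense_scar_only, None),
    (CtLabel.dense_fat, MriLabel.dense_scar): (HybridLabel.dense_fat_and_scar, None),
    (CtLabel.dense_fat, MriLabel.gray_zone): (HybridLabel.dense_fat_only, "gray_zone"),
    (CtLabel.admixture, MriLabel.dense_scar): (HybridLabel.dense_scar_only, "admixture"),
}


def merge_labels(ct: CtLabel | int, mri: MriLabel | int) -> HybridLabel:
    """Merge one (CT, MRI) label pair into its hybrid class."""
    try:
        key = (CtLabel(int(ct)), MriLabel(int(mri)))
    except ValueError as exc:
        raise ValueError(f"unknown label pair ({ct}, {mri})") from exc
    return _MERGE_TABLE[key][0]


def merge_label_volumes(
    ct_labels: TissueVolume, mri_labels: TissueVolume
) -> TissueVolume:
    """Vectorized merge of co-registered CT and MRI label volumes."""
    ct = np.asarray(ct_labels.data, dtype=int)
    mri = np.asarray(mri_labels.data, dtype=int)
    if ct.shape != mri.shape:
        raise ValueError("label volumes are not co-registered (shape mismatch)")
    lut = np.zeros((3, 3), dtype=np.int8)
    for (c, m), (h, _aux) in _MERGE_TABLE.items():
        lut[int(c), int(m)] = int(h)
    out = lut[ct, mri]
    mask = ct_labels.in_mask()
    out = np.where(mask, out, int(HybridLabel.non_injured))
    return TissueVolume(data=out, spacing=ct_labels.spacing, mask=mask)


# inFAT = dense fat + admixture; scar = dense scar + gray zone
_FAT_CT = (int(CtLabel.admixture), int(CtLabel.dense_fat))
_SCAR_MRI = (int(MriLabel.gray_zone), int(MriLabel.dense_scar))


def _sphere_kernel(radius_mm: float, spacing) -> np.ndarray:
    r = np.asarray(spacing, dtype=float)
    half = np.maximum(np.floor(radius_mm / r).astype(int), 0)
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, r)], indexing="ij"
    )
    d2 = sum(g**2 for g in grids)
    return (d2 <= radius_mm**2).astype(float)


def presence_fraction_maps(
    ct_labels: TissueVolume,
    mri_labels: TissueVolume,
    radius_mm: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel inFAT and scar fractions of the myocardium within a sphere.

    Convolution-based; the denominator is the number of myocardial voxels
    inside the sphere, so the fractions are intramural compositions.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    mask = ct_labels.in_mask().astype(float)
    kern = _sphere_kernel(radius_mm, ct_labels.spacing)
    denom = fftconvolve(mask, kern, mode="same")
    denom = np.maximum(denom, 1e-9)
    fat = np.isin(np.asarray(ct_labels.data, dtype=int), _FAT_CT) & ct_labels.in_mask()
    scar = (
        np.isin(np.asarray(mri_labels.data, dtype=int), _SCAR_MRI)
        & mri_labels.in_mask()
    )
    fat_frac = fftconvolve(fat.astype(float), kern, mode="same") / denom
    scar_frac = fftconvolve(scar.astype(float), kern, mode="same") / denom
    return np.clip(fat_frac, 0.0, 1.0), np.clip(scar_frac, 0.0, 1.0)


def region_at_point(
    point_mm: np.ndarray,
    ct_labels: TissueVolume,
    mri_labels: TissueVolume,
    radius_mm: float = 10.0,
    threshold: float = 0.10,
    origin_mm: np.ndarray | None = None,
) -> OverlapRegion:
    """Overlap-region class at a physical point (10%-within-1-cm rule)."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    spacing = np.asarray(ct_labels.spacing, dtype=float)
    origin = np.zeros(len(spacing)) if origin_mm is None else np.asarray(origin_mm)
    mask = ct_labels.in_mask()
    idx = np.argwhere(mask)
    centers = origin + (idx + 0.5) * spacing
    d2 = np.sum((centers - np.asarray(point_mm, dtype=float)) ** 2, axis=1)
    near = idx[d2 <= radius_mm**2]
    if len(near) == 0:
        return OverlapRegion.no_remodeling
    sel = tuple(near.T)
    ct = np.asarray(ct_labels.data, dtype=int)[sel]
    mri = np.asarray(mri_labels.data, dtype=int)[sel]
    fat_frac = np.isin(ct, _FAT_CT).mean()
    scar_frac = np.isin(mri, _SCAR_MRI).mean()
    return classify_region(fat_frac >= threshold, scar_frac >= threshold)


def classify_region(fat_present: bool, scar_present: bool) -> OverlapRegion:
    if fat_present and scar_present:
        return OverlapRegion.inFAT_inScar
    if fat_present:
        return OverlapRegion.inFAT_noScar
    if scar_present:
        return OverlapRegion.Scar_noFat
    return OverlapRegion.no_remodeling


def overlap_statistics(
    ct_labels: TissueVolume,
    mri_labels: TissueVolume,
    uvc,
    cfg: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Per-segment inFAT/scar masses and co-presence flags.

    Aggregating the ``both_present`` column over a cohort yields the
    bullseye-style percentage of segments containing both tissue types.
    """
    from .geometry import anatomical_segment, SEGMENT_NAMES

    cfg = cfg or SegmentationConfig()
    seg = anatomical_segment(uvc)
    mask = ct_labels.in_mask()
    ct = np.asarray(ct_labels.data, dtype=int)
    mri = np.asarray(mri_labels.data, dtype=int)
    voxel_mass = ct_labels.voxel_volume_mm3 * cfg.density_g_per_cm3 * 1e-3
    rows = []
    for name in SEGMENT_NAMES:
        in_seg = mask & (seg == name)
        fat_g = float(np.count_nonzero(in_seg & np.isin(ct, _FAT_CT))) * voxel_mass
        scar_g = float(np.count_nonzero(in_seg & np.isin(mri, _SCAR_MRI))) * voxel_mass
        rows.append(
            {
                "segment": name,
                "fat_mass_g": fat_g,
                "scar_mass_g": scar_g,
                "both_present": bool(fat_g > 0 and scar_g > 0),
            }
        )
    return pd.DataFrame(rows).set_index("segment")


def modality_view(hybrid_labels: TissueVolume, modality: str) -> TissueVolume:
    """Project a hybrid label volume onto what one modality sees.

    The CT-based model keeps only the adipose classes (admixture, dense
    fat); the LGE-based model keeps only the fibrotic classes (gray zone,
    dense scar).  Fibrofatty voxels appear as admixture on CT and gray
    zone on MRI; dense fat-and-scar appears dense on both.  Together with
    the hybrid volume these are the three model classes built per heart.
    """
    lab = np.asarray(hybrid_labels.data, dtype=int)
    out = np.zeros_like(lab)
    if modality == "ct":
        out[np.isin(lab, (int(HybridLabel.admixture_only),
                          int(HybridLabel.fibrofatty)))] = int(
            HybridLabel.admixture_only)
        out[np.isin(lab, (int(HybridLabel.dense_fat_only),
                          int(HybridLabel.dense_fat_and_scar)))] = int(
            HybridLabel.dense_fat_only)
    elif modality == "mri":
        out[np.isin(lab, (int(HybridLabel.gray_zone_only),
                          int(HybridLabel.fibrofatty)))] = int(
            HybridLabel.gray_zone_only)
        out[np.isin(lab, (int(HybridLabel.dense_scar_only),
                          int(HybridLabel.dense_fat_and_scar)))] = int(
            HybridLabel.dense_scar_only)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return TissueVolume(out.astype(np.int8), hybrid_labels.spacing,
                        hybrid_labels.mask)
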