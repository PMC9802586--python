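"""Synthetic CT-like and LGE-like ventricular image volumes.

Each synthetic heart is a voxelized half-ellipsoidal LV shell.  Scar and
inFAT lesions are planted as superellipsoidal blobs with dense cores and
heterogeneous rims, allocated across the seven anatomical segments with
an apex/inferior-heavy weighting, and fat lesions overlap scar according
to the configured per-segment overlap fractions.  Voxel intensities are
drawn inside the HU / FWHM bands of the planted class and lightly
smoothed, so that running the segmentation module on the images recovers
the planted truth up to partial-volume flips at lesion boundaries.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from ..geometry import (
    ShellParams,
    anatomical_segment,
    build_shell_grid,
    compute_uvc,
)
from ..segmentation import CtLabel, MriLabel, MYOCARDIAL_DENSITY_G_PER_CM3
from ..volume import TissueVolume
from .config import SynthConfig, stream
from .cohort import draw_masses

__all__ = ["gen_ventricle_images", "heart_geometry", "latent_masses_for_heart"]

# relative per-segment lesion mass weights (apex / inferior heavy)
_SCAR_SEGMENT_WEIGHTS = {
    "apex": 6.80, "mid_anterior": 2.26, "mid_septal": 3.67,
    "mid_inferior": 6.99, "basal_anterior": 0.64, "basal_inferior": 3.37,
    "basal_septal": 2.55,
}
_FAT_SEGMENT_WEIGHTS = {
    "apex": 5.04, "mid_anterior": 2.36, "mid_septal": 1.52,
    "mid_inferior": 3.45, "basal_anterior": 1.89, "basal_inferior": 3.67,
    "basal_septal": 1.07,
}

_GEOM_CACHE: dict = {}


def heart_geometry(config: SynthConfig):
    """Shell grid, UVC and per-voxel segment names (cached per shell spec)."""
    sh = config.shell
    key = (sh.long_axis_mm, sh.short_axis_mm, sh.wall_thickness_mm, sh.voxel_mm)
    if key not in _GEOM_CACHE:
        params = ShellParams(
            long_axis=sh.long_axis_mm,
            short_axis=sh.short_axis_mm,
            wall_thickness=sh.wall_thickness_mm,
        )
        grid = build_shell_grid(params, sh.voxel_mm)
        uvc = compute_uvc(grid)
        seg = anatomical_segment(uvc)
        _GEOM_CACHE[key] = (grid, uvc, seg)
    return _GEOM_CACHE[key]


def latent_masses_for_heart(config: SynthConfig, heart_index: int):
    """The (fat_g, scar_g) targets drawn for one heart (the image
    generator plants lesions totalling these masses)."""
    rng = stream(config, heart_index, "mass")
    fat, scar = draw_masses(config, 1, rng)
    return float(fat[0]), float(scar[0])


def _superellipsoid_blob(rng, center_idx, semi_axes_mm, spacing, shape, p=2.5):
    """Voxel indices inside a superellipsoid, sorted centre-outward."""
    half = np.ceil(np.asarray(semi_axes_mm) / spacing).astype(int)
    lo = np.maximum(np.asarray(center_idx) - half, 0)
    hi = np.minimum(np.asarray(center_idx) + half + 1, shape)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    rel = (idx - np.asarray(center_idx)) * spacing / np.asarray(semi_axes_mm)
    level = np.sum(np.abs(rel) ** p, axis=1)
    inside = level <= 1.0
    idx, level = idx[inside], level[inside]
    order = np.argsort(level)
    return idx[order], level[order]


def _plant_lesions(
    rng,
    mask,
    seg_names,
    target_voxels,
    weights: dict,
    spacing: float,
    shape,
    overlap_with: np.ndarray | None = None,
    overlap_fraction: dict | None = None,
    dense_frac_range=(0.4, 0.7),
    max_lesions: int = 400,
):
    """Grow blobs until ``target_voxels`` are labelled; returns (label, planted)
    with label 1 = heterogeneous rim, 2 = dense core."""
    label = np.zeros(shape, dtype=np.int8)
    planted = np.zeros(shape, dtype=bool)
    seg_list = list(weights)
    w = np.array([weights[s] for s in seg_list], dtype=float)
    w /= w.sum()
    n_planted = 0
    for _ in range(max_lesions):
        if n_planted >= target_voxels:
            break
        seg_choice = seg_list[rng.choice(len(seg_list), p=w)]
        in_seg = mask & (seg_names == seg_choice)
        f_ov = None
        if overlap_fraction is not None:
            f_ov = overlap_fraction.get(seg_choice, 0.5)
        candidates = np.argwhere(in_seg)
        if len(candidates) == 0:
            continue
        if f_ov is not None and f_ov > 0 and overlap_with is not None:
            seg_scar = np.argwhere(in_seg & overlap_with)
            if len(seg_scar) > 0 and rng.random() < f_ov:
                candidates = seg_scar
        center = candidates[rng.integers(len(candidates))]
        axes = rng.uniform(6.0, 14.0, size=3)
        blob, _ = _superellipsoid_blob(rng, center, axes, spacing, shape)
        sel = mask[tuple(blob.T)] & ~planted[tuple(blob.T)]
        blob = blob[sel]
        if len(blob) == 0:
            continue
        if f_ov is not None and overlap_with is not None:
            in_scar = overlap_with[tuple(blob.T)]
            n_ov = int(round(f_ov * len(blob)))
            take_ov = blob[in_scar][:n_ov]
            take_out = blob[~in_scar][: len(blob) - n_ov]
            blob = np.concatenate([take_ov, take_out]) if len(take_ov) else take_out
            if len(blob) == 0:
                continue
        room = target_voxels - n_planted
        blob = blob[:room]  # centre-outward ordering: truncation trims the rim
        dense_frac = rng.uniform(*dense_frac_range)
        n_dense = int(round(dense_frac * len(blob)))
        sel_t = tuple(blob.T)
        label[sel_t] = 1
        label[tuple(blob[:n_dense].T)] = 2
        planted[sel_t] = True
        n_planted += len(blob)
    return label, planted


def gen_ventricle_images(
    config: SynthConfig, heart_index: int
) -> tuple[TissueVolume, TissueVolume, tuple[TissueVolume, TissueVolume]]:
    """Synthesize one heart's (HU volume, LGE volume, truth label pair).

    Truth labels use the CT / MRI enumerations of the segmentation
    module; the returned volumes carry the myocardial mask and voxel
    spacing, and intensities consistent with the planted classes.
    """
    if heart_index >= config.cohort_n:
        raise ValueError("heart_index beyond configured cohort size")
    grid, uvc, seg = heart_geometry(config)
    mask = grid.mask
    h = grid.spacing[0]
    voxel_mass_g = grid.spacing[0] ** 3 * MYOCARDIAL_DENSITY_G_PER_CM3 * 1e-3

    fat_target_g, scar_target_g = latent_masses_for_heart(config, heart_index)
    rng = stream(config, heart_index, "images")

    scar_label, scar_planted = _plant_lesions(
        rng, mask, seg, int(round(scar_target_g / voxel_mass_g)),
        _SCAR_SEGMENT_WEIGHTS, h, mask.shape,
    )
    fat_label, _fat_planted = _plant_lesions(
        rng, mask, seg, int(round(fat_target_g / voxel_mass_g)),
        _FAT_SEGMENT_WEIGHTS, h, mask.shape,
        overlap_with=scar_planted, overlap_fraction=config.overlap_fraction,
    )

    ct_truth = np.zeros(mask.shape, dtype=np.int8)
    ct_truth[fat_label == 1] = int(CtLabel.admixture)
    ct_truth[fat_label == 2] = int(CtLabel.dense_fat)
    mri_truth = np.zeros(mask.shape, dtype=np.int8)
    mri_truth[scar_label == 1] = int(MriLabel.gray_zone)
    mri_truth[scar_label == 2] = int(MriLabel.dense_scar)

    # CT-like attenuation: positive-HU myocardium, hypoattenuated lesions
    hu = rng.normal(40.0, 15.0, size=mask.shape)
    hu[hu < 5.0] = 5.0
    hu[fat_label == 1] = rng.uniform(-48.0, -7.0, size=int((fat_label == 1).sum()))
    hu[fat_label == 2] = rng.uniform(-175.0, -55.0, size=int((fat_label == 2).sum()))
    hu = gaussian_filter(hu, sigma=0.4)
    hu[~mask] = -1000.0  # air-ish outside the myocardium

    # LGE-like intensity; the in-mask maximum is pinned after smoothing so
    # the FWHM thresholds sit exactly at 50 and 35
    lge = rng.uniform(5.0, 25.0, size=mask.shape)
    lge[scar_label == 1] = rng.uniform(36.0, 47.0, size=int((scar_label == 1).sum()))
    lge[scar_label == 2] = rng.uniform(60.0, 97.0, size=int((scar_label == 2).sum()))
    lge = gaussian_filter(lge, sigma=0.4)
    if (scar_label == 2).any():
        dense_idx = np.argwhere(scar_label == 2)
        peak = dense_idx[np.argmax(lge[tuple(dense_idx.T)])]
        lge[tuple(peak)] = 100.0
    lge[~mask] = 0.0

    meta = {"heart_index": heart_index, "fat_target_g": fat_target_g,
            "scar_target_g": scar_target_g}
    mk = mask.copy()
    hu_vol = TissueVolume(hu, grid.spacing, mk, meta=dict(meta))
    lge_vol = TissueVolume(lge, grid.spacing, mk, meta=dict(meta))
    truth = (
        TissueVolume(ct_truth, grid.spacing, mk, meta=dict(meta)),
        TissueVolume(mri_truth, grid.spacing, mk, meta=dict(meta)),
    )
    return hu_vol, lge_vol, truth
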