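"""VT-circuit decomposition from activation maps.

A window in universal ventricular coordinates is drawn around each VT
exit site (apicobasal half-width 0.2, rotational half-width 36 degrees,
full transmural extent).  The activation sequence within the window is
divided into eight uniformly spaced isochrones, which define the circuit
components: isochrone 1 is the exit, 2-3 the outer loop, 4 the entrance
and 5-8 the common pathway, with 6-7 forming the critical isthmus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import SegmentationConfig
from .substrate import (
    OverlapRegion,
    classify_region,
    _FAT_CT,
    _SCAR_MRI,
)

__all__ = [
    "COMPONENT_OF_ISOCHRONE",
    "VtCircuit",
    "compute_isochrones",
    "classify_components",
    "circuit_window",
    "component_composition",
    "measure_cv",
]

#: isochrone index (1..8) -> circuit component
COMPONENT_OF_ISOCHRONE = {
    1: "exit",
    2: "outer_loop",
    3: "outer_loop",
    4: "entrance",
    5: "common_pathway",
    6: "common_pathway",
    7: "common_pathway",
    8: "common_pathway",
}
#: isochrones additionally flagged as the critical isthmus
ISTHMUS_ISOCHRONES = (6, 7)

COMPONENT_NAMES = ["exit", "outer_loop", "entrance", "common_pathway"]


@dataclass
class VtCircuit:
    """Decomposed circuit: window, components and tissue composition."""

    exit_uvc: tuple
    window_mask: np.ndarray
    isochrones: np.ndarray
    components: np.ndarray            # object array of component names ('' outside)
    isthmus_mask: np.ndarray
    composition: pd.DataFrame | None = None
    isthmus_region: OverlapRegion | None = None
    cycle_length_ms: float | None = None


def compute_isochrones(activation_map: np.ndarray, n: int = 8) -> np.ndarray:
    """Bin activation times into ``n`` equal-width isochrones (1..``n``).

    NaN entries (never-activated tissue) stay 0.  Ties at bin edges fall
    to the lower bin; the final bin is closed so the latest activation
    maps to isochrone ``n``.
    """
    act = np.asarray(activation_map, dtype=float)
    finite = np.isfinite(act)
    if not finite.any():
        raise ValueError("activation map has no activated tissue")
    t0, t1 = float(np.nanmin(act)), float(np.nanmax(act))
    if t1 <= t0:
        raise ValueError("constant activation time: isochrones undefined")
    width = (t1 - t0) / n
    iso = np.zeros(act.shape, dtype=np.int8)
    # right-open bins [t0+(k-1)w, t0+kw), with edge ties to the lower bin
    # and the final bin right-closed
    scaled = (act[finite] - t0) / width
    k = np.ceil(scaled).astype(int)
    k[k < 1] = 1
    k[k > n] = n
    iso[finite] = k
    return iso


def classify_components(isochrone_map: np.ndarray) -> np.ndarray:
    """Map isochrone indices to circuit-component names ('' where 0)."""
    iso = np.asarray(isochrone_map, dtype=int)
    out = np.full(iso.shape, "", dtype="<U16")
    for k, name in COMPONENT_OF_ISOCHRONE.items():
        out[iso == k] = name
    return out


def circuit_window(
    exit_uvc,
    grid_uvc,
    ab_halfwidth: float = 0.2,
    rot_halfwidth_deg: float = 36.0,
) -> np.ndarray:
    """Boolean mask of locations within the UVC window around the exit.

    ``grid_uvc`` is either a :class:`fatvt.geometry.UVCField` or an
    (n, 3) array; the rotational distance is periodic and the transmural
    axis is unrestricted.
    """
    from .geometry import UVCField

    if isinstance(grid_uvc, UVCField):
        ab = grid_uvc.apicobasal
        rot = grid_uvc.rotational
        valid = grid_uvc.mask
    else:
        arr = np.asarray(grid_uvc, dtype=float)
        ab, rot = arr[..., 0], arr[..., 2]
        valid = np.isfinite(ab)
    eab, _etm, erot = (float(v) for v in exit_uvc)
    dab = np.abs(ab - eab)
    drot = np.abs((rot - erot + 180.0) % 360.0 - 180.0)
    with np.errstate(invalid="ignore"):
        inside = (dab <= ab_halfwidth) & (drot <= rot_halfwidth_deg)
    return inside & valid


def component_composition(
    component_map: np.ndarray,
    ct_labels,
    mri_labels,
    voxel_volume_mm3: float | None = None,
    isthmus_mask: np.ndarray | None = None,
    presence_threshold: float = 0.10,
    cfg: SegmentationConfig | None = None,
) -> tuple[pd.DataFrame, OverlapRegion | None]:
    """Fat/scar mass per circuit component, plus the isthmus region class.

    ``ct_labels`` / ``mri_labels`` are label arrays (or TissueVolumes)
    co-registered with ``component_map``.  The isthmus is classified into
    its dominant overlap region by the 10% presence rule evaluated over
    the isthmus volume.
    """
    cfg = cfg or SegmentationConfig()
    ct = np.asarray(getattr(ct_labels, "data", ct_labels), dtype=int)
    mri = np.asarray(getattr(mri_labels, "data", mri_labels), dtype=int)
    if voxel_volume_mm3 is None:
        voxel_volume_mm3 = getattr(ct_labels, "voxel_volume_mm3", 1.0)
    comp = np.asarray(component_map)
    voxel_mass = voxel_volume_mm3 * cfg.density_g_per_cm3 * 1e-3
    rows = []
    for name in COMPONENT_NAMES:
        sel = comp == name
        rows.append(
            {
                "component": name,
                "n_voxels": int(sel.sum()),
                "fat_mass_g": float(np.isin(ct[sel], _FAT_CT).sum()) * voxel_mass,
                "scar_mass_g": float(np.isin(mri[sel], _SCAR_MRI).sum()) * voxel_mass,
            }
        )
    table = pd.DataFrame(rows).set_index("component")
    isthmus_region = None
    if isthmus_mask is not None:
        m = np.asarray(isthmus_mask, dtype=bool)
        if m.any():
            fat_frac = float(np.isin(ct[m], _FAT_CT).mean())
            scar_frac = float(np.isin(mri[m], _SCAR_MRI).mean())
            isthmus_region = classify_region(
                fat_frac >= presence_threshold, scar_frac >= presence_threshold
            )
    return table, isthmus_region


def measure_cv(
    activation_map: np.ndarray,
    path: np.ndarray | None = None,
    spacing=1.0,
    region_mask: np.ndarray | None = None,
) -> float:
    """Conduction speed in mm/s from an activation map.

    With ``path`` (sequence of voxel indices along the propagation
    direction) the speed is total distance over activation-time span and
    the times must increase monotonically.  With ``region_mask`` the
    local gradient-based speeds 1/|grad t| are averaged over the region.
    """
    act = np.asarray(activation_map, dtype=float)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (act.ndim,))
    if path is not None:
        path = np.atleast_2d(np.asarray(path))
        t = act[tuple(path.T)]
        if np.any(~np.isfinite(t)):
            raise ValueError("path crosses never-activated tissue")
        dt_steps = np.diff(t)
        if np.any(dt_steps <= 0):
            raise ValueError("activation not monotone along path")
        seglen = np.linalg.norm(np.diff(path, axis=0) * spacing, axis=1)
        return float(seglen.sum() / (t[-1] - t[0]) * 1000.0)
    if act.ndim == 1:
        gmag = np.abs(np.gradient(act, spacing[0]))
    else:
        gmag = np.sqrt(sum(g**2 for g in np.gradient(act, *spacing)))
    mask = np.isfinite(act) if region_mask is None else (
        np.asarray(region_mask, dtype=bool) & np.isfinite(act)
    )
    g = gmag[mask]
    g = g[np.isfinite(g) & (g > 1e-9)]
    if len(g) == 0:
        raise ValueError("stationary activation map: speed undefined")
    return float(np.mean(1.0 / g) * 1000.0)
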