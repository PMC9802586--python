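"""Structured-grid ventricular shell geometry and universal coordinates.

The left ventricle is idealized as a half-ellipsoidal shell voxelized on a
regular grid.  Every myocardial voxel receives universal ventricular
coordinates (UVC): apicobasal in [0, 1] (apex -> base), transmural in
[0, 1] (endocardium -> epicardium) and rotational in [0, 360) degrees,
counterclockwise starting from the lateral wall.  UVC gives a common
reference frame in which tissue tags can be transferred between grids of
different shape and resolution, and in which anatomical (7-segment) and
AHA 17-segment partitions are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, binary_dilation
from scipy.spatial import cKDTree

__all__ = [
    "ShellParams",
    "ShellGrid",
    "UVCField",
    "build_shell_grid",
    "compute_uvc",
    "anatomical_segment",
    "aha_segment",
    "assign_fibers",
    "map_tags_via_uvc",
    "SEGMENT_NAMES",
]

#: 7-segment bullseye names: apex + {mid, basal} x {anterior/anterolateral,
#: inferior/inferolateral, septal}.
SEGMENT_NAMES = [
    "apex",
    "mid_anterior",
    "mid_inferior",
    "mid_septal",
    "basal_anterior",
    "basal_inferior",
    "basal_septal",
]

# Rotational sector boundaries (degrees, half-open) with 0 deg = lateral
# wall and the septum spanning 60-180 deg.
_SECTORS_3 = {
    "septal": (60.0, 180.0),
    "inferior": (180.0, 300.0),
    "anterior": (300.0, 360.0 + 60.0),  # wraps through 0
}


@dataclass
class ShellParams:
    """Half-ellipsoid left-ventricular shell dimensions (mm).

    ``long_axis`` is the base-to-apex outer length, ``short_axis`` the
    outer basal diameter, ``wall_thickness`` the (uniform) wall.
    """

    long_axis: float = 80.0
    short_axis: float = 60.0
    wall_thickness: float = 10.0

    def __post_init__(self) -> None:
        if self.wall_thickness <= 0:
            raise ValueError("wall thickness must be positive")
        if self.wall_thickness >= min(self.long_axis, self.short_axis / 2):
            raise ValueError("degenerate shell: wall thicker than cavity")


@dataclass
class ShellGrid:
    """Voxelized half-ellipsoid shell with surfaces identified."""

    mask: np.ndarray                 # myocardium
    cavity: np.ndarray               # LV blood pool
    outside: np.ndarray              # everything beyond the epicardium
    endo_surface: np.ndarray         # myocardial voxels facing the cavity
    epi_surface: np.ndarray          # myocardial voxels facing outside
    spacing: tuple[float, float, float]
    origin: np.ndarray               # physical coordinate of voxel (0,0,0) corner
    params: ShellParams
    outer_axes: tuple[float, float, float]  # semi-axes (a, b, c); apex at z=c
    inner_axes: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    def coords(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Physical voxel-center coordinates (mm), relative to the base center."""
        if idx is None:
            idx = np.argwhere(self.mask)
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * np.asarray(
            self.spacing
        )

    def analytic_shell_volume_mm3(self) -> float:
        ao, bo, co = self.outer_axes
        ai, bi, ci = self.inner_axes
        return 2.0 / 3.0 * np.pi * (ao * bo * co - ai * bi * ci)


@dataclass
class UVCField:
    """Per-voxel universal ventricular coordinates (NaN off-myocardium)."""

    apicobasal: np.ndarray
    transmural: np.ndarray
    rotational: np.ndarray  # degrees in [0, 360)
    mask: np.ndarray

    def stacked(self, idx: np.ndarray) -> np.ndarray:
        return np.stack(
            [self.apicobasal[tuple(idx.T)], self.transmural[tuple(idx.T)],
             self.rotational[tuple(idx.T)]], axis=1
        )


def build_shell_grid(
    params: ShellParams, resolution_mm: float, pad_voxels: int = 2
) -> ShellGrid:
    """Voxelize a half-ellipsoidal LV shell.

    The base plane is z = 0 with the apex at z = ``long_axis``; the grid
    covers the shell plus ``pad_voxels`` of surrounding space.  Raises for
    resolutions coarser than a third of the wall thickness (too few
    transmural layers for meaningful surfaces).
    """
    if resolution_mm > params.wall_thickness / 3.0 + 1e-12:
        raise ValueError(
            "resolution too coarse: need at least 3 voxels across the wall"
        )
    ao, bo = params.short_axis / 2.0, params.short_axis / 2.0
    co = params.long_axis
    w = params.wall_thickness
    ai, bi, ci = ao - w, bo - w, co - w

    h = float(resolution_mm)
    pad = pad_voxels * h
    nx = int(np.ceil((2 * ao + 2 * pad) / h))
    ny = int(np.ceil((2 * bo + 2 * pad) / h))
    nz = int(np.ceil((co + pad) / h))
    origin = np.array([-ao - pad, -bo - pad, 0.0])
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    x = origin[0] + (ix + 0.5) * h
    y = origin[1] + (iy + 0.5) * h
    z = origin[2] + (iz + 0.5) * h

    f_out = (x / ao) ** 2 + (y / bo) ** 2 + (z / co) ** 2
    f_in = (x / ai) ** 2 + (y / bi) ** 2 + (z / ci) ** 2
    mask = (f_out <= 1.0) & (f_in >= 1.0)
    cavity = f_in < 1.0
    outside = f_out > 1.0
    if not mask.any():
        raise ValueError("degenerate shell: no myocardial voxels")

    neigh = np.zeros((3, 3, 3), dtype=bool)
    neigh[1, 1, :] = neigh[1, :, 1] = neigh[:, 1, 1] = True
    endo = mask & binary_dilation(cavity, structure=neigh)
    epi = mask & binary_dilation(outside, structure=neigh)
    return ShellGrid(
        mask=mask, cavity=cavity, outside=outside,
        endo_surface=endo, epi_surface=epi,
        spacing=(h, h, h), origin=origin, params=params,
        outer_axes=(ao, bo, co), inner_axes=(ai, bi, ci),
    )


def compute_uvc(grid: ShellGrid) -> UVCField:
    """Universal ventricular coordinates on a shell grid.

    Transmural depth is the normalized Euclidean distance between the
    endocardial and epicardial surfaces (d_endo / (d_endo + d_epi),
    computed with distance transforms).  The apicobasal coordinate is the
    normalized polar angle of the ellipsoid-scaled direction (0 at the
    apex, 1 at the basal rim).  Rotational is the azimuth measured
    counterclockwise from the lateral (+x) direction, periodic in 360.
    """
    if not grid.mask.any():
        raise ValueError("empty myocardium")
    sampling = grid.spacing
    # distance to cavity / to outside; EDT measures distance to the nearest
    # zero voxel, so invert the region of interest
    d_endo = distance_transform_edt(~grid.cavity, sampling=sampling)
    d_epi = distance_transform_edt(~grid.outside, sampling=sampling)
    with np.errstate(invalid="ignore"):
        tm = d_endo / (d_endo + d_epi)
    idx = np.argwhere(grid.mask)
    xyz = grid.coords(idx)
    am, bm, cm = (np.asarray(grid.outer_axes) + np.asarray(grid.inner_axes)) / 2.0
    u = xyz / np.array([am, bm, cm])
    phi = np.arctan2(np.hypot(u[:, 0], u[:, 1]), u[:, 2])  # 0 at apex axis
    ab_vals = np.clip(phi / (np.pi / 2.0), 0.0, 1.0)
    rot_vals = np.degrees(np.arctan2(xyz[:, 1], xyz[:, 0])) % 360.0

    shape = grid.mask.shape
    ab = np.full(shape, np.nan)
    rot = np.full(shape, np.nan)
    tmv = np.full(shape, np.nan)
    ab[tuple(idx.T)] = ab_vals
    rot[tuple(idx.T)] = rot_vals
    tmv[tuple(idx.T)] = np.clip(tm[tuple(idx.T)], 0.0, 1.0)
    return UVCField(apicobasal=ab, transmural=tmv, rotational=rot, mask=grid.mask)


def _sector3(rot: np.ndarray) -> np.ndarray:
    """Map rotational degrees to one of the 3 wall sectors."""
    r = np.asarray(rot, dtype=float) % 360.0
    out = np.full(r.shape, "anterior", dtype="<U10")
    out[(r >= 60.0) & (r < 180.0)] = "septal"
    out[(r >= 180.0) & (r < 300.0)] = "inferior"
    return out


def anatomical_segment(uvc: UVCField | None, apicobasal=None, rotational=None):
    """7-way anatomical partition by apicobasal thirds and wall sectors.

    Accepts either a :class:`UVCField` or raw coordinate arrays.  Returns a
    string array; off-myocardium voxels map to the empty string.
    """
    if uvc is not None:
        apicobasal, rotational = uvc.apicobasal, uvc.rotational
        mask = uvc.mask
    else:
        mask = np.isfinite(np.asarray(apicobasal, dtype=float))
    ab = np.asarray(apicobasal, dtype=float)
    rot = np.asarray(rotational, dtype=float)
    seg = np.full(ab.shape, "", dtype="<U16")
    sector = _sector3(rot)
    apex = ab < 1.0 / 3.0
    mid = (ab >= 1.0 / 3.0) & (ab < 2.0 / 3.0)
    basal = ab >= 2.0 / 3.0
    seg[apex] = "apex"
    for name, where in (("mid", mid), ("basal", basal)):
        for s in ("anterior", "inferior", "septal"):
            seg[where & (sector == s)] = f"{name}_{s}"
    seg[~mask] = ""
    return seg


# AHA 17-segment sector layouts (degrees ccw from lateral; half-open).
# Basal = segments 1-6, mid = 7-12, apical = 13-16, apical cap = 17.
_AHA_RING6 = [  # (offset into ring, start_deg, end_deg)
    (1, 0.0, 60.0),      # anterior
    (2, 60.0, 120.0),    # anteroseptal
    (3, 120.0, 180.0),   # inferoseptal
    (4, 180.0, 240.0),   # inferior
    (5, 240.0, 300.0),   # inferolateral
    (6, 300.0, 360.0),   # anterolateral
]
_AHA_RING4 = [
    (13, 315.0, 405.0),  # apical anterior (wraps)
    (14, 45.0, 135.0),   # apical septal
    (15, 135.0, 225.0),  # apical inferior
    (16, 225.0, 315.0),  # apical lateral
]
AHA_APICAL_CAP = 0.15  # apicobasal coordinate below which lies the cap


def aha_segment(uvc: UVCField | None, apicobasal=None, rotational=None) -> np.ndarray:
    """Standard AHA 17-segment index (1..17; 0 off-myocardium)."""
    if uvc is not None:
        apicobasal, rotational = uvc.apicobasal, uvc.rotational
        mask = uvc.mask
    else:
        mask = np.isfinite(np.asarray(apicobasal, dtype=float))
    ab = np.asarray(apicobasal, dtype=float)
    rot = np.asarray(rotational, dtype=float) % 360.0
    seg = np.zeros(ab.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        basal = ab >= 2.0 / 3.0
        mid = (ab >= 1.0 / 3.0) & (ab < 2.0 / 3.0)
        apical = (ab >= AHA_APICAL_CAP) & (ab < 1.0 / 3.0)
        cap = ab < AHA_APICAL_CAP
    for k, lo, hi in _AHA_RING6:
        in_sector = (rot >= lo) & (rot < hi)
        seg[basal & in_sector] = k
        seg[mid & in_sector] = k + 6
    for k, lo, hi in _AHA_RING4:
        if hi > 360.0:
            in_sector = (rot >= lo) | (rot < hi - 360.0)
        else:
            in_sector = (rot >= lo) & (rot < hi)
        seg[apical & in_sector] = k
    seg[cap] = 17
    seg[~mask] = 0
    return seg


def assign_fibers(
    grid: ShellGrid,
    uvc: UVCField,
    endo_angle_deg: float = 60.0,
    epi_angle_deg: float = -60.0,
) -> np.ndarray:
    """Rule-based fiber field: helix angle linear in transmural depth.

    Returns an (n, 3) array of unit fiber vectors for the myocardial
    voxels (ordering of ``np.argwhere(grid.mask)``), each tangent to the
    local shell surface; the helix angle rotates from ``endo_angle_deg``
    at the endocardium to ``epi_angle_deg`` at the epicardium.
    """
    idx = np.argwhere(grid.mask)
    xyz = grid.coords(idx)
    tm = uvc.transmural[tuple(idx.T)]
    helix = np.radians(endo_angle_deg + (epi_angle_deg - endo_angle_deg) * tm)

    # local surface normal from the gradient of the ellipsoid level set,
    # with semi-axes interpolated to the voxel's transmural depth
    axes = (
        np.asarray(grid.inner_axes)[None, :] * (1.0 - tm[:, None])
        + np.asarray(grid.outer_axes)[None, :] * tm[:, None]
    )
    n = xyz / axes**2
    n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-12)

    zhat = np.array([0.0, 0.0, 1.0])
    e_c = np.cross(np.broadcast_to(zhat, n.shape), n)
    nc = np.linalg.norm(e_c, axis=1, keepdims=True)
    degenerate = nc[:, 0] < 1e-8  # on the apex axis
    e_c[degenerate] = np.array([1.0, 0.0, 0.0])
    nc[degenerate] = 1.0
    e_c /= nc
    e_l = np.cross(n, e_c)
    e_l /= np.maximum(np.linalg.norm(e_l, axis=1, keepdims=True), 1e-12)

    f = np.cos(helix)[:, None] * e_c + np.sin(helix)[:, None] * e_l
    f /= np.linalg.norm(f, axis=1, keepdims=True)
    return f


#: relative weight of a full rotational turn in UVC nearest-neighbour
#: distance: 360 deg maps to a circle of circumference 2.0 (apicobasal and
#: transmural each span 1.0)
_ROT_CIRCUMFERENCE = 2.0


def _uvc_embedding(uvc_points: np.ndarray) -> np.ndarray:
    """Embed (ab, tm, rot_deg) with the rotational axis on a circle."""
    ab, tm, rot = uvc_points[:, 0], uvc_points[:, 1], uvc_points[:, 2]
    rho = _ROT_CIRCUMFERENCE / (2.0 * np.pi)
    theta = np.radians(rot)
    return np.column_stack([ab, tm, rho * np.cos(theta), rho * np.sin(theta)])


def map_tags_via_uvc(
    source_tags: np.ndarray,
    source_uvc: np.ndarray,
    target_uvc: np.ndarray,
) -> np.ndarray:
    """Transfer per-element tags by nearest neighbour in UVC space.

    ``source_uvc`` and ``target_uvc`` are (n, 3) arrays of (apicobasal,
    transmural, rotational-degrees) triples; the rotational axis is
    treated periodically.  Mapping a grid onto itself is the identity.
    """
    source_tags = np.asarray(source_tags)
    source_uvc = np.asarray(source_uvc, dtype=float)
    target_uvc = np.asarray(target_uvc, dtype=float)
    if len(source_tags) == 0:
        raise ValueError("empty source")
    tree = cKDTree(_uvc_embedding(source_uvc))
    _, nearest = tree.query(_uvc_embedding(target_uvc))
    return source_tags[nearest]
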