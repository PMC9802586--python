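"""Electroanatomic-mapping (EAM) style analysis.

Surface points carry bipolar (BiV) and unipolar (UniV) electrogram
voltages, an activation time and an ablation flag.  Processing follows
clinical convention: points are projected to the nearest surface
location and dropped when more than 5 mm away; voltages are capped at
1.5 mV (BiV) / 8.3 mV (UniV); low- and medium-voltage zones use the
0.5 / 3.3 mV cutoffs.  Conduction slowing is quantified by isochronal
crowding -- the number of distinct activation isochrones (of 8) within a
1-cm radius on the mapped surface -- and a point is a deceleration zone
(DZ) when that count reaches 5.  Ablation-lesion radii depend on the
tissue at the lesion center; DZ volumes take all myocardium within 1 cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .circuits import compute_isochrones
from .segmentation import CtLabel, MriLabel
from .substrate import OverlapRegion
from .stats import fisher_or

__all__ = [
    "EamPoint",
    "EamConfig",
    "project_points",
    "classify_voltage",
    "isochronal_crowding",
    "lesion_volume",
    "dz_volume",
    "region_association_table",
    "LESION_RADII_MM",
]


@dataclass
class EamPoint:
    """One mapped surface point."""

    position: np.ndarray           # mm
    biv: float                     # mV (capped on analysis)
    univ: float                    # mV
    activation_time: float         # ms
    projected_position: np.ndarray | None = None
    projection_distance: float | None = None
    ablation: bool = False
    region: OverlapRegion | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class EamConfig:
    biv_lvz: float = 0.5       # mV
    biv_cap: float = 1.5
    univ_lvz: float = 3.3
    univ_cap: float = 8.3
    max_projection_mm: float = 5.0
    crowding_radius_mm: float = 10.0
    n_isochrones: int = 8
    dz_min_isochrones: int = 5

    def __post_init__(self) -> None:
        if not (self.biv_lvz < self.biv_cap and self.univ_lvz < self.univ_cap):
            raise ValueError("LVZ cutoffs must lie below the caps")


#: ablation-lesion radius (mm) by tissue class at the lesion center; dense
#: inFAT mirrors dense scar and admixture mirrors gray zone
LESION_RADII_MM = {
    "non_injured": 4.56,
    "gray_zone": 3.07,
    "admixture": 3.07,
    "dense_scar": 2.50,
    "dense_fat": 2.50,
}


def project_points(
    points: list[EamPoint],
    surface_xyz: np.ndarray,
    max_dist_mm: float = 5.0,
) -> tuple[list[EamPoint], dict]:
    """Project points onto the nearest surface location and filter.

    Returns the retained points (with projected positions filled in) and
    a registration-error summary over all input points.
    """
    if len(points) == 0 or len(surface_xyz) == 0:
        raise ValueError("need nonempty points and surface")
    tree = cKDTree(np.asarray(surface_xyz, dtype=float))
    pos = np.array([p.position for p in points], dtype=float)
    dist, nearest = tree.query(pos)
    kept = []
    for p, d, i in zip(points, dist, nearest):
        q = replace(
            p,
            projected_position=np.asarray(surface_xyz[i], dtype=float),
            projection_distance=float(d),
        )
        if d <= max_dist_mm:
            kept.append(q)
    summary = {
        "n_input": len(points),
        "n_kept": len(kept),
        "error_mean_mm": float(np.mean(dist)),
        "error_sd_mm": float(np.std(dist, ddof=1)) if len(dist) > 1 else 0.0,
    }
    return kept, summary


def classify_voltage(point: EamPoint | None, cfg: EamConfig | None = None,
                     biv: float | None = None, univ: float | None = None) -> dict:
    """LVZ / MVZ / normal class per voltage channel (after capping).

    Capping is idempotent and commutes with classification: a voltage at
    or above the cap is "normal".
    """
    cfg = cfg or EamConfig()
    if point is not None:
        biv, univ = point.biv, point.univ
    if biv < 0 or univ < 0:
        raise ValueError("negative voltage amplitude")
    biv_c = min(biv, cfg.biv_cap)
    univ_c = min(univ, cfg.univ_cap)
    out = {}
    out["biv"] = (
        "LVZ" if biv_c <= cfg.biv_lvz else ("MVZ" if biv_c < cfg.biv_cap else "normal")
    )
    out["univ"] = (
        "LVZ" if univ_c <= cfg.univ_lvz
        else ("MVZ" if univ_c < cfg.univ_cap else "normal")
    )
    out["biv_capped"] = biv_c
    out["univ_capped"] = univ_c
    return out


def _surface_geodesic_distances(
    xyz: np.ndarray, cutoff_mm: float, k_neighbors: int = 8
) -> "coo_matrix":
    """All-pairs geodesic distances (<= cutoff) over a surface point cloud.

    The surface is approximated by a k-nearest-neighbour graph with
    Euclidean edge lengths; Dijkstra with a cutoff keeps this sparse.
    """
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)
    k = min(k_neighbors + 1, n)
    tree = cKDTree(xyz)
    dist, idx = tree.query(xyz, k=k)
    rows = np.repeat(np.arange(n), k - 1)
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    graph = coo_matrix((vals, (rows, cols)), shape=(n, n))
    dmat = dijkstra(graph, directed=False, limit=cutoff_mm)
    return dmat


def isochronal_crowding(
    activation_times: np.ndarray,
    xyz: np.ndarray,
    cfg: EamConfig | None = None,
    geodesic: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point isochrone count within the crowding radius, and DZ flags.

    Activation times over the mapped surface are binned into 8 equal
    isochrones; for every point the number of distinct isochrones among
    its in-radius neighbours (graph-geodesic by default, Euclidean
    otherwise) is counted.  DZ = count >= 5.
    """
    cfg = cfg or EamConfig()
    times = np.asarray(activation_times, dtype=float)
    xyz = np.asarray(xyz, dtype=float)
    iso = compute_isochrones(times, n=cfg.n_isochrones)
    n = len(xyz)
    counts = np.zeros(n, dtype=int)
    if geodesic:
        dmat = _surface_geodesic_distances(xyz, cfg.crowding_radius_mm)
        within = np.isfinite(dmat)
        for i in range(n):
            nb = np.nonzero(within[i])[0]
            if len(nb) == 0:
                raise ValueError("point with no neighbours inside the radius")
            counts[i] = len(np.unique(iso[nb]))
    else:
        tree = cKDTree(xyz)
        for i in range(n):
            nb = tree.query_ball_point(xyz[i], cfg.crowding_radius_mm)
            counts[i] = len(np.unique(iso[nb]))
    return counts, counts >= cfg.dz_min_isochrones


def lesion_volume(
    center_mm,
    tissue_label_at_center,
    grid_mask: np.ndarray | None = None,
    spacing=1.0,
    origin_mm=None,
) -> tuple[float, float, np.ndarray | None]:
    """Ablation-lesion radius, nominal volume and affected-voxel mask.

    The nominal volume is the full sphere (4/3) pi r^3 of the
    tissue-dependent radius; the returned mask (when a grid is given) is
    that sphere clipped to the myocardium, which is what overlap
    accounting uses.
    """
    if isinstance(tissue_label_at_center, str):
        name = tissue_label_at_center
    else:
        lab = tissue_label_at_center
        name = lab.name if hasattr(lab, "name") else CtLabel(int(lab)).name
    if name not in LESION_RADII_MM:
        raise KeyError(f"unknown tissue class {name!r} for lesion sizing")
    r = LESION_RADII_MM[name]
    nominal = 4.0 / 3.0 * np.pi * r**3
    mask = None
    if grid_mask is not None:
        grid_mask = np.asarray(grid_mask, dtype=bool)
        spacing_v = np.broadcast_to(np.asarray(spacing, dtype=float),
                                    (grid_mask.ndim,))
        origin = (np.zeros(grid_mask.ndim) if origin_mm is None
                  else np.asarray(origin_mm, dtype=float))
        idx = np.indices(grid_mask.shape).reshape(grid_mask.ndim, -1).T
        centers = origin + (idx + 0.5) * spacing_v
        d2 = np.sum((centers - np.asarray(center_mm, dtype=float)) ** 2, axis=1)
        sphere = (d2 <= r**2).reshape(grid_mask.shape)
        mask = sphere & grid_mask
    return r, float(nominal), mask


def dz_volume(
    point_mm,
    grid_mask: np.ndarray,
    spacing=1.0,
    radius_mm: float = 10.0,
    origin_mm=None,
) -> np.ndarray:
    """Myocardial voxels within ``radius_mm`` of an EAM point (DZ volume)."""
    grid_mask = np.asarray(grid_mask, dtype=bool)
    spacing_v = np.broadcast_to(np.asarray(spacing, dtype=float), (grid_mask.ndim,))
    origin = (np.zeros(grid_mask.ndim) if origin_mm is None
              else np.asarray(origin_mm, dtype=float))
    idx = np.indices(grid_mask.shape).reshape(grid_mask.ndim, -1).T
    centers = origin + (idx + 0.5) * spacing_v
    d2 = np.sum((centers - np.asarray(point_mm, dtype=float)) ** 2, axis=1)
    return (d2 <= radius_mm**2).reshape(grid_mask.shape) & grid_mask


def region_association_table(
    regions: np.ndarray,
    dz_flags: np.ndarray,
    biv_classes: np.ndarray | None = None,
    univ_classes: np.ndarray | None = None,
) -> dict:
    """Per-region 2x2 tables (region presence x DZ) with Fisher odds ratios.

    Also reports, when voltage classes are given, the percentage
    composition of LVZ and MVZ points across the four overlap regions
    (each row sums to 100%).
    """
    regions = np.asarray([int(r) for r in regions])
    dz = np.asarray(dz_flags, dtype=bool)
    if len(regions) == 0:
        raise ValueError("empty point set")
    out = {"tables": {}, "fisher": {}}
    for reg in OverlapRegion:
        in_reg = regions == int(reg)
        a = int(np.sum(in_reg & dz))
        b = int(np.sum(in_reg & ~dz))
        c = int(np.sum(~in_reg & dz))
        d = int(np.sum(~in_reg & ~dz))
        table = np.array([[a, b], [c, d]])
        out["tables"][reg.name] = table
        out["fisher"][reg.name] = fisher_or(table)
    for channel, classes in (("biv", biv_classes), ("univ", univ_classes)):
        if classes is None:
            continue
        classes = np.asarray(classes)
        comp = {}
        for zone in ("LVZ", "MVZ"):
            sel = classes == zone
            total = int(sel.sum())
            comp[zone] = {
                reg.name: (100.0 * np.sum(sel & (regions == int(reg))) / total
                           if total else np.nan)
                for reg in OverlapRegion
            }
        out[f"{channel}_composition_pct"] = pd.DataFrame(comp).T
    return out
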