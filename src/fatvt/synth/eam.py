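"""Synthetic electroanatomic-mapping point sets.

Points are scattered around the endocardial surface of a synthetic
heart.  Activation times come from a graph fast-marching front (Dijkstra
over the surface with per-tissue slowness), mildly slowed inside
fat-containing regions, plus localized "slow sites" -- delay bumps that
produce genuine isochronal crowding at the points that carry them.

Slow sites are planted with per-region probabilities calibrated so that
the deceleration-zone odds recovered downstream (>= 5 of 8 isochrones
within 1 cm, region presence by the 10%-within-1-cm rule) approximate the
configured per-region DZ odds.  The calibration solves, per heart, the
per-region DZ probabilities consistent with the odds targets and the
pooled DZ rate, then converts them to per-point planting rates through
the local 1-cm neighbourhood occupancy (so that the probability of
"at least one slow site within 1 cm" matches the region target).

Voltages are drawn from the configured per-region BiV/UniV
distributions; ablation flags land preferentially on low-voltage points.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from ..eam import EamPoint, _surface_geodesic_distances
from ..substrate import OverlapRegion, presence_fraction_maps
from .config import SynthConfig, stream
from .images import heart_geometry

__all__ = ["gen_eam_points", "solve_region_dz_probabilities", "eam_points_frame"]

_REGION_ORDER = ["inFAT_inScar", "inFAT_noScar", "Scar_noFat", "no_remodeling"]


def solve_region_dz_probabilities(
    odds_targets: dict,
    region_prevalence: dict,
    overall_rate: float,
    n_iter: int = 200,
) -> dict:
    """Per-region DZ probabilities consistent with each-versus-rest odds.

    Fixed-point iteration: given current probabilities, the rest-odds of
    each region follow from the prevalence-weighted complement; each
    region's probability is then reset to odds_target x rest-odds, and
    the vector is rescaled to hold the pooled rate.
    """
    regions = [r for r in _REGION_ORDER if r in odds_targets]
    pi = np.array([max(region_prevalence.get(r, 0.0), 1e-9) for r in regions])
    pi = pi / pi.sum()
    p = np.full(len(regions), overall_rate)
    for _ in range(n_iter):
        p_new = np.empty_like(p)
        for k in range(len(regions)):
            rest = np.ones(len(regions), dtype=bool)
            rest[k] = False
            p_rest = float(np.sum(pi[rest] * p[rest]) / np.sum(pi[rest]))
            odd_rest = p_rest / (1.0 - p_rest)
            o = odds_targets[regions[k]] * odd_rest
            p_new[k] = o / (1.0 + o)
        # renormalize pooled rate
        pooled = float(np.sum(pi * p_new))
        p = np.clip(p_new * (overall_rate / max(pooled, 1e-9)), 1e-4, 0.999)
    return dict(zip(regions, p))


def _endo_surface_points(grid) -> np.ndarray:
    idx = np.argwhere(grid.endo_surface)
    return grid.coords(idx), idx


def gen_eam_points(
    truth: tuple,
    config: SynthConfig,
    seed_key=0,
) -> list[EamPoint]:
    """Generate one heart's synthetic EAM point list.

    ``truth`` is the (CT truth, MRI truth) label pair from the image
    generator; ``seed_key`` keys the RNG stream (use the heart index).
    Each point's metadata records the planted region and slow-site flag
    (the generator-side ground truth used by recovery tests).
    """
    ct_truth, mri_truth = truth
    grid, uvc, _seg = heart_geometry(config)
    if not grid.endo_surface.any():
        raise ValueError("empty endocardial surface")
    rng = stream(config, seed_key, "eam")

    surf_xyz, surf_idx = _endo_surface_points(grid)
    n_surf = len(surf_xyz)

    # --- per-surface-voxel overlap region (10% within 1 cm rule) ---------
    fat_frac, scar_frac = presence_fraction_maps(ct_truth, mri_truth, 10.0)
    sel = tuple(surf_idx.T)
    fat_here = fat_frac[sel] >= 0.10
    scar_here = scar_frac[sel] >= 0.10
    region_code = np.where(
        fat_here & scar_here, int(OverlapRegion.inFAT_inScar),
        np.where(fat_here, int(OverlapRegion.inFAT_noScar),
                 np.where(scar_here, int(OverlapRegion.Scar_noFat),
                          int(OverlapRegion.no_remodeling))),
    )

    # --- smooth activation front over the surface ------------------------
    k = min(9, n_surf)
    tree = cKDTree(surf_xyz)
    dist, idx = tree.query(surf_xyz, k=k)
    speed = np.full(n_surf, config.eam_base_speed_mm_ms)
    speed[fat_here] *= config.eam_fat_slowdown
    rows = np.repeat(np.arange(n_surf), k - 1)
    cols = idx[:, 1:].ravel()
    slowness = 2.0 / (speed[rows] + speed[cols])
    w = dist[:, 1:].ravel() * slowness
    graph = coo_matrix((w, (rows, cols)), shape=(n_surf, n_surf))
    # earliest activation at the basal septum (sinus-rhythm-like breakout,
    # and a stable reference across hearts)
    septal_dir = np.array([np.cos(np.radians(120.0)),
                           np.sin(np.radians(120.0)), 0.0])
    score = surf_xyz @ septal_dir - 2.0 * surf_xyz[:, 2]
    source = int(np.argmax(score))
    act_surf = dijkstra(graph, directed=False, indices=source)
    act_surf[~np.isfinite(act_surf)] = np.nanmax(act_surf[np.isfinite(act_surf)])

    # --- sample mapped points -------------------------------------------
    n_pts = min(config.eam_points_per_heart, n_surf)
    pick = rng.choice(n_surf, size=n_pts, replace=False)
    base_xyz = surf_xyz[pick]
    times = act_surf[pick].copy()
    regions = region_code[pick]

    # --- plant slow sites and their delay bumps --------------------------
    span = float(np.ptp(times))
    if span <= 0:
        span = 1.0
    # prevalence from the full surface-voxel field (lower sampling noise
    # than the mapped points themselves)
    prevalence = {
        r: float(np.mean(region_code == int(OverlapRegion[r])))
        for r in _REGION_ORDER
    }
    p_target = solve_region_dz_probabilities(
        config.dz_odds, prevalence, config.dz_overall_rate
    )
    p_plant = {
        r: float(np.clip(p + config.eam_dz_rate_delta.get(r, 0.0), 1e-3, 0.95))
        for r, p in p_target.items()
    }
    # Planting-rate calibration: a point is flagged DZ downstream
    # exactly when a slow site sits within the crowding radius, so the
    # per-point planting rates lam_j must solve, for every point i,
    #     1 - prod_{j in ball(i)} (1 - lam_j) = p_target(region_i).
    # Because regions interleave at the 1-cm scale this is a genuinely
    # per-point system; an iterative proportional fit in log space
    # converges to the feasible compromise.
    q = np.array([
        p_plant[OverlapRegion(int(r)).name] for r in regions
    ])
    q = np.clip(q, 1e-4, 0.95)
    tree_pts = cKDTree(base_xyz)
    balls = [np.asarray(tree_pts.query_ball_point(p, 10.0)) for p in base_xyz]
    target_log = np.log1p(-q)  # desired sum of log(1-lam) over each ball
    m = np.array([len(b) for b in balls], dtype=float)
    x = target_log / np.maximum(m, 1.0)  # initial per-point log(1-lam)
    for _ in range(60):
        ball_sum = np.array([x[b].sum() for b in balls])
        ratio = target_log / np.minimum(ball_sum, -1e-12)
        # spread each ball's correction over its members (log-IPF style)
        corr = np.zeros(n_pts)
        cnt = np.zeros(n_pts)
        for i, b in enumerate(balls):
            corr[b] += np.log(np.clip(ratio[i], 1e-3, 1e3))
            cnt[b] += 1.0
        x = x * np.exp(0.8 * corr / np.maximum(cnt, 1.0))
        x = np.clip(x, np.log(1e-6), -1e-12)
    lam = 1.0 - np.exp(x)
    # Variance-reduced planting: each slow site decides the DZ flag of
    # its whole 1-cm ball, so independent Bernoulli draws would leave
    # only ~(surface area / ball area) effective samples per heart.
    # Planting instead fixes each region's site count at its expected
    # value (stochastic rounding) and places sites lambda-weighted with
    # a minimum separation, which keeps the per-region DZ rates near
    # their calibration targets heart by heart.
    slow = np.zeros(n_pts, dtype=bool)
    min_sep = 10.0  # mm; avoids overlapping (wasted) sites
    for r in _REGION_ORDER:
        in_r = np.nonzero(regions == int(OverlapRegion[r]))[0]
        if len(in_r) == 0:
            continue
        expect = float(lam[in_r].sum())
        # deterministic quasi-random rounding by heart key: unbiased over
        # a cohort yet independent of generation order
        frac = (int(zlib.crc32(str(("sites", seed_key, r)).encode()))
                % 10007) / 10007.0
        n_sites = int(np.floor(expect + frac))
        if n_sites == 0:
            continue
        # favour region-pure neighbourhoods: a site deep inside its
        # region delivers its whole ball to that region, which keeps the
        # realized per-region rates close to their calibration targets
        purity = np.array([
            float(np.mean(regions[balls[j]] == regions[j])) for j in in_r
        ])
        weights = lam[in_r] * purity**2
        if weights.sum() <= 0:
            weights = lam[in_r]
        weights = weights / weights.sum()
        order = rng.choice(in_r, size=len(in_r), replace=False,
                           p=weights)
        placed = 0
        for cand in order:
            if placed >= n_sites:
                break
            prior = np.nonzero(slow)[0]
            if len(prior) and np.min(
                np.linalg.norm(base_xyz[prior] - base_xyz[cand], axis=1)
            ) < min_sep:
                continue
            slow[cand] = True
            placed += 1

    # Each slow site delays its surrounding points with a rank-spread
    # ramp (nearest points delayed most), which guarantees the full
    # range of delay values -- hence crowded isochrones -- inside the
    # crowding radius of the site.  Overlapping sites combine by max.
    amp = config.eam_bump_relative_amplitude * span
    R = config.eam_bump_radius_mm
    site_ids = np.nonzero(slow)[0]
    site_nb, site_order = [], []
    for i in site_ids:
        nb = tree_pts.query_ball_point(base_xyz[i], R)
        if len(nb) < 6:
            d_all = np.linalg.norm(base_xyz - base_xyz[i], axis=1)
            nb = list(np.argsort(d_all)[:6])
        nb = np.asarray(nb)
        d_nb = np.linalg.norm(base_xyz[nb] - base_xyz[i], axis=1)
        site_nb.append(nb)
        site_order.append(np.argsort(d_nb))  # nearest first

    def _apply(site_amp):
        delay = np.zeros(n_pts)
        for s, i in enumerate(site_ids):
            nb, order = site_nb[s], site_order[s]
            ramp = site_amp[s] * (1.0 - np.arange(len(nb)) / len(nb))
            contrib = np.zeros(len(nb))
            contrib[order] = ramp
            delay[nb] = np.maximum(delay[nb], contrib)
        return times + delay

    # Enforce the planted design: every slow site must register as a DZ
    # under the same crowding measurement the analysis applies; sites
    # whose ramp is swallowed by the global isochrone binning get their
    # amplitude strengthened and the map is re-checked.
    from ..eam import isochronal_crowding

    site_amp = np.full(len(site_ids), amp)
    out_times = _apply(site_amp)
    if len(site_ids):
        for _ in range(5):
            _counts, dzf = isochronal_crowding(out_times, base_xyz)
            failing = ~dzf[site_ids]
            if not failing.any():
                break
            site_amp[failing] *= 1.35
            out_times = _apply(site_amp)
    times = out_times

    # --- voltages, jitter, ablation flags --------------------------------
    points: list[EamPoint] = []
    jitter = rng.normal(0.0, config.eam_jitter_mm / np.sqrt(3.0), size=(n_pts, 3))
    for i in range(n_pts):
        vp = config.voltage_params[OverlapRegion(int(regions[i])).name]
        biv = max(float(rng.normal(vp.biv_mean, vp.biv_sd)), 0.05)
        univ = max(float(rng.normal(vp.univ_mean, vp.univ_sd)), 0.05)
        ablation = bool(rng.random() < (0.6 if biv <= 0.5 else 0.1))
        points.append(
            EamPoint(
                position=base_xyz[i] + jitter[i],
                biv=biv,
                univ=univ,
                activation_time=float(times[i]),
                ablation=ablation,
                region=OverlapRegion(int(regions[i])),
                meta={
                    "true_region": OverlapRegion(int(regions[i])).name,
                    "slow_site": bool(slow[i]),
                    "planted_dz_prob": float(p_target[
                        OverlapRegion(int(regions[i])).name
                    ]),
                    "surface_xyz": base_xyz[i],
                },
            )
        )
    return points


def eam_points_frame(points: list[EamPoint]) -> pd.DataFrame:
    """Tabular view of an EAM point list (CSV-friendly)."""
    return pd.DataFrame(
        {
            "x": [p.position[0] for p in points],
            "y": [p.position[1] for p in points],
            "z": [p.position[2] for p in points],
            "biv": [p.biv for p in points],
            "univ": [p.univ for p in points],
            "activation_ms": [p.activation_time for p in points],
            "ablation": [p.ablation for p in points],
            "region": [p.region.name if p.region is not None else ""
                       for p in points],
            "slow_site": [bool(p.meta.get("slow_site", False)) for p in points],
        }
    )
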