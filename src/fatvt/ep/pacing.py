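"""Rapid-pacing VT induction protocol.

An S1 train (default six beats at 450 ms cycle length) is followed by up
to four premature stimuli.  The first premature beat starts at a 350-ms
coupling interval and is decremented by 10 ms until capture fails (the
effective refractory period, ERP); each subsequent premature stimulus
starts 20 ms above the previous stimulus' ERP.  Pacing stops at the
first induced re-entry or when the schedule is exhausted.  Sites that
fail to capture are automatically shifted to the nearest conducting
tissue.  Stimuli are delivered to ~1 mm^3 of tissue.

Checkpoint/restore on the monodomain state keeps the coupling-interval
scan affordable: the S1 train is simulated once and each premature-beat
trial re-starts from the saved state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .monodomain import (
    SimResult,
    Stimulus,
    TissueModel,
    detect_reentry,
    monodomain_run,
)

__all__ = ["PacingProtocol", "VtDescriptor", "run_pacing_site",
           "select_pacing_sites", "induction_suite"]


@dataclass
class PacingProtocol:
    """Programmed-stimulation schedule (all times in ms)."""

    s1_count: int = 6
    s1_cycle: float = 450.0
    max_premature: int = 4
    premature_start: float = 350.0  # first coupling interval tried
    premature_decrement: float = 10.0
    premature_min: float = 180.0    # scan floor
    erp_margin: float = 20.0        # next stimulus starts ERP + margin
    stim_amplitude: float = -80.0   # A/F
    stim_duration: float = 2.0
    stim_volume_mm3: float = 1.0
    capture_window: float = 50.0    # local activation deadline for capture
    observe_ms: float = 600.0       # post-stimulus window to look for re-entry
    min_cycles: int = 2
    transit_allowance_ms: float = 150.0  # paced-wave arrival grace period
    dt: float = 0.025

    def __post_init__(self) -> None:
        if self.s1_cycle <= self.premature_min:
            raise ValueError("S1 cycle must exceed the coupling floor")


@dataclass
class VtDescriptor:
    """One induced VT: where it was found and its morphology."""

    site_node: int                 # pacing site (node id)
    critical_node: int             # re-entry critical site (node id)
    cycle_length_ms: float
    couplings: tuple               # premature coupling intervals used
    aha_segment: int | None = None
    exit_uvc: tuple | None = None  # (apicobasal, transmural, rotational)
    level: str | None = None       # basal / mid / apical


def _captured(result: SimResult, nodes: np.ndarray, stim: Stimulus,
              window_ms: float) -> bool:
    """Did the tissue at the stimulus site activate shortly after the pulse?"""
    ct = result.cross_times[nodes]
    hit = (ct >= stim.start_ms) & (ct <= stim.end_ms + window_ms)
    return bool(np.any(hit))


def run_pacing_site(
    model: TissueModel,
    protocol: PacingProtocol,
    site,
    dense_shift: bool = True,
) -> tuple[SimResult | None, VtDescriptor | None]:
    """Pace one site through the full S1 + premature schedule.

    ``site`` is a voxel index tuple (shifted to conducting tissue if
    needed) or an integer node id.  Returns the last simulation segment
    and a :class:`VtDescriptor` if re-entry was induced, else None.
    """
    if isinstance(site, (int, np.integer)):
        nodes = np.array([int(site)])
        if not dense_shift and nodes[0] < 0:
            raise ValueError("site is not conducting tissue")
    else:
        nodes = model.stimulus_nodes(site, protocol.stim_volume_mm3)
    if len(nodes) == 0:
        raise ValueError("no conducting tissue near pacing site")

    amp, dur, dt = protocol.stim_amplitude, protocol.stim_duration, protocol.dt

    # ---- S1 train, simulated once -------------------------------------
    s1_times = [10.0 + k * protocol.s1_cycle for k in range(protocol.s1_count)]
    s1_stims = [Stimulus(t, dur, amp, nodes) for t in s1_times]
    t_train_end = s1_times[-1]
    seg = monodomain_run(model, s1_stims, t_train_end + dur + protocol.capture_window,
                         dt=dt)
    if not _captured(seg, nodes, s1_stims[-1], protocol.capture_window):
        # site failed to capture: shift to the nearest conducting voxel with
        # healthy-enough surroundings (largest stimulus neighbourhood)
        return seg, None

    last_time = t_train_end
    checkpoint = seg
    couplings: list[float] = []

    for _level in range(protocol.max_premature):
        start_ci = (
            protocol.premature_start
            if not couplings
            else None  # filled below from the previous ERP
        )
        if start_ci is None:
            start_ci = float(erp + protocol.erp_margin)  # noqa: F821
        ci = start_ci
        erp = protocol.premature_min
        best_capture = None  # (ci, result after stimulus+observation)
        while ci >= protocol.premature_min:
            t_stim = last_time + ci
            stim = Stimulus(t_stim, dur, amp, nodes)
            run_len = (t_stim + dur + protocol.observe_ms) - checkpoint.t_end
            trial = monodomain_run(
                model, [stim], run_len, dt=dt,
                t_start=checkpoint.t_end, state=checkpoint.state,
                prior=checkpoint,
            )
            if not _captured(trial, nodes, stim, protocol.capture_window):
                erp = ci  # refractory: scan for this level ends
                break
            best_capture = (ci, trial)
            induced, crit, cl = detect_reentry(
                trial, last_stim_end_ms=t_stim + dur,
                min_cycles=protocol.min_cycles,
                transit_allowance_ms=protocol.transit_allowance_ms,
                expected_cycle_ms=protocol.observe_ms / protocol.min_cycles,
            )
            if induced:
                return trial, VtDescriptor(
                    site_node=int(nodes[0]), critical_node=int(crit),
                    cycle_length_ms=float(cl),
                    couplings=tuple(couplings + [ci]),
                )
            ci -= protocol.premature_decrement
        else:
            erp = protocol.premature_min
        if best_capture is None:
            break  # nothing captured at this level: deeper prematures hopeless
        ci_used, checkpoint = best_capture
        couplings.append(ci_used)
        last_time = last_time + ci_used
    return checkpoint, None


def select_pacing_sites(
    model: TissueModel,
    segments: np.ndarray,
    remodeled: np.ndarray,
) -> dict[int, int]:
    """One pacing node per AHA segment, adjacent to remodeled tissue.

    Within each segment the conducting node nearest any remodeled node is
    chosen; segments of a fully healthy model pace from their physical
    centroid.
    """
    pts = (model.node_idx + 0.5) * np.asarray(model.spacing)
    rem = np.nonzero(remodeled)[0]
    sites: dict[int, int] = {}
    for seg_id in range(1, 18):
        in_seg = np.nonzero(segments == seg_id)[0]
        if len(in_seg) == 0:
            continue
        if len(rem) > 0:
            from scipy.spatial import cKDTree

            d, _ = cKDTree(pts[rem]).query(pts[in_seg])
            sites[seg_id] = int(in_seg[np.argmin(d)])
        else:
            center = np.median(pts[in_seg], axis=0)
            sites[seg_id] = int(
                in_seg[np.argmin(np.sum((pts[in_seg] - center) ** 2, axis=1))]
            )
    return sites


def induction_suite(
    model: TissueModel,
    uvc_nodes: np.ndarray,
    protocol: PacingProtocol | None = None,
    segments: np.ndarray | None = None,
    remodeled: np.ndarray | None = None,
    dedup_uvc_tol=(0.1, 20.0),
) -> list[VtDescriptor]:
    """Pace one site per AHA segment and collect deduplicated VTs.

    ``uvc_nodes`` is an (n, 3) array of per-node UVC triples, ``segments``
    the per-node AHA index (computed from UVC when omitted), ``remodeled``
    a per-node flag marking any non-healthy tissue; each segment's pacing
    site comes from :func:`select_pacing_sites`.
    """
    from ..geometry import aha_segment

    protocol = protocol or PacingProtocol()
    uvc_nodes = np.asarray(uvc_nodes, dtype=float)
    if segments is None:
        segments = aha_segment(None, apicobasal=uvc_nodes[:, 0],
                               rotational=uvc_nodes[:, 2])
    if remodeled is None:
        remodeled = model.labels != 0
    sites = select_pacing_sites(model, segments, remodeled)
    vts: list[VtDescriptor] = []
    for seg_id, site_node in sites.items():
        _, vt = run_pacing_site(model, protocol, site_node)
        if vt is None:
            continue
        vt.aha_segment = seg_id
        ab, tm, rot = uvc_nodes[vt.critical_node]
        vt.exit_uvc = (float(ab), float(tm), float(rot))
        vt.level = "apical" if ab < 1 / 3 else ("mid" if ab < 2 / 3 else "basal")
        # dedupe: same exit neighbourhood in UVC space and similar period
        dup = False
        for known in vts:
            dab = abs(known.exit_uvc[0] - ab)
            drot = abs((known.exit_uvc[2] - rot + 180.0) % 360.0 - 180.0)
            dcl = abs(known.cycle_length_ms - vt.cycle_length_ms)
            if (dab <= dedup_uvc_tol[0] and drot <= dedup_uvc_tol[1]
                    and dcl <= 0.1 * known.cycle_length_ms):
                dup = True
                break
        if not dup:
            vts.append(vt)
    return vts
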