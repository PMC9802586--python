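"""Finite-difference monodomain reaction-diffusion solver.

Operator splitting: an explicit ionic update (Rush-Larsen gates, forward
Euler otherwise) followed by explicit anisotropic diffusion on the
conducting-voxel graph.  The diffusion tensor is diagonalized onto the
grid axes, D_aa = D_t + (D_l - D_t) f_a^2 with f the local unit fiber
vector (exact for axis-aligned fibers; an orthotropic approximation
otherwise).  Face diffusivities use harmonic means, which makes
non-conducting tissue and domain boundaries no-flux automatically: edges
into insulators simply do not exist.

Conductivities (S/m) convert to diffusivities (mm^2/ms) through the
surface-to-volume ratio times membrane capacitance, beta*Cm = 1400 F/m^3
(beta = 0.14 um^-1, Cm = 0.01 F/m^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .tentusscher import N_STATES, resting_state
from .lut import build_tables, step_cells_lut
from .tissue import tissue_params_for

__all__ = [
    "BETA_CM",
    "ACTIVATION_THRESHOLD_MV",
    "Stimulus",
    "TissueModel",
    "SimResult",
    "monodomain_run",
    "detect_reentry",
]

BETA_CM = 1400.0  # F/m^3
#: upstroke detection threshold for activation maps
ACTIVATION_THRESHOLD_MV = -40.0
#: crossings recorded per node (later crossings are counted but not stored)
MAX_CROSSINGS = 64

_SIGMA_TO_D = 1000.0 / BETA_CM  # S/m -> mm^2/ms


@dataclass
class Stimulus:
    """Square current pulse delivered to a set of nodes."""

    start_ms: float
    duration_ms: float
    amplitude: float  # A/F, negative = depolarizing
    nodes: np.ndarray  # node indices

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.duration_ms


class TissueModel:
    """Conducting-node graph with per-node EP parameters.

    Built from an integer label array of any dimensionality (1-3) via
    :meth:`from_labels`; node ordering follows ``np.argwhere`` of the
    conducting mask.
    """

    def __init__(self, labels, spacing, node_idx, conducting_mask,
                 factors, D_axes, shape):
        self.labels = labels
        self.spacing = spacing
        self.node_idx = node_idx
        self.conducting_mask = conducting_mask
        self.factors = factors          # (n, 4): gNa, gCaL, gKr, gKs
        self.D_axes = D_axes            # (n, ndim) mm^2/ms
        self.shape = shape
        self.n_nodes = len(node_idx)
        # voxel -> node lookup
        flat = np.full(int(np.prod(shape)), -1, dtype=np.int64)
        flat[np.ravel_multi_index(tuple(node_idx.T), shape)] = np.arange(
            self.n_nodes
        )
        self._node_of_voxel_flat = flat
        self._build_edges()

    @classmethod
    def from_labels(
        cls,
        labels: np.ndarray,
        spacing,
        modality: str = "hybrid",
        fibers: np.ndarray | None = None,
        mask: np.ndarray | None = None,
        isotropic: bool = False,
    ) -> "TissueModel":
        """Assemble a model from a tissue-label array.

        ``fibers`` is an optional per-voxel unit-vector array of shape
        ``labels.shape + (ndim,)``; fibers default to the first grid axis.
        With ``isotropic`` every axis uses the longitudinal conductivity;
        desk-scale 2D phantoms use this because the transverse
        conductivity lies below the discrete propagation limit at
        0.5 mm spacing (the transverse space constant is a fraction of a
        voxel), which would decouple the sheet into 1D strands.
        """
        labels = np.asarray(labels, dtype=int)
        ndim = labels.ndim
        spacing = tuple(float(s) for s in np.broadcast_to(spacing, (ndim,)))
        if mask is None:
            mask = np.ones(labels.shape, dtype=bool)
        uniq = np.unique(labels[mask])
        params = {int(v): tissue_params_for(int(v), modality) for v in uniq}
        conducting = np.zeros(labels.shape, dtype=bool)
        for v, p in params.items():
            if p.conducting:
                conducting |= mask & (labels == v)
        node_idx = np.argwhere(conducting)
        n = len(node_idx)
        if n == 0:
            raise ValueError("no conducting tissue")
        lab_nodes = labels[tuple(node_idx.T)]
        factors = np.ones((n, 4))
        D_axes = np.zeros((n, ndim))
        if fibers is not None:
            f = np.asarray(fibers, dtype=float)[tuple(node_idx.T)]
        else:
            f = np.zeros((n, ndim))
            f[:, 0] = 1.0
        for v, p in params.items():
            sel = lab_nodes == v
            if not p.conducting or not sel.any():
                continue
            factors[sel, 0] = p.ionic.gNa_factor
            factors[sel, 1] = p.ionic.gCaL_factor
            factors[sel, 2] = p.ionic.gKr_factor
            factors[sel, 3] = p.ionic.gKs_factor
            Dl = p.sigma_l * _SIGMA_TO_D
            Dt = p.sigma_t * _SIGMA_TO_D
            if isotropic:
                D_axes[sel] = Dl
            else:
                D_axes[sel] = Dt + (Dl - Dt) * f[sel] ** 2
        return cls(lab_nodes, spacing, node_idx, conducting, factors,
                   D_axes, labels.shape)

    def _build_edges(self) -> None:
        ei, ej, ew = [], [], []
        ndim = self.node_idx.shape[1]
        flat = self._node_of_voxel_flat
        for a in range(ndim):
            nb = self.node_idx.copy()
            nb[:, a] += 1
            valid = nb[:, a] < self.shape[a]
            src = np.nonzero(valid)[0]
            j = flat[np.ravel_multi_index(tuple(nb[valid].T), self.shape)]
            ok = j >= 0
            src, j = src[ok], j[ok]
            Di, Dj = self.D_axes[src, a], self.D_axes[j, a]
            w = 2.0 * Di * Dj / np.maximum(Di + Dj, 1e-30) / self.spacing[a] ** 2
            ei.append(src)
            ej.append(j)
            ew.append(w)
        self.edge_i = np.concatenate(ei).astype(np.int64)
        self.edge_j = np.concatenate(ej).astype(np.int64)
        self.edge_w = np.concatenate(ew)

    def node_of_voxel(self, voxel_idx) -> int:
        """Node id of a voxel index tuple (-1 if non-conducting)."""
        return int(
            self._node_of_voxel_flat[
                np.ravel_multi_index(tuple(np.asarray(voxel_idx)), self.shape)
            ]
        )

    def nodes_near(self, voxel_idx, radius_mm: float) -> np.ndarray:
        """Conducting nodes within a physical radius of a voxel center."""
        center = (np.asarray(voxel_idx, dtype=float) + 0.5) * np.asarray(
            self.spacing
        )
        pts = (self.node_idx + 0.5) * np.asarray(self.spacing)
        d2 = np.sum((pts - center) ** 2, axis=1)
        return np.nonzero(d2 <= radius_mm**2)[0]

    def stimulus_nodes(self, voxel_idx, volume_mm3: float = 1.0) -> np.ndarray:
        """Nodes inside a cube of the given volume centered on a voxel.

        If the exact cube holds no conducting node the site is shifted to
        the nearest conducting voxel (automatic capture-site adjustment).
        """
        half = volume_mm3 ** (1.0 / len(self.shape)) / 2.0
        center = (np.asarray(voxel_idx, dtype=float) + 0.5) * np.asarray(
            self.spacing
        )
        pts = (self.node_idx + 0.5) * np.asarray(self.spacing)
        inside = np.all(np.abs(pts - center) <= half + 1e-9, axis=1)
        if inside.any():
            return np.nonzero(inside)[0]
        nearest = int(np.argmin(np.sum((pts - center) ** 2, axis=1)))
        return np.array([nearest])

    def max_stable_dt(self) -> float:
        """Explicit-diffusion stability bound (informational)."""
        wsum = np.zeros(self.n_nodes)
        np.add.at(wsum, self.edge_i, self.edge_w)
        np.add.at(wsum, self.edge_j, self.edge_w)
        return 1.0 / max(wsum.max(), 1e-30)


@dataclass
class SimResult:
    """Output of a monodomain run (crossing history + activation map)."""

    model: TissueModel
    dt: float
    t_start: float
    t_end: float
    cross_times: np.ndarray       # (n, MAX_CROSSINGS), NaN-padded
    cross_count: np.ndarray       # (n,)
    state: np.ndarray             # final state (n, N_STATES)
    stimuli: list
    probe_nodes: np.ndarray | None = None
    probe_times: np.ndarray | None = None
    probe_v: np.ndarray | None = None
    induced: bool | None = None
    critical_site: int | None = None
    cycle_length_ms: float | None = None

    def activation_map(self, after_ms: float | None = None) -> np.ndarray:
        """Grid-shaped first-activation times (ms); NaN where never activated.

        ``after_ms`` selects the first crossing at or after that time.
        """
        out = np.full(self.model.shape, np.nan)
        ct = self.cross_times
        if after_ms is None:
            first = np.where(self.cross_count > 0, ct[:, 0], np.nan)
        else:
            masked = np.where(ct >= after_ms, ct, np.nan)
            with np.errstate(all="ignore"):
                first = np.nanmin(masked, axis=1)
        out[tuple(self.model.node_idx.T)] = first
        return out


@njit(cache=True, error_model="numpy")
def _run_kernel(S, dt, t0, n_steps, gna, gcal, gkr, gks, T,
                ei, ej, ew,
                stim_start, stim_end, stim_amp, stim_ptr, stim_nodes,
                act_thr, cross_times, cross_count,
                probe_nodes, probe_stride, probe_v):
    n = S.shape[0]
    istim = np.zeros(n)
    vprev = np.empty(n)
    lap = np.empty(n)
    n_probe_rows = probe_v.shape[0]
    for k in range(n_steps):
        t = t0 + k * dt
        for i in range(n):
            istim[i] = 0.0
        for s in range(stim_start.size):
            if stim_start[s] <= t < stim_end[s]:
                for q in range(stim_ptr[s], stim_ptr[s + 1]):
                    istim[stim_nodes[q]] += stim_amp[s]
        for i in range(n):
            vprev[i] = S[i, 0]
        step_cells_lut(S, dt, gna, gcal, gkr, gks, istim, T)
        for i in range(n):
            lap[i] = 0.0
        for e in range(ei.size):
            a = ei[e]
            b = ej[e]
            dv = S[b, 0] - S[a, 0]
            lap[a] += ew[e] * dv
            lap[b] -= ew[e] * dv
        for i in range(n):
            S[i, 0] += dt * lap[i]
        for i in range(n):
            if vprev[i] < act_thr and S[i, 0] >= act_thr:
                c = cross_count[i]
                if c < cross_times.shape[1]:
                    cross_times[i, c] = t + dt
                cross_count[i] = c + 1
        if probe_nodes.size > 0 and k % probe_stride == 0:
            row = k // probe_stride
            if row < n_probe_rows:
                for pi in range(probe_nodes.size):
                    probe_v[row, pi] = S[probe_nodes[pi], 0]
        if k % 2000 == 1999:
            bad = False
            for i in range(n):
                if not np.isfinite(S[i, 0]):
                    bad = True
                    break
            if bad:
                return k
    return -1


def monodomain_run(
    model: TissueModel,
    stimuli: list[Stimulus],
    duration_ms: float,
    dt: float = 0.025,
    t_start: float = 0.0,
    state: np.ndarray | None = None,
    probe_nodes=None,
    probe_stride: int = 40,
    prior: SimResult | None = None,
) -> SimResult:
    """Run the monodomain model for ``duration_ms`` starting at ``t_start``.

    ``state``/``prior`` allow continuing from a checkpoint: pass the final
    state of an earlier result (its crossing history is carried over).
    Raises on numerical blow-up with the offending step in the message.
    """
    if dt > 0.025 + 1e-12:
        raise ValueError("dt must be <= 25 us")
    dt_max = model.max_stable_dt()
    if dt > dt_max:
        raise ValueError(
            f"dt={dt} ms exceeds the explicit-diffusion stability bound "
            f"{dt_max:.4f} ms for this grid; refine dt or coarsen dx"
        )
    n = model.n_nodes
    if state is None:
        S = np.tile(resting_state(), (n, 1))
    else:
        S = np.array(state, dtype=float, copy=True)
    if prior is not None:
        cross_times = prior.cross_times.copy()
        cross_count = prior.cross_count.copy()
    else:
        cross_times = np.full((n, MAX_CROSSINGS), np.nan)
        cross_count = np.zeros(n, dtype=np.int64)
    n_steps = int(round(duration_ms / dt))
    stim_start = np.array([s.start_ms for s in stimuli], dtype=float)
    stim_end = np.array([s.end_ms for s in stimuli], dtype=float)
    stim_amp = np.array([s.amplitude for s in stimuli], dtype=float)
    lens = [len(s.nodes) for s in stimuli]
    stim_ptr = np.concatenate([[0], np.cumsum(lens)]).astype(np.int64)
    stim_nodes = (
        np.concatenate([np.asarray(s.nodes, dtype=np.int64) for s in stimuli])
        if stimuli
        else np.zeros(0, dtype=np.int64)
    )
    probe_nodes = (
        np.asarray(probe_nodes, dtype=np.int64)
        if probe_nodes is not None
        else np.zeros(0, dtype=np.int64)
    )
    n_rows = (n_steps + probe_stride - 1) // probe_stride if probe_nodes.size else 0
    probe_v = np.full((n_rows, probe_nodes.size), np.nan)

    bad_step = _run_kernel(
        S, dt, t_start, n_steps,
        np.ascontiguousarray(model.factors[:, 0]),
        np.ascontiguousarray(model.factors[:, 1]),
        np.ascontiguousarray(model.factors[:, 2]),
        np.ascontiguousarray(model.factors[:, 3]),
        build_tables(dt),
        model.edge_i, model.edge_j, model.edge_w,
        stim_start, stim_end, stim_amp, stim_ptr, stim_nodes,
        ACTIVATION_THRESHOLD_MV, cross_times, cross_count,
        probe_nodes, probe_stride, probe_v,
    )
    if bad_step >= 0 or not np.all(np.isfinite(S[:, 0])):
        raise FloatingPointError(
            f"monodomain instability near step {bad_step} "
            f"(t ~ {t_start + max(bad_step, 0) * dt:.2f} ms, dt={dt}, "
            f"max dt for diffusion {model.max_stable_dt():.4f} ms)"
        )
    probe_times = (
        t_start + np.arange(n_rows) * probe_stride * dt if n_rows else None
    )
    return SimResult(
        model=model, dt=dt, t_start=t_start, t_end=t_start + duration_ms,
        cross_times=cross_times, cross_count=cross_count, state=S,
        stimuli=list(stimuli), probe_nodes=probe_nodes if probe_nodes.size else None,
        probe_times=probe_times, probe_v=probe_v if n_rows else None,
    )


def detect_reentry(
    result: SimResult,
    last_stim_end_ms: float,
    min_cycles: int = 2,
    period_tolerance: float = 0.25,
    transit_allowance_ms: float = 150.0,
    expected_cycle_ms: float = 250.0,
) -> tuple[bool, int | None, float | None]:
    """Decide whether the run ended in sustained re-entry.

    The directly paced wavefront may activate any node once within
    ``transit_allowance_ms`` of the last stimulus; re-entry requires at
    least ``min_cycles`` further activations at a common critical site
    with a stable inter-activation period (coefficient of variation below
    ``period_tolerance``).  Returns (induced, critical node, cycle length).
    """
    if result.t_end - last_stim_end_ms < min_cycles * expected_cycle_ms:
        raise ValueError(
            "history too short: need at least "
            f"{min_cycles} x {expected_cycle_ms} ms after the last stimulus"
        )
    ct = result.cross_times
    late = np.where(ct > last_stim_end_ms + transit_allowance_ms, ct, np.nan)
    n_late = np.sum(np.isfinite(late), axis=1)
    best, best_node = 0, None
    for i in np.nonzero(n_late >= min_cycles)[0]:
        if n_late[i] > best:
            best, best_node = int(n_late[i]), int(i)
    if best_node is None or best < min_cycles:
        return False, None, None
    times = np.sort(late[best_node][np.isfinite(late[best_node])])
    periods = np.diff(times)
    if len(periods) == 0:
        return False, None, None
    mean_p = float(np.mean(periods))
    if mean_p <= 0:
        return False, None, None
    cov = float(np.std(periods) / mean_p)
    if len(periods) >= 2 and cov > period_tolerance:
        return False, None, None
    return True, best_node, mean_p
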