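"""2D test substrates: desk-scale stand-ins for the 3D VT substrate.

Three kinds:

``homogeneous``
    all non-injured myocardium (a negative control -- rapid pacing must
    not induce re-entry here);
``dense_block``
    a central non-conducting dense-scar block in healthy tissue;
``channel``
    the canonical isthmus geometry: a slow conducting corridor of
    border-zone tissue (fibrofatty infiltration by default) crossing a
    dense non-conducting wall, with flared mouths.  A second, healthy
    gap through the wall closes the re-entrant loop -- the role played
    by the surrounding ventricular wall in 3D.  A premature beat blocks
    antegradely in the corridor (longer refractoriness), conducts
    through the healthy gap, and re-enters the corridor retrogradely;
    the slow corridor transit makes the loop period exceed the tissue
    refractory period, so the re-entry sustains.

All sheets use isotropic coupling at each tissue's longitudinal
conductivity: at the 0.5 mm desk-scale grid the transverse conductivity
lies below the discrete propagation limit and would decouple the sheet
into 1D strands.
"""

from __future__ import annotations

import numpy as np

from ..substrate import HybridLabel
from ..volume import TissueVolume
from .config import SynthConfig

__all__ = ["gen_2d_substrate"]

_BORDER_LABEL = {
    "admixture": HybridLabel.admixture_only,
    "gray_zone": HybridLabel.gray_zone_only,
    "fibrofatty": HybridLabel.fibrofatty,
}


def gen_2d_substrate(
    kind: str, config: SynthConfig | None = None, seed=0
) -> TissueVolume:
    """Generate a 2D sheet of hybrid tissue labels.

    The sheet is ``config.sheet_size_mm`` square at ``config.sheet_dx_mm``
    resolution.  For ``channel`` the corridor is
    ``config.channel_width_mm`` wide, filled with ``config.channel_border``
    tissue, and crosses a dense wall of ``config.wall_mm``; the healthy
    return gap is ``config.return_gap_mm`` wide.  Metadata records the
    corridor geometry (used by tests and the pacing drivers).
    """
    config = config or SynthConfig()
    h = config.sheet_dx_mm
    n = int(round(config.sheet_size_mm / h))
    labels = np.full((n, n), int(HybridLabel.non_injured), dtype=np.int8)
    meta = {"kind": kind, "seed": seed}

    if kind == "homogeneous":
        pass
    elif kind == "dense_block":
        q = n // 4
        labels[q: 3 * q, q: 3 * q] = int(HybridLabel.dense_scar_only)
    elif kind == "channel":
        if config.channel_border not in _BORDER_LABEL:
            raise ValueError(f"unknown channel border {config.channel_border!r}")
        border = int(_BORDER_LABEL[config.channel_border])
        wall = int(round(config.wall_mm / h))
        r0 = (n - wall) // 2
        r1 = r0 + wall
        labels[r0:r1, :] = int(HybridLabel.dense_scar_only)
        # healthy return gap on the left side
        g = int(round(config.return_gap_mm / h))
        g0 = max(int(round(0.115 * n)), 1)
        labels[r0:r1, g0: g0 + g] = int(HybridLabel.non_injured)
        # slow corridor on the right side, with flared mouths
        cw = max(int(round(config.channel_width_mm / h)), 2)
        c0 = int(round(0.74 * n))
        flare = int(round(config.channel_flare_mm / h))
        for x in range(r0, r1):
            d_end = min(x - r0, r1 - 1 - x)
            extra = max(0, flare - d_end)
            labels[x, c0 - extra: c0 + cw + extra] = border
        meta.update(
            wall_rows=(r0, r1), corridor_cols=(c0, c0 + cw),
            gap_cols=(g0, g0 + g), border_label=border,
        )
    else:
        raise ValueError(f"unknown substrate kind {kind!r}")
    return TissueVolume(labels, (h, h), meta=meta)
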