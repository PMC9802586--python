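"""Tissue-class electrophysiology parameterization.

Non-injured myocardium conducts at 0.08 / 0.00889 S/m (longitudinal /
transverse) with baseline ionic properties.  Gray zone and fat-myocardium
admixture share the infarct border-zone parameterization: transverse
conductivity reduced by 90% and peak INa / ICaL / IKr / IKs reduced by
62% / 69% / 70% / 80%.  Fibrofatty infiltrated myocardium additionally
halves both conductivities (an estimated 25% conduction-velocity
decrease).  Dense fat, dense scar and dense fat-and-scar are
non-conducting insulators.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..segmentation import CtLabel, MriLabel
from ..substrate import HybridLabel

__all__ = ["IonicScaling", "TissueParams", "tissue_params_for",
           "SIGMA_L_HEALTHY", "SIGMA_T_HEALTHY", "BORDER_ZONE_SCALING",
           "BASELINE_SCALING"]

SIGMA_L_HEALTHY = 0.08      # S/m
SIGMA_T_HEALTHY = 0.00889   # S/m


@dataclass(frozen=True)
class IonicScaling:
    """Multiplicative factors on maximal conductances (in (0, 1])."""

    gNa_factor: float = 1.0
    gCaL_factor: float = 1.0
    gKr_factor: float = 1.0
    gKs_factor: float = 1.0

    def __post_init__(self) -> None:
        for f in (self.gNa_factor, self.gCaL_factor, self.gKr_factor,
                  self.gKs_factor):
            if not (0.0 < f <= 1.0):
                raise ValueError("ionic factors must lie in (0, 1]")


BASELINE_SCALING = IonicScaling()
#: border-zone remodeling: 62/69/70/80% reductions of INa/ICaL/IKr/IKs
BORDER_ZONE_SCALING = IonicScaling(
    gNa_factor=0.38, gCaL_factor=0.31, gKr_factor=0.30, gKs_factor=0.20
)


@dataclass(frozen=True)
class TissueParams:
    sigma_l: float          # S/m
    sigma_t: float          # S/m
    ionic: IonicScaling
    conducting: bool = True

    def __post_init__(self) -> None:
        if self.conducting and not (self.sigma_l >= self.sigma_t > 0):
            raise ValueError("need sigma_l >= sigma_t > 0 for conducting tissue")


_NON_CONDUCTING = TissueParams(
    sigma_l=SIGMA_L_HEALTHY, sigma_t=SIGMA_T_HEALTHY,
    ionic=BASELINE_SCALING, conducting=False,
)

_HEALTHY = TissueParams(SIGMA_L_HEALTHY, SIGMA_T_HEALTHY, BASELINE_SCALING)
_BORDER = TissueParams(  # gray zone & admixture: transverse x0.1
    SIGMA_L_HEALTHY, SIGMA_T_HEALTHY * 0.1, BORDER_ZONE_SCALING
)
_FIBROFATTY = TissueParams(  # both conductivities an additional x0.5
    SIGMA_L_HEALTHY * 0.5, SIGMA_T_HEALTHY * 0.1 * 0.5, BORDER_ZONE_SCALING
)

_HYBRID_PARAMS = {
    HybridLabel.non_injured: _HEALTHY,
    HybridLabel.admixture_only: _BORDER,
    HybridLabel.gray_zone_only: _BORDER,
    HybridLabel.fibrofatty: _FIBROFATTY,
    HybridLabel.dense_fat_only: _NON_CONDUCTING,
    HybridLabel.dense_scar_only: _NON_CONDUCTING,
    HybridLabel.dense_fat_and_scar: _NON_CONDUCTING,
}

_CT_PARAMS = {
    CtLabel.non_injured: _HEALTHY,
    CtLabel.admixture: _BORDER,
    CtLabel.dense_fat: _NON_CONDUCTING,
}

_MRI_PARAMS = {
    MriLabel.non_injured: _HEALTHY,
    MriLabel.gray_zone: _BORDER,
    MriLabel.dense_scar: _NON_CONDUCTING,
}


def tissue_params_for(label, modality: str = "hybrid") -> TissueParams:
    """EP parameters for a tissue label.

    ``modality`` selects the label enumeration: "hybrid" (7-class),
    "ct" (3-class CT) or "mri" (3-class LGE).
    """
    table = {"hybrid": (_HYBRID_PARAMS, HybridLabel),
             "ct": (_CT_PARAMS, CtLabel),
             "mri": (_MRI_PARAMS, MriLabel)}[modality]
    params, enum = table
    return params[enum(int(label))]
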