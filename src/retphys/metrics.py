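"""Per-eye hemodynamic and oxygen metrics with strict unit contracts.

Flow in each vein is the product of its blood velocity and lumen
cross-sectional area, ``Q = V * (pi/4) * D^2``; summing veins gives total
retinal blood flow (TRBF).  Arterial and venous oxygen contents (O2A, O2V) are
unweighted vessel averages; their difference is O2AV.  Oxygen delivery,
metabolism and extraction fraction follow ``DO2 = TRBF * O2A``,
``MO2 = TRBF * O2AV``, ``OEF = MO2 / DO2``.

Unit conventions (fixed by dimensional analysis):

* ``Q [uL/min] = V [mm/s] * (pi/4) * D[um]^2 * 6e-5``
  (1 mm/s * 1 um^2 = 1e3 um^3/s = 1e-6 uL/s = 6e-5 uL/min)
* ``DO2, MO2 [nL O2/min] = TRBF [uL/min] * content [mL O2/dL] * 10``
  (1 mL/dL = 0.01 mL O2 per mL blood; 1 uL * 0.01 = 10 nL O2)

DO2/MO2/OEF are computed per eye first and only then averaged across animals;
because the mean of a product is not the product of means, group-level values
are not recoverable from group mean TRBF and contents.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "EyeMetrics",
    "vein_flow",
    "total_flow",
    "oxygen_contents",
    "delivery_metabolism",
    "eye_metrics_from_vessels",
]

log = logging.getLogger(__name__)

FLOW_UL_MIN_PER_MM_S_UM2 = 6e-5
DELIVERY_NL_MIN_PER_UL_MLDL = 10.0


@dataclass(frozen=True)
class EyeMetrics:
    """One eye's aggregate hemodynamic and oxygen metrics."""

    d_a_um: float
    d_v_um: float
    v_v_mm_s: float
    trbf_ul_min: float
    o2a_ml_dl: float
    o2v_ml_dl: float
    o2av_ml_dl: float
    do2_nl_min: float
    mo2_nl_min: float
    oef: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def vein_flow(velocity_mm_s: float, diameter_um: float) -> float:
    """Blood flow in one vein, uL/min, from velocity (mm/s) and diameter (um)."""
    if velocity_mm_s < 0:
        raise ValueError(f"velocity must be >= 0, got {velocity_mm_s!r}")
    if diameter_um <= 0:
        raise ValueError(f"diameter must be > 0, got {diameter_um!r}")
    area_um2 = (math.pi / 4.0) * diameter_um**2
    return velocity_mm_s * area_um2 * FLOW_UL_MIN_PER_MM_S_UM2


def total_flow(vein_flows_ul_min: list[float]) -> float:
    """Total retinal blood flow: arithmetic sum over veins, uL/min."""
    if len(vein_flows_ul_min) == 0:
        log.warning("total_flow: no veins; returning NaN")
        return math.nan
    flows = np.asarray(vein_flows_ul_min, dtype=float)
    if np.any(flows < 0):
        raise ValueError("vein flows must be >= 0")
    return float(flows.sum())


def oxygen_contents(
    artery_contents_ml_dl: list[float], vein_contents_ml_dl: list[float]
) -> tuple[float, float, float]:
    """Per-eye (O2A, O2V, O2AV) from per-vessel contents, mL O2/dL.

    O2A and O2V are unweighted means over arteries and veins respectively;
    O2AV = O2A - O2V.  A negative O2AV is physiologically anomalous and is
    flagged via a warning but returned unchanged.  Missing either vessel class
    returns NaN sentinels.
    """
    if len(artery_contents_ml_dl) == 0 or len(vein_contents_ml_dl) == 0:
        log.warning("oxygen_contents: missing a vessel class; returning NaN")
        return math.nan, math.nan, math.nan
    o2a = float(np.mean(artery_contents_ml_dl))
    o2v = float(np.mean(vein_contents_ml_dl))
    o2av = o2a - o2v
    if o2av < 0:
        log.warning("oxygen_contents: negative O2AV %.3f (venous > arterial)", o2av)
    return o2a, o2v, o2av


def delivery_metabolism(
    trbf_ul_min: float, o2a_ml_dl: float, o2av_ml_dl: float
) -> tuple[float, float, float]:
    """(DO2, MO2, OEF): oxygen delivery and metabolism in nL O2/min, OEF unitless.

    ``OEF = MO2/DO2`` reduces algebraically to ``O2AV/O2A`` — independent of
    flow — which the implementation exploits for a well-conditioned ratio.
    DO2 = 0 with a nonzero MO2 is contradictory and raises.
    """
    if trbf_ul_min < 0:
        raise ValueError(f"trbf must be >= 0, got {trbf_ul_min!r}")
    do2 = trbf_ul_min * o2a_ml_dl * DELIVERY_NL_MIN_PER_UL_MLDL
    mo2 = trbf_ul_min * o2av_ml_dl * DELIVERY_NL_MIN_PER_UL_MLDL
    if do2 == 0.0:
        if mo2 != 0.0:
            raise ValueError("DO2 = 0 with nonzero MO2 is inconsistent")
        return do2, mo2, math.nan
    oef = o2av_ml_dl / o2a_ml_dl
    return do2, mo2, oef


def eye_metrics_from_vessels(vessels: pd.DataFrame) -> EyeMetrics:
    """Aggregate a per-vessel table into one eye's :class:`EyeMetrics`.

    ``vessels`` needs columns ``vessel_type`` ('artery'/'vein'),
    ``diameter_um``, ``content_ml_dl`` and, for veins, ``velocity_mm_s``.
    Eye-level diameters and velocity are unweighted vessel means; per-vein
    flows use each vein's own velocity and diameter before summation.
    """
    arteries = vessels[vessels["vessel_type"] == "artery"]
    veins = vessels[vessels["vessel_type"] == "vein"]
    d_a = float(arteries["diameter_um"].mean()) if len(arteries) else math.nan
    d_v = float(veins["diameter_um"].mean()) if len(veins) else math.nan
    v_v = float(veins["velocity_mm_s"].mean()) if len(veins) else math.nan
    flows = [
        vein_flow(v, d)
        for v, d in zip(veins["velocity_mm_s"], veins["diameter_um"])
    ]
    trbf = total_flow(flows)
    o2a, o2v, o2av = oxygen_contents(
        list(arteries["content_ml_dl"]), list(veins["content_ml_dl"])
    )
    if math.isnan(trbf) or math.isnan(o2a):
        do2 = mo2 = oef = math.nan
    else:
        do2, mo2, oef = delivery_metabolism(trbf, o2a, o2av)
    return EyeMetrics(
        d_a_um=d_a,
        d_v_um=d_v,
        v_v_mm_s=v_v,
        trbf_ul_min=trbf,
        o2a_ml_dl=o2a,
        o2v_ml_dl=o2v,
        o2av_ml_dl=o2av,
        do2_nl_min=do2,
        mo2_nl_min=mo2,
        oef=oef,
    )
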