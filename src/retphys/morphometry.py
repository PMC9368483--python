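"""Retinal layer morphometry from boundary depth lists.

Histology sections give ordered layer-boundary depths measured from the inner
limiting membrane outward; consecutive differences are layer thicknesses.  In
mouse retina the nerve fiber layer and retinal ganglion cell layer cannot be
separated, so their combined thickness is derived from the inner retina as
``NFL/RGCL = IRL - (IPL + INL)``.  Measurements taken nasal and temporal to
the optic nerve head are averaged per layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "LayerBoundaries",
    "ThicknessRecord",
    "layer_thicknesses",
    "region_average",
    "inner_retina_fraction",
]

log = logging.getLogger(__name__)

#: boundary order: ILM (0), NFL/RGCL outer, IPL outer, INL outer (= IRL outer),
#: OPL outer, ONL outer, PRL outer (= total retinal thickness)
LAYER_SEQUENCE = ("nfl_rgcl", "ipl", "inl", "opl", "onl", "prl")
N_BOUNDARIES = len(LAYER_SEQUENCE) + 1


@dataclass(frozen=True)
class LayerBoundaries:
    """Ordered boundary depths (um from the inner limiting membrane)."""

    region: str  # 'nasal' or 'temporal'
    depths_um: np.ndarray

    def __post_init__(self) -> None:
        if self.region not in ("nasal", "temporal"):
            raise ValueError(f"region must be 'nasal' or 'temporal', got {self.region!r}")
        d = np.asarray(self.depths_um, dtype=float)
        if d.ndim != 1 or d.size != N_BOUNDARIES:
            raise ValueError(f"expected {N_BOUNDARIES} boundary depths, got {d.size}")
        if d[0] != 0.0:
            raise ValueError("first boundary depth must be 0 (inner limiting membrane)")
        if np.any(np.diff(d) <= 0):
            raise ValueError("boundary depths must be strictly increasing")
        object.__setattr__(self, "depths_um", d)


@dataclass(frozen=True)
class ThicknessRecord:
    """Per-layer thicknesses (um) plus the derived IRL and TRT."""

    nfl_rgcl: float
    ipl: float
    inl: float
    opl: float
    onl: float
    prl: float
    irl: float
    trt: float
    region: str = "averaged"

    def as_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name) for f in fields(self) if f.name != "region"
        }


def layer_thicknesses(boundaries: LayerBoundaries) -> ThicknessRecord:
    """Thicknesses from consecutive boundary differences.

    The inner retina (IRL) spans the inner limiting membrane to the INL outer
    edge; NFL/RGCL is computed as ``IRL - (IPL + INL)`` rather than read as a
    plain difference, matching how it is derived when the two innermost layers
    cannot be delineated directly.
    """
    d = boundaries.depths_um
    t = np.diff(d)
    named = dict(zip(LAYER_SEQUENCE, t))
    irl = float(d[3])  # ILM -> INL outer edge
    nfl_rgcl = irl - (named["ipl"] + named["inl"])
    return ThicknessRecord(
        nfl_rgcl=float(nfl_rgcl),
        ipl=float(named["ipl"]),
        inl=float(named["inl"]),
        opl=float(named["opl"]),
        onl=float(named["onl"]),
        prl=float(named["prl"]),
        irl=irl,
        trt=float(d[-1]),
        region=boundaries.region,
    )


def region_average(
    nasal: ThicknessRecord | None, temporal: ThicknessRecord | None
) -> ThicknessRecord:
    """Element-wise mean of nasal and temporal records.

    If one region is missing (poor section quality) the other is returned
    as-is with a logged flag rather than discarding the eye.
    """
    if nasal is None and temporal is None:
        raise ValueError("both regions missing")
    if nasal is None or temporal is None:
        present = nasal if nasal is not None else temporal
        log.warning("region_average: only %s region available", present.region)
        return ThicknessRecord(**present.as_dict(), region="single-region")
    vals = {
        k: 0.5 * (nasal.as_dict()[k] + temporal.as_dict()[k])
        for k in nasal.as_dict()
    }
    return ThicknessRecord(**vals, region="averaged")


def inner_retina_fraction(record: ThicknessRecord) -> float:
    """NFL/RGCL share of the inner retina, percent: ``100 * NFL_RGCL / IRL``."""
    if record.irl <= 0:
        raise ValueError("inner retina thickness must be > 0")
    return 100.0 * record.nfl_rgcl / record.irl
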