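"""Phosphorescence-lifetime oximetry.

Frequency-domain phosphorescence lifetime imaging measures vascular oxygen
tension: an oxygen-sensitive probe (Pd-porphyrin) is excited with sinusoidally
modulated light, and the phase lag ``phi`` of the emitted phosphorescence gives
the lifetime ``tau = tan(phi) / (2 pi f_mod)``.  Oxygen quenches the
phosphorescence, so lifetime maps to oxygen tension through the Stern-Volmer
relation ``1/tau = 1/tau0 + kq * PO2``.  Saturation follows a Hill-form
hemoglobin dissociation curve, and total blood oxygen content sums the
hemoglobin-bound and physically dissolved fractions.

Units: lifetimes in seconds, PO2 in mmHg, saturation as a fraction in [0, 1],
content in mL O2 per dL of blood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "OximetryConstants",
    "OxygenState",
    "PhosphorescenceTrace",
    "estimate_phase",
    "estimate_lifetime",
    "lifetime_to_po2",
    "po2_to_lifetime",
    "po2_to_so2",
    "oxygen_content",
    "content_to_po2",
]


@dataclass(frozen=True)
class OximetryConstants:
    """Physical constants of the oximetry chain.

    The defaults are literature values for Pd-porphyrin probes and C57BL/6
    mouse hemoglobin; they are deliberately identical across experimental
    groups so that group contrasts are unaffected by their absolute accuracy.

    Parameters
    ----------
    tau0_s : float
        Unquenched (zero-oxygen) phosphorescence lifetime, seconds.
    kq_per_mmhg_s : float
        Stern-Volmer quenching constant, 1/(mmHg*s).
    p50_mmhg : float
        Half-saturation oxygen tension of the dissociation curve, mmHg.
    hill_n : float
        Hill cooperativity exponent (dimensionless, >= 1).
    hb_g_dl : float
        Hemoglobin concentration, g/dL.
    hb_capacity_ml_g : float
        Oxygen binding capacity of hemoglobin, mL O2 per g Hb.
    solubility_ml_dl_mmhg : float
        Plasma oxygen solubility coefficient, mL O2 / dL / mmHg.
    tau_tolerance : float
        Relative tolerance above ``tau0_s`` within which a noisy lifetime is
        clamped to PO2 = 0 rather than rejected.
    """

    tau0_s: float = 637e-6
    kq_per_mmhg_s: float = 381.0
    p50_mmhg: float = 40.0
    hill_n: float = 2.59
    hb_g_dl: float = 15.0
    hb_capacity_ml_g: float = 1.39
    solubility_ml_dl_mmhg: float = 0.003
    tau_tolerance: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "tau0_s",
            "kq_per_mmhg_s",
            "p50_mmhg",
            "hill_n",
            "hb_g_dl",
            "hb_capacity_ml_g",
            "solubility_ml_dl_mmhg",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        if self.hill_n < 1:
            raise ValueError(f"hill_n must be >= 1, got {self.hill_n!r}")
        if not 0 <= self.tau_tolerance < 1:
            raise ValueError("tau_tolerance must be in [0, 1)")

    @property
    def hb_binding_ml_dl(self) -> float:
        """Maximum hemoglobin-bound oxygen, mL O2/dL (capacity * [Hb])."""
        return self.hb_capacity_ml_g * self.hb_g_dl


@dataclass(frozen=True)
class OxygenState:
    """PO2 / SO2 / content triple for one vessel."""

    po2_mmhg: float
    so2: float
    content_ml_dl: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.so2 <= 1.0):
            raise ValueError(f"so2 must be in [0, 1], got {self.so2!r}")
        if not np.isfinite(self.po2_mmhg) or self.po2_mmhg < 0:
            raise ValueError("po2_mmhg must be finite and >= 0")
        if not np.isfinite(self.content_ml_dl):
            raise ValueError("content_ml_dl must be finite")


@dataclass(frozen=True)
class PhosphorescenceTrace:
    """One modulated-excitation phosphorescence record.

    Either raw time-domain samples (``time_s`` + ``signal``) or a precomputed
    phase (``phase_rad``) may be supplied; at least one must be present.
    """

    modulation_frequency_hz: float
    time_s: np.ndarray | None = None
    signal: np.ndarray | None = None
    phase_rad: float | None = None
    noise_model: str = "none"
    vessel_id: str = ""

    def __post_init__(self) -> None:
        if self.modulation_frequency_hz <= 0:
            raise ValueError("modulation_frequency_hz must be > 0")
        has_samples = self.time_s is not None and self.signal is not None
        if not has_samples and self.phase_rad is None:
            raise ValueError("trace needs time/signal samples or a phase_rad")
        if has_samples:
            t = np.asarray(self.time_s, dtype=float)
            s = np.asarray(self.signal, dtype=float)
            if t.shape != s.shape or t.ndim != 1 or t.size < 3:
                raise ValueError("time_s and signal must be equal-length 1-D, n >= 3")
            object.__setattr__(self, "time_s", t)
            object.__setattr__(self, "signal", s)


def estimate_phase(trace: PhosphorescenceTrace) -> float:
    """Phase lag of the trace at its modulation frequency, radians.

    For sampled traces the phase comes from a linear least-squares fit of the
    signal onto ``[1, cos(wt), sin(wt)]``; writing the modulated emission as
    ``A + m*cos(wt - phi)`` the fitted cosine/sine coefficients are
    ``m*cos(phi)`` and ``m*sin(phi)``, so ``phi = atan2(S, C)``.
    """
    if trace.phase_rad is not None and trace.time_s is None:
        return float(trace.phase_rad)
    w = 2.0 * np.pi * trace.modulation_frequency_hz
    t = trace.time_s
    design = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(design, trace.signal, rcond=None)
    _, c, s = coef
    return float(np.arctan2(s, c))


def estimate_lifetime(trace: PhosphorescenceTrace) -> float:
    """Phosphorescence lifetime in seconds: ``tau = tan(phi)/(2 pi f_mod)``.

    Raises
    ------
    ValueError
        If the estimated phase falls outside the physical range (0, pi/2).
    """
    phi = estimate_phase(trace)
    if not 0.0 < phi < np.pi / 2:
        raise ValueError(
            f"non-physical phase {phi:.4f} rad; lifetimes require phase in (0, pi/2)"
        )
    return float(np.tan(phi) / (2.0 * np.pi * trace.modulation_frequency_hz))


def lifetime_to_po2(tau_s: float, constants: OximetryConstants) -> float:
    """Oxygen tension from lifetime via Stern-Volmer: ``(tau0/tau - 1)/(kq*tau0)``.

    Lifetimes slightly above ``tau0`` (within ``tau_tolerance``) are clamped to
    PO2 = 0 — measurement noise can push an anoxic vessel's lifetime past the
    unquenched limit.  Larger excursions are rejected.
    """
    tau0 = constants.tau0_s
    if not np.isfinite(tau_s) or tau_s <= 0:
        raise ValueError(f"lifetime must be finite and > 0, got {tau_s!r}")
    if tau_s > tau0 * (1.0 + constants.tau_tolerance):
        raise ValueError(
            f"lifetime {tau_s:.3e} s exceeds unquenched tau0 {tau0:.3e} s "
            "beyond the noise tolerance"
        )
    if tau_s >= tau0:
        return 0.0
    return (tau0 / tau_s - 1.0) / (constants.kq_per_mmhg_s * tau0)


def po2_to_lifetime(po2_mmhg: float, constants: OximetryConstants) -> float:
    """Stern-Volmer forward model: ``tau = tau0 / (1 + kq*tau0*PO2)``."""
    if po2_mmhg < 0:
        raise ValueError(f"po2 must be >= 0, got {po2_mmhg!r}")
    tau0 = constants.tau0_s
    return tau0 / (1.0 + constants.kq_per_mmhg_s * tau0 * po2_mmhg)


def po2_to_so2(po2_mmhg: float, constants: OximetryConstants) -> float:
    """Hemoglobin saturation from the Hill dissociation curve.

    ``SO2 = PO2^n / (P50^n + PO2^n)``; exactly 0.5 at PO2 = P50, 0 at anoxia,
    approaching 1 asymptotically.
    """
    if po2_mmhg < 0:
        raise ValueError(f"po2 must be >= 0, got {po2_mmhg!r}")
    if po2_mmhg == 0:
        return 0.0
    # logistic in log-PO2 keeps both tails well conditioned
    t = constants.hill_n * (math.log(constants.p50_mmhg) - math.log(po2_mmhg))
    return float(expit(-t))


def oxygen_content(po2_mmhg: float, constants: OximetryConstants) -> float:
    """Total blood oxygen content, mL O2/dL.

    Hemoglobin-bound (``capacity * [Hb] * SO2``) plus physically dissolved
    (``alpha * PO2``); strictly increasing in PO2.
    """
    so2 = po2_to_so2(po2_mmhg, constants)
    return constants.hb_binding_ml_dl * so2 + constants.solubility_ml_dl_mmhg * po2_mmhg


def content_to_po2(
    content_ml_dl: float,
    constants: OximetryConstants,
    po2_max_mmhg: float = 800.0,
    tol_mmhg: float = 1e-9,
) -> float:
    """Numerical inverse of :func:`oxygen_content` by bracketed root finding.

    Because content is strictly monotone in PO2 the inverse is unique; the
    search is confined to ``[0, po2_max_mmhg]`` and contents above the content
    at the upper bound are rejected.
    """
    if content_ml_dl < 0:
        raise ValueError(f"content must be >= 0, got {content_ml_dl!r}")
    if content_ml_dl == 0:
        return 0.0
    upper = oxygen_content(po2_max_mmhg, constants)
    if content_ml_dl > upper:
        raise ValueError(
            f"content {content_ml_dl:.4f} mL O2/dL exceeds the maximum "
            f"{upper:.4f} reachable at {po2_max_mmhg} mmHg"
        )
    return float(
        brentq(
            lambda p: oxygen_content(p, constants) - content_ml_dl,
            0.0,
            po2_max_mmhg,
            xtol=tol_mmhg,
        )
    )


def oxygen_state(po2_mmhg: float, constants: OximetryConstants) -> OxygenState:
    """Bundle PO2 with its derived saturation and content."""
    return OxygenState(
        po2_mmhg=float(po2_mmhg),
        so2=po2_to_so2(po2_mmhg, constants),
        content_ml_dl=oxygen_content(po2_mmhg, constants),
    )
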