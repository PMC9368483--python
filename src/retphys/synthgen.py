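"""Calibrated synthetic two-group cohort generator.

Emulates a preclinical imaging study comparing wild-type (WT) and 5XFAD
(Alzheimer-model) mice: per-animal "truth-level" physiological metrics are
drawn from group-calibrated distributions, and "raw-level" measurement signals
(modulated phosphorescence traces, microsphere tracks, angiographic caliber
profiles, retinal layer boundaries) are synthesized from those truths so the
full measurement chain can be exercised end to end.

Calibration structure
---------------------
Per-animal metrics are normal within each group, at the group means/SDs of the
calibration tables.  Arterial oxygen content (O2A), venous velocity (V_V),
NFL/RGCL thickness and venous oxygen content (O2V) are drawn jointly from a
single-factor multivariate normal (O2A is the factor).  The O2A-V_V and
O2A-NFL within-group correlations are chosen by one-dimensional root finding
so that the POOLED (both groups combined) correlations match configured
targets — the pooled association is what such studies report, and group
separation and within-group coupling both contribute.  The O2A-O2V
correlation is set so the arteriovenous content difference O2AV has its
calibrated spread (arterial and venous contents co-vary within an animal).
TRBF and the oxygen delivery/metabolism metrics are not drawn — they are
derived per animal from that animal's vessel truths, which is what makes the
noiseless signal round trip an identity.

Negative draws of strictly positive quantities are rejected and redrawn.
Only the violating metric's independent residual is redrawn, so rejection
never leaks bias into other metrics through the correlation structure; the
truncation bias itself is confined to metrics whose calibration places
appreciable mass below zero (at the default tables, only venous oxygen
content — see the methods note).  Identical seeds give identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .morphometry import LAYER_SEQUENCE, LayerBoundaries
from .oximetry import (
    OximetryConstants,
    PhosphorescenceTrace,
    content_to_po2,
    po2_to_lifetime,
)
from .velocimetry import CaliberProfile, MicrosphereTrack
from .metrics import delivery_metabolism, total_flow, vein_flow

__all__ = [
    "GroupCalibration",
    "CohortConfig",
    "VesselTruth",
    "SyntheticAnimal",
    "WT_CALIBRATION",
    "FAD_CALIBRATION",
    "default_cohort_config",
    "calibrate_within_correlation",
    "calibrate_o2av_correlation",
    "pooled_moments",
    "generate_cohort",
    "cohort_truth_table",
    "synthesize_phase_trace",
    "synthesize_tracks",
    "synthesize_caliber_profile",
]

#: metrics drawn directly from group calibrations (flow metrics are derived)
DRAWN_METRICS = (
    "d_a_um",
    "d_v_um",
    "v_v_mm_s",
    "o2a_ml_dl",
    "o2v_ml_dl",
    "nfl_rgcl",
    "ipl",
    "inl",
    "opl",
    "onl",
    "prl",
    "trt_oct",
    "abeta42_retina",
    "abeta40_retina",
    "abeta42_brain",
    "abeta40_brain",
)

#: the jointly drawn block (order matters for the correlation matrix);
#: O2A acts as the common factor of the single-factor structure
CORRELATED_BLOCK = ("o2a_ml_dl", "v_v_mm_s", "nfl_rgcl", "o2v_ml_dl")


@dataclass(frozen=True)
class GroupCalibration:
    """Per-group means and SDs for every truth-level metric.

    ``trbf_ul_min`` may be present as a consistency reference (the generator
    derives TRBF from vessel truths rather than drawing it).
    """

    group: str
    n_animals: int
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")
        missing = [m for m in DRAWN_METRICS if m not in self.means or m not in self.sds]
        if missing:
            raise ValueError(f"calibration missing metrics: {missing}")
        for k, v in self.means.items():
            if not v > 0:
                raise ValueError(f"mean for {k} must be > 0, got {v!r}")
        for k, v in self.sds.items():
            if not v > 0:
                raise ValueError(f"sd for {k} must be > 0, got {v!r}")


# Group calibration tables: WT and 5XFAD cohorts of male mice at 3 months,
# 13 imaged eyes per group (hemodynamics/oximetry); histology and protein
# subsets have smaller n in the source cohorts but the generator draws every
# metric for every animal.  The 5XFAD IPL/INL/PRL entries reuse the WT values
# (group difference reported as non-significant without printed means).
WT_CALIBRATION = GroupCalibration(
    group="WT",
    n_animals=13,
    means={
        "d_a_um": 27.0, "d_v_um": 30.0, "v_v_mm_s": 10.5, "trbf_ul_min": 1.73,
        "o2a_ml_dl": 6.5, "o2v_ml_dl": 2.8, "o2av_ml_dl": 3.7,
        "nfl_rgcl": 16.2, "ipl": 36.7, "inl": 31.0,
        "opl": 14.6, "onl": 44.3, "prl": 29.1,
        "trt_oct": 242.0,
        "abeta42_retina": 2.4, "abeta40_retina": 2.5,
        "abeta42_brain": 1.4, "abeta40_brain": 9.3,
    },
    sds={
        "d_a_um": 2.0, "d_v_um": 3.0, "v_v_mm_s": 3.1, "trbf_ul_min": 0.52,
        "o2a_ml_dl": 1.4, "o2v_ml_dl": 1.9, "o2av_ml_dl": 1.3,
        "nfl_rgcl": 4.2, "ipl": 4.0, "inl": 4.4,
        "opl": 2.0, "onl": 4.6, "prl": 3.9,
        "trt_oct": 11.0,
        "abeta42_retina": 0.8, "abeta40_retina": 0.2,
        "abeta42_brain": 0.5, "abeta40_brain": 3.0,
    },
)

FAD_CALIBRATION = GroupCalibration(
    group="5XFAD",
    n_animals=13,
    means={
        "d_a_um": 27.0, "d_v_um": 33.0, "v_v_mm_s": 6.6, "trbf_ul_min": 1.63,
        "o2a_ml_dl": 7.8, "o2v_ml_dl": 4.3, "o2av_ml_dl": 3.5,
        "nfl_rgcl": 15.1, "ipl": 36.7, "inl": 31.0,
        "opl": 17.2, "onl": 47.6, "prl": 29.1,
        "trt_oct": 235.0,
        "abeta42_retina": 5.4, "abeta40_retina": 4.9,
        "abeta42_brain": 6.1, "abeta40_brain": 8.2,
    },
    sds={
        "d_a_um": 3.0, "d_v_um": 3.0, "v_v_mm_s": 1.4, "trbf_ul_min": 0.50,
        "o2a_ml_dl": 1.2, "o2v_ml_dl": 1.6, "o2av_ml_dl": 1.1,
        "nfl_rgcl": 2.8, "ipl": 4.0, "inl": 4.4,
        "opl": 1.3, "onl": 2.7, "prl": 3.9,
        "trt_oct": 6.0,
        "abeta42_retina": 2.6, "abeta40_retina": 1.5,
        "abeta42_brain": 1.9, "abeta40_brain": 1.2,
    },
)


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs, with study-condition defaults.

    Noise defaults emulate the reference instrumentation: 104 Hz sphere
    imaging, near-optimal excitation modulation for the probe's lifetime
    range, ~1 um sphere-centroid jitter, phase noise equivalent to ~1.5 mmHg
    PO2 reproducibility, 1% angiographic intensity noise with ~4 um vessel
    edge spread, and 10% within-eye vessel-to-vessel variability.
    """

    calibrations: tuple[GroupCalibration, ...] = (WT_CALIBRATION, FAD_CALIBRATION)
    oximetry: OximetryConstants = field(default_factory=OximetryConstants)
    n_veins_per_eye: int = 4
    n_arteries_per_eye: int = 4
    frame_rate_hz: float = 104.0
    modulation_frequency_hz: float = 250.0
    pooled_correlation_o2a_vv: float = -0.57
    pooled_correlation_o2a_nfl: float = -0.53
    within_eye_cv: float = 0.10
    region_asymmetry_sd: float = 0.03
    histology_shrinkage: float = 1.0
    phase_noise_sd_rad: float = 0.005
    n_spheres_per_vein: int = 5
    n_track_frames: int = 10
    track_noise_um: float = 1.0
    pixel_pitch_um: float = 0.5
    edge_width_um: float = 4.0
    gaussian_blur_sigma_um: float = 0.0
    profile_noise_frac: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.calibrations) == 0:
            raise ValueError("at least one group calibration required")
        if self.frame_rate_hz <= 0 or self.modulation_frequency_hz <= 0:
            raise ValueError("frame_rate_hz and modulation_frequency_hz must be > 0")
        for name in ("pooled_correlation_o2a_vv", "pooled_correlation_o2a_nfl"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must be in (-1, 1), got {v!r}")
        if self.n_veins_per_eye < 1 or self.n_arteries_per_eye < 1:
            raise ValueError("need at least one vein and one artery per eye")
        if not 0 <= self.within_eye_cv < 1:
            raise ValueError("within_eye_cv must be in [0, 1)")
        if not 0 < self.histology_shrinkage <= 1:
            raise ValueError("histology_shrinkage must be in (0, 1]")

    def noiseless(self) -> "CohortConfig":
        """Copy with every measurement degradation switched off."""
        return replace(
            self,
            within_eye_cv=0.0,
            region_asymmetry_sd=0.0,
            phase_noise_sd_rad=0.0,
            track_noise_um=0.0,
            profile_noise_frac=0.0,
            gaussian_blur_sigma_um=0.0,
        )


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    return replace(CohortConfig(), rng_seed=seed, **overrides)


@dataclass(frozen=True)
class VesselTruth:
    """One vessel's underlying (noise-free) quantities."""

    vessel_id: str
    vessel_type: str  # 'artery' | 'vein'
    diameter_um: float
    velocity_mm_s: float  # NaN for arteries (velocity measured in veins only)
    po2_mmhg: float
    content_ml_dl: float


@dataclass
class SyntheticAnimal:
    """One synthetic animal: truths plus the raw signals derived from them."""

    animal_id: str
    group: str
    metrics: dict[str, float]
    vessels: list[VesselTruth]
    traces: list[PhosphorescenceTrace]
    tracks: list[MicrosphereTrack]
    profiles: list[CaliberProfile]
    boundaries: dict[str, LayerBoundaries]


# ---------------------------------------------------------------------------
# pooled-correlation calibration


def pooled_moments(
    calibrations: tuple[GroupCalibration, ...],
    xkey: str,
    ykey: str,
    rho_within: float,
) -> tuple[float, float, float]:
    """(var_x, var_y, cov_xy) of the two-group pooled population.

    Groups are weighted by their n; within-group correlation ``rho_within`` is
    assumed common to both groups.  The pooled covariance combines the
    within-group part with the between-group covariance of the means.
    """
    ns = np.array([c.n_animals for c in calibrations], dtype=float)
    w = ns / ns.sum()
    mx = np.array([c.means[xkey] for c in calibrations])
    my = np.array([c.means[ykey] for c in calibrations])
    sx = np.array([c.sds[xkey] for c in calibrations])
    sy = np.array([c.sds[ykey] for c in calibrations])
    mxp = float(w @ mx)
    myp = float(w @ my)
    var_x = float(w @ (sx**2 + (mx - mxp) ** 2))
    var_y = float(w @ (sy**2 + (my - myp) ** 2))
    cov = float(w @ (rho_within * sx * sy + (mx - mxp) * (my - myp)))
    return var_x, var_y, cov


def calibrate_within_correlation(
    calibrations: tuple[GroupCalibration, ...],
    xkey: str,
    ykey: str,
    target_pooled_r: float,
) -> float:
    """Within-group correlation whose pooled two-group correlation hits the target.

    Pooled r is affine in the within-group correlation, so a bracketed root
    find on (-1, 1) either succeeds or the target is unreachable at the given
    group separation (raised as ValueError).
    """

    def gap(rho_w: float) -> float:
        vx, vy, cov = pooled_moments(calibrations, xkey, ykey, rho_w)
        return cov / math.sqrt(vx * vy) - target_pooled_r

    lo, hi = -0.999999, 0.999999
    if gap(lo) * gap(hi) > 0:
        raise ValueError(
            f"pooled correlation {target_pooled_r} for ({xkey}, {ykey}) is not "
            "achievable with any within-group correlation at these calibrations"
        )
    return float(brentq(gap, lo, hi, xtol=1e-12))


def calibrate_o2av_correlation(cal: GroupCalibration) -> float:
    """Within-animal O2A-O2V correlation implied by the group's O2AV spread.

    From ``var(O2AV) = var(O2A) + var(O2V) - 2 rho sd(O2A) sd(O2V)``; a
    calibration without an ``o2av_ml_dl`` entry yields 0 (independence).
    """
    if "o2av_ml_dl" not in cal.sds:
        return 0.0
    sa, sv, sav = cal.sds["o2a_ml_dl"], cal.sds["o2v_ml_dl"], cal.sds["o2av_ml_dl"]
    rho = (sa**2 + sv**2 - sav**2) / (2.0 * sa * sv)
    if not -1.0 < rho < 1.0:
        raise ValueError(
            f"O2AV sd {sav} is inconsistent with the O2A/O2V sds "
            f"(implies correlation {rho:.3f})"
        )
    return float(rho)


def _validate_loadings(loadings: np.ndarray) -> np.ndarray:
    """Check the single-factor structure x_i = l_i * f + sqrt(1-l_i^2) * e_i.

    The first block variable (O2A) is the factor itself (loading 1), so
    ``corr(O2A, x_i) = l_i`` and ``corr(x_i, x_j) = l_i * l_j``.  The implied
    correlation matrix is positive semi-definite exactly when every loading
    lies in (-1, 1); anything else is rejected.
    """
    loadings = np.asarray(loadings, dtype=float)
    if np.any(np.abs(loadings) >= 1.0):
        raise ValueError(
            "within-group correlation matrix is not positive semi-definite: "
            f"factor loadings {loadings} must all lie in (-1, 1)"
        )
    return loadings


# ---------------------------------------------------------------------------
# raw-signal forward models


def synthesize_phase_trace(
    po2_truth_mmhg: float,
    constants: OximetryConstants,
    modulation_frequency_hz: float,
    phase_noise_sd_rad: float = 0.0,
    n_samples: int = 96,
    n_periods: int = 2,
    rng: np.random.Generator | None = None,
    vessel_id: str = "",
) -> PhosphorescenceTrace:
    """Forward model: PO2 -> lifetime -> modulated-emission time trace.

    The noise-free phase is ``arctan(2 pi f tau)`` with ``tau`` from the
    Stern-Volmer relation at ``po2_truth_mmhg``; the modulation depth is the
    physical ``1/sqrt(1 + (2 pi f tau)^2)``.  Phase noise (one Gaussian draw
    per trace) perturbs the phase before the sinusoid is rendered, emulating
    demodulation jitter.
    """
    if po2_truth_mmhg < 0:
        raise ValueError("po2_truth must be >= 0")
    tau = po2_to_lifetime(po2_truth_mmhg, constants)
    w = 2.0 * math.pi * modulation_frequency_hz
    phi = math.atan(w * tau)
    noise_model = "none"
    if phase_noise_sd_rad > 0:
        if rng is None:
            rng = np.random.default_rng()
        phi += phase_noise_sd_rad * rng.standard_normal()
        noise_model = f"gaussian-phase sd={phase_noise_sd_rad}"
    depth = 1.0 / math.sqrt(1.0 + (w * tau) ** 2)
    t = np.arange(n_samples) * (n_periods / modulation_frequency_hz / n_samples)
    signal = 1.0 + depth * np.cos(w * t - phi)
    return PhosphorescenceTrace(
        modulation_frequency_hz=modulation_frequency_hz,
        time_s=t,
        signal=signal,
        noise_model=noise_model,
        vessel_id=vessel_id,
    )


def synthesize_tracks(
    velocity_truth_mm_s: float,
    n_spheres: int,
    frame_rate_hz: float,
    noise_sd_um: float = 0.0,
    n_frames: int = 10,
    direction_rad: float | None = None,
    rng: np.random.Generator | None = None,
    vein_id: str = "vein",
) -> list[MicrosphereTrack]:
    """Microsphere tracks advancing at the true velocity along a straight vessel.

    Consecutive positions step ``velocity / frame_rate`` (in um) along a common
    vessel axis; Gaussian centroid jitter of ``noise_sd_um`` is added to both
    coordinates.  ``n_spheres = 0`` returns an empty list.
    """
    if velocity_truth_mm_s <= 0:
        raise ValueError("velocity_truth must be > 0")
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate must be > 0")
    if n_frames < 2:
        raise ValueError("tracks need at least 2 frames")
    if n_spheres == 0:
        return []
    if rng is None:
        rng = np.random.default_rng()
    if direction_rad is None:
        direction_rad = float(rng.uniform(0.0, 2.0 * math.pi))
    ux, uy = math.cos(direction_rad), math.sin(direction_rad)
    step_um = velocity_truth_mm_s * 1000.0 / frame_rate_hz
    tracks = []
    for k in range(n_spheres):
        x0, y0 = rng.uniform(0.0, 50.0, size=2)
        s = np.arange(n_frames) * step_um
        x = x0 + s * ux
        y = y0 + s * uy
        if noise_sd_um > 0:
            x = x + noise_sd_um * rng.standard_normal(n_frames)
            y = y + noise_sd_um * rng.standard_normal(n_frames)
        tracks.append(
            MicrosphereTrack(
                track_id=f"{vein_id}_sph{k}",
                vein_id=vein_id,
                frame_index=np.arange(n_frames),
                x_um=x,
                y_um=y,
                frame_rate_hz=frame_rate_hz,
            )
        )
    return tracks


def synthesize_caliber_profile(
    diameter_truth_um: float,
    pixel_pitch_um: float = 0.5,
    edge_width_um: float = 4.0,
    gaussian_blur_sigma_um: float = 0.0,
    noise_frac: float = 0.0,
    background: float = 0.1,
    amplitude: float = 1.0,
    rng: np.random.Generator | None = None,
    vessel_id: str = "",
) -> CaliberProfile:
    """1-D angiographic cross-profile whose FWHM equals the true diameter.

    The lumen is a boxcar of width ``diameter_truth_um`` convolved with a
    uniform edge-spread kernel of width ``edge_width_um`` (a trapezoid whose
    half-maximum crossings sit exactly at +/- D/2); an optional extra Gaussian
    blur emulates stronger optical spread, and multiplicative-free Gaussian
    intensity noise of ``noise_frac * amplitude`` is added per pixel.
    """
    if diameter_truth_um < 2 * pixel_pitch_um:
        raise ValueError(
            f"diameter {diameter_truth_um} um below two pixel pitches "
            f"({2 * pixel_pitch_um} um); profile would be degenerate"
        )
    half = diameter_truth_um / 2.0
    extent = diameter_truth_um + edge_width_um + 4.0 * gaussian_blur_sigma_um
    pos = np.arange(-extent, extent + pixel_pitch_um / 2, pixel_pitch_um)
    e = max(edge_width_um, 1e-9)
    # trapezoid: 1 inside, linear ramp of width e centred on each wall
    inten = np.clip((half + e / 2.0 - np.abs(pos)) / e, 0.0, 1.0)
    if gaussian_blur_sigma_um > 0:
        from scipy.ndimage import gaussian_filter1d

        inten = gaussian_filter1d(
            inten, gaussian_blur_sigma_um / pixel_pitch_um, mode="nearest"
        )
    inten = background + amplitude * inten
    if noise_frac > 0:
        if rng is None:
            rng = np.random.default_rng()
        inten = inten + noise_frac * amplitude * rng.standard_normal(pos.size)
    return CaliberProfile(vessel_id=vessel_id, positions_um=pos, intensities=inten)


# ---------------------------------------------------------------------------
# cohort generation


def _recentered_jitter(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Multiplicative within-eye deviations with exactly zero mean.

    Recentring makes the eye-level vessel average equal the per-animal truth
    identically, so within-eye variability never biases eye-level metrics.
    """
    if cv == 0.0 or n == 1:
        return np.zeros(n)
    for _ in range(1000):
        z = rng.standard_normal(n)
        dev = cv * (z - z.mean())
        if np.all(1.0 + dev > 0.05):
            return dev
    raise RuntimeError("could not draw positive within-eye deviations")


def _positive_draw(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    shift: float = 0.0,
    max_tries: int = 1000,
) -> float:
    """``mean + shift + sd * z`` with z redrawn until the value is positive.

    Only the independent residual is redrawn, so a rejected draw never
    perturbs any other metric of the animal; truncation bias is confined to
    metrics whose calibration puts appreciable mass below zero.
    """
    for _ in range(max_tries):
        x = mean + shift + sd * rng.standard_normal()
        if x > 0:
            return x
    raise RuntimeError("rejection sampling failed; SDs too large relative to means")


def _draw_animal_metrics(
    rng: np.random.Generator,
    cal: GroupCalibration,
    loadings: np.ndarray,
    max_tries: int = 1000,
) -> dict[str, float]:
    """One animal's truth metrics; negative draws rejected and redrawn."""
    factor_key = CORRELATED_BLOCK[0]
    for _ in range(max_tries):
        f = rng.standard_normal()
        o2a = cal.means[factor_key] + cal.sds[factor_key] * f
        if o2a > 0:
            break
    else:
        raise RuntimeError("rejection sampling failed for the factor variable")
    vals = {factor_key: o2a}
    for key, lam in zip(CORRELATED_BLOCK[1:], loadings):
        resid_sd = math.sqrt(1.0 - lam * lam)
        vals[key] = _positive_draw(
            rng,
            cal.means[key],
            cal.sds[key] * resid_sd,
            shift=cal.sds[key] * lam * f,
            max_tries=max_tries,
        )
    for key in DRAWN_METRICS:
        if key in CORRELATED_BLOCK:
            continue
        vals[key] = _positive_draw(rng, cal.means[key], cal.sds[key],
                                   max_tries=max_tries)
    return vals


def _build_animal(
    rng: np.random.Generator,
    animal_id: str,
    group: str,
    drawn: dict[str, float],
    config: CohortConfig,
    raw_signals: bool = True,
) -> SyntheticAnimal:
    cv = config.within_eye_cv
    n_a, n_v = config.n_arteries_per_eye, config.n_veins_per_eye

    # per-vessel truths centred exactly on the per-animal values
    art_d = drawn["d_a_um"] * (1.0 + _recentered_jitter(rng, n_a, cv))
    art_c = drawn["o2a_ml_dl"] * (1.0 + _recentered_jitter(rng, n_a, cv))
    vein_d = drawn["d_v_um"] * (1.0 + _recentered_jitter(rng, n_v, cv))
    vein_v = drawn["v_v_mm_s"] * (1.0 + _recentered_jitter(rng, n_v, cv))
    vein_c = drawn["o2v_ml_dl"] * (1.0 + _recentered_jitter(rng, n_v, cv))

    vessels: list[VesselTruth] = []
    traces: list[PhosphorescenceTrace] = []
    tracks: list[MicrosphereTrack] = []
    profiles: list[CaliberProfile] = []

    def add_vessel(vid: str, vtype: str, d: float, v: float, content: float) -> None:
        po2 = content_to_po2(content, config.oximetry)
        vessels.append(
            VesselTruth(
                vessel_id=vid,
                vessel_type=vtype,
                diameter_um=d,
                velocity_mm_s=v,
                po2_mmhg=po2,
                content_ml_dl=content,
            )
        )
        if not raw_signals:
            return
        traces.append(
            synthesize_phase_trace(
                po2,
                config.oximetry,
                config.modulation_frequency_hz,
                phase_noise_sd_rad=config.phase_noise_sd_rad,
                rng=rng,
                vessel_id=vid,
            )
        )
        profiles.append(
            synthesize_caliber_profile(
                d,
                pixel_pitch_um=config.pixel_pitch_um,
                edge_width_um=config.edge_width_um,
                gaussian_blur_sigma_um=config.gaussian_blur_sigma_um,
                noise_frac=config.profile_noise_frac,
                rng=rng,
                vessel_id=vid,
            )
        )

    for i in range(n_a):
        add_vessel(f"{animal_id}_art{i}", "artery", float(art_d[i]), math.nan,
                   float(art_c[i]))
    for i in range(n_v):
        vid = f"{animal_id}_vein{i}"
        add_vessel(vid, "vein", float(vein_d[i]), float(vein_v[i]), float(vein_c[i]))
        if not raw_signals:
            continue
        tracks.extend(
            synthesize_tracks(
                float(vein_v[i]),
                config.n_spheres_per_vein,
                config.frame_rate_hz,
                noise_sd_um=config.track_noise_um,
                n_frames=config.n_track_frames,
                rng=rng,
                vein_id=vid,
            )
        )

    # derived flow/oxygen truths from the vessel truths (not drawn)
    flows = [vein_flow(float(v), float(d)) for v, d in zip(vein_v, vein_d)]
    trbf = total_flow(flows)
    o2av = drawn["o2a_ml_dl"] - drawn["o2v_ml_dl"]
    do2, mo2, oef = delivery_metabolism(trbf, drawn["o2a_ml_dl"], o2av)

    # layer boundaries: regional thicknesses symmetric about the truth so the
    # nasal/temporal average reproduces it exactly
    shrink = config.histology_shrinkage
    layer_truth = np.array([drawn[k] for k in LAYER_SEQUENCE]) * shrink
    asym = (
        rng.normal(0.0, config.region_asymmetry_sd, size=layer_truth.size)
        if config.region_asymmetry_sd > 0
        else np.zeros(layer_truth.size)
    )
    asym = np.clip(asym, -0.45, 0.45)
    boundaries = {}
    for region, sign in (("nasal", 1.0), ("temporal", -1.0)):
        t_region = layer_truth * (1.0 + sign * asym)
        depths = np.concatenate([[0.0], np.cumsum(t_region)])
        boundaries[region] = LayerBoundaries(region=region, depths_um=depths)

    metrics = dict(drawn)
    for k in LAYER_SEQUENCE:
        metrics[k] = float(layer_truth[list(LAYER_SEQUENCE).index(k)])
    metrics.update(
        trbf_ul_min=trbf,
        o2av_ml_dl=o2av,
        do2_nl_min=do2,
        mo2_nl_min=mo2,
        oef=oef,
    )
    return SyntheticAnimal(
        animal_id=animal_id,
        group=group,
        metrics=metrics,
        vessels=vessels,
        traces=traces,
        tracks=tracks,
        profiles=profiles,
        boundaries=boundaries,
    )


def generate_cohort(
    config: CohortConfig, raw_signals: bool = True
) -> list[SyntheticAnimal]:
    """Generate the full two-group cohort described by ``config``.

    Deterministic given ``config.rng_seed``; each animal consumes its own
    spawned random stream so cohorts of different sizes share their leading
    animals' draws.  ``raw_signals=False`` skips trace/track/profile
    synthesis (truth tables and boundaries only) without changing any drawn
    truth value — useful for large calibration-fidelity checks.
    """
    rho_vv = calibrate_within_correlation(
        config.calibrations, "o2a_ml_dl", "v_v_mm_s", config.pooled_correlation_o2a_vv
    )
    rho_nfl = calibrate_within_correlation(
        config.calibrations, "o2a_ml_dl", "nfl_rgcl", config.pooled_correlation_o2a_nfl
    )
    rho_o2v = calibrate_o2av_correlation(config.calibrations[0])
    loadings = _validate_loadings([rho_vv, rho_nfl, rho_o2v])

    root = np.random.SeedSequence(config.rng_seed)
    animals: list[SyntheticAnimal] = []
    # one spawned stream per animal: cohorts of different sizes share their
    # leading animals' draws, and animals are independent by construction
    children = root.spawn(sum(c.n_animals for c in config.calibrations))
    k = 0
    for cal in config.calibrations:
        for i in range(cal.n_animals):
            rng = np.random.default_rng(children[k])
            k += 1
            animal_id = f"{cal.group}_{i:03d}"
            drawn = _draw_animal_metrics(rng, cal, loadings)
            animals.append(
                _build_animal(rng, animal_id, cal.group, drawn, config, raw_signals)
            )
    return animals


def cohort_truth_table(animals: list[SyntheticAnimal]) -> pd.DataFrame:
    """Per-animal truth metrics as a tidy DataFrame (one row per animal)."""
    rows = []
    for a in animals:
        row = {"animal_id": a.animal_id, "group": a.group}
        row.update(a.metrics)
        rows.append(row)
    return pd.DataFrame(rows)
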