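"""End-to-end orchestration: generate -> measure -> aggregate -> report.

The pipeline mirrors the study workflow: synthesize (or load) a cohort,
run every raw signal through the measurement modules (lifetime fit ->
Stern-Volmer -> dissociation curve for oximetry; track regression for
velocity; FWHM for caliber; boundary differencing for morphometry),
aggregate per-vessel results into per-eye metrics, and produce the cohort
statistics report.  All interchange is CSV plus a JSON sidecar recording the
configuration and seed; re-running with the same config and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .metrics import eye_metrics_from_vessels
from .morphometry import layer_thicknesses, region_average
from .oximetry import (
    OximetryConstants,
    estimate_lifetime,
    lifetime_to_po2,
    oxygen_content,
    po2_to_so2,
)
from .stats import build_report
from .synthgen import (
    CohortConfig,
    SyntheticAnimal,
    cohort_truth_table,
    generate_cohort,
)
from .velocimetry import profile_diameter, vein_velocity

__all__ = [
    "measure_vessels",
    "measure_thickness",
    "measure_cohort",
    "run_pipeline",
    "validate_config",
    "load_config",
]

_STAGES = ("truth", "vessels", "eyes", "thickness", "report_json", "report_txt")


# ---------------------------------------------------------------------------
# measurement stages


def measure_vessels(
    animal: SyntheticAnimal, constants: OximetryConstants
) -> pd.DataFrame:
    """Per-vessel measured quantities for one animal.

    Oximetry: phase -> lifetime -> PO2 -> SO2 -> content per vessel trace.
    Velocimetry: per-vein mean of per-track regression speeds.
    Caliber: FWHM of each vessel's cross-profile.
    """
    by_vein: dict[str, list] = {}
    for tr in animal.tracks:
        by_vein.setdefault(tr.vein_id, []).append(tr)
    trace_by_vessel = {t.vessel_id: t for t in animal.traces}
    profile_by_vessel = {p.vessel_id: p for p in animal.profiles}

    rows = []
    for vessel in animal.vessels:
        vid = vessel.vessel_id
        tau = estimate_lifetime(trace_by_vessel[vid])
        po2 = lifetime_to_po2(tau, constants)
        d = profile_diameter(profile_by_vessel[vid])
        v = (
            vein_velocity(by_vein.get(vid, []))
            if vessel.vessel_type == "vein"
            else math.nan
        )
        rows.append(
            {
                "animal_id": animal.animal_id,
                "group": animal.group,
                "vessel_id": vid,
                "vessel_type": vessel.vessel_type,
                "diameter_um": d,
                "velocity_mm_s": v,
                "lifetime_s": tau,
                "po2_mmhg": po2,
                "so2": po2_to_so2(po2, constants),
                "content_ml_dl": oxygen_content(po2, constants),
            }
        )
    return pd.DataFrame(rows)


def measure_thickness(animal: SyntheticAnimal) -> dict[str, float]:
    """Region-averaged layer thicknesses from the animal's boundary lists."""
    nasal = layer_thicknesses(animal.boundaries["nasal"])
    temporal = layer_thicknesses(animal.boundaries["temporal"])
    return region_average(nasal, temporal).as_dict()


def measure_cohort(
    animals: list[SyntheticAnimal], config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full measurement chain over a cohort.

    Returns
    -------
    vessels : DataFrame
        One row per vessel (diameter, velocity, lifetime, PO2, SO2, content).
    eyes : DataFrame
        One row per animal: measured eye-level hemodynamic/oxygen metrics,
        measured layer thicknesses, and the truth-level metrics that have no
        raw signal (OCT TRT, protein levels), ready for the stats stage.
    thickness : DataFrame
        One row per animal with the region-averaged thickness record.
    """
    vessel_frames = []
    eye_rows = []
    thickness_rows = []
    for animal in animals:
        vdf = measure_vessels(animal, config.oximetry)
        vessel_frames.append(vdf)
        eye = eye_metrics_from_vessels(vdf).as_dict()
        thick = measure_thickness(animal)
        thickness_rows.append(
            {"animal_id": animal.animal_id, "group": animal.group, **thick}
        )
        row = {"animal_id": animal.animal_id, "group": animal.group}
        row.update(eye)
        row.update(thick)
        for key in (
            "trt_oct",
            "abeta42_retina",
            "abeta40_retina",
            "abeta42_brain",
            "abeta40_brain",
        ):
            row[key] = animal.metrics[key]
        eye_rows.append(row)
    return (
        pd.concat(vessel_frames, ignore_index=True),
        pd.DataFrame(eye_rows),
        pd.DataFrame(thickness_rows),
    )


# ---------------------------------------------------------------------------
# configuration files


def _config_to_dict(config: CohortConfig, alpha: float) -> dict:
    d = dataclasses.asdict(config)
    d["calibrations"] = [dataclasses.asdict(c) for c in config.calibrations]
    d["oximetry"] = dataclasses.asdict(config.oximetry)
    return {"cohort": d, "alpha": alpha}


_SCALAR_KEYS = {
    f.name for f in dataclasses.fields(CohortConfig)
} - {"calibrations", "oximetry"}


def validate_config(payload: dict) -> tuple[CohortConfig, float]:
    """Build a validated (CohortConfig, alpha) pair from a parsed mapping.

    Unknown keys raise (strict mode) so that typos in unit-suffixed names
    (``tau0_s``, ``frame_rate_hz``, ...) surface immediately instead of
    silently falling back to defaults.
    """
    if not isinstance(payload, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(payload) - {"cohort", "alpha"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    alpha = float(payload.get("alpha", 0.05))
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    cohort = dict(payload.get("cohort", {}))
    unknown = set(cohort) - _SCALAR_KEYS - {"calibrations", "oximetry"}
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    kwargs: dict = {k: cohort[k] for k in _SCALAR_KEYS if k in cohort}
    if "oximetry" in cohort:
        ox = cohort["oximetry"]
        valid = {f.name for f in dataclasses.fields(OximetryConstants)}
        unknown = set(ox) - valid
        if unknown:
            raise ValueError(f"unknown oximetry keys: {sorted(unknown)}")
        kwargs["oximetry"] = OximetryConstants(**ox)
    if "calibrations" in cohort:
        from .synthgen import GroupCalibration

        kwargs["calibrations"] = tuple(
            GroupCalibration(**c) for c in cohort["calibrations"]
        )
    return CohortConfig(**kwargs), alpha


def load_config(path: str | Path) -> tuple[CohortConfig, float]:
    """Parse and validate a YAML pipeline configuration file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return validate_config(payload)


# ---------------------------------------------------------------------------
# full run


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format="%.10g")
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: CohortConfig, outdir: str | Path, alpha: float = 0.05
) -> dict:
    """Execute generate -> measure -> metrics -> stats and write all outputs.

    Writes per-stage CSVs, ``report.json``/``report.txt``, and a
    ``manifest.json`` recording the config, seed, package version and the
    SHA-256 of every output.  Returns the manifest dict.  Any stage failure
    removes partial outputs before re-raising.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        animals = generate_cohort(config)
        truth = cohort_truth_table(animals)
        vessels, eyes, thickness = measure_cohort(animals, config)
        report = build_report(eyes, alpha=alpha)

        hashes = {}
        for name, df in (
            ("truth", truth),
            ("vessels", vessels),
            ("eyes", eyes),
            ("thickness", thickness),
        ):
            path = outdir / f"{name}.csv"
            hashes[name] = _write_csv(df, path)
            written.append(path)
        for name, text in (
            ("report_json", report.to_json()),
            ("report_txt", report.to_text() + "\n"),
        ):
            path = outdir / ("report.json" if name == "report_json" else "report.txt")
            path.write_text(text)
            hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()
            written.append(path)

        config_dict = _config_to_dict(config, alpha)
        manifest = {
            "version": __version__,
            "seed": config.rng_seed,
            "alpha": alpha,
            "config_sha256": hashlib.sha256(
                json.dumps(config_dict, sort_keys=True).encode()
            ).hexdigest(),
            "stages": list(_STAGES),
            "outputs": {k: hashes[k] for k in _STAGES},
            "n_animals": len(animals),
        }
        sidecar = outdir / "config.json"
        sidecar.write_text(json.dumps(config_dict, indent=2, sort_keys=True))
        written.append(sidecar)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:  # partial-output cleanup, stage-tagged error
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed: {exc}") from exc
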