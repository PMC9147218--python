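"""Run configuration and the end-to-end validation pipeline.

Glues the simulator, 2D measurement and agreement layers into the
simulate -> measure -> agree -> report experiment, with a YAML run
configuration validated up front (field-path error messages, nothing written
on an invalid config) and deterministic outputs under a mandatory seed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import agreement, simulator
from .fluoro2d import RadiographPair, measure_cup, read_landmarks_2d, write_landmarks_2d
from .simulator import AcquisitionGeometry, NoiseModel, SimulatedStudy, StudyDesign

__all__ = [
    "ConfigError",
    "DataError",
    "RunConfig",
    "load_config",
    "run_simulate",
    "run_measure",
    "run_agree",
    "run_validate",
]

_PAIR_FILE_RE = re.compile(
    r"pair_(?P<pose>[A-Za-z0-9]+)_(?P<condition>[A-Za-z0-9_]+?)_r(?P<rater>\d+)s(?P<session>\d+)\.csv$"
)


class ConfigError(ValueError):
    """Invalid run configuration (reported with the offending field path)."""


class DataError(ValueError):
    """Invalid or inconsistent data files."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one validation run needs, resolved and validated."""

    design: StudyDesign = field(default_factory=simulator.default_design)
    geometry: AcquisitionGeometry = field(default_factory=simulator.default_geometry)
    noise: dict[str, NoiseModel] = field(default_factory=simulator.default_noise_models)
    n_boot: int = 2000
    seed: int = 0


def _build(cls, data: Mapping[str, Any], path: str):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown field(s) {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("inclination_levels", "anteversion_levels", "conditions"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    for key in ("beam_axis", "detector_u", "detector_v"):
        if key in kwargs:
            kwargs[key] = np.asarray(kwargs[key], dtype=float)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(source: str | Path | Mapping[str, Any] | None,
                seed: int | None = None) -> RunConfig:
    """Load and validate a run configuration from YAML (or a mapping).

    ``seed`` overrides the config seed; one of the two must be present —
    reproducibility is not optional.
    """
    if source is None:
        raw: dict[str, Any] = {}
    elif isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{source}: config root must be a mapping")

    known = {"design", "geometry", "noise", "n_boot", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"config: unknown section(s) {sorted(unknown)}")

    design = _build(StudyDesign, raw.get("design", {}), "design")
    geometry = _build(AcquisitionGeometry, raw.get("geometry", {}), "geometry")
    noise = simulator.default_noise_models()
    for cond, spec in (raw.get("noise") or {}).items():
        noise[cond] = _build(NoiseModel, spec or {}, f"noise.{cond}")
    n_boot = raw.get("n_boot", 2000)
    if not isinstance(n_boot, int) or n_boot < 100:
        raise ConfigError("n_boot: must be an integer >= 100")

    final_seed = seed if seed is not None else raw.get("seed")
    if final_seed is None:
        raise ConfigError("seed: a master seed is required (config key or --seed)")
    missing = [c for c in design.conditions if c not in noise]
    if missing:
        raise ConfigError(f"noise: no model for condition(s) {missing}")
    return RunConfig(design=design, geometry=geometry, noise=noise,
                     n_boot=int(n_boot), seed=int(final_seed))


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def run_simulate(config: RunConfig, out_dir: str | Path) -> SimulatedStudy:
    """Simulate the study and write landmark files plus the truth table."""
    study = simulator.simulate_study(
        design=config.design, geometry=config.geometry,
        noise_per_condition=config.noise, master_seed=config.seed,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pair in study.pairs:
        name = f"pair_{pair.pose_id}_{pair.condition}_r{pair.rater}s{pair.session}.csv"
        write_landmarks_2d(out / name, pair)
    _write_table(study.truth, out / "truth.csv")
    return study


def run_measure(landmark_dir: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Measure every landmark pair file in a directory.

    Row-level failures (degenerate landmarks, non-elliptical rims) are
    collected and reported; the run continues past them.
    """
    paths = sorted(Path(landmark_dir).glob("pair_*.csv"))
    if not paths:
        raise DataError(f"{landmark_dir}: no pair_*.csv landmark files found")
    rows: list[dict] = []
    errors: list[str] = []
    for path in paths:
        m = _PAIR_FILE_RE.search(path.name)
        if m is None:
            errors.append(f"{path.name}: unrecognized file name pattern")
            continue
        try:
            full_pelvis, cup_view = read_landmarks_2d(path)
            pair = RadiographPair(
                full_pelvis=full_pelvis, cup_view=cup_view,
                pose_id=m["pose"], condition=m["condition"],
                rater=int(m["rater"]), session=int(m["session"]),
            )
            meas = measure_cup(pair)
        except (ValueError, KeyError) as exc:
            errors.append(f"{path.name}: {exc}")
            continue
        for angle, value in (("inclination", meas.pose.inclination),
                             ("anteversion", meas.pose.anteversion)):
            rows.append({
                "placement_id": f"{m['pose']}-{m['condition']}",
                "pose_id": m["pose"],
                "condition": m["condition"],
                "rater": int(m["rater"]),
                "session": int(m["session"]),
                "method": "fluoro2d",
                "angle": angle,
                "value": value,
                "ri": meas.radiographic.ri,
                "ra": meas.radiographic.ra,
                "fit_rms": meas.fit_rms,
                "flags": ";".join(meas.flags),
            })
    if not rows:
        raise DataError("no pair measured successfully; first error: "
                        + (errors[0] if errors else "none"))
    return pd.DataFrame(rows), errors


def run_agree(measurements: pd.DataFrame, truth: pd.DataFrame | None,
              config: RunConfig) -> pd.DataFrame:
    """All three agreement analyses stacked into one report table."""
    analyses = ["interrater", "intrarater", "intermethod"]
    parts = []
    for analysis in analyses:
        if analysis == "intermethod" and truth is None:
            continue
        try:
            parts.append(agreement.agreement_report(
                measurements, truth=truth, analysis=analysis,
                n_boot=config.n_boot, seed=config.seed,
            ))
        except ValueError as exc:
            raise DataError(str(exc)) from exc
    return pd.concat(parts, ignore_index=True)


def run_validate(config: RunConfig, out_dir: str | Path) -> dict:
    """End-to-end experiment: simulate, measure, agree, write all artifacts.

    Returns the machine-readable summary that is also written as JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = run_simulate(config, out / "landmarks")
    _write_table(study.measurements, out / "measurements.csv")
    report = run_agree(study.measurements, study.truth, config)
    _write_table(report, out / "agreement_report.csv")
    (out / "agreement_report.txt").write_text(
        agreement.render_report(report) + "\n"
    )
    summary = {
        "seed": config.seed,
        "n_pairs": len(study.pairs),
        "n_measurement_rows": int(len(study.measurements)),
        "analyses": {},
    }
    for analysis, part in report.groupby("analysis", sort=False):
        half_widths = ((part["loa_high"] - part["loa_low"]) / 2.0)
        summary["analyses"][analysis] = {
            "min_icc": None if part["icc"].isna().all() else float(part["icc"].min()),
            "max_abs_bias": float(part["bias"].abs().max()),
            "max_loa_half_width": float(half_widths.max()),
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
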