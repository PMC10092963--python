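"""File formats, configuration and the joint two-channel report.

Traces travel as plain CSV (inspectable, small: at most a few hundred
thousand samples), configuration as YAML or JSON validated by pydantic
models with unknown keys rejected, and reports as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .densitometry import (
    DensitometryCalibration,
    IntensityTrace,
    SegmentationParams,
    analyze_clearance,
)
from .dls import OpticalGeometry, SpeckleTrace, aggregate_replicates
from .errors import ConfigError, HepaflowError, TraceParseError

logger = logging.getLogger(__name__)

__all__ = [
    "read_trace",
    "write_trace",
    "RunConfig",
    "load_config",
    "run_joint_report",
]

#: Canonical units of every configurable physical quantity.  A config may
#: declare units explicitly; any other string is a load-time error.
CANONICAL_UNITS = {
    "calibration": {
        "epsilon": "L/(mg*cm)",
        "path_z": "cm",
        "u0": "V",
        "delta_u": "V",
        "sensitivity_s": "A/W",
        "load_r": "Ohm",
    },
    "geometry": {
        "wavelength": "nm",
        "distance_l": "cm",
        "beam_waist": "mm",
        "rho": "cm",
    },
    "acquisition": {
        "densitometry_rate": "1/min",
        "speckle_rate": "Hz",
        "record_length": "s",
    },
}


def _check_units(block: str, units: dict[str, str]) -> None:
    canon = CANONICAL_UNITS.get(block, {})
    for key, unit in units.items():
        if key not in canon:
            raise ValueError(f"unknown quantity '{block}.units.{key}'")
        if unit != canon[key]:
            raise ValueError(
                f"unit mismatch at '{block}.units.{key}': got '{unit}', expected '{canon[key]}'"
            )


class CalibrationConfig(BaseModel):
    """Densitometry calibration block (see :class:`DensitometryCalibration`)."""

    model_config = ConfigDict(extra="forbid")

    epsilon: float = Field(gt=0, description="decadic extinction coefficient, L/(mg*cm)")
    path_z: float = Field(gt=0, description="optical path length, cm")
    u0: float = Field(default=1.0, gt=0, description="zero-dye reference voltage, V")
    delta_u: float = Field(default=0.0, ge=0, description="voltage noise SD, V")
    sensitivity_s: float = Field(default=1.0, gt=0, description="photodiode sensitivity, A/W")
    load_r: float = Field(default=1.0, gt=0, description="load resistance, Ohm")
    units: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _units_ok(self) -> "CalibrationConfig":
        _check_units("calibration", self.units)
        return self

    def to_calibration(self) -> DensitometryCalibration:
        return DensitometryCalibration(
            epsilon=self.epsilon,
            path_z=self.path_z,
            u0=self.u0,
            delta_u=self.delta_u,
            sensitivity_s=self.sensitivity_s,
            load_r=self.load_r,
        )


class GeometryConfig(BaseModel):
    """DLS optical-scheme block (see :class:`OpticalGeometry`).

    ``sigma`` may be supplied directly; otherwise it is derived from the
    wavefront curvature radius ``rho_cm`` as sigma = l/rho + 1.
    """

    model_config = ConfigDict(extra="forbid")

    wavelength_nm: float = Field(default=650.0, gt=0)
    distance_l_cm: float = Field(default=7.5, gt=0)
    beam_waist_mm: float = Field(default=0.5, gt=0)
    sigma: float | None = Field(default=None, ge=1)
    rho_cm: float | None = Field(default=None, gt=0)
    units: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _consistent(self) -> "GeometryConfig":
        if self.sigma is not None and self.rho_cm is not None:
            raise ValueError("give either 'sigma' or 'rho_cm', not both")
        _check_units("geometry", self.units)
        return self

    def to_geometry(self) -> OpticalGeometry:
        if self.rho_cm is not None:
            return OpticalGeometry.from_rho(
                self.wavelength_nm, self.distance_l_cm, self.beam_waist_mm, self.rho_cm
            )
        return OpticalGeometry(
            self.wavelength_nm, self.distance_l_cm, self.beam_waist_mm, self.sigma or 1.0
        )


class AcquisitionConfig(BaseModel):
    """Per-channel sampling parameters."""

    model_config = ConfigDict(extra="forbid")

    densitometry_rate_per_min: float = Field(default=60.0, gt=0)
    speckle_rate_hz: float = Field(default=2.0e6, gt=0)
    record_length_s: float = Field(default=0.2, gt=0)
    n_replicates: int = Field(default=10, ge=1)
    units: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _units_ok(self) -> "AcquisitionConfig":
        _check_units("acquisition", self.units)
        return self


class SegmentationConfig(BaseModel):
    """Thresholds of the clearance-trace segmentation."""

    model_config = ConfigDict(extra="forbid")

    k_threshold: float = Field(default=5.0, gt=0)
    sustain: int = Field(default=5, ge=1)
    guard: int = Field(default=5, ge=0)
    baseline_init: int = Field(default=20, ge=5)
    smooth_window: int = Field(default=5, ge=1)
    anchor_frac: float = Field(default=0.5, gt=0, le=1)
    t1_sigma_mult: float = Field(default=5.0, gt=0)
    t1_tol_floor: float = Field(default=1e-9, ge=0)

    def to_params(self) -> SegmentationParams:
        return SegmentationParams(**self.model_dump())


class OutputConfig(BaseModel):
    """Report destination and verbosity."""

    model_config = ConfigDict(extra="forbid")

    report_path: str | None = None
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"


class RunConfig(BaseModel):
    """Top-level configuration tying all blocks together."""

    model_config = ConfigDict(extra="forbid")

    calibration: CalibrationConfig
    geometry: GeometryConfig = GeometryConfig()
    acquisition: AcquisitionConfig = AcquisitionConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    output: OutputConfig = OutputConfig()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON configuration file.

    Unknown keys and unit mismatches are rejected with the offending path
    named in the error message.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"  at '{'.'.join(str(p) for p in err['loc'])}': {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(f"invalid config {path}:\n" + "\n".join(lines)) from exc


def _read_csv(path: Path, required: tuple[str, str]) -> pd.DataFrame:
    if not path.exists():
        raise TraceParseError(f"trace file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV structure
        raise TraceParseError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceParseError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    for col in required:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header row, one for 1-based line numbers
            raise TraceParseError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} in column "
                f"'{col}' at line {bad[0] + 2}"
            )
        nan_rows = df.index[numeric.isna()]
        if len(nan_rows):
            raise TraceParseError(f"{path}: empty cell in column '{col}' at line {nan_rows[0] + 2}")
        df[col] = numeric
    return df


def read_trace(
    path: str | Path,
    kind: Literal["densitometry", "speckle"],
    sampling_rate: float | None = None,
) -> IntensityTrace | SpeckleTrace:
    """Read a delimited-text trace of the given channel kind.

    Densitometry files carry columns ``time`` (minutes) and ``voltage``
    (V); speckle files carry ``time_s`` and ``intensity``, with the
    sampling rate taken from the time column unless given explicitly.
    """
    path = Path(path)
    if kind == "densitometry":
        df = _read_csv(path, ("time", "voltage"))
        try:
            return IntensityTrace(
                times=df["time"].to_numpy(),
                voltages=df["voltage"].to_numpy(),
                meta={"source": str(path)},
            )
        except ValueError as exc:
            raise TraceParseError(f"{path}: {exc}") from exc
    if kind == "speckle":
        df = _read_csv(path, ("time_s", "intensity"))
        if sampling_rate is None:
            dt = np.diff(df["time_s"].to_numpy())
            if len(dt) == 0 or np.any(dt <= 0):
                raise TraceParseError(f"{path}: time_s must be strictly increasing")
            sampling_rate = 1.0 / float(np.median(dt))
        try:
            return SpeckleTrace(
                samples=df["intensity"].to_numpy(),
                sampling_rate=sampling_rate,
                meta={"source": str(path)},
            )
        except ValueError as exc:
            raise TraceParseError(f"{path}: {exc}") from exc
    raise ValueError(f"unknown trace kind {kind!r}")


def write_trace(trace: IntensityTrace | SpeckleTrace, path: str | Path) -> None:
    """Write a trace as CSV with full float precision (round-trip safe)."""
    path = Path(path)
    if isinstance(trace, IntensityTrace):
        df = pd.DataFrame({"time": trace.times, "voltage": trace.voltages})
    else:
        t = np.arange(len(trace)) / trace.sampling_rate
        df = pd.DataFrame({"time_s": t, "intensity": trace.samples})
    df.to_csv(path, index=False, float_format="%.17g")


def run_joint_report(
    clearance_trace: IntensityTrace | None,
    speckle_traces: list[SpeckleTrace] | None,
    config: RunConfig,
    seed: int | None = None,
) -> dict:
    """Joint two-channel report: PDR and flow velocity side by side.

    The two estimates are only juxtaposed; no combined index is computed
    (the statistical link between hepatic clearance and peripheral
    microcirculation is an open question).  A failing channel is reported
    with its cause while the other is still emitted.
    """
    report: dict = {
        "software": {"name": "hepaflow", "version": __version__},
        "seed": seed,
        "config": config.model_dump(),
        "densitometry": {"status": "missing"},
        "dls": {"status": "missing"},
    }
    if clearance_trace is not None:
        try:
            res, seg = analyze_clearance(
                clearance_trace,
                config.calibration.to_calibration(),
                config.segmentation.to_params(),
            )
            report["densitometry"] = {
                "status": "ok",
                "pdr_pct_per_min": res.pdr,
                "c1_mg_per_l": res.c1,
                "intercept_pct": res.intercept,
                "r_squared": res.r_squared,
                "residual_sd_pct": res.residual_sd,
                "n_points": res.n_points,
                "n_excluded": res.n_excluded,
                "segmentation": {
                    "baseline_window": list(seg.baseline_window),
                    "t0_min": seg.t0,
                    "peak_time_min": seg.peak_time,
                    "t1_min": seg.t1,
                    "elimination_window": list(seg.elimination_window),
                    "u0_v": seg.u0,
                },
            }
        except (HepaflowError, ValueError) as exc:
            logger.error("densitometry channel failed: %s", exc)
            report["densitometry"] = {"status": "failed", "cause": str(exc)}
    if speckle_traces:
        try:
            est = aggregate_replicates(speckle_traces, config.geometry.to_geometry())
            report["dls"] = {
                "status": "ok",
                "mean_velocity_mm_per_s": est.mean_velocity,
                "sd_velocity_mm_per_s": est.sd_velocity,
                "n_replicates": est.n_replicates,
                "n_failed": est.n_failed,
                "velocities_mm_per_s": list(est.velocities),
                "tau_c_s": list(est.tau_c_values),
            }
        except (HepaflowError, ValueError) as exc:
            logger.error("DLS channel failed: %s", exc)
            report["dls"] = {"status": "failed", "cause": str(exc)}
    return report
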