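"""File formats, configuration schema, and the end-to-end pipeline runner.

Time series travel as headered CSV (units encoded in the column names,
e.g. ``time_s``, ``sto2_frac``); 3-D grids as HDF5 (see
:meth:`nirsox.montecarlo.FluenceGrid.save`). The run configuration is a
schema-validated YAML/JSON document; unknown keys are rejected with a
message naming the offending field. All randomness flows from the single
configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import __version__
from .dsp import AcquisitionConfig, VitalsResult, demultiplex, vitals_from_frames
from .inversion import ChannelCalibration, PipelineConfig, StO2Result, sto2_pipeline
from .optics import ChromophoreSpectra, ProbeGeometry, ScatteringModel

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "read_raw_stream",
    "write_raw_stream",
    "run_pipeline",
    "PipelineBundle",
]

log = logging.getLogger("nirsox")


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySection(_Section):
    rho1_mm: float = 4.0
    rho2_mm: float = 7.0

    @model_validator(mode="after")
    def _ordered(self):
        if not 0 < self.rho1_mm < self.rho2_mm:
            raise ValueError("rho2_mm must exceed rho1_mm (both positive)")
        return self


class SpectraSection(_Section):
    eps_hb_660: float = 0.81
    eps_hbo2_660: float = 0.08
    eps_hb_850: float = 0.19
    eps_hbo2_850: float = 0.25


class ScatteringSection(_Section):
    k_scale: float = 13.38
    h_660_per_nm: float = 6.9e-4
    h_850_per_nm: float = 5.9e-4


class AcquisitionSection(_Section):
    frame_rate_hz: float = 50.0
    duty: float = 0.10
    adc_rate_hz: float = 100.0
    slot_order: Tuple[str, ...] = ("red", "nir")


class CalibrationSection(_Section):
    gain_pd1: float = 1.0
    gain_pd2: float = 4.3
    dark_pd1: float = 0.0
    dark_pd2: float = 0.0


class DspSection(_Section):
    dc_cutoff_hz: float = 0.2
    dc_order: int = 2
    smooth_window_s: float = 5.0
    rho_mode: Literal["log_mean", "midpoint"] = "log_mean"
    vitals_window_s: float = 30.0
    vitals_step_s: float = 10.0
    spo2_cal_a: float = 1.10
    spo2_cal_b: float = 0.25
    confidence_floor: float = 10.0


class SimulatorSection(_Section):
    protocol_scale: float = 0.02
    noise_sd_rel: float = 0.01
    noise_drift_rel: float = 0.01
    noise_drift_period_s: float = 60.0
    ambient: float = 0.0
    source_scale: float = 1.0e4


class RunConfig(_Section):
    """Top-level validated configuration for pipeline and simulator runs."""

    geometry: GeometrySection = GeometrySection()
    spectra: SpectraSection = SpectraSection()
    scattering: ScatteringSection = ScatteringSection()
    acquisition: AcquisitionSection = AcquisitionSection()
    calibration: CalibrationSection = CalibrationSection()
    dsp: DspSection = DspSection()
    simulator: SimulatorSection = SimulatorSection()
    seed: int = 0
    log_level: str = "INFO"

    # -- converters to the domain objects ------------------------------
    def probe_geometry(self) -> ProbeGeometry:
        return ProbeGeometry(self.geometry.rho1_mm, self.geometry.rho2_mm)

    def chromophore_spectra(self) -> ChromophoreSpectra:
        s = self.spectra
        return ChromophoreSpectra(
            {
                ("Hb", 660.0): s.eps_hb_660,
                ("HbO2", 660.0): s.eps_hbo2_660,
                ("Hb", 850.0): s.eps_hb_850,
                ("HbO2", 850.0): s.eps_hbo2_850,
            }
        )

    def scattering_model(self) -> ScatteringModel:
        return ScatteringModel(
            k_scale=self.scattering.k_scale,
            h={660.0: self.scattering.h_660_per_nm, 850.0: self.scattering.h_850_per_nm},
        )

    def acquisition_config(self) -> AcquisitionConfig:
        a = self.acquisition
        return AcquisitionConfig(
            frame_rate_hz=a.frame_rate_hz,
            duty=a.duty,
            adc_rate_hz=a.adc_rate_hz,
            slot_order=tuple(a.slot_order),
        )

    def channel_calibration(self) -> ChannelCalibration:
        c = self.calibration
        return ChannelCalibration(c.gain_pd1, c.gain_pd2, c.dark_pd1, c.dark_pd2)

    def pipeline_config(self) -> PipelineConfig:
        d = self.dsp
        return PipelineConfig(
            dc_cutoff_hz=d.dc_cutoff_hz,
            dc_order=d.dc_order,
            smooth_window_s=d.smooth_window_s,
            rho_mode=d.rho_mode,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML or JSON run configuration (None -> defaults)."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def read_raw_stream(path: str | Path) -> pd.DataFrame:
    """Read a raw multiplexed stream CSV (time_s, pd1, pd2).

    Returns the frame with an added boolean ``gap`` column marking samples
    that follow a timing discontinuity; raises on empty or malformed input
    (pandas reports the offending line number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty input file") from exc
    missing = [c for c in ("time_s", "pd1", "pd2") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    t = df["time_s"].to_numpy(dtype=float)
    gap = np.zeros(len(df), dtype=bool)
    if len(t) > 2:
        dt = np.median(np.diff(t))
        gap[1:] = np.diff(t) > 1.5 * dt
    df["gap"] = gap
    return df


def write_raw_stream(df: pd.DataFrame, path: str | Path) -> None:
    """Write a raw stream CSV with stable float formatting."""
    df[[c for c in df.columns if c != "gap"]].to_csv(
        path, index=False, float_format="%.10g"
    )


@dataclass
class PipelineBundle:
    """Everything a pipeline run produces."""

    frames: pd.DataFrame
    sto2: StO2Result
    vitals: VitalsResult
    config_hash: str


def run_pipeline(
    config: RunConfig,
    in_path: str | Path,
    out_path: str | Path | None = None,
    vitals_path: str | Path | None = None,
) -> PipelineBundle:
    """Demultiplex -> StO2 inversion -> vitals, single pass.

    Deterministic: identical input + config give byte-identical outputs.
    Writes the StO2 results CSV to ``out_path`` (and windowed vitals to
    ``vitals_path``) when given.
    """
    log.info(
        "nirsox %s pipeline start (config %s)", __version__, config.config_hash()
    )
    raw = read_raw_stream(in_path)
    frames = demultiplex(raw, config.acquisition_config())
    result = sto2_pipeline(
        frames,
        geom=config.probe_geometry(),
        spectra=config.chromophore_spectra(),
        scattering=config.scattering_model(),
        cal=config.channel_calibration(),
        config=config.pipeline_config(),
    )
    vit = vitals_from_frames(
        frames,
        window_s=config.dsp.vitals_window_s,
        step_s=config.dsp.vitals_step_s,
        dc_cutoff_hz=config.dsp.dc_cutoff_hz,
        spo2_cal=(config.dsp.spo2_cal_a, config.dsp.spo2_cal_b),
        confidence_floor=config.dsp.confidence_floor,
    )
    if out_path is not None:
        cols = ["time_s", "sto2", "k_mu_a_660", "k_mu_a_850", "flag"]
        result.data[cols].to_csv(out_path, index=False, float_format="%.10g")
    if vitals_path is not None:
        vit.data.to_csv(vitals_path, index=False, float_format="%.10g")
    log.info("pipeline done: %d frames", len(frames))
    return PipelineBundle(frames, result, vit, config.config_hash())
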