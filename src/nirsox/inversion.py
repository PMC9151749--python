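"""Spatially resolved spectroscopy inversion: detector intensities to StO2.

The probe measures DC light intensities at two source-detector separations
(4 and 7 mm) for each wavelength (660, 850 nm). The spatial gradient of
absorbance

    dA/drho ~= [A(rho2) - A(rho1)] / (rho2 - rho1) = log10(I1/I2)/(rho2-rho1)

is independent of the unknown source intensity. In the semi-infinite
diffusion regime it equals (mu_eff + 2/rho)/ln10, so the scaled absorption
coefficient follows as

    k mu_a = (ln10 * dA/drho - 2/rho_eff)^2 / (3 (1 - h lambda))

where the unknown scattering magnitude k cancels later in the StO2 ratio.
The two-wavelength pair (k mu_a,660, k mu_a,850) is inverted through the
extinction matrix for scaled hemoglobin concentrations, whose ratio is StO2.

A single-detector modified Beer-Lambert comparator (requiring baseline
total hemoglobin, initial StO2 and an effective pathlength) is provided
for method comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

import numpy as np
import pandas as pd

from . import dsp
from .optics import (
    LN10,
    ChromophoreSpectra,
    ConcentrationPair,
    ProbeGeometry,
    ScatteringModel,
    hemoglobin_solve,
    sto2_from_concentrations,
)

__all__ = [
    "ChannelCalibration",
    "DetectorFrame",
    "StO2Result",
    "MbllState",
    "PipelineConfig",
    "optical_density",
    "absorbance_gradient_estimate",
    "kmua_from_gradient",
    "sto2_pipeline",
    "mbll_sto2",
]

#: Frame-table column names for the four gain-corrected intensity channels.
FRAME_COLUMNS = ("time_s", "i660_pd1", "i660_pd2", "i850_pd1", "i850_pd2")


@dataclass(frozen=True)
class ChannelCalibration:
    """Per-detector relative gain and dark offset.

    Default gains follow the transimpedance-amplifier feedback resistors
    (1 MOhm for the near detector, 4.3 MOhm for the far one): raw readings
    are divided by these to place both channels on a common responsivity
    scale. Absolute responsivity cancels in the absorbance gradient once
    the relative correction is applied.
    """

    gain_pd1: float = 1.0
    gain_pd2: float = 4.3
    dark_pd1: float = 0.0
    dark_pd2: float = 0.0

    def __post_init__(self) -> None:
        if not (self.gain_pd1 > 0 and self.gain_pd2 > 0):
            raise ValueError("gains must be positive")

    def correct(self, raw_pd1, raw_pd2):
        """Return gain-corrected (i_pd1, i_pd2)."""
        return (
            (np.asarray(raw_pd1, dtype=float) - self.dark_pd1) / self.gain_pd1,
            (np.asarray(raw_pd2, dtype=float) - self.dark_pd2) / self.gain_pd2,
        )


@dataclass(frozen=True)
class DetectorFrame:
    """One time-stamped set of gain-corrected intensities, wavelength x detector."""

    time_s: float
    intensity: Mapping[Tuple[float, int], float]  # (wavelength_nm, detector 1|2)
    valid: bool = True


@dataclass
class StO2Result:
    """Tissue-oxygenation time series with intermediate quantities.

    ``data`` columns: time_s, sto2, k_mu_a_660, k_mu_a_850, kc_hb, kc_hbo2,
    flag (0 = good; bit 1 = non-physical gradient; bit 2 = clipped
    concentration; bit 4 = undefined saturation; bit 8 = invalid input).
    """

    data: pd.DataFrame

    FLAG_NONPHYSICAL = 1
    FLAG_CLIPPED = 2
    FLAG_UNDEFINED = 4
    FLAG_INVALID_INPUT = 8

    @property
    def sto2(self) -> np.ndarray:
        return self.data["sto2"].to_numpy()

    @property
    def time_s(self) -> np.ndarray:
        return self.data["time_s"].to_numpy()

    @property
    def flags(self) -> np.ndarray:
        return self.data["flag"].to_numpy()


@dataclass(frozen=True)
class MbllState:
    """Baseline calibration for the single-detector modified Beer-Lambert route.

    ``pathlength_cm`` is the externally supplied differential pathlength —
    a scalar, or a per-wavelength pair (the differential pathlength factors
    at 660 and 850 nm differ by several percent).
    """

    initial_sto2: float
    total_hemoglobin_mmol_l: float
    pathlength_cm: float | Tuple[float, float]

    def __post_init__(self) -> None:
        if not 0 <= self.initial_sto2 <= 1:
            raise ValueError("initial StO2 must be in [0, 1]")
        if not self.total_hemoglobin_mmol_l > 0:
            raise ValueError("total hemoglobin must be positive")
        if np.any(np.asarray(self.pathlength_cm) <= 0):
            raise ValueError("pathlength must be positive")

    def pathlengths(self) -> Tuple[float, float]:
        if np.isscalar(self.pathlength_cm):
            return (float(self.pathlength_cm), float(self.pathlength_cm))
        l1, l2 = self.pathlength_cm
        return float(l1), float(l2)


@dataclass(frozen=True)
class PipelineConfig:
    """Signal-conditioning choices for the streaming StO2 pipeline."""

    dc_cutoff_hz: float = 0.2
    dc_order: int = 2
    smooth_window_s: float = 5.0
    rho_mode: str = "log_mean"  # or "midpoint"
    clip: bool = True

    def rho_eff_cm(self, geom: ProbeGeometry) -> float:
        if self.rho_mode == "log_mean":
            return geom.log_mean_rho_cm
        if self.rho_mode == "midpoint":
            return geom.mid_rho_cm
        raise ValueError("rho_mode must be 'log_mean' or 'midpoint'")


def optical_density(i, i0):
    """Absorbance A = -log10(i/i0); NaN where either intensity is <= 0."""
    i = np.asarray(i, dtype=float)
    i0 = np.asarray(i0, dtype=float)
    bad = (i <= 0) | (i0 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(bad, np.nan, -np.log10(np.where(bad, 1.0, i / i0)))
    return float(a) if a.ndim == 0 else a


def absorbance_gradient_estimate(
    i_pd1,
    i_pd2,
    geom: ProbeGeometry,
    cal: ChannelCalibration | None = None,
):
    """Two-point absorbance gradient (cm^-1) from raw detector intensities.

    ``[A(rho2) - A(rho1)]/(rho2 - rho1) = log10(I1/I2)/(rho2 - rho1)`` after
    gain correction; the unknown source intensity I0 cancels. Returns NaN
    where either corrected intensity is non-positive.
    """
    if cal is None:
        i1 = np.asarray(i_pd1, dtype=float)
        i2 = np.asarray(i_pd2, dtype=float)
    else:
        i1, i2 = cal.correct(i_pd1, i_pd2)
    drho_cm = geom.rho2_cm - geom.rho1_cm
    bad = (i1 <= 0) | (i2 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        grad = np.where(
            bad, np.nan, np.log10(np.where(bad, 1.0, i1 / i2)) / drho_cm
        )
    return float(grad) if grad.ndim == 0 else grad


def kmua_from_gradient(grad, rho_eff_cm: float, h_per_nm: float, wavelength_nm: float):
    """Scaled absorption k*mu_a (cm^-1) from the absorbance gradient.

    ``k mu_a = (ln10 grad - 2/rho_eff)^2 / (3 (1 - h lambda))``. Gradients
    at or below the zero-absorption fixed point 2/(rho_eff ln10) are
    non-physical (negative absorption); they return NaN rather than raising,
    so isolated noisy samples flow through streaming use as flagged gaps.

    Returns (k_mu_a, physical_mask).
    """
    grad = np.asarray(grad, dtype=float)
    arg = LN10 * grad - 2.0 / rho_eff_cm
    physical = arg >= 0  # zero absorption sits exactly on the boundary
    denom = 3.0 * (1.0 - h_per_nm * wavelength_nm)
    kmua = np.where(physical, arg, 0.0) ** 2 / denom
    kmua = np.where(physical, kmua, np.nan)
    if kmua.ndim == 0:
        return float(kmua), bool(physical)
    return kmua, physical


def sto2_pipeline(
    frames: pd.DataFrame,
    geom: ProbeGeometry | None = None,
    spectra: ChromophoreSpectra | None = None,
    scattering: ScatteringModel | None = None,
    cal: ChannelCalibration | None = None,
    config: PipelineConfig | None = None,
) -> StO2Result:
    """Full StO2 chain on a demultiplexed frame table.

    Per sample: low-pass Butterworth DC extraction of each intensity
    channel, two-point absorbance gradient per wavelength, 5-s moving
    average of the gradient (an optical-density quantity) before inversion,
    conversion to scaled absorption coefficients, the 2x2 hemoglobin solve,
    and the saturation ratio. Output is clipped to [0, 1] with per-sample
    quality flags; isolated bad samples never abort the stream.

    ``frames`` must carry the columns ``time_s, i660_pd1, i660_pd2,
    i850_pd1, i850_pd2`` with raw (not yet gain-corrected) intensities on a
    uniform time base.
    """
    geom = geom or ProbeGeometry()
    spectra = spectra or ChromophoreSpectra()
    scattering = scattering or ScatteringModel()
    cal = cal or ChannelCalibration()
    config = config or PipelineConfig()

    missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise ValueError(f"frame table missing columns: {missing}")
    t = frames["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two frames")
    fs = 1.0 / float(np.median(np.diff(t)))
    n = len(t)
    if t[-1] - t[0] < config.smooth_window_s:
        raise ValueError(
            f"need >= {config.smooth_window_s} s of data for the smoothing window"
        )

    flags = np.zeros(n, dtype=int)
    invalid_in = np.zeros(n, dtype=bool)
    for col in FRAME_COLUMNS[1:]:
        invalid_in |= ~np.isfinite(frames[col].to_numpy(dtype=float))
    if "flag" in frames.columns:
        invalid_in |= frames["flag"].to_numpy() != 0
    flags[invalid_in] |= StO2Result.FLAG_INVALID_INPUT

    rho_eff = config.rho_eff_cm(geom)
    lam1, lam2 = geom.wavelengths
    kmua = {}
    for lam, c1, c2 in ((lam1, "i660_pd1", "i660_pd2"), (lam2, "i850_pd1", "i850_pd2")):
        # hold-last-value repair of invalid samples (already flagged) so the
        # IIR filter state is not poisoned by isolated NaNs
        raw1 = frames[c1].ffill().bfill().to_numpy(dtype=float)
        raw2 = frames[c2].ffill().bfill().to_numpy(dtype=float)
        # DC (non-pulsatile) component of each channel.
        dc1 = dsp.dc_extract(raw1, fs, cutoff_hz=config.dc_cutoff_hz, order=config.dc_order)
        dc2 = dsp.dc_extract(raw2, fs, cutoff_hz=config.dc_cutoff_hz, order=config.dc_order)
        grad = absorbance_gradient_estimate(dc1, dc2, geom, cal)
        grad = dsp.moving_average(grad, fs, window_s=config.smooth_window_s)
        km, physical = kmua_from_gradient(grad, rho_eff, scattering.h_at(lam), lam)
        flags[~physical & ~invalid_in] |= StO2Result.FLAG_NONPHYSICAL
        kmua[lam] = km

    pair = hemoglobin_solve(kmua[lam1], kmua[lam2], spectra, (lam1, lam2))
    clipped = (np.asarray(pair.kc_hb) < 0) | (np.asarray(pair.kc_hbo2) < 0)
    flags[clipped & np.isfinite(np.asarray(pair.kc_hb))] |= StO2Result.FLAG_CLIPPED
    sto2, valid = sto2_from_concentrations(pair, clip=config.clip)
    sto2 = np.clip(sto2, 0.0, 1.0)
    flags[~valid] |= StO2Result.FLAG_UNDEFINED

    data = pd.DataFrame(
        {
            "time_s": t,
            "sto2": sto2,
            "k_mu_a_660": kmua[lam1],
            "k_mu_a_850": kmua[lam2],
            "kc_hb": pair.kc_hb,
            "kc_hbo2": pair.kc_hbo2,
            "flag": flags,
        }
    )
    return StO2Result(data)


def mbll_sto2(
    state: MbllState,
    delta_a_660,
    delta_a_850,
    spectra: ChromophoreSpectra | None = None,
    wavelengths: Tuple[float, float] = (660.0, 850.0),
):
    """Single-detector modified Beer-Lambert StO2(t) from absorbance changes.

    Concentration changes follow from the 2x2 extinction solve of
    ``delta_A / pathlength``; the saturation is then

        StO2(t) = (C_tot StO2(0) + dC_HbO2) / (C_tot + dC_HbO2 + dC_Hb)

    Returns (sto2, valid) where samples with a non-positive denominator are
    flagged invalid (NaN).
    """
    spectra = spectra or ChromophoreSpectra()
    l660, l850 = state.pathlengths()
    pair = hemoglobin_solve(
        np.asarray(delta_a_660, dtype=float) / l660 * LN10,
        np.asarray(delta_a_850, dtype=float) / l850 * LN10,
        spectra,
        wavelengths,
    )
    dc_hb = np.asarray(pair.kc_hb)
    dc_hbo2 = np.asarray(pair.kc_hbo2)
    c_tot = state.total_hemoglobin_mmol_l
    num = c_tot * state.initial_sto2 + dc_hbo2
    den = c_tot + dc_hbo2 + dc_hb
    valid = den > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        sto2 = np.where(valid, num / np.where(valid, den, 1.0), np.nan)
    if sto2.ndim == 0:
        return float(sto2), bool(valid)
    return sto2, valid
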