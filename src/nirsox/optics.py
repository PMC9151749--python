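"""Chromophore spectra, tissue optical-property models, and hemoglobin algebra.

This module holds the linear-algebraic core of spatially resolved NIRS
oximetry: molar extinction coefficients of deoxy- and oxyhemoglobin at the
two probe wavelengths (660 and 850 nm), the linear scattering model
``mu_s' = k (1 - h * lambda)``, and the 2x2 solve that converts a pair of
(scaled) absorption coefficients into (scaled) hemoglobin concentrations and
finally into tissue oxygen saturation StO2.

Units
-----
Optical coefficients are per centimetre; extinction coefficients are
L mmol^-1 cm^-1; concentrations are mmol L^-1 (possibly carrying an unknown
common scale factor ``k`` that cancels in the StO2 ratio); probe geometry is
expressed in millimetres at the API surface and converted to centimetres
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

import numpy as np

__all__ = [
    "LN10",
    "RED_NM",
    "NIR_NM",
    "DEFAULT_WAVELENGTHS",
    "ChromophoreSpectra",
    "ScatteringModel",
    "OpticalProperties",
    "ConcentrationPair",
    "ProbeGeometry",
    "MUSCLE_RED",
    "MUSCLE_NIR",
    "reduced_scattering",
    "absorption_from_concentrations",
    "hemoglobin_solve",
    "sto2_from_concentrations",
]

LN10 = float(np.log(10.0))

RED_NM = 660.0
NIR_NM = 850.0
DEFAULT_WAVELENGTHS: Tuple[float, float] = (RED_NM, NIR_NM)

#: Default molar extinction coefficients, L mmol^-1 cm^-1.
_DEFAULT_EPSILON: Mapping[Tuple[str, float], float] = {
    ("HbO2", NIR_NM): 0.25,
    ("Hb", NIR_NM): 0.19,
    ("HbO2", RED_NM): 0.08,
    ("Hb", RED_NM): 0.81,
}

#: Default normalized scattering slopes h (per nm), midpoints of the
#: tissue-dependent ranges for muscle at each wavelength.
_DEFAULT_H: Mapping[float, float] = {NIR_NM: 5.9e-4, RED_NM: 6.9e-4}


class ConfigurationError(ValueError):
    """Raised for invalid optical configuration (e.g. singular spectra)."""


@dataclass(frozen=True)
class ChromophoreSpectra:
    """Extinction coefficients of Hb and HbO2 at the probe wavelengths.

    Parameters
    ----------
    epsilon : mapping
        ``(chromophore, wavelength_nm) ->`` extinction coefficient in
        L mmol^-1 cm^-1. Chromophores are ``"Hb"`` and ``"HbO2"``.
    """

    epsilon: Mapping[Tuple[str, float], float] = field(
        default_factory=lambda: dict(_DEFAULT_EPSILON)
    )

    def __post_init__(self) -> None:
        for key, value in self.epsilon.items():
            if not value > 0:
                raise ConfigurationError(f"extinction coefficient {key} must be > 0")

    def get(self, chromophore: str, wavelength_nm: float) -> float:
        try:
            return self.epsilon[(chromophore, float(wavelength_nm))]
        except KeyError as exc:
            raise ConfigurationError(
                f"no extinction coefficient for {chromophore} at {wavelength_nm} nm"
            ) from exc

    def extinction_matrix(
        self, wavelengths: Tuple[float, float] = DEFAULT_WAVELENGTHS
    ) -> np.ndarray:
        """Return ``[[eps_Hb(l1), eps_HbO2(l1)], [eps_Hb(l2), eps_HbO2(l2)]]``.

        Raises
        ------
        ConfigurationError
            If the matrix is singular (|det| <= 1e-9), in which case the
            two-wavelength system cannot separate the chromophores.
        """
        l1, l2 = wavelengths
        mat = np.array(
            [
                [self.get("Hb", l1), self.get("HbO2", l1)],
                [self.get("Hb", l2), self.get("HbO2", l2)],
            ]
        )
        if abs(np.linalg.det(mat)) <= 1e-9:
            raise ConfigurationError("extinction matrix is singular")
        return mat


@dataclass(frozen=True)
class ScatteringModel:
    """Linear wavelength model of reduced scattering, mu_s' = k (1 - h*lambda).

    ``k_scale`` (cm^-1) sets the overall magnitude; ``h`` (nm^-1, per
    wavelength) is the normalized slope of reduced scattering versus
    wavelength, a tissue property assumed invariant between individuals.
    """

    k_scale: float = 1.0
    h: Mapping[float, float] = field(default_factory=lambda: dict(_DEFAULT_H))

    def __post_init__(self) -> None:
        if not self.k_scale > 0:
            raise ConfigurationError("k_scale must be positive")
        for lam, h in self.h.items():
            if not 1.0 - h * lam > 0:
                raise ConfigurationError(
                    f"1 - h*lambda must stay positive (h={h}, lambda={lam})"
                )

    def h_at(self, wavelength_nm: float) -> float:
        try:
            return self.h[float(wavelength_nm)]
        except KeyError as exc:
            raise ConfigurationError(
                f"no scattering slope h for {wavelength_nm} nm"
            ) from exc

    def reduced_scattering(self, wavelength_nm: float) -> float:
        return reduced_scattering(self, wavelength_nm)


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous-tissue optical properties at one wavelength.

    mu_a and mu_s_prime are per cm; ``g`` is the Henyey-Greenstein
    anisotropy; mu_s is recovered as mu_s'/(1-g).
    """

    mu_a: float
    mu_s_prime: float
    g: float = 0.0
    refractive_index: float = 1.37

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_a) or self.mu_a < 0:
            raise ValueError("mu_a must be finite and >= 0")
        if not np.isfinite(self.mu_s_prime) or self.mu_s_prime <= 0:
            raise ValueError("mu_s_prime must be finite and > 0")
        if not 0 <= self.g < 1:
            raise ValueError("anisotropy g must satisfy 0 <= g < 1")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient (cm^-1) from the similarity relation."""
        return self.mu_s_prime / (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s (cm^-1)."""
        return self.mu_a + self.mu_s


#: Muscle-tissue optical properties at the two probe wavelengths.
MUSCLE_RED = OpticalProperties(mu_a=0.53, mu_s_prime=8.53, g=0.87)
MUSCLE_NIR = OpticalProperties(mu_a=0.49, mu_s_prime=6.67, g=0.93)


@dataclass(frozen=True)
class ConcentrationPair:
    """Hemoglobin concentrations scaled by a common unknown positive factor k.

    The factor cancels in the StO2 ratio, so only relative values matter.
    Entries may be numpy arrays for time series.
    """

    kc_hb: np.ndarray | float
    kc_hbo2: np.ndarray | float


@dataclass(frozen=True)
class ProbeGeometry:
    """Source-detector geometry: two detectors at rho1 < rho2 from the LEDs."""

    rho1_mm: float = 4.0
    rho2_mm: float = 7.0
    wavelengths: Tuple[float, float] = DEFAULT_WAVELENGTHS

    def __post_init__(self) -> None:
        if not 0 < self.rho1_mm < self.rho2_mm:
            raise ValueError("require 0 < rho1 < rho2")

    @property
    def rho1_cm(self) -> float:
        return self.rho1_mm / 10.0

    @property
    def rho2_cm(self) -> float:
        return self.rho2_mm / 10.0

    @property
    def log_mean_rho_cm(self) -> float:
        """Logarithmic mean (rho2-rho1)/ln(rho2/rho1), in cm.

        Using this effective distance in the 2/rho geometric term makes the
        two-point finite difference of a 1/rho^2 intensity law exact.
        """
        return (self.rho2_cm - self.rho1_cm) / np.log(self.rho2_cm / self.rho1_cm)

    @property
    def mid_rho_cm(self) -> float:
        """Arithmetic midpoint of the detector distances, in cm."""
        return 0.5 * (self.rho1_cm + self.rho2_cm)


def reduced_scattering(model: ScatteringModel, wavelength_nm: float) -> float:
    """Reduced scattering coefficient mu_s' = k_scale * (1 - h*lambda), cm^-1."""
    h = model.h_at(wavelength_nm)
    factor = 1.0 - h * wavelength_nm
    if factor <= 0:
        raise ValueError(f"1 - h*lambda = {factor} <= 0 at {wavelength_nm} nm")
    return model.k_scale * factor


def absorption_from_concentrations(
    c_hb, c_hbo2, spectra: ChromophoreSpectra, wavelength_nm: float
):
    """Absorption coefficient mu_a = ln(10) (eps_Hb C_Hb + eps_HbO2 C_HbO2).

    Concentrations in mmol L^-1 (scalars or arrays); returns cm^-1.
    """
    eps_hb = spectra.get("Hb", wavelength_nm)
    eps_hbo2 = spectra.get("HbO2", wavelength_nm)
    return LN10 * (eps_hb * np.asarray(c_hb) + eps_hbo2 * np.asarray(c_hbo2))


def hemoglobin_solve(
    k_mu_a_1,
    k_mu_a_2,
    spectra: ChromophoreSpectra | None = None,
    wavelengths: Tuple[float, float] = DEFAULT_WAVELENGTHS,
) -> ConcentrationPair:
    """Invert the two-wavelength absorption system for (kC_Hb, kC_HbO2).

    Solves ``[kC_Hb, kC_HbO2] = (1/ln10) E^-1 [k mu_a(l1), k mu_a(l2)]``
    where ``E`` is the extinction matrix. The unknown scale k carries
    through unchanged. Accepts scalars or equally shaped arrays.
    """
    spectra = spectra or ChromophoreSpectra()
    mat = spectra.extinction_matrix(wavelengths)
    det = mat[0, 0] * mat[1, 1] - mat[0, 1] * mat[1, 0]
    a1 = np.asarray(k_mu_a_1, dtype=float)
    a2 = np.asarray(k_mu_a_2, dtype=float)
    kc_hb = (mat[1, 1] * a1 - mat[0, 1] * a2) / (det * LN10)
    kc_hbo2 = (-mat[1, 0] * a1 + mat[0, 0] * a2) / (det * LN10)
    if kc_hb.ndim == 0:
        return ConcentrationPair(float(kc_hb), float(kc_hbo2))
    return ConcentrationPair(kc_hb, kc_hbo2)


def sto2_from_concentrations(pair: ConcentrationPair, clip: bool = True):
    """Tissue oxygen saturation StO2 = kC_HbO2 / (kC_Hb + kC_HbO2).

    The common scale k cancels. With ``clip=True`` (default), negative
    concentrations — possible under measurement noise — are clipped to zero
    before the ratio and the sample is flagged; samples whose total clipped
    hemoglobin is zero are flagged invalid and returned as NaN.

    Returns
    -------
    sto2 : float or ndarray
        Saturation in [0, 1], NaN where undefined.
    valid : bool or ndarray of bool
        False where the sample was undefined (total <= 0).
    """
    hb = np.asarray(pair.kc_hb, dtype=float)
    hbo2 = np.asarray(pair.kc_hbo2, dtype=float)
    if clip:
        hb = np.clip(hb, 0.0, None)
        hbo2 = np.clip(hbo2, 0.0, None)
    total = hb + hbo2
    valid = total > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        sto2 = np.where(valid, hbo2 / np.where(valid, total, 1.0), np.nan)
    if sto2.ndim == 0:
        return float(sto2), bool(valid)
    return sto2, valid
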