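"""Closed-form semi-infinite diffusion model for spatially resolved NIRS.

In the diffusion regime (mu_a << mu_s'), the spatial gradient of absorbance
measured at the tissue surface of a semi-infinite medium is

    dA/drho = (1/ln10) * (mu_eff + 2/rho),   mu_eff = sqrt(3 mu_a mu_s')

which is exactly the derivative of -log10 of the intensity law

    I(rho) ∝ exp(-mu_eff * rho) / rho**2.

That intensity law is therefore used as the fast forward model for the
synthetic-signal generator, making the generator and the SRS inverter exact
mathematical mirrors of one another.

All distances here are in centimetres, matching the per-cm coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .optics import LN10

__all__ = [
    "DiffusionMedium",
    "effective_attenuation",
    "absorbance_gradient_forward",
    "relative_intensity",
]


@dataclass(frozen=True)
class DiffusionMedium:
    """Absorbing, scattering medium in the diffusion regime (mu_a << mu_s')."""

    mu_a: float
    mu_s_prime: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError("mu_a must be >= 0")
        if not self.mu_s_prime > 0:
            raise ValueError("mu_s_prime must be > 0")
        if self.mu_a / self.mu_s_prime > 0.1:
            warnings.warn(
                "mu_a/mu_s' > 0.1: diffusion approximation becomes inaccurate",
                stacklevel=3,
            )


def effective_attenuation(medium: DiffusionMedium) -> float:
    """Effective attenuation coefficient sqrt(3 mu_a mu_s'), cm^-1."""
    return float(np.sqrt(3.0 * medium.mu_a * medium.mu_s_prime))


def absorbance_gradient_forward(medium: DiffusionMedium, rho_cm):
    """Forward model for the absorbance gradient dA/drho (cm^-1) at rho (cm)."""
    rho = np.asarray(rho_cm, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be > 0")
    out = (effective_attenuation(medium) + 2.0 / rho) / LN10
    return float(out) if out.ndim == 0 else out


def relative_intensity(medium: DiffusionMedium, rho_cm):
    """Relative detected intensity I(rho) = exp(-mu_eff rho) / rho^2.

    Dimensionless up to a source-strength constant that cancels in the
    two-distance gradient; defined so that -log10(I) has exactly the
    absorbance gradient of :func:`absorbance_gradient_forward`.
    """
    rho = np.asarray(rho_cm, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be > 0")
    out = np.exp(-effective_attenuation(medium) * rho) / rho**2
    return float(out) if out.ndim == 0 else out
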