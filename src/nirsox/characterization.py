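"""Device-characterization studies: light penetration, heating, StO2 accuracy.

These are the standard simulation workflows for the implanted probe,
packaged so scripts and tests share one implementation:

- Monte Carlo fluence maps of the two sources in muscle, with the derived
  penetration depth (axial 1e-3 mW/mm^2 crossing) and illuminated volume;
- the Pennes bioheat study of dual-LED operation at 10 % duty (die heat
  plus absorbed light) with near-field temperature-rise probes;
- closed-loop StO2 accuracy: noise-free diffusion round trip, and recovery
  from Monte Carlo surface tallies at the 4/7 mm detectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .bioheat import (
    ThermalField,
    ThermalProperties,
    led_heat_power,
    led_source_map,
    optical_source_map,
    solve_pennes,
    stability_dt,
)
from .diffusion import DiffusionMedium, relative_intensity
from .inversion import absorbance_gradient_estimate, kmua_from_gradient
from .montecarlo import (
    FluenceGrid,
    McConfig,
    NIR_SOURCE,
    RED_SOURCE,
    VoxelGrid,
    simulate_fluence,
    surface_exit_profile,
)
from .optics import (
    ChromophoreSpectra,
    MUSCLE_NIR,
    MUSCLE_RED,
    OpticalProperties,
    ProbeGeometry,
    ScatteringModel,
    absorption_from_concentrations,
    hemoglobin_solve,
    sto2_from_concentrations,
)

__all__ = [
    "muscle_fluence",
    "ThermalStudyResult",
    "thermal_study",
    "srs_noise_free_roundtrip_error",
    "mc_srs_recovery",
]

#: Red and NIR LED electricals: forward voltage (V), current (A), optical power (W).
LED_ELECTRICAL = {
    "red": (2.1, 1.7e-3, 0.77e-3),
    "nir": (1.55, 3.0e-3, 0.58e-3),
}

#: Center-to-center spacing of the two dies on the probe tip (mm).
LED_SPACING_MM = 0.8


def muscle_fluence(
    wavelength: str,
    n_photons: int,
    seed: int,
    edge_mm: float = 0.2,
    lateral_mm: float = 16.0,
    depth_mm: float = 12.0,
    boundary: str = "fresnel",
) -> FluenceGrid:
    """Fluence map of one probe source in muscle tissue."""
    source = {"red": RED_SOURCE, "nir": NIR_SOURCE}[wavelength]
    props = {"red": MUSCLE_RED, "nir": MUSCLE_NIR}[wavelength]
    grid = VoxelGrid.desk(lateral_mm=lateral_mm, depth_mm=depth_mm, edge_mm=edge_mm)
    return simulate_fluence(
        source, props, grid, McConfig(n_photons=n_photons, seed=seed), boundary=boundary
    )


@dataclass
class ThermalStudyResult:
    """Outcome of the dual-LED heating study."""

    field: ThermalField
    near_field_rise_c: Dict[float, float]  # distance above LEDs (mm) -> max dT
    max_rise_beyond_1p5mm_c: float

    @property
    def max_near_field_rise_c(self) -> float:
        return max(self.near_field_rise_c.values())


def thermal_study(
    red_fluence: FluenceGrid | None,
    nir_fluence: FluenceGrid | None,
    duty: float = 0.10,
    dx_mm: float = 0.1,
    domain_mm: float = 20.0,
    duration_s: float = 300.0,
    props: ThermalProperties | None = None,
    probe_distances_mm: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
) -> ThermalStudyResult:
    """Five minutes of dual-LED operation inside muscle.

    The two dies sit at the domain center, spaced LED_SPACING_MM apart;
    each dissipates its duty-averaged electrical-minus-optical power over
    its footprint. The absorbed-light term phi*mu_a (already duty-averaged
    through the fluence normalization) is added on the emission side when
    fluence grids are supplied. Fixed-temperature far boundaries.

    Near-field probes sit at the stated distances above each die (the
    maximum over the two columns is reported per distance); the far-field
    figure is the maximum rise over all voxels farther than 1.5 mm from
    either die footprint.
    """
    props = props or ThermalProperties()
    n = int(round(domain_mm / dx_mm))
    shape = (n, n, n)
    c = domain_mm / 2.0
    die_z_top = c + 0.135  # die half-thickness above center
    centers = {
        "red": (c - LED_SPACING_MM / 2.0, c, c),
        "nir": (c + LED_SPACING_MM / 2.0, c, c),
    }
    heats = {
        name: led_heat_power(*LED_ELECTRICAL[name], duty) for name in ("red", "nir")
    }
    q = led_source_map(
        shape, dx_mm, [centers["red"], centers["nir"]], [heats["red"], heats["nir"]]
    )
    for name, fluence in (("red", red_fluence), ("nir", nir_fluence)):
        if fluence is None:
            continue
        x0, y0, _ = centers[name]
        q += optical_source_map(shape, dx_mm, fluence, (x0, y0, die_z_top))

    dt = stability_dt(props, dx_mm)
    field = solve_pennes(
        ThermalField(np.zeros(shape, dtype=np.float64), dx_mm, 0.0),
        props,
        q,
        dt,
        duration_s,
    )[-1]

    near = {
        d: max(
            field.probe((centers["red"][0], c, die_z_top + d)),
            field.probe((centers["nir"][0], c, die_z_top + d)),
        )
        for d in probe_distances_mm
    }

    # distance of every voxel center from the union of the two die boxes
    half = np.array([0.17, 0.17, 0.135])
    coords = [(np.arange(n) + 0.5) * dx_mm for _ in range(3)]
    dist_min = np.full(shape, np.inf)
    for center in centers.values():
        d2 = np.zeros(shape)
        for axis in range(3):
            delta = np.abs(coords[axis] - center[axis]) - half[axis]
            delta = np.clip(delta, 0.0, None) ** 2
            shape_axis = [1, 1, 1]
            shape_axis[axis] = n
            d2 = d2 + delta.reshape(shape_axis)
        dist_min = np.minimum(dist_min, np.sqrt(d2))
    far_mask = dist_min > 1.5
    max_far = float(field.delta_t[far_mask].max())

    return ThermalStudyResult(field, near, max_far)


def srs_noise_free_roundtrip_error(
    levels: Sequence[float] = tuple(np.round(np.arange(0.1, 0.95, 0.1), 2)),
    total_hemoglobin_mmol_l: float = 0.9,
    geom: ProbeGeometry | None = None,
    scattering: ScatteringModel | None = None,
    spectra: ChromophoreSpectra | None = None,
) -> float:
    """Max |recovered - true| StO2 over noise-free diffusion round trips."""
    geom = geom or ProbeGeometry()
    scattering = scattering or ScatteringModel(k_scale=13.38)
    spectra = spectra or ChromophoreSpectra()
    worst = 0.0
    for sto2_true in levels:
        kmua = {}
        for lam in geom.wavelengths:
            mu_a = absorption_from_concentrations(
                (1 - sto2_true) * total_hemoglobin_mmol_l,
                sto2_true * total_hemoglobin_mmol_l,
                spectra,
                lam,
            )
            medium = DiffusionMedium(mu_a, scattering.reduced_scattering(lam))
            grad = absorbance_gradient_estimate(
                relative_intensity(medium, geom.rho1_cm),
                relative_intensity(medium, geom.rho2_cm),
                geom,
            )
            kmua[lam], _ = kmua_from_gradient(
                grad, geom.log_mean_rho_cm, scattering.h_at(lam), lam
            )
        rec, _ = sto2_from_concentrations(
            hemoglobin_solve(*[kmua[lam] for lam in geom.wavelengths], spectra)
        )
        worst = max(worst, abs(rec - sto2_true))
    return worst


def mc_srs_recovery(
    levels: Sequence[float] = (0.3, 0.5, 0.7, 0.9),
    n_photons: int = 300_000,
    seed: int = 1,
    total_hemoglobin_mmol_l: float = 0.9,
    boundary: str = "escape",
) -> Dict[float, float]:
    """StO2 recovered from Monte Carlo detector tallies at 4 and 7 mm.

    For each saturation level, full transport simulations (with muscle
    anisotropy) produce the surface exit intensities at the two detector
    radii; the standard inversion chain then runs on those intensities.
    The matched-index boundary is the configuration mirrored by the
    diffusion model underlying the inversion.
    """
    geom = ProbeGeometry()
    scattering = ScatteringModel(k_scale=13.38)
    spectra = ChromophoreSpectra()
    g_of = {660.0: MUSCLE_RED.g, 850.0: MUSCLE_NIR.g}
    src_of = {660.0: RED_SOURCE, 850.0: NIR_SOURCE}
    grid = VoxelGrid.desk(lateral_mm=18.0, depth_mm=9.0, edge_mm=0.25)
    out: Dict[float, float] = {}
    for i, sto2_true in enumerate(levels):
        kmua = {}
        for j, lam in enumerate(geom.wavelengths):
            mu_a = absorption_from_concentrations(
                (1 - sto2_true) * total_hemoglobin_mmol_l,
                sto2_true * total_hemoglobin_mmol_l,
                spectra,
                lam,
            )
            props = OpticalProperties(
                mu_a, scattering.reduced_scattering(lam), g_of[lam]
            )
            fg = simulate_fluence(
                src_of[lam],
                props,
                grid,
                McConfig(n_photons=n_photons, seed=seed + 10 * i + j),
                boundary=boundary,
            )
            _, intensity = surface_exit_profile(
                fg, np.array([geom.rho1_mm, geom.rho2_mm])
            )
            grad = absorbance_gradient_estimate(intensity[0], intensity[1], geom)
            kmua[lam], _ = kmua_from_gradient(
                grad, geom.log_mean_rho_cm, scattering.h_at(lam), lam
            )
        rec, _ = sto2_from_concentrations(
            hemoglobin_solve(*[kmua[lam] for lam in geom.wavelengths], spectra)
        )
        out[float(sto2_true)] = float(rec)
    return out
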