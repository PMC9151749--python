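"""Pennes bioheat finite-difference solver and thermistor calibration.

Models tissue heating around the implanted probe:

    rho Cp dT/dt = div(k grad T) + Q_the + phi * mu_a

where ``Q_the`` is the volumetric heat from the micro-LED dies (electrical
minus optical power, duty-averaged) and ``phi mu_a`` is the absorbed-light
term taken from a Monte Carlo fluence field. Perfusion and metabolic terms
are neglected (constant-background assumption), so the solution is the
temperature *rise* over the baseline. The solver is an explicit
forward-time central-space scheme on a uniform cubic grid with
fixed-temperature (zero-rise) far boundaries, compiled with numba.

The NTC thermistor companion converts measured resistance to temperature
via R = R0 exp(B (1/T - 1/T0)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from numba import njit

from .montecarlo import FluenceGrid

__all__ = [
    "ThermalProperties",
    "ThermistorCalibration",
    "ThermalField",
    "LED_FOOTPRINT_MM",
    "led_heat_power",
    "led_source_map",
    "optical_source_map",
    "stability_dt",
    "solve_pennes",
    "thermistor_temperature",
    "thermistor_resistance",
]

#: Micro-LED die dimensions (length, width, thickness), mm.
LED_FOOTPRINT_MM: Tuple[float, float, float] = (0.34, 0.34, 0.27)


@dataclass(frozen=True)
class ThermalProperties:
    """Tissue thermal constants; defaults are standard skeletal muscle."""

    conductivity_w_mk: float = 0.49
    density_kg_m3: float = 1090.0
    heat_capacity_j_kgk: float = 3421.0

    def __post_init__(self) -> None:
        if min(self.conductivity_w_mk, self.density_kg_m3, self.heat_capacity_j_kgk) <= 0:
            raise ValueError("thermal properties must be positive")

    @property
    def diffusivity_m2_s(self) -> float:
        return self.conductivity_w_mk / (self.density_kg_m3 * self.heat_capacity_j_kgk)


@dataclass(frozen=True)
class ThermistorCalibration:
    """NTC bead constants: R = R0 exp(B (1/T - 1/T0)).

    R0 = 10 kOhm and B = 3380 K are the device values; T0 defaults to the
    datasheet reference of 25 degC (298.15 K).
    """

    r0_ohm: float = 10_000.0
    b_k: float = 3380.0
    t0_k: float = 298.15

    def __post_init__(self) -> None:
        if min(self.r0_ohm, self.b_k, self.t0_k) <= 0:
            raise ValueError("thermistor constants must be positive")


@dataclass
class ThermalField:
    """Temperature-rise field (K above baseline) on a uniform cubic grid."""

    delta_t: np.ndarray  # (nx, ny, nz), K
    dx_mm: float
    time_s: float

    def probe(self, point_mm: Sequence[float]) -> float:
        """Temperature rise at a physical point, trilinearly interpolated
        between voxel centers."""
        lo = []
        frac = []
        for p, n in zip(point_mm, self.delta_t.shape):
            u = p / self.dx_mm - 0.5
            i = int(np.clip(np.floor(u), 0, n - 2))
            lo.append(i)
            frac.append(np.clip(u - i, 0.0, 1.0))
        out = 0.0
        for dx_i in (0, 1):
            for dy_i in (0, 1):
                for dz_i in (0, 1):
                    w = (
                        (frac[0] if dx_i else 1 - frac[0])
                        * (frac[1] if dy_i else 1 - frac[1])
                        * (frac[2] if dz_i else 1 - frac[2])
                    )
                    out += w * self.delta_t[lo[0] + dx_i, lo[1] + dy_i, lo[2] + dz_i]
        return float(out)


def led_heat_power(
    forward_voltage_v: float,
    current_a: float,
    optical_power_w: float,
    duty: float,
) -> float:
    """Duty-averaged heat dissipation of an LED: duty * (V I - P_opt), watts."""
    if not 0 < duty <= 1:
        raise ValueError("duty must be in (0, 1]")
    electrical = forward_voltage_v * current_a
    if optical_power_w > electrical:
        raise ValueError("optical power exceeds electrical power")
    return duty * (electrical - optical_power_w)


def led_source_map(
    shape: Tuple[int, int, int],
    dx_mm: float,
    led_centers_mm: Sequence[Tuple[float, float, float]],
    led_powers_w: Sequence[float],
    footprint_mm: Tuple[float, float, float] = LED_FOOTPRINT_MM,
) -> np.ndarray:
    """Volumetric heat-source map (W/m^3) for LED dies at given centers.

    Each die's power is distributed uniformly over the voxels its printed
    footprint overlaps.
    """
    q = np.zeros(shape, dtype=np.float64)
    vol_m3 = (dx_mm * 1e-3) ** 3
    for center, power in zip(led_centers_mm, led_powers_w):
        sl = []
        for axis, (c, f, n) in enumerate(zip(center, footprint_mm, shape)):
            lo = int(np.floor((c - f / 2) / dx_mm))
            hi = max(lo + 1, int(np.ceil((c + f / 2) / dx_mm)))
            lo = max(0, lo)
            hi = min(n, hi)
            if hi <= lo:
                raise ValueError("LED footprint outside the grid")
            sl.append(slice(lo, hi))
        nvox = (sl[0].stop - sl[0].start) * (sl[1].stop - sl[1].start) * (
            sl[2].stop - sl[2].start
        )
        q[tuple(sl)] += power / (nvox * vol_m3)
    return q


def optical_source_map(
    shape: Tuple[int, int, int],
    dx_mm: float,
    fluence: FluenceGrid,
    offset_mm: Tuple[float, float, float],
) -> np.ndarray:
    """Absorbed-light heat term phi * mu_a resampled onto the thermal grid.

    ``fluence`` carries mW/mm^2; with mu_a per cm the product is
    0.1 mW/mm^3 = 1e5 W/m^3 per unit. ``offset_mm`` places the fluence
    grid's surface-center origin inside the thermal grid. The fluence
    field is block-averaged when the thermal grid is coarser and
    voxel-replicated when it is finer (the field is smooth on these
    scales). Any duty-cycle averaging is inherited from the fluence
    normalization.
    """
    ratio = dx_mm / fluence.grid.edge_mm
    f = fluence.fluence
    if ratio >= 1 - 1e-6:
        r = int(round(ratio))
        if abs(ratio - r) > 1e-6:
            raise ValueError("thermal dx must be a multiple of the fluence edge")
        if r > 1:
            nx, ny, nz = (s // r for s in f.shape)
            f = f[: nx * r, : ny * r, : nz * r].reshape(nx, r, ny, r, nz, r).mean(
                axis=(1, 3, 5)
            )
    else:
        inv = 1.0 / ratio
        r = int(round(inv))
        if abs(inv - r) > 1e-6:
            raise ValueError("fluence edge must be a multiple of the thermal dx")
        f = np.repeat(np.repeat(np.repeat(f, r, axis=0), r, axis=1), r, axis=2)
    q_local = f * fluence.props.mu_a * 1e5  # W/m^3
    q = np.zeros(shape, dtype=np.float64)
    # fluence grid origin: lateral center at source, z=0 at the surface
    ox = int(round(offset_mm[0] / dx_mm)) - f.shape[0] // 2
    oy = int(round(offset_mm[1] / dx_mm)) - f.shape[1] // 2
    oz = int(round(offset_mm[2] / dx_mm))
    xs = slice(max(0, ox), min(shape[0], ox + f.shape[0]))
    ys = slice(max(0, oy), min(shape[1], oy + f.shape[1]))
    zs = slice(max(0, oz), min(shape[2], oz + f.shape[2]))
    q[xs, ys, zs] = q_local[
        xs.start - ox : xs.stop - ox,
        ys.start - oy : ys.stop - oy,
        zs.start - oz : zs.stop - oz,
    ]
    return q


def stability_dt(props: ThermalProperties, dx_mm: float) -> float:
    """Largest stable explicit time step dx^2 rho Cp / (6 k), seconds."""
    dx = dx_mm * 1e-3
    return dx * dx / (6.0 * props.diffusivity_m2_s)


@njit(cache=True, fastmath=True)
def _fd_steps(t_field, source_k_s, alpha, n_steps):
    nx, ny, nz = t_field.shape
    t_new = t_field.copy()
    for _ in range(n_steps):
        for i in range(1, nx - 1):
            for j in range(1, ny - 1):
                for k in range(1, nz - 1):
                    lap = (
                        t_field[i - 1, j, k]
                        + t_field[i + 1, j, k]
                        + t_field[i, j - 1, k]
                        + t_field[i, j + 1, k]
                        + t_field[i, j, k - 1]
                        + t_field[i, j, k + 1]
                        - 6.0 * t_field[i, j, k]
                    )
                    t_new[i, j, k] = (
                        t_field[i, j, k] + alpha * lap + source_k_s[i, j, k]
                    )
        tmp = t_field
        t_field = t_new
        t_new = tmp
    return t_field


def solve_pennes(
    field0: ThermalField,
    props: ThermalProperties,
    source_w_m3: np.ndarray,
    dt_s: float,
    duration_s: float,
    snapshot_every_s: float | None = None,
) -> list[ThermalField]:
    """March the explicit Pennes scheme forward and return field snapshots.

    Boundary voxels are held at zero rise (fixed far-field temperature).
    Raises if ``dt_s`` violates the explicit stability bound, suggesting
    the largest stable step.

    Returns the list of snapshots (always including the final time).
    """
    dt_max = stability_dt(props, field0.dx_mm)
    if dt_s > dt_max * (1 + 1e-9):
        raise ValueError(
            f"dt={dt_s:g}s violates the explicit stability bound; use dt <= {dt_max:g}s"
        )
    if source_w_m3.shape != field0.delta_t.shape:
        raise ValueError("source map shape must match the field")
    if np.any(source_w_m3 < 0):
        raise ValueError("heat sources must be non-negative")

    dx = field0.dx_mm * 1e-3
    alpha = props.diffusivity_m2_s * dt_s / (dx * dx)
    rho_cp = props.density_kg_m3 * props.heat_capacity_j_kgk
    source_k_s = np.ascontiguousarray(source_w_m3 * (dt_s / rho_cp))

    n_total = int(round(duration_s / dt_s))
    if snapshot_every_s is None:
        chunks = [n_total]
    else:
        per = max(1, int(round(snapshot_every_s / dt_s)))
        chunks = [per] * (n_total // per)
        if n_total % per:
            chunks.append(n_total % per)

    field = np.ascontiguousarray(field0.delta_t.astype(np.float64))
    out: list[ThermalField] = []
    t = field0.time_s
    for n_steps in chunks:
        field = _fd_steps(field, source_k_s, alpha, n_steps)
        t += n_steps * dt_s
        out.append(ThermalField(field.copy(), field0.dx_mm, t))
    return out


def thermistor_temperature(r_ohm, cal: ThermistorCalibration | None = None):
    """Temperature (K) from NTC resistance: T = 1/(1/T0 + ln(R/R0)/B)."""
    cal = cal or ThermistorCalibration()
    r = np.asarray(r_ohm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("resistance must be positive")
    t = 1.0 / (1.0 / cal.t0_k + np.log(r / cal.r0_ohm) / cal.b_k)
    return float(t) if t.ndim == 0 else t


def thermistor_resistance(t_k, cal: ThermistorCalibration | None = None):
    """Inverse of :func:`thermistor_temperature`: R = R0 exp(B (1/T - 1/T0))."""
    cal = cal or ThermistorCalibration()
    t = np.asarray(t_k, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    r = cal.r0_ohm * np.exp(cal.b_k * (1.0 / t - 1.0 / cal.t0_k))
    return float(r) if r.ndim == 0 else r
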