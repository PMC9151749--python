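"""Seeded generator of physiologically structured raw probe streams.

Stands in for in vivo data: a segment-wise StO2 protocol (baseline /
arterial occlusion / recovery / venous congestion) is converted to
hemoglobin concentration time lines, to absorption coefficients through
the extinction spectra, to detector intensities through the semi-infinite
diffusion intensity law at the two source-detector separations, and
finally time-multiplexed into the LED frame structure with channel gains,
optional ambient/dark slots, white noise and slow drift.

Because the generator shares its physics (diffusion intensity law,
extinction spectra, single-k scattering model) with the inversion chain,
the commanded StO2 is recovered exactly in the noise-free limit — the
round-trip identity the test-suite is built on. Pulsation is modeled as a
small arterial (high-saturation) volume oscillation at the cardiac and
respiratory frequencies, so AC/DC ratio-of-ratios SpO2 is meaningful, and
pulsatility is switched off in occlusion segments, emulating the loss of
the pulsatile component the device observes during ischemia/congestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .diffusion import DiffusionMedium, relative_intensity
from .dsp import AcquisitionConfig
from .inversion import ChannelCalibration
from .optics import (
    ChromophoreSpectra,
    ProbeGeometry,
    ScatteringModel,
    absorption_from_concentrations,
)

__all__ = [
    "Segment",
    "PhysioProfile",
    "NoiseModel",
    "concentration_timeline",
    "generate_raw_stream",
    "porcine_protocol_profile",
]


@dataclass(frozen=True)
class Segment:
    """One protocol phase: hold a target StO2 for a duration."""

    duration_s: float
    sto2: float
    pulsatile: bool = True

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("segment duration must be positive")
        if not 0 <= self.sto2 <= 1:
            raise ValueError("StO2 must be in [0, 1]")


@dataclass(frozen=True)
class PhysioProfile:
    """Physiological scenario driving the generator.

    Total hemoglobin of 0.90 mmol/L places the baseline absorption
    coefficients near the muscle values used in the optical simulations;
    a 2 % pulsatile fraction is a typical perfusion index; cardiac and
    respiratory defaults (120 beats/min, 18 breaths/min) sit inside the
    porcine 1.7-2.5 Hz and ~0.3 Hz observation bands.
    """

    segments: Tuple[Segment, ...] = (Segment(60.0, 0.70),)
    total_hemoglobin_mmol_l: float = 0.90
    heart_rate_bpm: float = 120.0
    respiration_bpm: float = 18.0
    pulse_fraction: float = 0.02
    resp_fraction: float = 0.008
    arterial_saturation: float = 0.97
    transition_tau_s: float = 10.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("need at least one segment")
        if not self.total_hemoglobin_mmol_l > 0:
            raise ValueError("total hemoglobin must be positive")
        if self.pulse_fraction < 0 or self.resp_fraction < 0:
            raise ValueError("modulation fractions must be >= 0")
        if not 0 <= self.arterial_saturation <= 1:
            raise ValueError("arterial saturation must be in [0, 1]")

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement imperfections: white noise, slow drift, ambient light.

    ``sd_rel`` is the white-noise SD relative to each noise-free sample;
    drift is a slow per-wavelength multiplicative sinusoid emulating LED
    output wander (common to both detectors, so it cancels in the
    absorbance gradient); ``ambient`` is an absolute offset present in
    every slot and removable via a dark slot.
    """

    sd_rel: float = 0.01
    drift_rel: float = 0.01
    drift_period_s: float = 60.0
    ambient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_rel < 0 or self.drift_rel < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @classmethod
    def off(cls, seed: int = 0) -> "NoiseModel":
        return cls(sd_rel=0.0, drift_rel=0.0, ambient=0.0, seed=seed)


def _commanded_sto2(profile: PhysioProfile, t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant targets smoothed by exponential transitions.

    Returns (sto2, pulsatile_envelope); the envelope relaxes with the same
    time constant so pulsation fades rather than snapping at occlusion
    onset.
    """
    tau = profile.transition_tau_s
    sto2 = np.empty_like(t)
    env = np.empty_like(t)
    level = profile.segments[0].sto2
    p_level = 1.0 if profile.segments[0].pulsatile else 0.0
    start = 0.0
    for seg in profile.segments:
        sel = (t >= start - 1e-12) & (t < start + seg.duration_s - 1e-12)
        target = seg.sto2
        p_target = 1.0 if seg.pulsatile else 0.0
        if tau > 0:
            decay = np.exp(-(t[sel] - start) / tau)
        else:
            decay = np.zeros_like(t[sel])
        sto2[sel] = target + (level - target) * decay
        env[sel] = p_target + (p_level - p_target) * decay
        if tau > 0:
            end_decay = np.exp(-seg.duration_s / tau)
        else:
            end_decay = 0.0
        level = target + (level - target) * end_decay
        p_level = p_target + (p_level - p_target) * end_decay
        start += seg.duration_s
    sel = t >= start - 1e-12
    sto2[sel] = level
    env[sel] = p_level
    return sto2, env


def concentration_timeline(profile: PhysioProfile, dt_s: float) -> pd.DataFrame:
    """Hemoglobin concentration time lines C_Hb(t), C_HbO2(t).

    The non-pulsatile pools are StO2-partitioned total hemoglobin; the
    pulsatile component is an added arterial volume oscillation
    (saturation ``arterial_saturation``) at the cardiac and respiratory
    frequencies, scaled by the segment's pulsatility envelope.

    Returns a DataFrame with columns ``time_s, c_hb, c_hbo2, sto2_cmd,
    pulse_env`` where ``sto2_cmd`` is the commanded (transition-smoothed)
    saturation before modulation.
    """
    if not dt_s > 0:
        raise ValueError("dt must be positive")
    n = int(round(profile.duration_s / dt_s))
    t = np.arange(n) * dt_s
    sto2, env = _commanded_sto2(profile, t)
    c_tot = profile.total_hemoglobin_mmol_l
    cardiac = np.sin(2 * np.pi * profile.heart_rate_bpm / 60.0 * t)
    resp = np.sin(2 * np.pi * profile.respiration_bpm / 60.0 * t)
    arterial = (
        c_tot
        * env
        * (profile.pulse_fraction * cardiac + profile.resp_fraction * resp)
    )
    sa = profile.arterial_saturation
    c_hbo2 = sto2 * c_tot + sa * arterial
    c_hb = (1.0 - sto2) * c_tot + (1.0 - sa) * arterial
    return pd.DataFrame(
        {"time_s": t, "c_hb": c_hb, "c_hbo2": c_hbo2, "sto2_cmd": sto2, "pulse_env": env}
    )


def generate_raw_stream(
    profile: PhysioProfile,
    geom: ProbeGeometry | None = None,
    scattering: ScatteringModel | None = None,
    acq: AcquisitionConfig | None = None,
    noise: NoiseModel | None = None,
    spectra: ChromophoreSpectra | None = None,
    cal: ChannelCalibration | None = None,
    source_scale: float = 1.0e4,
) -> pd.DataFrame:
    """Raw time-multiplexed two-detector stream for the given scenario.

    Per ADC sample: the slot decides the lit wavelength; mu_a(lambda, t)
    follows from the concentrations, the semi-infinite diffusion intensity
    law gives I(rho) at both detectors with mu_s'(lambda) = k (1 - h
    lambda), channel gains (TIA ratio) and ambient/noise/drift are applied.
    Deterministic for a fixed ``noise.seed``.

    Returns a DataFrame ``time_s, pd1, pd2`` at the ADC rate.
    """
    geom = geom or ProbeGeometry()
    # Default magnitude puts mu_s'(850) at the muscle value 6.67 /cm.
    scattering = scattering or ScatteringModel(k_scale=13.38)
    acq = acq or AcquisitionConfig()
    noise = noise or NoiseModel()
    spectra = spectra or ChromophoreSpectra()
    cal = cal or ChannelCalibration()

    dt = 1.0 / acq.adc_rate_hz
    conc = concentration_timeline(profile, dt)
    t = conc["time_s"].to_numpy()
    n = len(t)
    slot_names = np.tile(np.array(acq.slot_order), n // acq.slots_per_frame + 1)[:n]

    rng = np.random.default_rng(noise.seed)
    lam_of = {"red": geom.wavelengths[0], "nir": geom.wavelengths[1]}
    pd1 = np.zeros(n)
    pd2 = np.zeros(n)
    gains = (cal.gain_pd1, cal.gain_pd2)
    darks = (cal.dark_pd1, cal.dark_pd2)
    for slot in dict.fromkeys(acq.slot_order):  # deterministic order
        sel = slot_names == slot
        if slot == "dark":
            base1 = np.full(sel.sum(), noise.ambient)
            base2 = np.full(sel.sum(), noise.ambient)
        else:
            lam = lam_of[slot]
            mu_a = absorption_from_concentrations(
                conc["c_hb"].to_numpy()[sel],
                conc["c_hbo2"].to_numpy()[sel],
                spectra,
                lam,
            )
            mu_sp = scattering.reduced_scattering(lam)
            mu_eff = np.sqrt(3.0 * mu_a * mu_sp)
            # relative_intensity inlined for array mu_eff
            i1 = np.exp(-mu_eff * geom.rho1_cm) / geom.rho1_cm**2
            i2 = np.exp(-mu_eff * geom.rho2_cm) / geom.rho2_cm**2
            if noise.drift_rel > 0:
                phase = 0.0 if slot == "red" else np.pi / 3
                drift = 1.0 + noise.drift_rel * np.sin(
                    2 * np.pi * t[sel] / noise.drift_period_s + phase
                )
            else:
                drift = 1.0
            base1 = source_scale * drift * i1 + noise.ambient
            base2 = source_scale * drift * i2 + noise.ambient
        base1 = base1 * gains[0] + darks[0]
        base2 = base2 * gains[1] + darks[1]
        if noise.sd_rel > 0:
            base1 = base1 * (1.0 + noise.sd_rel * rng.standard_normal(base1.size))
            base2 = base2 * (1.0 + noise.sd_rel * rng.standard_normal(base2.size))
        pd1[sel] = base1
        pd2[sel] = base2

    return pd.DataFrame({"time_s": t, "pd1": pd1, "pd2": pd2})


def porcine_protocol_profile(scale: float = 1.0) -> PhysioProfile:
    """The flap occlusion protocol: two cycles of baseline / arterial
    occlusion (ischemia) / recovery / venous occlusion (congestion) /
    recovery, 15 minutes per phase, scaled by ``scale`` for desk-size runs.

    Occlusion phases are non-pulsatile with depressed StO2. The episode
    StO2 levels (baseline 0.70, ischemia 0.40, congestion 0.45) are
    configurable placeholders for levels only shown graphically in vivo.
    The transition time constant shrinks with the protocol so scaled-down
    profiles keep distinguishable plateaus.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    seg_s = 15.0 * 60.0 * scale
    cycle = [
        Segment(seg_s, 0.70, pulsatile=True),
        Segment(seg_s, 0.40, pulsatile=False),
        Segment(seg_s, 0.70, pulsatile=True),
        Segment(seg_s, 0.45, pulsatile=False),
        Segment(seg_s, 0.70, pulsatile=True),
    ]
    tau = float(np.clip(seg_s / 90.0, 0.5, 10.0))
    return PhysioProfile(segments=tuple(cycle * 2), transition_tau_s=tau)
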