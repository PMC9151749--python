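"""Signal conditioning and vital-sign extraction.

Covers the conditioning chain of the wireless probe: demultiplexing the
time-multiplexed photodetector stream into per-wavelength frames, DC/AC
separation with a causal second-order Butterworth low-pass (0.2 Hz), the
5-s moving average, short-time Fourier spectrograms, spectral heart-rate
and respiration estimation, ratio-of-ratios SpO2, and the Bland-Altman /
zero-lag normalized cross-correlation comparison statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "AcquisitionConfig",
    "VitalsResult",
    "demultiplex",
    "dc_extract",
    "moving_average",
    "spectrogram",
    "heart_rate",
    "respiration_rate",
    "spo2_ratio_of_ratios",
    "bland_altman",
    "normalized_xcorr_zero_lag",
    "vitals_from_frames",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """LED multiplexing and ADC timing.

    The LEDs run at ``frame_rate`` Hz with ``duty`` fraction each; every
    ADC sample (at ``adc_rate`` per detector) falls in one slot of
    ``slot_order``, cycling once per LED frame. The defaults (50 Hz frames,
    100 Sa/s) give two slots per frame — one red-lit, one NIR-lit. A
    ``"dark"`` slot may be included (raising the ADC rate accordingly) to
    measure ambient light, which is then subtracted from the lit slots.
    """

    frame_rate_hz: float = 50.0
    duty: float = 0.10
    adc_rate_hz: float = 100.0
    slot_order: Tuple[str, ...] = ("red", "nir")

    def __post_init__(self) -> None:
        if not 0 < self.duty <= 0.5:
            raise ValueError("duty must be in (0, 0.5]")
        slots = self.adc_rate_hz / self.frame_rate_hz
        if abs(slots - round(slots)) > 1e-9 or round(slots) != len(self.slot_order):
            raise ValueError(
                "adc_rate / frame_rate must equal the number of slots "
                f"({self.adc_rate_hz}/{self.frame_rate_hz} vs {len(self.slot_order)})"
            )
        for s in self.slot_order:
            if s not in ("red", "nir", "dark"):
                raise ValueError(f"unknown slot {s!r}")
        if "red" not in self.slot_order or "nir" not in self.slot_order:
            raise ValueError("slot order must contain 'red' and 'nir'")

    @property
    def slots_per_frame(self) -> int:
        return len(self.slot_order)


@dataclass
class VitalsResult:
    """Windowed vital signs: heart rate, respiration, SpO2, confidences."""

    data: pd.DataFrame  # time_s, hr_bpm, hr_conf, rr_bpm, rr_conf, spo2, flag


def demultiplex(raw: pd.DataFrame, acq: AcquisitionConfig | None = None) -> pd.DataFrame:
    """Split a time-multiplexed two-detector stream into per-frame intensities.

    ``raw`` columns: ``time_s, pd1, pd2`` sampled at the ADC rate, one
    sample per LED slot. Returns one row per complete LED frame with
    columns ``time_s, i660_pd1, i660_pd2, i850_pd1, i850_pd2, flag``
    (flag 1 marks frames adjacent to a timing gap). Ambient (dark-slot)
    readings, when present, are subtracted from the lit-slot intensities.

    Sample-to-slot assignment follows the sample index within each frame;
    a clock drift beyond half a slot against the nominal time base forces a
    resynchronization (with a flagged frame).
    """
    acq = acq or AcquisitionConfig()
    for col in ("time_s", "pd1", "pd2"):
        if col not in raw.columns:
            raise ValueError(f"raw stream missing column {col!r}")
    t = raw["time_s"].to_numpy(dtype=float)
    if len(t) < acq.slots_per_frame:
        raise ValueError("stream shorter than one LED frame")
    dt_nominal = 1.0 / acq.adc_rate_hz
    # Gap detection: a missing sample shows as a time step > 1.5 slots.
    gaps = np.nonzero(np.diff(t) > 1.5 * dt_nominal)[0]
    gap_mask = np.zeros(len(t), dtype=bool)
    gap_mask[gaps] = True
    if gaps.size:
        gap_mask[np.minimum(gaps + 1, len(t) - 1)] = True

    # Slot index from the time base itself, so a dropped sample resyncs.
    slot_idx = np.rint((t - t[0]) / dt_nominal).astype(int) % acq.slots_per_frame
    frame_idx = np.rint((t - t[0]) / dt_nominal).astype(int) // acq.slots_per_frame

    pd1 = raw["pd1"].to_numpy(dtype=float)
    pd2 = raw["pd2"].to_numpy(dtype=float)
    n_frames = frame_idx[-1] + 1
    cols = {
        "red": (np.full(n_frames, np.nan), np.full(n_frames, np.nan)),
        "nir": (np.full(n_frames, np.nan), np.full(n_frames, np.nan)),
        "dark": (np.zeros(n_frames), np.zeros(n_frames)),
    }
    t_frame = np.full(n_frames, np.nan)
    flag = np.zeros(n_frames, dtype=int)
    for k, slot_name in enumerate(acq.slot_order):
        sel = slot_idx == k
        fi = frame_idx[sel]
        cols[slot_name][0][fi] = pd1[sel]
        cols[slot_name][1][fi] = pd2[sel]
        if k == 0:
            t_frame[fi] = t[sel]
        if slot_name == "red":
            flag[fi[gap_mask[sel]]] |= 1
    # Frames missing any lit slot (dropped sample) are flagged.
    incomplete = ~np.isfinite(cols["red"][0]) | ~np.isfinite(cols["nir"][0])
    flag[incomplete] |= 1
    # Fill frame timestamps for frames whose slot-0 sample was the dropped one.
    missing_t = ~np.isfinite(t_frame)
    t_frame[missing_t] = t[0] + np.nonzero(missing_t)[0] * acq.slots_per_frame * dt_nominal

    out = pd.DataFrame(
        {
            "time_s": t_frame,
            "i660_pd1": cols["red"][0] - cols["dark"][0],
            "i660_pd2": cols["red"][1] - cols["dark"][1],
            "i850_pd1": cols["nir"][0] - cols["dark"][0],
            "i850_pd2": cols["nir"][1] - cols["dark"][1],
            "flag": flag,
        }
    )
    return out


def dc_extract(
    series,
    fs_hz: float,
    cutoff_hz: float = 0.2,
    order: int = 2,
    zero_phase: bool = False,
) -> np.ndarray:
    """Non-pulsatile (DC) component via a Butterworth low-pass.

    Causal single-pass by default (streaming semantics), initialized at the
    first sample so a constant input passes through unchanged; unity gain
    at DC, -3 dB at the cutoff. ``zero_phase=True`` uses forward-backward
    filtering for offline reproduction without phase delay.
    """
    x = np.asarray(series, dtype=float)
    if not cutoff_hz < fs_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    if zero_phase:
        return sps.sosfiltfilt(sos, x)
    zi = sps.sosfilt_zi(sos) * x[0]
    y, _ = sps.sosfilt(sos, x, zi=zi)
    return y


def moving_average(series, fs_hz: float, window_s: float = 5.0) -> np.ndarray:
    """Trailing arithmetic mean over ``window_s`` seconds.

    During the first window the mean expands over the available samples, so
    a unit step ramps linearly for one window length before settling.
    NaN samples are ignored within each window (streaming robustness).
    """
    n = int(round(window_s * fs_hz))
    if n < 1:
        raise ValueError("window shorter than one sample")
    x = pd.Series(np.asarray(series, dtype=float))
    return x.rolling(window=n, min_periods=1).mean().to_numpy()


def spectrogram(
    series,
    fs_hz: float,
    window_s: float = 30.0,
    overlap: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time Fourier magnitude map (Hann taper).

    Returns (freqs_hz, times_s, magnitude) where magnitude[i, j] is the
    spectral magnitude at freqs[i], times[j].
    """
    x = np.asarray(series, dtype=float)
    nper = int(round(window_s * fs_hz))
    if nper > x.size:
        raise ValueError("window longer than the series")
    nover = int(round(overlap * nper))
    f, t, z = sps.stft(
        x, fs=fs_hz, window="hann", nperseg=nper, noverlap=nover, boundary=None
    )
    return f, t, np.abs(z)


def _band_peak(
    series, fs_hz: float, band: Tuple[float, float], confidence_floor: float
) -> Tuple[float, float, bool]:
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        return np.nan, 0.0, False
    x = x - x.mean()
    nper = min(x.size, max(256, int(round(fs_hz * 60))))
    f, pxx = sps.welch(x, fs=fs_hz, nperseg=nper)
    sel = (f >= band[0]) & (f <= band[1])
    if not np.any(sel) or not np.any(pxx[sel] > 0):
        return np.nan, 0.0, False
    fb, pb = f[sel], pxx[sel]
    i = int(np.argmax(pb))
    med = float(np.median(pb))
    conf = float(pb[i] / med) if med > 0 else np.inf
    present = conf >= confidence_floor
    return float(fb[i]), conf, present


def heart_rate(
    series,
    fs_hz: float,
    band: Tuple[float, float] = (0.8, 5.0),
    confidence_floor: float = 10.0,
) -> Tuple[float, float, bool]:
    """Heart rate (beats/min) from the dominant in-band spectral peak.

    Returns (bpm, confidence, present): ``confidence`` is the peak-to-median
    in-band spectral power ratio; ``present`` is False when no peak clears
    the confidence floor — the pulsatility-loss indication during vascular
    occlusion. bpm is NaN when absent.
    """
    f, conf, present = _band_peak(series, fs_hz, band, confidence_floor)
    return (f * 60.0 if present else np.nan), conf, present


def respiration_rate(
    series,
    fs_hz: float,
    band: Tuple[float, float] = (0.1, 0.7),
    confidence_floor: float = 10.0,
) -> Tuple[float, float, bool]:
    """Respiration rate (breaths/min); same estimator as heart_rate, lower band."""
    f, conf, present = _band_peak(series, fs_hz, band, confidence_floor)
    return (f * 60.0 if present else np.nan), conf, present


def spo2_ratio_of_ratios(
    ac_660: float,
    dc_660: float,
    ac_850: float,
    dc_850: float,
    cal_a: float = 1.10,
    cal_b: float = 0.25,
) -> float:
    """Pulse oximetry from the ratio of ratios R = (AC/DC)_660 / (AC/DC)_850.

    SpO2 = clamp(a - b R, 0, 1). The linear coefficients are the
    conventional empirical calibration line, not a device calibration:
    absolute SpO2 from this instrument requires a co-oximetry calibration.
    """
    if dc_660 <= 0 or dc_850 <= 0:
        raise ValueError("DC components must be positive")
    if ac_850 <= 0:
        raise ValueError("no pulsatile component at the reference wavelength")
    r = (ac_660 / dc_660) / (ac_850 / dc_850)
    return float(np.clip(cal_a - cal_b * r, 0.0, 1.0))


def bland_altman(x, y) -> Tuple[float, float]:
    """Mean and sample SD (n-1) of paired differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    d = x - y
    return float(d.mean()), float(d.std(ddof=1)) if d.size > 1 else 0.0


def normalized_xcorr_zero_lag(x, y) -> float:
    """Pearson-type normalized inner product of mean-removed series at lag 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero-variance input")
    return float((xc * yc).sum() / denom)


def vitals_from_frames(
    frames: pd.DataFrame,
    window_s: float = 30.0,
    step_s: float = 10.0,
    dc_cutoff_hz: float = 0.2,
    spo2_cal: Tuple[float, float] = (1.10, 0.25),
    confidence_floor: float = 10.0,
    pulse_amp_floor: float = 2e-3,
) -> VitalsResult:
    """Windowed HR / respiration / SpO2 from a demultiplexed frame table.

    Uses the near-detector NIR channel for rates (strongest pulsatile
    signal), and the AC/DC ratio of both wavelengths at the near detector
    for SpO2. A pulse counts as present only when the in-band spectral
    peak clears ``confidence_floor`` AND the relative AC amplitude
    (perfusion index) exceeds ``pulse_amp_floor`` — spectral confidence
    alone is scale-invariant and would fire on numerically tiny residue.
    Windows without a detected pulse get flag 1 and NaN SpO2 — the binary
    blood-flow indication during occlusion episodes.
    """
    t = frames["time_s"].to_numpy(dtype=float)
    fs = 1.0 / float(np.median(np.diff(t)))
    sig_nir = frames["i850_pd1"].to_numpy(dtype=float)
    sig_red = frames["i660_pd1"].to_numpy(dtype=float)
    dc_nir = dc_extract(sig_nir, fs, cutoff_hz=dc_cutoff_hz)
    dc_red = dc_extract(sig_red, fs, cutoff_hz=dc_cutoff_hz)
    ac_nir = sig_nir - dc_nir
    ac_red = sig_red - dc_red

    rows = []
    start = t[0]
    while start + window_s <= t[-1] + 1e-9:
        sel = (t >= start) & (t < start + window_s)
        hr, hr_conf, hr_ok = heart_rate(
            ac_nir[sel], fs, confidence_floor=confidence_floor
        )
        dc_level = float(np.mean(dc_nir[sel]))
        rel_amp = float(np.sqrt(2.0) * np.std(ac_nir[sel])) / dc_level if dc_level > 0 else 0.0
        if rel_amp < pulse_amp_floor:
            hr, hr_ok = np.nan, False
        rr, rr_conf, _ = respiration_rate(
            dc_nir[sel] - dc_nir[sel].mean(), fs, confidence_floor=confidence_floor
        )
        if hr_ok:
            amp_nir = float(np.sqrt(2.0) * np.std(ac_nir[sel]))
            amp_red = float(np.sqrt(2.0) * np.std(ac_red[sel]))
            try:
                spo2 = spo2_ratio_of_ratios(
                    amp_red,
                    float(np.mean(dc_red[sel])),
                    amp_nir,
                    float(np.mean(dc_nir[sel])),
                    *spo2_cal,
                )
            except ValueError:
                spo2 = np.nan
        else:
            spo2 = np.nan
        rows.append(
            {
                "time_s": start + window_s / 2,
                "hr_bpm": hr,
                "hr_conf": hr_conf,
                "rr_bpm": rr,
                "rr_conf": rr_conf,
                "spo2": spo2,
                "flag": 0 if hr_ok else 1,
            }
        )
        start += step_s
    return VitalsResult(pd.DataFrame(rows))
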