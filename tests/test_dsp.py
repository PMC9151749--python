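"""Demultiplexing, filtering, vitals extraction, and comparison statistics."""

import numpy as np
import pandas as pd
import pytest

from nirsox.dsp import (
    AcquisitionConfig,
    bland_altman,
    dc_extract,
    demultiplex,
    heart_rate,
    moving_average,
    normalized_xcorr_zero_lag,
    respiration_rate,
    spectrogram,
    spo2_ratio_of_ratios,
    vitals_from_frames,
)
from nirsox.synthetic import (
    NoiseModel,
    PhysioProfile,
    Segment,
    generate_raw_stream,
)


def _stream(values_by_slot, acq, n_frames=10):
    """Build a raw stream with constant per-slot values."""
    rows = []
    dt = 1.0 / acq.adc_rate_hz
    i = 0
    for f in range(n_frames):
        for slot in acq.slot_order:
            v = values_by_slot[slot]
            rows.append({"time_s": i * dt, "pd1": v, "pd2": v})
            i += 1
    return pd.DataFrame(rows)


class TestDemultiplex:
    def test_dark_slot_subtraction(self):
        acq = AcquisitionConfig(adc_rate_hz=150.0, slot_order=("red", "nir", "dark"))
        raw = _stream({"red": 2.0, "nir": 3.0, "dark": 1.0}, acq)
        frames = demultiplex(raw, acq)
        good = frames[frames["flag"] == 0]
        assert np.allclose(good["i660_pd1"], 1.0)
        assert np.allclose(good["i850_pd1"], 2.0)

    def test_generator_round_trip_exact(self, geom, scattering, spectra):
        """Noise-free generated streams demultiplex back to the generator's
        pre-mux intensities."""
        from nirsox.diffusion import DiffusionMedium, relative_intensity
        from nirsox.optics import absorption_from_concentrations

        profile = PhysioProfile(
            segments=(Segment(10.0, 0.70),), pulse_fraction=0.0, resp_fraction=0.0
        )
        raw = generate_raw_stream(
            profile, geom=geom, scattering=scattering, noise=NoiseModel.off()
        )
        frames = demultiplex(raw)
        mu_a = absorption_from_concentrations(0.3 * 0.9, 0.7 * 0.9, spectra, 660.0)
        medium = DiffusionMedium(mu_a, scattering.reduced_scattering(660.0))
        expected_pd1 = 1e4 * relative_intensity(medium, geom.rho1_cm) * 1.0
        assert np.allclose(frames["i660_pd1"], expected_pd1, rtol=1e-12)

    def test_missing_sample_flagged_no_crash(self):
        acq = AcquisitionConfig()
        raw = _stream({"red": 2.0, "nir": 3.0}, acq, n_frames=20)
        raw = raw.drop(index=11).reset_index(drop=True)  # drop one sample
        frames = demultiplex(raw, acq)
        assert (frames["flag"] != 0).any()
        assert len(frames) == 20

    def test_rejects_malformed_config(self):
        with pytest.raises(ValueError, match="slots"):
            AcquisitionConfig(adc_rate_hz=100.0, slot_order=("red", "nir", "dark"))


class TestDcExtract:
    def test_constant_passthrough(self):
        y = dc_extract(np.full(1000, 3.7), fs_hz=50.0)
        assert np.allclose(y, 3.7, atol=1e-9)

    def test_attenuation_at_2hz(self):
        fs = 50.0
        t = np.arange(0, 120, 1 / fs)
        y = dc_extract(np.sin(2 * np.pi * 2.0 * t), fs)
        resid = np.sqrt(2) * y[len(y) // 2 :].std()
        # second-order Butterworth magnitude at 10x cutoff: ~1/sqrt(1+10^4)
        assert resid == pytest.approx(0.01, abs=0.005)

    def test_half_power_at_cutoff(self):
        fs = 50.0
        t = np.arange(0, 600, 1 / fs)
        y = dc_extract(np.sin(2 * np.pi * 0.2 * t), fs, cutoff_hz=0.2)
        gain = np.sqrt(2) * y[len(y) // 2 :].std()
        assert gain == pytest.approx(1 / np.sqrt(2), abs=0.01)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            dc_extract(np.zeros(10), fs_hz=1.0, cutoff_hz=0.6)

    def test_ac_dc_reconstruction_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        dc = dc_extract(x, 50.0)
        assert np.allclose(dc + (x - dc), x, atol=0.0)


class TestMovingAverage:
    def test_constant(self):
        assert np.allclose(moving_average(np.full(100, 2.5), 10.0), 2.5)

    def test_step_ramp(self):
        fs = 10.0
        x = np.concatenate([np.zeros(100), np.ones(100)])
        y = moving_average(x, fs, window_s=5.0)
        t = np.arange(200) / fs
        ramp = np.clip((t - 9.9) / 5.0, 0, 1)
        assert np.allclose(y, ramp, atol=0.021)
        assert np.allclose(y[160:], 1.0)

    def test_alternating_cancels(self):
        x = np.tile([1.0, 1.0, -1.0, -1.0], 250)
        y = moving_average(x, fs_hz=50.0, window_s=5.0)
        assert np.abs(y[300:]).max() <= 0.01

    def test_window_shorter_than_sample_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.zeros(10), fs_hz=10.0, window_s=0.01)


class TestSpectrogram:
    def test_single_tone_ridge(self):
        fs = 50.0
        t = np.arange(0, 120, 1 / fs)
        f, tt, mag = spectrogram(np.sin(2 * np.pi * 2.0 * t), fs)
        ridge = f[np.argmax(mag, axis=0)]
        assert np.allclose(ridge, 2.0, atol=0.05)

    def test_two_tone_ridges(self):
        fs = 50.0
        t = np.arange(0, 120, 1 / fs)
        x = np.sin(2 * np.pi * 0.3 * t) + np.sin(2 * np.pi * 2.0 * t)
        f, tt, mag = spectrogram(x, fs)
        mean_mag = mag.mean(axis=1)
        peaks = f[np.argsort(mean_mag)[-2:]]
        assert sorted(np.round(peaks, 1)) == [0.3, 2.0]

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            spectrogram(np.zeros(100), fs_hz=50.0, window_s=30.0)


class TestRates:
    def test_heart_rate_from_two_hz_tone(self):
        fs = 50.0
        t = np.arange(0, 60, 1 / fs)
        bpm, conf, ok = heart_rate(np.sin(2 * np.pi * 2.0 * t), fs)
        assert ok and bpm == pytest.approx(120.0, abs=1.0)

    def test_zero_amplitude_flagged_absent(self):
        bpm, conf, ok = heart_rate(np.zeros(3000), 50.0)
        assert not ok and np.isnan(bpm)

    def test_amplitude_invariance(self):
        fs = 50.0
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 1.9 * t)
        b1, _, _ = heart_rate(x, fs)
        b2, _, _ = heart_rate(1e4 * x, fs)
        assert b1 == b2

    def test_respiration_from_p3_hz(self):
        fs = 50.0
        t = np.arange(0, 120, 1 / fs)
        bpm, conf, ok = respiration_rate(np.sin(2 * np.pi * 0.3 * t), fs)
        assert ok and bpm == pytest.approx(18.0, abs=0.5)

    def test_respiration_absent_without_inband_energy(self):
        fs = 50.0
        t = np.arange(0, 60, 1 / fs)
        bpm, conf, ok = respiration_rate(np.sin(2 * np.pi * 2.0 * t), fs)
        assert not ok

    def test_white_noise_low_confidence(self):
        rng = np.random.default_rng(7)
        for _ in range(2):
            bpm, conf, ok = heart_rate(rng.standard_normal(6000), 50.0)
            assert not ok


class TestSpo2:
    def test_calibration_line_points(self):
        # R = 0.4 -> 1.10 - 0.25*0.4 = 1.00; R = 1.0 -> 0.85
        assert spo2_ratio_of_ratios(0.4, 1.0, 1.0, 1.0) == pytest.approx(1.00)
        assert spo2_ratio_of_ratios(1.0, 1.0, 1.0, 1.0) == pytest.approx(0.85)

    def test_rejects_absent_pulse(self):
        with pytest.raises(ValueError):
            spo2_ratio_of_ratios(0.1, 1.0, 0.0, 1.0)

    def test_generator_arterial_saturation_recovered(self):
        """SpO2 from the generated pulsatile stream sits near the arterial
        saturation to within the calibration line's self-consistency."""
        profile = PhysioProfile(segments=(Segment(60.0, 0.70),))
        raw = generate_raw_stream(profile, noise=NoiseModel.off())
        from nirsox.dsp import demultiplex

        vit = vitals_from_frames(demultiplex(raw))
        spo2 = vit.data["spo2"].dropna()
        assert len(spo2) > 0
        assert np.allclose(spo2, 0.97, atol=0.03)


class TestComparisonStats:
    def test_bland_altman_identical(self):
        assert bland_altman([1, 2, 3], [1, 2, 3]) == (0.0, 0.0)

    def test_bland_altman_offset_sign_convention(self):
        x = np.array([1.0, 2.0, 3.0])
        mean, sd = bland_altman(x, x + 2.0)
        assert mean == pytest.approx(-2.0) and sd == pytest.approx(0.0)

    def test_bland_altman_hand_example(self):
        mean, sd = bland_altman([1, 2, 3], [1, 1, 4])
        assert mean == pytest.approx(0.0)
        assert sd == pytest.approx(1.0)  # sample SD, n-1

    def test_bland_altman_antisymmetry(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        mxy, sxy = bland_altman(x, y)
        myx, syx = bland_altman(y, x)
        assert mxy == pytest.approx(-myx) and sxy == pytest.approx(syx)

    def test_bland_altman_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2, 3])

    def test_xcorr_bounds_and_orthogonality(self):
        t = np.linspace(0, 4 * np.pi, 1000, endpoint=False)
        assert normalized_xcorr_zero_lag(np.sin(t), np.sin(t)) == pytest.approx(1.0)
        assert normalized_xcorr_zero_lag(np.sin(t), -np.sin(t)) == pytest.approx(-1.0)
        assert normalized_xcorr_zero_lag(np.sin(t), np.cos(t)) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_xcorr_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            normalized_xcorr_zero_lag(np.ones(10), np.arange(10.0))


def test_vitals_recovery_with_noise():
    """HR 100 beats/min recovered within 2 bpm at moderate noise."""
    profile = PhysioProfile(
        segments=(Segment(90.0, 0.70),), heart_rate_bpm=100.0
    )
    raw = generate_raw_stream(profile, noise=NoiseModel(sd_rel=0.002, seed=4))
    from nirsox.dsp import demultiplex

    vit = vitals_from_frames(demultiplex(raw))
    hr = vit.data["hr_bpm"].dropna()
    assert len(hr) > 0
    assert np.allclose(hr, 100.0, atol=2.0)
    rr = vit.data["rr_bpm"].dropna()
    assert np.allclose(rr, 18.0, atol=1.0)
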