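"""SRS inversion chain: optical density, gradients, and the StO2 pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nirsox.diffusion import DiffusionMedium, effective_attenuation, relative_intensity
from nirsox.dsp import demultiplex
from nirsox.inversion import (
    ChannelCalibration,
    MbllState,
    PipelineConfig,
    StO2Result,
    absorbance_gradient_estimate,
    kmua_from_gradient,
    mbll_sto2,
    optical_density,
    sto2_pipeline,
)
from nirsox.optics import (
    LN10,
    ChromophoreSpectra,
    ProbeGeometry,
    ScatteringModel,
    absorption_from_concentrations,
    hemoglobin_solve,
    sto2_from_concentrations,
)
from nirsox.synthetic import (
    NoiseModel,
    PhysioProfile,
    Segment,
    generate_raw_stream,
)


def _chain_sto2(sto2_true, c_tot, geom, scattering, spectra):
    """Forward-generate diffusion intensities at rho1/rho2 and invert."""
    kmua = {}
    for lam in geom.wavelengths:
        mu_a = absorption_from_concentrations(
            (1 - sto2_true) * c_tot, sto2_true * c_tot, spectra, lam
        )
        medium = DiffusionMedium(mu_a, scattering.reduced_scattering(lam))
        i1 = relative_intensity(medium, geom.rho1_cm)
        i2 = relative_intensity(medium, geom.rho2_cm)
        grad = absorbance_gradient_estimate(i1, i2, geom)
        kmua[lam], ok = kmua_from_gradient(
            grad, geom.log_mean_rho_cm, scattering.h_at(lam), lam
        )
        assert ok
    pair = hemoglobin_solve(*[kmua[lam] for lam in geom.wavelengths], spectra)
    sto2, valid = sto2_from_concentrations(pair)
    assert valid
    return sto2


@pytest.mark.parametrize("i, i0, expected", [(1.0, 1.0, 0.0), (0.1, 1.0, 1.0), (0.01, 1.0, 2.0)])
def test_optical_density_decades(i, i0, expected):
    assert optical_density(i, i0) == pytest.approx(expected, rel=1e-12)


def test_optical_density_invalid_flagged():
    assert np.isnan(optical_density(-1.0, 1.0))
    assert np.isnan(optical_density(1.0, 0.0))


class TestAbsorbanceGradient:
    def test_equal_intensities_zero(self, geom):
        assert absorbance_gradient_estimate(5.0, 5.0, geom) == 0.0

    def test_decade_over_three_mm(self):
        g = ProbeGeometry(rho1_mm=4.0, rho2_mm=7.0)
        assert absorbance_gradient_estimate(10.0, 1.0, g) == pytest.approx(
            1.0 / 0.3, rel=1e-12
        )

    def test_gain_correction_applied(self, geom):
        cal = ChannelCalibration(gain_pd1=1.0, gain_pd2=4.3)
        raw1, raw2 = 5.0, 5.0 * 4.3  # equal after correction
        assert absorbance_gradient_estimate(raw1, raw2, geom, cal) == pytest.approx(0.0)

    def test_matches_log_mean_identity(self, geom, scattering, spectra):
        """Intensities from the diffusion law give exactly
        (mu_eff + 2/rho_lm)/ln10 with rho_lm the logarithmic mean."""
        medium = DiffusionMedium(0.53, 8.53)
        i1 = relative_intensity(medium, geom.rho1_cm)
        i2 = relative_intensity(medium, geom.rho2_cm)
        grad = absorbance_gradient_estimate(i1, i2, geom)
        expected = (
            effective_attenuation(medium) + 2.0 / geom.log_mean_rho_cm
        ) / LN10
        assert grad == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_intensity_flagged(self, geom):
        assert np.isnan(absorbance_gradient_estimate(0.0, 1.0, geom))


class TestKmuaFromGradient:
    def test_zero_absorption_fixed_point(self):
        rho = 0.536
        grad = 2.0 / (rho * LN10)
        kmua, ok = kmua_from_gradient(grad, rho, 5.9e-4, 850.0)
        assert ok and kmua == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        kmua, ok = kmua_from_gradient(3.0, 0.536, 5.9e-4, 850.0)
        assert ok and kmua == pytest.approx(6.747, abs=2e-3)

    def test_round_trip_identity(self, geom):
        """Gradient from the diffusion forward model with mu_s' = k(1-h*lam)
        returns exactly k * mu_a."""
        k_scale, h, lam, mu_a = 13.38, 5.9e-4, 850.0, 0.49
        medium = DiffusionMedium(mu_a, k_scale * (1 - h * lam))
        from nirsox.diffusion import absorbance_gradient_forward

        grad = absorbance_gradient_forward(medium, geom.log_mean_rho_cm)
        kmua, ok = kmua_from_gradient(grad, geom.log_mean_rho_cm, h, lam)
        assert ok
        assert kmua == pytest.approx(k_scale * mu_a, rel=1e-12)

    def test_nonphysical_gradient_flagged_not_raised(self):
        kmua, ok = kmua_from_gradient(0.1, 0.536, 5.9e-4, 850.0)
        assert not ok and np.isnan(kmua)


def test_srs_exactness_across_saturations(geom, scattering, spectra):
    """Noise-free diffusion-forward intensities invert to the true StO2 to
    better than 1e-9 for StO2 from 0.1 to 0.9 (log-mean rho cancels the
    geometric term identically)."""
    for sto2_true in np.round(np.arange(0.1, 0.95, 0.1), 2):
        rec = _chain_sto2(float(sto2_true), 0.9, geom, scattering, spectra)
        assert abs(rec - sto2_true) <= 1e-9


@given(scale=st.floats(0.1, 10.0))
@settings(max_examples=20, deadline=None)
def test_gain_invariance_common_scale(scale):
    """Scaling both detector gains together leaves StO2 unchanged; scaling
    one alone does not (documented calibration sensitivity)."""
    geom = ProbeGeometry()
    scattering = ScatteringModel(k_scale=13.38)
    spectra = ChromophoreSpectra()

    hardware = ChannelCalibration(1.0, 4.3)

    def invert(cal):
        # hardware applies the true TIA gains; `cal` is what the inversion
        # believes them to be
        kmua = {}
        for lam in geom.wavelengths:
            mu_a = absorption_from_concentrations(0.27, 0.63, spectra, lam)
            medium = DiffusionMedium(mu_a, scattering.reduced_scattering(lam))
            raw1 = relative_intensity(medium, geom.rho1_cm) * hardware.gain_pd1
            raw2 = relative_intensity(medium, geom.rho2_cm) * hardware.gain_pd2
            grad = absorbance_gradient_estimate(raw1, raw2, geom, cal)
            kmua[lam], _ = kmua_from_gradient(
                grad, geom.log_mean_rho_cm, scattering.h_at(lam), lam
            )
        s, _ = sto2_from_concentrations(
            hemoglobin_solve(*[kmua[lam] for lam in geom.wavelengths], spectra)
        )
        return s

    base = invert(ChannelCalibration(1.0, 4.3))
    scaled = invert(ChannelCalibration(scale, 4.3 * scale))
    assert scaled == pytest.approx(base, abs=1e-9)
    lopsided = invert(ChannelCalibration(1.0, 4.3 * 1.5))
    assert abs(lopsided - base) > 1e-3


class TestPipeline:
    def _run(self, profile, noise=None, **kwargs):
        raw = generate_raw_stream(profile, noise=noise or NoiseModel.off())
        frames = demultiplex(raw)
        return sto2_pipeline(frames, **kwargs)

    def test_constant_saturation_recovered(self):
        res = self._run(
            PhysioProfile(
                segments=(Segment(30.0, 0.70),), pulse_fraction=0.0, resp_fraction=0.0
            )
        )
        tail = res.sto2[res.time_s > 10.0]
        assert np.nanmax(np.abs(tail - 0.70)) <= 0.02

    def test_pure_oxyhemoglobin_saturates_at_one(self):
        res = self._run(
            PhysioProfile(
                segments=(Segment(20.0, 1.0),), pulse_fraction=0.0, resp_fraction=0.0
            )
        )
        tail = res.sto2[res.time_s > 10.0]
        assert np.nanmin(tail) >= 0.99
        assert np.nanmax(tail) <= 1.0

    def test_ischemia_step_transition(self):
        """A commanded 0.70 -> 0.40 step settles within the smoothing
        window plus filter memory, transitioning monotonically."""
        profile = PhysioProfile(
            segments=(Segment(20.0, 0.70), Segment(25.0, 0.40)),
            pulse_fraction=0.0,
            resp_fraction=0.0,
            transition_tau_s=0.0,
        )
        res = self._run(profile)
        before = res.sto2[(res.time_s > 15.0) & (res.time_s < 19.9)]
        after = res.sto2[res.time_s > 32.0]
        assert np.nanmax(np.abs(before - 0.70)) <= 0.02
        assert np.nanmax(np.abs(after - 0.40)) <= 0.02
        during = res.sto2[(res.time_s >= 19.9) & (res.time_s <= 32.0)]
        assert np.all(np.diff(during) <= 1e-3)  # monotone within jitter

    def test_isolated_bad_samples_flagged_not_fatal(self):
        profile = PhysioProfile(
            segments=(Segment(20.0, 0.7),), pulse_fraction=0.0, resp_fraction=0.0
        )
        raw = generate_raw_stream(profile, noise=NoiseModel.off())
        frames = demultiplex(raw)
        frames.loc[200, "i660_pd1"] = np.nan
        res = sto2_pipeline(frames)
        assert res.flags[200] & StO2Result.FLAG_INVALID_INPUT
        assert np.isfinite(res.sto2[res.time_s > 10.0]).any()

    def test_output_in_unit_interval_or_flagged(self):
        profile = PhysioProfile(segments=(Segment(20.0, 0.7),))
        raw = generate_raw_stream(profile, noise=NoiseModel(sd_rel=0.05, seed=9))
        res = sto2_pipeline(demultiplex(raw))
        good = res.flags == 0
        assert np.all((res.sto2[good] >= 0) & (res.sto2[good] <= 1))

    def test_requires_window_of_data(self):
        profile = PhysioProfile(segments=(Segment(3.0, 0.7),))
        raw = generate_raw_stream(profile, noise=NoiseModel.off())
        with pytest.raises(ValueError, match="smoothing window"):
            sto2_pipeline(demultiplex(raw))


class TestMbll:
    def test_no_change_fixed_point(self):
        state = MbllState(0.6, 1.0, 5.0)
        sto2, valid = mbll_sto2(state, 0.0, 0.0)
        assert valid and sto2 == pytest.approx(0.6, rel=1e-12)

    def test_direct_arithmetic_example(self, spectra):
        """Concentration deltas (+0.1 HbO2, -0.1 Hb) on a 0.6/1.0 baseline
        give 0.70 exactly."""
        state = MbllState(0.6, 1.0, 5.0)
        mat = spectra.extinction_matrix()
        delta_a = mat @ np.array([-0.1, 0.1]) * state.pathlengths()[0]
        sto2, valid = mbll_sto2(state, delta_a[0], delta_a[1], spectra)
        assert valid and sto2 == pytest.approx(0.70, rel=1e-9)

    def test_negative_denominator_flagged(self, spectra):
        state = MbllState(0.5, 0.1, 1.0)
        mat = spectra.extinction_matrix()
        delta_a = mat @ np.array([-1.0, -1.0]) * 1.0  # huge washout
        sto2, valid = mbll_sto2(state, delta_a[0], delta_a[1], spectra)
        assert not valid and np.isnan(sto2)

    def test_cross_method_consistency(self, geom, scattering, spectra):
        """On model-consistent synthetic data (small saturation excursion,
        per-wavelength differential pathlengths from the diffusion model),
        the single-detector MBLL route agrees with the spatially resolved
        route within 0.03."""
        c_tot = 0.9
        sto2_t = np.concatenate([np.full(40, 0.70), np.linspace(0.70, 0.60, 60)])
        mu_a = {
            lam: absorption_from_concentrations(
                (1 - sto2_t) * c_tot, sto2_t * c_tot, spectra, lam
            )
            for lam in geom.wavelengths
        }
        # per-wavelength DPL at baseline: dA/dmu_a at the near detector
        pathlengths = []
        a_t = {}
        for lam in geom.wavelengths:
            musp = scattering.reduced_scattering(lam)
            mu_eff = np.sqrt(3.0 * mu_a[lam] * musp)
            intensity = np.exp(-mu_eff * geom.rho1_cm) / geom.rho1_cm**2
            a_t[lam] = -np.log10(intensity / intensity[0])
            dpf = 3.0 * musp / (2.0 * np.sqrt(3.0 * mu_a[lam][0] * musp))
            pathlengths.append(geom.rho1_cm * dpf)
        state = MbllState(0.70, c_tot, tuple(pathlengths))
        mb, valid = mbll_sto2(
            state, a_t[geom.wavelengths[0]], a_t[geom.wavelengths[1]], spectra
        )
        assert valid.all()
        srs = np.array(
            [
                _chain_sto2(float(s), c_tot, geom, scattering, spectra)
                for s in sto2_t
            ]
        )
        assert np.max(np.abs(mb - srs)) <= 0.03
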