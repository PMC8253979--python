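"""Denaturation transitions: λ_max extraction, sigmoid and Gaussian fits."""

import numpy as np
import pytest

from moltenfit.containers import EmissionSpectrum
from moltenfit.errors import AlignmentError, FitError
from moltenfit.simulate import BandModel, NoiseModel, gen_spectral_series
from moltenfit.transitions import (
    BoundaryMaximumWarning,
    GaussianProfile,
    SigmoidTransition,
    extract_lambda_max,
    fit_gaussian_profile,
    fit_sigmoid_transition,
    subtract_blank,
    transition_profile,
)

WL = np.arange(250.0, 470.0, 1.0)


def gaussian_spectrum(center, sd=20.0, amp=1.0, offset=0.0):
    inten = offset + amp * np.exp(-0.5 * ((WL - center) / sd) ** 2)
    return EmissionSpectrum(wavelength=WL, intensity=inten)


class TestSubtractBlank:
    def test_self_subtraction_zeroes(self):
        sp = gaussian_spectrum(336.0)
        out = subtract_blank(sp, sp)
        assert np.allclose(out.intensity, 0.0)

    def test_zero_blank_identity(self):
        sp = gaussian_spectrum(336.0)
        blank = EmissionSpectrum(wavelength=WL, intensity=np.zeros_like(WL))
        out = subtract_blank(sp, blank)
        assert np.allclose(out.intensity, sp.intensity)

    def test_constant_blank_restores_band(self):
        band = gaussian_spectrum(340.0)
        shifted = EmissionSpectrum(wavelength=WL,
                                   intensity=band.intensity + 0.37)
        blank = EmissionSpectrum(wavelength=WL,
                                 intensity=np.full(WL.size, 0.37))
        out = subtract_blank(shifted, blank)
        assert np.allclose(out.intensity, band.intensity)

    def test_grid_mismatch(self):
        sp = gaussian_spectrum(336.0)
        other = EmissionSpectrum(wavelength=WL + 0.5,
                                 intensity=np.ones_like(WL))
        with pytest.raises(AlignmentError):
            subtract_blank(sp, other)


class TestExtractLambdaMax:
    def test_symmetric_band_exact(self):
        assert extract_lambda_max(gaussian_spectrum(336.0)) == pytest.approx(
            336.0, abs=0.1
        )

    def test_off_grid_center(self):
        assert extract_lambda_max(
            gaussian_spectrum(336.4)
        ) == pytest.approx(336.4, abs=0.1)

    def test_lognormal_analytic_mode(self):
        band = BandModel(center=351.0, shape="lognormal")
        sp = EmissionSpectrum(wavelength=WL, intensity=band.profile(WL))
        assert extract_lambda_max(sp) == pytest.approx(351.0, abs=0.3)

    def test_flat_spectrum_boundary_warning(self):
        sp = EmissionSpectrum(wavelength=WL, intensity=np.linspace(0, 1,
                                                                   WL.size))
        with pytest.warns(BoundaryMaximumWarning):
            extract_lambda_max(sp)

    def test_scale_equivariance_and_offset_invariance(self):
        sp = gaussian_spectrum(340.0)
        scaled = EmissionSpectrum(wavelength=WL,
                                  intensity=7.3 * sp.intensity)
        offset = EmissionSpectrum(wavelength=WL,
                                  intensity=sp.intensity + 2.0)
        base = extract_lambda_max(sp)
        assert extract_lambda_max(scaled) == pytest.approx(base, abs=1e-9)
        assert extract_lambda_max(offset) == pytest.approx(base, abs=1e-9)


class TestSigmoidTransition:
    TRUTH = dict(lambda_n=336.0, lambda_u=361.0, midpoint=2.0, width=0.2)

    def profile(self, **over):
        p = {**self.TRUTH, **over}
        d = np.arange(0, 4.01, 0.4)
        lam = SigmoidTransition.model(d, p["lambda_n"], p["lambda_u"],
                                      p["midpoint"], p["width"])
        return np.column_stack([d, lam])

    def test_zero_noise_exact_recovery(self):
        fit = fit_sigmoid_transition(self.profile(), n_bootstrap=0)
        assert fit.lambda_n_ == pytest.approx(336.0, abs=1e-4)
        assert fit.lambda_u_ == pytest.approx(361.0, abs=1e-4)
        assert fit.midpoint_ == pytest.approx(2.0, abs=1e-4)
        assert fit.width_ == pytest.approx(0.2, abs=1e-4)

    def test_midpoint_value_is_mean_of_asymptotes(self):
        fit = fit_sigmoid_transition(self.profile(), n_bootstrap=0)
        mid_lam = fit.predict([fit.midpoint_])[0]
        assert mid_lam == pytest.approx(
            (fit.lambda_n_ + fit.lambda_u_) / 2, abs=1e-9
        )

    def test_midpoint_slope_matches_numerical_derivative(self):
        fit = fit_sigmoid_transition(self.profile(), n_bootstrap=0)
        h = 1e-6
        num = (fit.predict([fit.midpoint_ + h])[0]
               - fit.predict([fit.midpoint_ - h])[0]) / (2 * h)
        assert fit.midpoint_slope_ == pytest.approx(num, rel=1e-5)

    def test_low_cooperativity_flag(self):
        steep = fit_sigmoid_transition(self.profile(width=0.2),
                                       n_bootstrap=0)
        shallow = fit_sigmoid_transition(self.profile(width=1.5),
                                         n_bootstrap=0)
        assert not steep.low_cooperativity_
        assert shallow.low_cooperativity_

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_sigmoid_transition(self.profile()[:5], n_bootstrap=0)


class TestGaussianProfile:
    def test_closed_form_peak_height(self):
        # unit area, unit FWHM: height sqrt(4 ln2 / pi)
        h = GaussianProfile.model(0.0, 0.0, 1.0, 0.0, 1.0)
        assert h == pytest.approx(np.sqrt(4 * np.log(2) / np.pi), rel=1e-12)

    def test_fwhm_definition(self):
        y0, area, xc, w = 0.2, 3.0, 1.5, 1.0
        peak = GaussianProfile.model(xc, y0, area, xc, w)
        half = GaussianProfile.model(xc + w / 2, y0, area, xc, w)
        assert half - y0 == pytest.approx((peak - y0) / 2, rel=1e-12)

    def test_zero_noise_exact_recovery(self):
        x = np.linspace(0, 4, 11)
        y = GaussianProfile.model(x, 0.2, 3.0, 1.5, 1.0)
        fit = fit_gaussian_profile(np.column_stack([x, y]))
        assert fit.y0_ == pytest.approx(0.2, abs=1e-6)
        assert fit.area_ == pytest.approx(3.0, rel=1e-6)
        assert fit.center_ == pytest.approx(1.5, abs=1e-6)
        assert fit.fwhm_ == pytest.approx(1.0, rel=1e-6)

    def test_monotone_profile_suggests_sigmoid(self):
        x = np.linspace(0, 4, 11)
        with pytest.raises(FitError, match="sigmoid"):
            fit_gaussian_profile(np.column_stack([x, x * 2 + 1]))


class TestTransitionProfile:
    def test_row_per_denaturant_point(self, trp_band, noiseless):
        series = gen_spectral_series(336, 361, 2.0, 0.3, trp_band,
                                     [0.0, 4.0], WL, noiseless)
        prof = transition_profile(series)
        assert prof.shape == (2, 2)

    def test_constant_center_constant_profile(self, trp_band, noiseless):
        series = gen_spectral_series(340, 340.0001, 2.0, 0.3, trp_band,
                                     np.arange(0, 4.01, 0.4), WL, noiseless)
        prof = transition_profile(series)
        assert np.ptp(prof[:, 1]) < 0.3

    def test_intensity_mode_reads_fixed_wavelength(self, trp_band,
                                                   noiseless):
        series = gen_spectral_series(336, 361, 2.0, 0.3, trp_band,
                                     np.arange(0, 4.01, 0.4), WL, noiseless,
                                     attenuation_per_m=0.2)
        prof = transition_profile(series, mode="intensity",
                                  at_wavelength=336.0)
        # intensity at the native maximum decreases as the band red-shifts
        # and attenuates
        assert prof[0, 1] > prof[-1, 1]
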