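"""TCSPC: convolution, reconvolution fits, anisotropy, hydrodynamics."""

import numpy as np
import pytest

from moltenfit.containers import DecayHistogram, PolarizedDecays
from moltenfit.errors import ParameterError
from moltenfit.simulate import (
    NoiseModel,
    gen_decay,
    gen_irf,
    gen_polarized_decays,
)
from moltenfit.timeresolved import (
    AnisotropyDecay,
    HydrodynamicParams,
    ReconvolutionLifetime,
    anisotropy_from_polarized,
    average_lifetime,
    choose_n_components,
    convolve_model,
    fit_anisotropy_decay,
    fit_reconvolution,
    predicted_rotational_correlation,
)


def delta_irf(n=400, dt=0.055):
    counts = np.zeros(n, dtype=int)
    counts[0] = 1_000_000
    return DecayHistogram(counts=counts, channel_width=dt, role="irf")


def brute_force_convolution(irf_counts, decay_curve):
    """O(n²) double-loop oracle for the causal discrete convolution."""
    irf_area = np.asarray(irf_counts, float) / np.sum(irf_counts)
    n = len(decay_curve)
    out = np.zeros(n)
    for k in range(n):
        for j in range(k + 1):
            out[k] += irf_area[j] * decay_curve[k - j]
    return out


class TestConvolveModel:
    def test_delta_irf_identity(self):
        irf = delta_irf()
        t = irf.times
        model = convolve_model(irf, [(1.0, 2.0)])
        assert np.allclose(model, np.exp(-t / 2.0), rtol=1e-12)

    def test_linearity(self):
        irf = gen_irf(1.0, 3.0, 400, 0.055)
        one = convolve_model(irf, [(1.0, 2.84)])
        two = convolve_model(irf, [(2.0, 2.84)])
        assert np.allclose(two, 2 * one, rtol=1e-12)

    def test_against_brute_force_oracle(self):
        irf = gen_irf(1.0, 3.0, 700, 0.055)
        t = irf.times
        curve = 1.7 * np.exp(-t / 2.84) + 0.4 * np.exp(-t / 0.9)
        oracle = brute_force_convolution(irf.counts, curve)
        model = convolve_model(irf, [(1.7, 2.84), (0.4, 0.9)])
        assert np.allclose(model, oracle, rtol=1e-10, atol=1e-12)

    def test_shift_limits(self):
        irf = delta_irf()
        with pytest.raises(ParameterError):
            convolve_model(irf, [(1.0, 2.0)], shift=0.056 * 11)

    def test_empty_components(self):
        with pytest.raises(ParameterError):
            convolve_model(delta_irf(), [])


class TestReconvolutionFit:
    def test_zero_noise_identity(self, small_irf):
        decay = gen_decay(small_irf, [(1.0, 2.84)], 10_000,
                          NoiseModel(seed=0))
        fit = fit_reconvolution(decay, small_irf, 1, random_state=0)
        assert fit.lifetimes_[0] == pytest.approx(2.84, rel=1e-3)
        assert fit.chi2_red_ < 0.05

    def test_poisson_recovery_and_chi2(self, full_irf):
        decay = gen_decay(full_irf, [(1.0, 2.84)], 10_000,
                          NoiseModel(poisson=True, seed=42))
        fit = fit_reconvolution(decay, full_irf, 1, random_state=0)
        assert fit.lifetimes_[0] == pytest.approx(2.84, rel=0.03)
        assert 0.8 <= fit.chi2_red_ <= 1.2

    def test_model_mismatch_inflates_chi2(self, small_irf):
        decay = gen_decay(small_irf, [(1.0, 0.8), (1.0, 5.0)], 50_000,
                          NoiseModel(poisson=True, seed=7))
        under = fit_reconvolution(decay, small_irf, 1, random_state=0)
        right = fit_reconvolution(decay, small_irf, 2, random_state=0)
        assert under.chi2_red_ > 3.0
        assert right.chi2_red_ < 1.5

    def test_component_selection(self, small_irf):
        decay = gen_decay(small_irf, [(1.0, 0.8), (1.0, 5.0)], 50_000,
                          NoiseModel(poisson=True, seed=7))
        fit = choose_n_components(decay, small_irf, max_components=3)
        assert fit.lifetimes_.size == 2

    def test_chi2_calibration_over_replicates(self, small_irf):
        # correct-model Neyman chi2 on Poisson data averages to ~1
        chis = []
        for seed in range(100):
            decay = gen_decay(small_irf, [(1.0, 2.84)], 10_000,
                              NoiseModel(poisson=True, seed=seed))
            fit = fit_reconvolution(decay, small_irf, 1, random_state=0)
            chis.append(fit.chi2_red_)
        assert 0.9 <= np.mean(chis) <= 1.1


class TestAverageLifetime:
    def make(self, amps, taus):
        fit = ReconvolutionLifetime()
        fit.amplitudes_ = np.asarray(amps, float)
        fit.lifetimes_ = np.asarray(taus, float)
        return fit

    def test_single_component_both_weightings(self):
        fit = self.make([0.7], [3.2])
        assert average_lifetime(fit, "amplitude") == pytest.approx(3.2)
        assert average_lifetime(fit, "intensity") == pytest.approx(3.2)

    def test_hand_arithmetic(self):
        fit = self.make([0.5, 0.5], [2.0, 4.0])
        assert average_lifetime(fit, "amplitude") == pytest.approx(3.0)
        assert average_lifetime(fit, "intensity") == pytest.approx(10 / 3)

    def test_chebyshev_ordering(self, rng):
        for _ in range(50):
            k = rng.integers(1, 5)
            fit = self.make(rng.uniform(0.1, 2, k), rng.uniform(0.1, 30, k))
            assert average_lifetime(fit, "amplitude") <= average_lifetime(
                fit, "intensity"
            ) + 1e-12


class TestAnisotropyConstruction:
    def test_balanced_channels_zero_r(self):
        counts = np.full(100, 400)
        pol = PolarizedDecays(
            parallel=DecayHistogram(counts=counts, channel_width=0.055),
            perpendicular=DecayHistogram(counts=counts,
                                         channel_width=0.055),
            g_factor=1.0,
        )
        _, r, _ = anisotropy_from_polarized(pol)
        assert np.allclose(r, 0.0)

    def test_hand_value(self):
        pol = PolarizedDecays(
            parallel=DecayHistogram(counts=np.full(10, 300),
                                    channel_width=0.055),
            perpendicular=DecayHistogram(counts=np.full(10, 100),
                                         channel_width=0.055),
            g_factor=1.0,
        )
        _, r, _ = anisotropy_from_polarized(pol)
        assert np.allclose(r, 0.4)

    def test_magic_angle_recomposition(self, small_irf):
        pol = gen_polarized_decays([(1.0, 5.0)], 0.0, [(0.25, 26.0)], 1.0,
                                   small_irf, 100_000, NoiseModel(seed=0))
        total = (pol.parallel.meta["expected"]
                 + 2.0 * pol.g_factor * pol.perpendicular.meta["expected"])
        # total intensity is the IRF-convolved isotropic decay: fitting it
        # returns the lifetime with no anisotropy contamination
        decay = DecayHistogram(counts=np.round(total).astype(int),
                               channel_width=small_irf.channel_width)
        fit = fit_reconvolution(decay, small_irf, 1, random_state=0)
        assert fit.lifetimes_[0] == pytest.approx(5.0, rel=0.01)


class TestAnisotropyFit:
    def test_zero_noise_exact_recovery(self):
        t = np.arange(0, 40, 0.055)
        r = 0.25 * np.exp(-t / 26.0)
        fit = fit_anisotropy_decay(t, r, n_components=1)
        assert fit.thetas_[0] == pytest.approx(26.0, rel=1e-6)
        assert fit.amplitudes_[0] == pytest.approx(0.25, rel=1e-6)
        assert fit.r_inf_ == pytest.approx(0.0, abs=1e-8)

    def test_two_component_ordering(self):
        t = np.arange(0, 60, 0.055)
        r = 0.12 * np.exp(-t / 1.0) + 0.13 * np.exp(-t / 33.0)
        fit = fit_anisotropy_decay(t, r, n_components=2)
        assert fit.thetas_[0] == pytest.approx(1.0, rel=0.01)
        assert fit.thetas_[1] == pytest.approx(33.0, rel=0.01)

    def test_poisson_recovery(self, full_irf):
        pol = gen_polarized_decays([(1.0, 5.0)], 0.0, [(0.25, 26.0)], 1.0,
                                   full_irf, 100_000,
                                   NoiseModel(poisson=True, seed=5))
        t, r, s = anisotropy_from_polarized(pol)
        peak_t = pol.parallel.times[np.argmax(pol.parallel.meta["expected"])]
        fit = fit_anisotropy_decay(t, r, sigma=s, n_components=1,
                                   window=(peak_t + 1.0, peak_t + 30.0))
        assert fit.thetas_[0] == pytest.approx(26.0, rel=0.2)

    def test_r0_limit_enforced_by_generator(self, small_irf):
        with pytest.raises(ParameterError):
            gen_polarized_decays([(1.0, 5.0)], 0.0, [(0.45, 26.0)], 1.0,
                                 small_irf, 1000, NoiseModel(seed=0))


class TestHydrodynamics:
    def test_mass_42_kda(self):
        assert predicted_rotational_correlation(42.0) == pytest.approx(
            16.6, abs=0.2
        )

    def test_linear_in_mass_and_viscosity_inverse_in_temperature(self):
        base = predicted_rotational_correlation(50.0)
        assert predicted_rotational_correlation(100.0) == pytest.approx(
            2 * base
        )
        visc = HydrodynamicParams(viscosity=2 * 1.002)
        assert predicted_rotational_correlation(50.0, visc) == pytest.approx(
            2 * base
        )
        hot = HydrodynamicParams(temperature=2 * 293.0)
        assert predicted_rotational_correlation(50.0, hot) == pytest.approx(
            base / 2
        )

    def test_zero_mass_limit(self):
        assert predicted_rotational_correlation(0.0) == 0.0
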