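"""Generators: zero-noise identities, determinism, photon statistics."""

import numpy as np
import pytest

from moltenfit.binding import predict_anisotropy
from moltenfit.errors import ParameterError
from moltenfit.simulate import (
    BandModel,
    NoiseModel,
    gen_decay,
    gen_irf,
    gen_polarized_decays,
    gen_quench_series,
    gen_spectral_series,
    gen_titration,
)

WL = np.arange(250.0, 470.0, 1.0)


class TestTitrationGenerator:
    def test_zero_noise_matches_isotherm(self):
        grid = np.linspace(0, 40, 12)
        curve = gen_titration(2.5, 0.18, 0.26, 1.2, grid, NoiseModel(seed=0))
        assert np.allclose(curve.r,
                           predict_anisotropy(1.2, grid, 2.5, 0.18, 0.26))

    def test_t0_zero_gives_free_anisotropy(self):
        grid = np.array([0.0, 1, 2, 4, 8, 16])
        curve = gen_titration(2.5, 0.18, 0.26, 1.2, grid, NoiseModel(seed=0))
        assert curve.r[0] == pytest.approx(0.18)

    def test_monotone_when_r_at_larger(self):
        grid = np.linspace(0, 40, 20)
        curve = gen_titration(2.5, 0.18, 0.26, 1.2, grid, NoiseModel(seed=0))
        assert np.all(np.diff(curve.r) >= -1e-12)

    def test_invalid_kd(self):
        with pytest.raises(ParameterError):
            gen_titration(-1.0, 0.18, 0.26, 1.2, np.linspace(0, 40, 12),
                          NoiseModel(seed=0))

    def test_deterministic_given_seed(self):
        grid = np.linspace(0, 40, 12)
        nm = NoiseModel(additive_sd=0.004, seed=9)
        a = gen_titration(2.5, 0.18, 0.26, 1.2, grid, nm)
        b = gen_titration(2.5, 0.18, 0.26, 1.2, grid, nm)
        assert np.array_equal(a.r, b.r)


class TestSpectralGenerator:
    def test_low_denaturant_band_at_native(self, trp_band):
        series = gen_spectral_series(336, 361, 2.0, 0.2, trp_band, [0.0],
                                     WL, NoiseModel(seed=0))
        sp = series.spectra[0]
        grid_max = sp.wavelength[np.argmax(sp.intensity)]
        assert abs(grid_max - 336.0) <= 1.0

    def test_high_denaturant_band_at_unfolded(self, trp_band):
        series = gen_spectral_series(336, 361, 2.0, 0.2, trp_band, [40.0],
                                     WL, NoiseModel(seed=0))
        sp = series.spectra[0]
        grid_max = sp.wavelength[np.argmax(sp.intensity)]
        assert abs(grid_max - 361.0) <= 1.0

    def test_window_margin_enforced(self, trp_band):
        with pytest.raises(ParameterError):
            gen_spectral_series(336, 361, 2.0, 0.2, trp_band, [0.0],
                                np.arange(300.0, 380.0, 1.0),
                                NoiseModel(seed=0))


class TestQuenchGenerator:
    def test_intercept_exact(self):
        qs = gen_quench_series(1.98, 0.0, np.array([0.0, 0.1, 0.2, 0.3,
                                                    0.4, 0.5]),
                               NoiseModel(seed=0))
        assert qs.ratio[0] == 1.0

    def test_pure_dynamic_hand_value(self):
        qs = gen_quench_series(2.0, 0.0, np.array([0.0, 0.5]) ,
                               NoiseModel(seed=0))
        assert qs.ratio[1] == pytest.approx(2.0)

    def test_product_hand_value(self):
        qs = gen_quench_series(1.0, 1.0, np.array([0.0, 1.0]),
                               NoiseModel(seed=0))
        assert qs.ratio[1] == pytest.approx(4.0)

    def test_negative_constant_rejected(self):
        with pytest.raises(ParameterError):
            gen_quench_series(-0.5, 0.0, np.array([0.0, 0.5]),
                              NoiseModel(seed=0))


class TestIRFGenerator:
    def test_mode_at_t0(self):
        irf = gen_irf(1.0, 5.0, 400, 0.055)
        mode = irf.times[np.argmax(irf.counts)]
        assert abs(mode - 5.0) <= 0.055

    def test_total_counts_normalization(self):
        irf = gen_irf(1.0, 5.0, 400, 0.055, total_counts=10**6)
        assert abs(irf.total_counts - 10**6) <= 400  # per-channel rounding

    def test_symmetry_about_t0(self):
        irf = gen_irf(1.0, 11.0, 801, 0.055)
        k0 = int(np.argmax(irf.counts))
        left = irf.counts[k0 - 50 : k0]
        right = irf.counts[k0 + 1 : k0 + 51][::-1]
        assert np.allclose(left, right, atol=2)

    def test_narrow_fwhm_warns(self):
        with pytest.warns(UserWarning):
            gen_irf(0.01, 5.0, 400, 0.055)


class TestDecayGenerator:
    def test_poisson_off_equals_expected(self, small_irf):
        decay = gen_decay(small_irf, [(1.0, 2.84)], 5000, NoiseModel(seed=0))
        assert np.array_equal(decay.counts,
                              np.round(decay.meta["expected"]).astype(int))

    def test_peak_normalization(self, small_irf):
        decay = gen_decay(small_irf, [(1.0, 2.84)], 5000, NoiseModel(seed=0))
        assert decay.meta["expected"].max() == pytest.approx(5000)

    def test_seed_isolation(self, small_irf):
        a = gen_decay(small_irf, [(1.0, 2.84)], 5000,
                      NoiseModel(poisson=True, seed=1))
        b = gen_decay(small_irf, [(1.0, 2.84)], 5000,
                      NoiseModel(poisson=True, seed=2))
        assert not np.array_equal(a.counts, b.counts)
        assert np.allclose(a.meta["expected"], b.meta["expected"])

    def test_poisson_variance_matches_mean(self):
        # var ≈ mean per channel across 200 replicates, within 3σ of the
        # sampling spread of a variance estimate
        irf = gen_irf(1.0, 2.0, 160, 0.055)
        reps = np.stack([
            gen_decay(irf, [(1.0, 2.0)], 2000,
                      NoiseModel(poisson=True, seed=s)).counts
            for s in range(200)
        ])
        mean = reps.mean(axis=0)
        var = reps.var(axis=0, ddof=1)
        pick = mean > 100
        z = (var[pick] / mean[pick] - 1.0) / np.sqrt(2.0 / 199)
        assert np.abs(z.mean()) < 3.0 / np.sqrt(pick.sum())
        assert np.all(np.abs(z) < 5.0)


class TestPolarizedGenerator:
    def test_isotropic_truth_gives_identical_channels(self, small_irf):
        pol = gen_polarized_decays([(1.0, 5.0)], 0.0, [(0.0, 26.0)], 1.0,
                                   small_irf, 10_000, NoiseModel(seed=0))
        assert np.allclose(pol.parallel.meta["expected"],
                           pol.perpendicular.meta["expected"], rtol=1e-12)

    def test_limiting_anisotropy_ratio_three(self, small_irf):
        pol = gen_polarized_decays([(1.0, 5.0)], 0.4, [], 1.0, small_irf,
                                   10_000, NoiseModel(seed=0))
        exp_par = pol.parallel.meta["expected"]
        exp_perp = pol.perpendicular.meta["expected"]
        good = exp_perp > 1e-6 * exp_perp.max()
        assert np.allclose(exp_par[good] / exp_perp[good], 3.0, rtol=1e-9)

    def test_magic_angle_identity(self, small_irf):
        pol = gen_polarized_decays([(1.0, 5.0)], 0.0, [(0.25, 26.0)], 0.8,
                                   small_irf, 10_000, NoiseModel(seed=0))
        total = (pol.parallel.meta["expected"]
                 + 2 * 0.8 * pol.perpendicular.meta["expected"])
        t = small_irf.times
        from moltenfit.timeresolved import convolve_model

        iso = convolve_model(small_irf, [(1.0, 5.0)])
        scale = total.max() / iso.max()
        assert np.allclose(total, scale * iso, rtol=1e-9, atol=1e-9)
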