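"""Synthetic-data generators for every assay the pipeline consumes.

Each generator produces data with the statistical structure the
corresponding analysis assumes — mass-action binding with additive
anisotropy noise, a two-state spectral shift with additive per-point
noise, multiplicative noise on self-normalized quench ratios, and Poisson
photon counts convolved with a finite-width IRF — and embeds the ground
truth in the container metadata so that parameter-recovery tests need no
side channel. All generators are deterministic given (seed, parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .binding import predict_anisotropy
from .containers import (
    DecayHistogram,
    EmissionSpectrum,
    PolarizedDecays,
    QuenchSeries,
    SpectralSeries,
    TitrationCurve,
)
from .errors import ParameterError
from .timeresolved import convolve_model
from .transitions import SigmoidTransition

__all__ = [
    "BandModel",
    "NoiseModel",
    "gen_titration",
    "gen_spectral_series",
    "gen_quench_series",
    "gen_irf",
    "gen_decay",
    "gen_polarized_decays",
]


@dataclass
class BandModel:
    """An emission band with its mode at ``center``.

    ``width`` is a Gaussian-σ-like scale: ``shape='gaussian'`` uses
    exp(−(λ−c)²/(2w²)); ``shape='lognormal'`` uses the asymmetric
    (Siano-type) log-normal band exp(−ln2·[ln(1 + 2b(λ−c)/W)/b]²) with
    W = 2·sqrt(2 ln2)·w, whose mode is also exactly at the center —
    realistic for tryptophan emission, which tails to the red. The
    default width of 25 nm (≈59 nm FWHM) matches a typical tryptophan
    emission band.
    """

    center: float
    width: float = 25.0
    amplitude: float = 1.0
    shape: str = "lognormal"
    asymmetry: float = 0.4

    def __post_init__(self):
        if not self.width > 0:
            raise ParameterError("band width must be positive")
        if self.amplitude < 0:
            raise ParameterError("band amplitude must be non-negative")
        if self.shape not in ("gaussian", "lognormal"):
            raise ParameterError("shape must be 'gaussian' or 'lognormal'")

    def profile(self, wavelength, center: Optional[float] = None
                ) -> np.ndarray:
        """Band intensity on a wavelength grid, optionally re-centered."""
        c = self.center if center is None else center
        wl = np.asarray(wavelength, dtype=float)
        if self.shape == "gaussian":
            return self.amplitude * np.exp(
                -((wl - c) ** 2) / (2.0 * self.width**2)
            )
        b = self.asymmetry
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.width
        arg = 1.0 + 2.0 * b * (wl - c) / fwhm
        out = np.zeros_like(wl)
        ok = arg > 0
        out[ok] = self.amplitude * np.exp(
            -np.log(2.0) * (np.log(arg[ok]) / b) ** 2
        )
        return out


@dataclass
class NoiseModel:
    """Noise settings shared by the generators.

    additive_sd applies to spectra and anisotropy readings,
    multiplicative_sd to quench ratios; ``poisson`` turns on per-channel
    Poisson sampling of photon-count histograms.
    """

    additive_sd: float = 0.0
    multiplicative_sd: float = 0.0
    poisson: bool = False
    seed: Optional[int] = None

    def __post_init__(self):
        if self.additive_sd < 0 or self.multiplicative_sd < 0:
            raise ParameterError("noise standard deviations must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_titration(kd: float, r_a: float, r_at: float, a0: float,
                  grid, noise: NoiseModel) -> TitrationCurve:
    """Anisotropy titration from the quadratic isotherm plus additive
    Gaussian noise. Truth parameters are stored in ``meta['truth']``."""
    if kd <= 0:
        raise ParameterError("kd must be positive")
    if a0 <= 0:
        raise ParameterError("a0 must be positive")
    grid = np.asarray(grid, dtype=float)
    if grid.size < 6 or np.any(grid < 0):
        raise ParameterError("grid must have >= 6 non-negative points")
    r = predict_anisotropy(a0, grid, kd, r_a, r_at)
    if noise.additive_sd > 0:
        r = r + noise.rng().normal(0.0, noise.additive_sd, size=r.size)
    return TitrationCurve(
        a0=a0, t0=grid, r=r,
        meta={"truth": {"kd": kd, "r_a": r_a, "r_at": r_at, "a0": a0},
              "noise_sd": noise.additive_sd, "seed": noise.seed},
    )


def gen_spectral_series(lambda_n: float, lambda_u: float, midpoint: float,
                        width: float, band: BandModel, denaturant_grid,
                        wavelength_grid, noise: NoiseModel,
                        attenuation_per_m: float = 0.0) -> SpectralSeries:
    """Emission spectra whose band center follows the two-state sigmoid
    between ``lambda_n`` and ``lambda_u``.

    ``attenuation_per_m`` linearly scales the amplitude down with
    denaturant (fraction lost per M), emulating the intensity loss seen
    on unfolding. Additive Gaussian noise is applied per point.
    """
    wl = np.asarray(wavelength_grid, dtype=float)
    margin = 2.0 * band.width
    for lam in (lambda_n, lambda_u):
        if lam - wl[0] < margin or wl[-1] - lam < margin:
            raise ParameterError(
                "wavelength window must cover both asymptotes by two band "
                "widths"
            )
    dgrid = np.asarray(denaturant_grid, dtype=float)
    rng = noise.rng()
    spectra = []
    for d in dgrid:
        center = SigmoidTransition.model(d, lambda_n, lambda_u, midpoint,
                                         width)
        scale = max(1.0 - attenuation_per_m * d, 0.05)
        inten = scale * band.profile(wl, center=float(center))
        if noise.additive_sd > 0:
            inten = inten + rng.normal(0.0, noise.additive_sd, size=wl.size)
        spectra.append(EmissionSpectrum(
            wavelength=wl, intensity=inten, denaturant_m=float(d),
            meta={"truth_center": float(center)},
        ))
    series = SpectralSeries(spectra=spectra, denaturant=dgrid)
    series.spectra[0].meta["truth"] = {
        "lambda_n": lambda_n, "lambda_u": lambda_u,
        "midpoint": midpoint, "width": width, "seed": noise.seed,
    }
    return series


def gen_quench_series(k_dyn: float, k_static: float, grid,
                      noise: NoiseModel,
                      ratio_kind: str = "intensity") -> QuenchSeries:
    """Stern–Volmer ratios from the dynamic×static product model with
    multiplicative log-normal-free noise: ratio × (1 + ε), ε ~ N(0, sd)."""
    if k_dyn < 0 or k_static < 0:
        raise ParameterError("quenching constants must be non-negative")
    q = np.asarray(grid, dtype=float)
    if np.any(q < 0):
        raise ParameterError("quencher grid must be non-negative")
    ratio = (1.0 + k_dyn * q) * (1.0 + k_static * q)
    if noise.multiplicative_sd > 0:
        ratio = ratio * (
            1.0 + noise.rng().normal(0.0, noise.multiplicative_sd,
                                     size=q.size)
        )
    return QuenchSeries(
        q=q, ratio=ratio, ratio_kind=ratio_kind,
        meta={"truth": {"k_dyn": k_dyn, "k_static": k_static},
              "seed": noise.seed},
    )


def gen_irf(fwhm: float, t0: float, n_channels: int,
            channel_width: float = 0.055,
            total_counts: int = 1_000_000) -> DecayHistogram:
    """Gaussian instrument response function histogram.

    Deterministic (no sampling): the Gaussian profile is scaled to
    ``total_counts`` and rounded per channel.
    """
    if fwhm <= 0:
        raise ParameterError("fwhm must be positive")
    t = np.arange(n_channels) * channel_width
    if not t[0] <= t0 <= t[-1]:
        raise ParameterError("t0 outside the time window")
    if fwhm < channel_width:
        warnings.warn("IRF narrower than one channel", UserWarning)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    profile = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    counts = np.round(profile / profile.sum() * total_counts).astype(int)
    return DecayHistogram(counts=counts, channel_width=channel_width,
                          role="irf", meta={"fwhm": fwhm, "t0": t0})


def gen_decay(irf: DecayHistogram, components: Sequence,
              peak_counts: int, noise: NoiseModel) -> DecayHistogram:
    """Fluorescence decay: IRF ⊛ ΣAᵢexp(−t/τᵢ) scaled to ``peak_counts``
    at the model peak, Poisson-sampled per channel when the photon flag
    is on. The noise-free expected curve is stored in
    ``meta['expected']``."""
    components = list(components)
    if not components:
        raise ParameterError("component list is empty")
    for a, tau in components:
        if a <= 0 or tau <= 0:
            raise ParameterError("amplitudes and lifetimes must be positive")
    expected = np.maximum(convolve_model(irf, components), 0.0)
    expected = expected * (peak_counts / expected.max())
    if noise.poisson:
        counts = noise.rng().poisson(expected)
    else:
        counts = np.round(expected).astype(int)
    return DecayHistogram(
        counts=counts, channel_width=irf.channel_width, role="decay",
        meta={"expected": expected,
              "truth": {"components": components,
                        "peak_counts": peak_counts},
              "seed": noise.seed},
    )


def gen_polarized_decays(components: Sequence, r_inf: float,
                         aniso_components: Sequence, g_factor: float,
                         irf: DecayHistogram, peak_counts: int,
                         noise: NoiseModel) -> PolarizedDecays:
    """Matched polarized decays for anisotropy analysis.

    The isotropic decay I(t) = ΣAᵢexp(−t/τᵢ) is split into
    I_∥ ∝ I·(1+2r)/3 and I_⊥ ∝ I·(1−r)/3/G with
    r(t) = r∞ + Σaⱼexp(−t/θⱼ); each channel is convolved with the
    unit-area IRF, jointly scaled so the parallel expected peak equals
    ``peak_counts``, and Poisson-sampled when the photon flag is on. The
    division of the perpendicular channel by G at generation time is the
    package's single self-consistent convention: analysis-side
    multiplication by G restores the balance.
    """
    if g_factor <= 0:
        raise ParameterError("G-factor must be positive")
    t = irf.times
    r_t = np.full(t.size, float(r_inf))
    for a, theta in aniso_components:
        if theta <= 0:
            raise ParameterError("rotational correlation times must be > 0")
        r_t += a * np.exp(-t / theta)
    if r_t[0] > 0.4 + 1e-12:
        raise ParameterError("r(0) exceeds the one-photon limit of 0.4")
    if np.any(r_t < -0.2 - 1e-12) or np.any(r_t > 0.4 + 1e-12):
        raise ParameterError("r(t) outside [-0.2, 0.4] over the window")
    intensity = np.zeros(t.size)
    for a, tau in components:
        if a <= 0 or tau <= 0:
            raise ParameterError("amplitudes and lifetimes must be positive")
        intensity += a * np.exp(-t / tau)

    irf_area = irf.counts.astype(float) / irf.counts.sum()

    def _conv(curve):
        from scipy.signal import fftconvolve
        n = curve.size
        if n <= 256:
            return np.convolve(irf_area, curve)[:n]
        return fftconvolve(irf_area, curve)[:n]

    exp_par = np.maximum(_conv(intensity * (1.0 + 2.0 * r_t) / 3.0), 0.0)
    exp_perp = np.maximum(_conv(intensity * (1.0 - r_t) / 3.0), 0.0) / g_factor
    scale = peak_counts / exp_par.max()
    exp_par, exp_perp = exp_par * scale, exp_perp * scale
    rng = noise.rng()
    if noise.poisson:
        c_par = rng.poisson(exp_par)
        c_perp = rng.poisson(exp_perp)
    else:
        c_par = np.round(exp_par).astype(int)
        c_perp = np.round(exp_perp).astype(int)
    truth = {"components": list(components), "r_inf": r_inf,
             "aniso_components": list(aniso_components),
             "g_factor": g_factor, "seed": noise.seed}
    par = DecayHistogram(counts=c_par, channel_width=irf.channel_width,
                         role="decay",
                         meta={"expected": exp_par, "truth": truth})
    perp = DecayHistogram(counts=c_perp, channel_width=irf.channel_width,
                          role="decay",
                          meta={"expected": exp_perp, "truth": truth})
    return PolarizedDecays(parallel=par, perpendicular=perp,
                           g_factor=g_factor)
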