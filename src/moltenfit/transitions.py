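"""Chemical-denaturation transition analysis.

A folded protein's tryptophan emission maximum (λ_max) red-shifts as
denaturant exposes the fluorophores to solvent. The unfolding profile
λ_max(D) is summarized by a two-asymptote sigmoid

    λ(D) = λ_N + (λ_U − λ_N) / (1 + exp((x − D)/a))

where λ_N and λ_U are the native and unfolded emission maxima, x the
transition midpoint (M) and ``a`` the transition width (M) — inversely
proportional to the midpoint slope, (λ_U − λ_N)/(4a). A steep transition
(small ``a`` relative to the denaturant span) indicates cooperative
unfolding; a shallow one is the low-cooperativity signature of molten
globules. Non-monotone profiles (e.g. ANS emission of a globular control
that transiently populates a molten-globule state) are summarized by a
Gaussian peak instead.
"""

from __future__ import annotations

import warnings
from typing import Optional

import lmfit
import numpy as np
from sklearn.base import BaseEstimator

from .containers import EmissionSpectrum, SpectralSeries
from .errors import AlignmentError, FitError
from .errors import ParameterError

__all__ = [
    "subtract_blank",
    "extract_lambda_max",
    "transition_profile",
    "SigmoidTransition",
    "GaussianProfile",
    "fit_sigmoid_transition",
    "fit_gaussian_profile",
    "BoundaryMaximumWarning",
]


class BoundaryMaximumWarning(UserWarning):
    """The spectral maximum sits at the window edge; λ_max is unreliable."""


def subtract_blank(spectrum: EmissionSpectrum,
                   blank: EmissionSpectrum) -> EmissionSpectrum:
    """Subtract a blank (e.g. denaturant background) spectrum pointwise.

    Grids must match exactly. Negative intensities are allowed in the
    result and flagged in the metadata.
    """
    if spectrum.wavelength.size != blank.wavelength.size or not np.allclose(
        spectrum.wavelength, blank.wavelength
    ):
        raise AlignmentError("spectrum and blank wavelength grids differ")
    corrected = spectrum.intensity - blank.intensity
    meta = dict(spectrum.meta)
    meta["blank_subtracted"] = True
    if np.any(corrected < 0):
        meta["negative_after_blank"] = True
    return EmissionSpectrum(
        wavelength=spectrum.wavelength.copy(),
        intensity=corrected,
        excitation_nm=spectrum.excitation_nm,
        denaturant_m=spectrum.denaturant_m,
        meta=meta,
    )


def _smooth_quadratic(y: np.ndarray, window: int) -> np.ndarray:
    """Moving-window local quadratic (Savitzky–Golay style) smoothing."""
    from scipy.signal import savgol_filter

    window = min(window, y.size if y.size % 2 else y.size - 1)
    if window < 5:
        return y.astype(float)
    return savgol_filter(y, window_length=window, polyorder=2)


def extract_lambda_max(spectrum: EmissionSpectrum, window: int = 7) -> float:
    """Estimate the emission maximum wavelength at sub-grid resolution.

    Smooths with a local quadratic filter, then refines the argmax by
    parabolic interpolation through the three points around it. A maximum
    at the window edge triggers :class:`BoundaryMaximumWarning` and returns
    the edge wavelength.
    """
    if window % 2 == 0:
        raise ParameterError("smoothing window must be odd")
    wl, inten = spectrum.wavelength, spectrum.intensity
    if wl.size < 2 * window:
        raise ParameterError("spectrum too short for the smoothing window")
    smooth = _smooth_quadratic(inten, window)
    k = int(np.argmax(smooth))
    if k == 0 or k == wl.size - 1:
        warnings.warn(
            "spectral maximum at window edge", BoundaryMaximumWarning
        )
        return float(wl[k])
    # vertex of the local quadratic fitted over the window around the
    # smoothed argmax — far lower variance than a three-point parabola
    h = window // 2
    lo, hi = max(k - h, 0), min(k + h + 1, wl.size)
    x = wl[lo:hi] - wl[k]
    coef = np.polyfit(x, inten[lo:hi], 2)
    if coef[0] < 0:
        vertex = -coef[1] / (2.0 * coef[0])
        if abs(vertex) <= max(x[-1], -x[0]):
            return float(wl[k] + vertex)
    # degenerate curvature: fall back to the smoothed grid argmax
    return float(wl[k])


def transition_profile(series: SpectralSeries, mode: str = "lambda_max",
                       at_wavelength: Optional[float] = None,
                       window: int = 7) -> np.ndarray:
    """Reduce a spectral series to a (D, value) profile.

    ``mode='lambda_max'`` extracts the emission maximum per spectrum;
    ``mode='intensity'`` reads the intensity at ``at_wavelength`` (linear
    interpolation), as used for ANS intensity profiles.

    Returns an array of shape (n, 2): column 0 denaturant (M), column 1
    the profile value.
    """
    values = np.empty(len(series))
    if mode == "lambda_max":
        for i, sp in enumerate(series.spectra):
            values[i] = extract_lambda_max(sp, window=window)
    elif mode == "intensity":
        if at_wavelength is None:
            raise ParameterError("intensity mode requires at_wavelength")
        for i, sp in enumerate(series.spectra):
            values[i] = np.interp(at_wavelength, sp.wavelength, sp.intensity)
    else:
        raise ParameterError(f"unknown profile mode: {mode!r}")
    return np.column_stack([series.denaturant, values])


class SigmoidTransition(BaseEstimator):
    """Two-state sigmoidal unfolding-transition estimator.

    Fits λ(D) = λ_N + (λ_U − λ_N)/(1 + exp((x − D)/a)) so that λ_N is the
    low-denaturant asymptote and λ_U the high-denaturant one.

    Parameters
    ----------
    n_bootstrap : int, default 200
        Point-resampling bootstrap replicates for uncertainties.
    random_state : int or None
    low_coop_factor : float, default 0.25
        A fit with width a > low_coop_factor × span(D) is flagged
        low-cooperativity.

    Attributes
    ----------
    lambda_n_, lambda_u_ : asymptotic emission maxima, nm.
    midpoint_ : transition midpoint x, M.
    width_ : transition width a, M.
    shift_ : total red shift λ_U − λ_N, nm.
    midpoint_slope_ : (λ_U − λ_N)/(4a), nm/M.
    low_cooperativity_ : bool flag.
    lambda_n_err_, lambda_u_err_, midpoint_err_, width_err_ : bootstrap SDs.
    rss_ : residual sum of squares.
    """

    def __init__(self, n_bootstrap=200, random_state=None,
                 low_coop_factor=0.25):
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state
        self.low_coop_factor = low_coop_factor

    @staticmethod
    def model(d, lambda_n, lambda_u, midpoint, width):
        d = np.asarray(d, dtype=float)
        return lambda_n + (lambda_u - lambda_n) / (
            1.0 + np.exp((midpoint - d) / width)
        )

    def _fit_once(self, d, y, span):
        # bound the asymptotes to within one observed dynamic range of the
        # data so a shallow transition cannot trade an enormous amplitude
        # against an enormous width
        y_span = max(float(np.ptp(y)), 1e-6)
        y_lo = y[np.argmin(d)]
        y_hi = y[np.argmax(d)]
        p = lmfit.Parameters()
        p.add("lambda_n", value=float(y_lo),
              min=float(y_lo) - y_span, max=float(y_lo) + 0.5 * y_span)
        p.add("lambda_u", value=float(y_hi),
              min=float(y_hi) - 0.5 * y_span, max=float(y_hi) + y_span)
        p.add("midpoint", value=float(np.median(d)),
              min=float(d.min()) - 0.5 * span, max=float(d.max()) + 0.5 * span)
        p.add("width", value=0.15 * span, min=1e-4 * span, max=2.0 * span)

        def resid(params):
            return self.model(d, *[params[k].value for k in
                                   ("lambda_n", "lambda_u", "midpoint",
                                    "width")]) - y

        res = lmfit.minimize(resid, p, method="leastsq")
        if not res.success:
            raise FitError("sigmoid transition fit did not converge")
        return res

    def fit(self, X, y=None):
        """Fit the sigmoid to a profile.

        ``X`` is either an (n, 2) array [(D, λ_max)] or the denaturant
        grid with ``y`` the λ_max values.
        """
        X = np.asarray(X, dtype=float)
        if y is None:
            d, lam = X[:, 0], X[:, 1]
        else:
            d, lam = X.ravel(), np.asarray(y, dtype=float).ravel()
        if np.unique(d).size < 6:
            raise FitError("need at least 6 denaturant points")
        span = float(np.ptp(d))
        res = self._fit_once(d, lam, span)
        for name, attr in (("lambda_n", "lambda_n_"), ("lambda_u", "lambda_u_"),
                           ("midpoint", "midpoint_"), ("width", "width_")):
            setattr(self, attr, float(res.params[name].value))
        self.rss_ = float(res.chisqr)
        self.shift_ = self.lambda_u_ - self.lambda_n_
        self.midpoint_slope_ = self.shift_ / (4.0 * self.width_)
        self.low_cooperativity_ = bool(
            self.width_ > self.low_coop_factor * span
        )
        self.lambda_n_err_ = self.lambda_u_err_ = float("nan")
        self.midpoint_err_ = self.width_err_ = float("nan")
        if self.n_bootstrap:
            rng = np.random.default_rng(self.random_state)
            n = d.size
            samples = []
            for _ in range(self.n_bootstrap):
                idx = rng.integers(0, n, size=n)
                if np.unique(d[idx]).size < 6:
                    continue
                try:
                    r = self._fit_once(d[idx], lam[idx], span)
                except FitError:
                    continue
                samples.append([r.params[k].value for k in
                                ("lambda_n", "lambda_u", "midpoint", "width")])
            if len(samples) >= 10:
                sd = np.std(np.asarray(samples), axis=0, ddof=1)
                (self.lambda_n_err_, self.lambda_u_err_,
                 self.midpoint_err_, self.width_err_) = map(float, sd)
        return self

    def predict(self, X):
        d = np.asarray(X, dtype=float).ravel()
        return self.model(d, self.lambda_n_, self.lambda_u_,
                          self.midpoint_, self.width_)


class GaussianProfile(BaseEstimator):
    """Area-normalized Gaussian peak estimator for non-monotone profiles.

    Model: y = y0 + A·exp(−4 ln2 (x − x_c)²/w²) / (w·sqrt(π/(4 ln2)))
    with ``A`` the area, ``x_c`` the center and ``w`` the full width at
    half maximum.
    """

    def __init__(self):
        pass

    @staticmethod
    def model(x, y0, area, center, fwhm):
        x = np.asarray(x, dtype=float)
        norm = fwhm * np.sqrt(np.pi / (4.0 * np.log(2.0)))
        return y0 + area * np.exp(
            -4.0 * np.log(2.0) * (x - center) ** 2 / fwhm**2
        ) / norm

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if y is None:
            x, yy = X[:, 0], X[:, 1]
        else:
            x, yy = X.ravel(), np.asarray(y, dtype=float).ravel()
        if x.size < 5:
            raise FitError("need at least 5 points")
        k = int(np.argmax(yy))
        if k == 0 or k == x.size - 1:
            raise FitError(
                "profile is monotone; a sigmoid transition model is more "
                "appropriate than a Gaussian peak"
            )
        span = float(np.ptp(x))
        p = lmfit.Parameters()
        p.add("y0", value=float(np.min(yy)))
        p.add("center", value=float(x[k]), min=float(x.min()),
              max=float(x.max()))
        p.add("fwhm", value=0.3 * span, min=1e-3 * span, max=5.0 * span)
        height0 = float(yy[k] - np.min(yy))
        p.add("area", value=max(height0, 1e-12) * 0.3 * span, min=0.0)

        def resid(params):
            return self.model(
                x, params["y0"].value, params["area"].value,
                params["center"].value, params["fwhm"].value
            ) - yy

        res = lmfit.minimize(resid, p, method="leastsq")
        if not res.success:
            raise FitError("Gaussian profile fit did not converge")
        self.y0_ = float(res.params["y0"].value)
        self.area_ = float(res.params["area"].value)
        self.center_ = float(res.params["center"].value)
        self.fwhm_ = float(res.params["fwhm"].value)
        self.rss_ = float(res.chisqr)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return self.model(x, self.y0_, self.area_, self.center_, self.fwhm_)


def fit_sigmoid_transition(profile, n_bootstrap=200, random_state=None):
    """Fit :class:`SigmoidTransition` to an (D, λ_max) profile table."""
    return SigmoidTransition(
        n_bootstrap=n_bootstrap, random_state=random_state
    ).fit(np.asarray(profile, dtype=float))


def fit_gaussian_profile(profile):
    """Fit :class:`GaussianProfile` to an (D, y) profile table."""
    return GaussianProfile().fit(np.asarray(profile, dtype=float))
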