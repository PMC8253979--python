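"""Stern–Volmer quenching analysis.

Collisional (dynamic) quenching by a diffusing quencher Q lowers both the
steady-state intensity and the excited-state lifetime:

    F0/F = τ0/τ = 1 + K_SV·[Q]                       (linear model)

Static quenching — ground-state "dark" complex formation — lowers the
intensity without touching the lifetime of the still-emitting population.
When both act, the steady-state ratio curves upward and follows the
product form

    F0/F = (1 + K_dyn·[Q]) · (1 + K_static·[Q])

which expands to the quadratic polynomial often fitted empirically, but
with coefficients that are the physically meaningful constants. Comparing
the steady-state fit with the lifetime-ratio fit discriminates the
mechanism: a lifetime Stern–Volmer plot that stays shallow or flat while
the intensity plot climbs is the signature of a static component.
"""

from __future__ import annotations

import warnings

import lmfit
import numpy as np
from sklearn.base import BaseEstimator

from .containers import QuenchSeries
from .errors import ComparabilityError, FitError

__all__ = [
    "inner_filter_correct",
    "SternVolmer",
    "fit_sv_linear",
    "fit_sv_product",
    "classify_mechanism",
]


def inner_filter_correct(intensity, a_ex, a_em):
    """Inner-filter correction: F_corr = F · 10^((A_ex + A_em)/2).

    ``a_ex``/``a_em`` are sample absorbances at the excitation and emission
    wavelengths. Corrections with total absorbance above 2 are unreliable
    and trigger a warning.
    """
    intensity = np.asarray(intensity, dtype=float)
    a_ex = np.asarray(a_ex, dtype=float)
    a_em = np.asarray(a_em, dtype=float)
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise ValueError("absorbances must be non-negative")
    if np.any(a_ex + a_em > 2):
        warnings.warn(
            "total absorbance exceeds 2; inner-filter correction unreliable",
            UserWarning,
        )
    return intensity * 10.0 ** ((a_ex + a_em) / 2.0)


def _aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike information criterion for an LS fit."""
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return float(aic)


class SternVolmer(BaseEstimator):
    """Stern–Volmer quenching estimator.

    Parameters
    ----------
    model : {'linear', 'product', 'auto'}
        'linear' fits ratio = 1 + K_SV·[Q]; 'product' fits
        (1 + K_dyn·[Q])(1 + K_static·[Q]); 'auto' fits both and keeps the
        AICc-preferred one.
    free_intercept : bool, default False
        Allow the [Q]=0 intercept to float instead of pinning it at 1.
        Ratios are self-normalized, so the pinned intercept is the default.

    Attributes
    ----------
    model_ : the model actually kept ('linear' or 'product').
    ksv_ : linear Stern–Volmer constant, M⁻¹ (linear model).
    k_dyn_, k_static_ : product-model constants, M⁻¹ (ordered so that
        k_dyn_ ≥ k_static_; the product form is symmetric in the pair).
    aicc_, aicc_linear_, aicc_product_ : model-selection scores.
    rss_ : residual sum of squares of the kept model.
    polynomial_ : ndarray [c0, c1, c2] — the raw quadratic expansion of
        the kept model, as a diagnostic.
    """

    def __init__(self, model="linear", free_intercept=False):
        self.model = model
        self.free_intercept = free_intercept

    def _fit_linear(self, q, ratio):
        p = lmfit.Parameters()
        slope0 = max((ratio[-1] - 1.0) / max(q[-1], 1e-12), 1e-6)
        p.add("ksv", value=slope0, min=0.0)
        p.add("f0", value=1.0, vary=self.free_intercept)

        def resid(params):
            return params["f0"].value + params["ksv"].value * q - ratio

        return lmfit.minimize(resid, p, method="leastsq")

    def _fit_product(self, q, ratio):
        slope0 = max((ratio[-1] - 1.0) / max(q[-1], 1e-12), 1e-6)
        p = lmfit.Parameters()
        p.add("k_dyn", value=slope0, min=0.0)
        p.add("k_static", value=0.3 * slope0, min=0.0)
        p.add("f0", value=1.0, vary=self.free_intercept)

        def resid(params):
            return (
                params["f0"].value
                * (1.0 + params["k_dyn"].value * q)
                * (1.0 + params["k_static"].value * q)
                - ratio
            )

        return lmfit.minimize(resid, p, method="leastsq")

    def fit(self, X, y=None):
        """Fit to a :class:`QuenchSeries` or to arrays ([Q], ratio)."""
        if isinstance(X, QuenchSeries):
            q, ratio = X.q, X.ratio
        else:
            q = np.asarray(X, dtype=float).ravel()
            ratio = np.asarray(y, dtype=float).ravel()
        if q.size < 4:
            raise FitError("need at least 4 quencher points")
        if not np.any(np.isclose(q, 0.0)):
            raise FitError("series must include the [Q]=0 reference point")
        # a systematically decreasing ratio means no quenching signal
        slope_check = np.polyfit(q, ratio, 1)[0]
        if slope_check < 0 and ratio[-1] < 1.0 - 1e-9:
            raise FitError("ratios decrease with [Q]; not a quenching series")

        res_lin = self._fit_linear(q, ratio)
        k_lin = 1 + int(self.free_intercept)
        self.aicc_linear_ = _aicc(res_lin.chisqr, q.size, k_lin)

        res_prod = None
        self.aicc_product_ = np.inf
        if self.model in ("product", "auto") and q.size >= 5:
            res_prod = self._fit_product(q, ratio)
            self.aicc_product_ = _aicc(
                res_prod.chisqr, q.size, 2 + int(self.free_intercept)
            )
        elif self.model == "product":
            raise FitError("product model needs at least 5 points")

        use_product = self.model == "product" or (
            self.model == "auto" and self.aicc_product_ < self.aicc_linear_
        )
        if use_product:
            kd = float(res_prod.params["k_dyn"].value)
            ks = float(res_prod.params["k_static"].value)
            self.k_dyn_, self.k_static_ = max(kd, ks), min(kd, ks)
            self.ksv_ = float("nan")
            self.rss_ = float(res_prod.chisqr)
            self.model_ = "product"
            self.aicc_ = self.aicc_product_
            self.polynomial_ = np.array(
                [1.0, self.k_dyn_ + self.k_static_,
                 self.k_dyn_ * self.k_static_]
            )
        else:
            self.ksv_ = float(res_lin.params["ksv"].value)
            self.k_dyn_ = self.k_static_ = float("nan")
            self.rss_ = float(res_lin.chisqr)
            self.model_ = "linear"
            self.aicc_ = self.aicc_linear_
            self.polynomial_ = np.array([1.0, self.ksv_, 0.0])
        self.q_range_ = (float(q.min()), float(q.max()))
        return self

    def predict(self, X):
        q = np.asarray(X, dtype=float).ravel()
        c0, c1, c2 = self.polynomial_
        return c0 + c1 * q + c2 * q * q

    @property
    def effective_slope_(self) -> float:
        """Initial slope d(ratio)/d[Q] at [Q]=0 of the kept model, M⁻¹."""
        return float(self.polynomial_[1])


def fit_sv_linear(series: QuenchSeries) -> SternVolmer:
    """Fit the linear Stern–Volmer model (intercept pinned at 1)."""
    return SternVolmer(model="linear").fit(series)


def fit_sv_product(series: QuenchSeries) -> SternVolmer:
    """Fit the dynamic×static product model."""
    return SternVolmer(model="product").fit(series)


def classify_mechanism(steady: SternVolmer, lifetime: SternVolmer,
                       slope_factor: float = 1.3) -> dict:
    """Discriminate collisional from static-plus-collisional quenching.

    Evidence for a static component, either of:

    * the steady-state effective slope exceeds the lifetime K_SV by more
      than ``slope_factor``, or
    * the steady-state series prefers the product model by AICc while the
      lifetime series does not.

    Returns a dict with ``mechanism`` ('collisional' or
    'static_plus_collisional') and an evidence summary.
    """
    lo = max(steady.q_range_[0], lifetime.q_range_[0])
    hi = min(steady.q_range_[1], lifetime.q_range_[1])
    spans = [steady.q_range_[1] - steady.q_range_[0],
             lifetime.q_range_[1] - lifetime.q_range_[0]]
    if hi - lo < 0.5 * max(spans):
        raise ComparabilityError(
            "steady-state and lifetime series overlap on less than half "
            "of the quencher range"
        )
    lifetime_ksv = (
        lifetime.ksv_ if lifetime.model_ == "linear"
        else lifetime.effective_slope_
    )
    slope_excess = steady.effective_slope_ / max(lifetime_ksv, 1e-12)
    steady_prefers_product = steady.aicc_product_ < steady.aicc_linear_
    lifetime_prefers_product = (
        lifetime.aicc_product_ < lifetime.aicc_linear_
    )
    static = slope_excess > slope_factor or (
        steady_prefers_product and not lifetime_prefers_product
    )
    return {
        "mechanism": "static_plus_collisional" if static else "collisional",
        "slope_excess": float(slope_excess),
        "steady_prefers_product": bool(steady_prefers_product),
        "lifetime_prefers_product": bool(lifetime_prefers_product),
        "steady_effective_slope": steady.effective_slope_,
        "lifetime_ksv": float(lifetime_ksv),
    }
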