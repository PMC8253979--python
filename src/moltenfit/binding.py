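"""Equilibrium binding from steady-state anisotropy titrations.

The assay: a fluorescently labeled species A at fixed total concentration
``A0`` is titrated with an unlabeled partner T (total ``T0``). Binding
slows tumbling and raises the steady-state anisotropy from the free value
``r_A`` toward the saturated value ``r_AT``. Because ``A0`` is comparable
to the dissociation constant, ligand depletion is non-negligible and the
bound fraction must come from the exact mass-action (tight-binding,
"quadratic") solution rather than the hyperbolic approximation:

    f_b = [A0 + T0 + K_D − sqrt((A0 + T0 + K_D)² − 4·A0·T0)] / (2·A0)
    r(T0) = r_A + (r_AT − r_A) · f_b

All concentrations are in μM; anisotropies are dimensionless and bounded
by the one-photon physical limits [−0.2, 0.4].
"""

from __future__ import annotations

from typing import Optional

import lmfit
import numpy as np
from sklearn.base import BaseEstimator

from .containers import TitrationCurve
from .errors import FitError, ParameterError

__all__ = ["bound_fraction", "predict_anisotropy", "fit_binding", "BindingIsotherm"]

ANISO_MIN, ANISO_MAX = -0.2, 0.4


def bound_fraction(a0, t0, kd):
    """Fraction of the labeled species A bound at total titrant ``t0``.

    Exact solution of (A0 − x)(T0 − x) = K_D·x for the complex
    concentration x, returned as x/A0. Vectorized over ``t0``.

    Parameters are in a common concentration unit (μM by package
    convention); only ratios matter.
    """
    a0 = float(a0)
    if not a0 > 0:
        raise ParameterError("a0 must be positive")
    t0 = np.asarray(t0, dtype=float)
    kd = float(kd)
    if kd < 0 or np.any(t0 < 0):
        raise ParameterError("t0 and kd must be non-negative")
    s = a0 + t0 + kd
    disc = s * s - 4.0 * a0 * t0
    # disc >= (a0 - t0)^2 + kd^2 >= 0 analytically; clip round-off only
    disc = np.maximum(disc, 0.0)
    # conjugate form of [s - sqrt(disc)]/(2 a0): no cancellation when
    # kd >> a0, t0
    frac = 2.0 * t0 / (s + np.sqrt(disc))
    return np.clip(frac, 0.0, 1.0)


def predict_anisotropy(a0, t0, kd, r_a, r_at):
    """Steady-state anisotropy predicted by the quadratic isotherm."""
    return r_a + (r_at - r_a) * bound_fraction(a0, t0, kd)


class BindingIsotherm(BaseEstimator):
    """Tight-binding (quadratic) anisotropy isotherm estimator.

    Fits (K_D, r_A, r_AT) to a titration by nonlinear least squares with a
    multi-start initialization heuristic, and estimates parameter
    uncertainties by a seeded nonparametric bootstrap over points.

    Parameters
    ----------
    a0 : float
        Total labeled-species concentration, μM. Fixed, not fitted.
    n_bootstrap : int, default 200
        Bootstrap resamples for the uncertainty estimates; 0 disables.
    random_state : int or None
        Seed for the bootstrap resampler.
    n_restarts : int, default 5
        Perturbed restarts tried before declaring non-convergence.

    Attributes
    ----------
    kd_, r_a_, r_at_ : fitted parameters.
    kd_err_, r_a_err_, r_at_err_ : bootstrap standard deviations
        (NaN when ``n_bootstrap`` is 0).
    rss_ : residual sum of squares at the optimum.
    low_dynamic_range_ : bool
        True when the observed anisotropy change is below three times the
        residual noise estimate — the fit is then poorly constrained.
    """

    def __init__(self, a0=1.0, n_bootstrap=200, random_state=None, n_restarts=5):
        self.a0 = a0
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state
        self.n_restarts = n_restarts

    # -- internal -----------------------------------------------------
    def _make_params(self, kd, r_a, r_at):
        p = lmfit.Parameters()
        p.add("kd", value=max(kd, 1e-6), min=1e-9)
        p.add("r_a", value=r_a, min=ANISO_MIN, max=ANISO_MAX)
        p.add("r_at", value=r_at, min=ANISO_MIN, max=ANISO_MAX)
        return p

    def _residual(self, params, t0, r):
        return (
            predict_anisotropy(
                self.a0, t0, params["kd"].value, params["r_a"].value,
                params["r_at"].value,
            )
            - r
        )

    def _initial_guesses(self, t0, r, rng):
        r_a0 = r[np.argmin(t0)]
        r_at0 = r[np.argmax(t0)]
        half = r_a0 + 0.5 * (r_at0 - r_a0)
        idx = int(np.argmin(np.abs(r - half)))
        kd0 = max(t0[idx], 1e-3)
        yield kd0, r_a0, r_at0
        for _ in range(self.n_restarts):
            yield (
                kd0 * float(np.exp(rng.uniform(-1.5, 1.5))),
                float(np.clip(r_a0 + rng.normal(0, 0.02), ANISO_MIN, ANISO_MAX)),
                float(np.clip(r_at0 + rng.normal(0, 0.02), ANISO_MIN, ANISO_MAX)),
            )

    def _fit_once(self, t0, r, rng):
        best = None
        for guess in self._initial_guesses(t0, r, rng):
            params = self._make_params(*guess)
            try:
                res = lmfit.minimize(
                    self._residual, params, args=(t0, r), method="leastsq"
                )
            except Exception:
                continue
            if res.success and (best is None or res.chisqr < best.chisqr):
                best = res
        return best

    # -- API ----------------------------------------------------------
    def fit(self, X, y=None):
        """Fit the isotherm.

        ``X`` may be a :class:`TitrationCurve` (``y`` ignored, ``a0`` taken
        from the curve) or an array of total titrant concentrations T0 (μM)
        with ``y`` the anisotropy readings.
        """
        if isinstance(X, TitrationCurve):
            t0, r = X.t0, X.r
            self.a0 = X.a0
        else:
            t0 = np.asarray(X, dtype=float).ravel()
            r = np.asarray(y, dtype=float).ravel()
        if np.unique(t0).size < 5:
            raise FitError("need at least 5 distinct titrant concentrations")
        rng = np.random.default_rng(self.random_state)
        best = self._fit_once(t0, r, rng)
        if best is None:
            raise FitError("binding fit did not converge after restarts")
        self.kd_ = float(best.params["kd"].value)
        self.r_a_ = float(best.params["r_a"].value)
        self.r_at_ = float(best.params["r_at"].value)
        self.rss_ = float(best.chisqr)
        dof = max(t0.size - 3, 1)
        noise = np.sqrt(self.rss_ / dof)
        self.low_dynamic_range_ = bool(np.ptp(r) < 3.0 * noise)

        self.kd_err_ = self.r_a_err_ = self.r_at_err_ = float("nan")
        if self.n_bootstrap:
            samples = []
            n = t0.size
            for _ in range(self.n_bootstrap):
                idx = rng.integers(0, n, size=n)
                res = self._fit_once(t0[idx], r[idx], rng)
                if res is not None:
                    samples.append(
                        [res.params[k].value for k in ("kd", "r_a", "r_at")]
                    )
            if len(samples) >= 10:
                sd = np.std(np.asarray(samples), axis=0, ddof=1)
                self.kd_err_, self.r_a_err_, self.r_at_err_ = map(float, sd)
        return self

    def predict(self, X):
        """Anisotropy at titrant concentrations ``X`` (μM)."""
        t0 = np.asarray(X, dtype=float).ravel()
        return predict_anisotropy(self.a0, t0, self.kd_, self.r_a_, self.r_at_)


def fit_binding(curve: TitrationCurve, n_bootstrap: int = 200,
                random_state: Optional[int] = None) -> BindingIsotherm:
    """Convenience wrapper: fit :class:`BindingIsotherm` to a titration."""
    return BindingIsotherm(
        a0=curve.a0, n_bootstrap=n_bootstrap, random_state=random_state
    ).fit(curve)
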