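"""Smooth, differentiable fits of cultivation observables.

Two classic curve families from process-data analysis are provided as
scikit-learn style regressors:

* :class:`SigmoidCurve` — four-parameter logistic,
  ``y(t) = y0 + a / (1 + exp(-(t - t0)/tau))``, used for biomass, surfactin,
  nutrient depletion and ComX activity;
* :class:`ExponentialCurve` — three-parameter exponential,
  ``y(t) = y0 + a * exp(k * t)``.

Both expose closed-form values *and* closed-form first derivatives, which
downstream code uses as the biomass forcing of the ComX kinetic model and for
instantaneous specific productivities.  Fitting is deterministic: the
initial guess is a fixed rule of the data, so refitting the same points
always returns the same parameters.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    ConvergenceError,
    InsufficientDataError,
    InsufficientVariationError,
)

_EXP_CLIP = 500.0  # avoid overflow in exp() far outside the data range


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -_EXP_CLIP, _EXP_CLIP)))


def _as_1d(x):
    return np.ravel(np.asarray(x, dtype=float))


class _CurveBase(RegressorMixin, BaseEstimator):
    """Shared fit plumbing for the closed-form curve families."""

    _param_names: tuple = ()
    _min_points: int = 2

    def _check_xy(self, t, y):
        t, y = _as_1d(t), _as_1d(y)
        if t.shape != y.shape:
            raise ValueError("time and y must have the same length")
        mask = np.isfinite(t) & np.isfinite(y)
        t, y = t[mask], y[mask]
        if len(t) < self._min_points:
            raise InsufficientDataError(
                f"need at least {self._min_points} points, got {len(t)}"
            )
        return t, y

    def _solve(self, t, y, starts):
        """Run least squares from each start; keep the best final cost."""
        best = None
        for x0 in starts:
            res = least_squares(
                lambda p: self._value(p, t) - y, x0, method="lm", xtol=1e-14,
                ftol=1e-14, gtol=1e-14, max_nfev=20000,
            )
            if best is None or res.cost < best.cost:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise ConvergenceError("curve fit failed",
                                   best=None if best is None else best.x)
        # optimiser sanity: never do worse than the flat fit
        flat_sse = float(np.sum((y - y.mean()) ** 2))
        sse = float(2.0 * best.cost)
        if sse > flat_sse * (1 + 1e-12) + 1e-12:
            return self._flat_params(t, y), flat_sse
        return best.x, sse

    def fit(self, t, y):
        t, y = self._check_xy(t, y)
        params, sse = self._fit_impl(t, y)
        for name, value in zip(self._param_names, params):
            setattr(self, name + "_", float(value))
        self.residual_sse_ = float(sse)
        self.n_obs_ = len(t)
        return self

    def predict(self, t):
        """Curve value at ``t`` (scalar or array)."""
        self._check_fitted()
        out = self._value(self._params(), np.asarray(t, dtype=float))
        return float(out) if np.isscalar(t) else out

    def derivative(self, t):
        """Closed-form first derivative dy/dt at ``t``."""
        self._check_fitted()
        out = self._deriv(self._params(), np.asarray(t, dtype=float))
        return float(out) if np.isscalar(t) else out

    def _params(self):
        return np.array([getattr(self, n + "_") for n in self._param_names])

    def _check_fitted(self):
        if not hasattr(self, self._param_names[0] + "_"):
            raise AttributeError(
                f"{type(self).__name__} is not fitted; call fit() or from_params()"
            )

    @classmethod
    def from_params(cls, *values, residual_sse=0.0):
        """Build a fitted-state curve directly from known parameters."""
        obj = cls()
        for name, value in zip(cls._param_names, values):
            setattr(obj, name + "_", float(value))
        obj.residual_sse_ = float(residual_sse)
        return obj


class SigmoidCurve(_CurveBase):
    """Four-parameter logistic curve ``y0 + a/(1 + exp(-(t - t0)/tau))``.

    Fitted attributes: ``y0_`` (baseline), ``a_`` (amplitude), ``t0_``
    (inflection time, h), ``tau_`` (shape scale, h), ``residual_sse_``.
    The derivative is ``(a/tau) * s * (1 - s)`` with ``s`` the logistic
    factor, so the inflection slope is ``a / (4 tau)``.
    """

    _param_names = ("y0", "a", "t0", "tau")
    _min_points = 5

    @staticmethod
    def _value(p, t):
        y0, a, t0, tau = p
        return y0 + a * _logistic((t - t0) / tau)

    @staticmethod
    def _deriv(p, t):
        y0, a, t0, tau = p
        s = _logistic((t - t0) / tau)
        return (a / tau) * s * (1.0 - s)

    @staticmethod
    def _flat_params(t, y):
        return np.array([y.mean(), 0.0, t.mean(), (t.max() - t.min()) / 10 or 1.0])

    def _fit_impl(self, t, y):
        rng = float(y.max() - y.min())
        if rng == 0.0:
            raise InsufficientVariationError("y values are all equal")
        # deterministic initial guess: baseline = min, amplitude = range,
        # t0 = earliest half-range crossing, tau = time span / 10
        half = y.min() + rng / 2.0
        above = np.nonzero(y >= half)[0]
        t0 = float(t[above[0]]) if above.size else float(t[len(t) // 2])
        tau0 = (t.max() - t.min()) / 10.0 or 1.0
        starts = [
            np.array([y.min(), rng, t0, tau0]),
            np.array([y.max(), -rng, t0, tau0]),   # decreasing data
            np.array([y.min(), rng, t0, -tau0]),
        ]
        return self._solve(t, y, starts)


class ExponentialCurve(_CurveBase):
    """Three-parameter exponential curve ``y0 + a * exp(k * t)``.

    Fitted attributes: ``y0_``, ``a_``, ``k_`` (1/h), ``residual_sse_``.
    By construction ``value(0) = y0 + a``.
    """

    _param_names = ("y0", "a", "k")
    _min_points = 4

    @staticmethod
    def _value(p, t):
        y0, a, k = p
        return y0 + a * np.exp(np.clip(k * t, -_EXP_CLIP, _EXP_CLIP))

    @staticmethod
    def _deriv(p, t):
        y0, a, k = p
        return a * k * np.exp(np.clip(k * t, -_EXP_CLIP, _EXP_CLIP))

    @staticmethod
    def _flat_params(t, y):
        return np.array([y.mean(), 0.0, 0.0])

    def _fit_impl(self, t, y):
        rng = float(y.max() - y.min())
        scale = rng if rng > 0 else max(abs(y.mean()), 1.0)
        # initial slope from a log-linear regression above a shifted baseline
        y0g = y.min() - 0.05 * scale
        resid = np.maximum(y - y0g, 1e-12 * scale)
        k0, loga0 = np.polyfit(t, np.log(resid), 1)
        starts = [
            np.array([y0g, np.exp(loga0), k0]),
            np.array([y.max() + 0.05 * scale, -(scale or 1.0), k0]),  # decay shape
            np.array([y.mean(), 0.0, 0.0]),
        ]
        return self._solve(t, y, starts)


class ConstantCurve:
    """Degenerate value-plus-derivative curve: constant value, zero slope.

    Useful as the biomass forcing for steady-state and analytic checks.
    """

    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.value, dtype=float)
        return float(out) if out.ndim == 0 else out

    def derivative(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t, dtype=float)
        return float(out) if out.ndim == 0 else out


def fit_sigmoid4(time, y) -> SigmoidCurve:
    """Least-squares four-parameter logistic fit (>= 5 points)."""
    return SigmoidCurve().fit(time, y)


def fit_exp3(time, y) -> ExponentialCurve:
    """Least-squares three-parameter exponential fit (>= 4 points)."""
    return ExponentialCurve().fit(time, y)


def eval_fit(fit, t):
    """Return ``(value, derivative)`` of a fitted curve at ``t``.

    Both are closed-form expressions; no numerical differencing is involved.
    """
    return fit.predict(t), fit.derivative(t)
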