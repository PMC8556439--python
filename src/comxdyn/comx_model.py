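"""Kinetic model of extracellular ComX activity during batch cultivation.

ComX activity a(t) [Miller units] is produced in proportion to both the
standing biomass and its growth rate, and removed by a putative
ComX-specific protease (CSP) whose activity EA(t) is itself induced by ComX:

    da/dt  = b * X(t) + d * dX/dt - e * EA(t)
    dEA/dt = f * a(t) - g * EA(t)

with X(t) the cell dry weight [g/L] supplied as a smooth curve with an
analytic derivative.  Given the biomass forcing the system is linear in
(a, EA); for constant biomass X it relaxes (through damped oscillation for
the default rates) to the closed-form steady state

    a_ss  = b * X * g / (e * f),      EA_ss = f * a_ss / g = b * X / e.

Default parameter values and fitting bounds are the study ranges: the
production and degradation coefficients (a0, b, d, e) are free within
narrow ranges while the protease formation/decay rates f and g are fixed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .curvefit import ConstantCurve
from .exceptions import ComxdynError, DomainError, NoSteadyStateError

#: Parameter bounds: name -> (low, high, fixed).  f and g are fixed rates;
#: the remaining four are estimated within their ranges.
PARAM_BOUNDS = {
    "a0": (21.0, 32.0, False),
    "b": (17.72, 19.95, False),
    "d": (436.0, 516.0, False),
    "e": (1.36, 1.58, False),
    "f": (0.115, 0.115, True),
    "g": (0.328, 0.328, True),
}

PARAM_NAMES = tuple(PARAM_BOUNDS)


@dataclass
class ComXModelParams:
    """Parameters of the coupled ComX / protease model.

    Units: ``a0`` MU; ``b`` (MU*L)/(g*h); ``d`` (MU*L)/g; ``e`` MU/(EA*h);
    ``f`` EA/(MU*h); ``g`` 1/h.  Defaults are the midpoints of the study
    ranges (and the fixed values for f, g).
    """

    a0: float = 26.5
    b: float = 18.835
    d: float = 476.0
    e: float = 1.47
    f: float = 0.115
    g: float = 0.328
    bounds: dict = field(default_factory=lambda: dict(PARAM_BOUNDS))

    def __post_init__(self):
        for name in PARAM_NAMES:
            if getattr(self, name) < 0:
                raise DomainError(f"parameter {name} must be >= 0")
        if not self.g > 0:
            raise DomainError("protease decay rate g must be > 0")
        for name, (lo, hi, _) in self.bounds.items():
            if lo > hi:
                raise DomainError(f"bounds for {name} are not ordered")

    @property
    def free_names(self) -> tuple:
        return tuple(n for n, (_, _, fx) in self.bounds.items() if not fx)

    def values(self) -> dict:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    def with_values(self, **kwargs) -> "ComXModelParams":
        return replace(self, **kwargs)

    @classmethod
    def midpoint(cls, bounds: dict | None = None) -> "ComXModelParams":
        """Parameters at the midpoint of each bound interval."""
        bounds = dict(bounds or PARAM_BOUNDS)
        mids = {n: (lo + hi) / 2.0 for n, (lo, hi, _) in bounds.items()}
        return cls(bounds=bounds, **mids)


@dataclass
class ComXTrajectory:
    """Simulated ComX / protease time course on a grid.

    ``a_comx`` [MU] and ``ea_csp`` [dA/(h*mL)] are clipped at zero on output
    (a warning is emitted if the raw solution dipped below -1e-9); ``cdw``
    is the driving biomass evaluated on the same grid.
    """

    time: np.ndarray
    a_comx: np.ndarray
    ea_csp: np.ndarray
    cdw: np.ndarray
    solver_report: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time,
                "comx_MU_model": self.a_comx,
                "ea_csp_model": self.ea_csp,
                "cdw_g_L": self.cdw,
            }
        )


def as_curve(biomass):
    """Coerce ``biomass`` into an object with predict/derivative methods.

    Accepts a fitted curve, a ``(value_fn, derivative_fn)`` pair, or a scalar
    (treated as constant biomass).
    """
    if hasattr(biomass, "predict") and hasattr(biomass, "derivative"):
        return biomass
    if np.isscalar(biomass):
        return ConstantCurve(float(biomass))
    if isinstance(biomass, (tuple, list)) and len(biomass) == 2:
        f, df = biomass

        class _Pair:
            predict = staticmethod(f)
            derivative = staticmethod(df)

        return _Pair()
    raise TypeError("biomass must be a curve, a (f, df) pair, or a scalar")


def simulate(
    params: ComXModelParams,
    biomass,
    t_grid,
    ea0: float = 0.0,
    rtol: float = 1e-8,
) -> ComXTrajectory:
    """Integrate the coupled ComX / protease system on ``t_grid``.

    Parameters
    ----------
    params : ComXModelParams
        Kinetic parameters; ``params.a0`` is the initial ComX activity.
    biomass : curve | (f, df) | float
        Cell dry weight forcing X(t), with analytic derivative.
    t_grid : array-like of hours, strictly increasing.
    ea0 : float
        Initial protease activity (default 0: no ComX-induced protease at
        inoculation).
    rtol : float
        Relative solver tolerance (stiff-capable LSODA integrator).
    """
    t = np.ravel(np.asarray(t_grid, dtype=float))
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise DomainError("t_grid must contain >= 2 strictly increasing times")
    curve = as_curve(biomass)
    x_grid = np.asarray(curve.predict(t), dtype=float)
    if np.any(x_grid < 0):
        raise DomainError("biomass must be non-negative on the grid")
    b, d, e, f, g = params.b, params.d, params.e, params.f, params.g

    def rhs(ti, state):
        a, ea = state
        return (
            b * curve.predict(ti) + d * curve.derivative(ti) - e * ea,
            f * a - g * ea,
        )

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [params.a0, float(ea0)],
        t_eval=t,
        method="LSODA",
        rtol=rtol,
        atol=rtol * 1e-2,
    )
    if not sol.success:
        raise ComxdynError(f"ODE solver failed: {sol.message}")
    a_raw, ea_raw = sol.y
    if min(a_raw.min(), ea_raw.min()) < -1e-9:
        warnings.warn(
            "trajectory dipped below zero and was clipped on output",
            RuntimeWarning,
            stacklevel=2,
        )
    return ComXTrajectory(
        time=t,
        a_comx=np.maximum(a_raw, 0.0),
        ea_csp=np.maximum(ea_raw, 0.0),
        cdw=x_grid,
        solver_report={
            "method": "LSODA",
            "rtol": rtol,
            "nfev": int(sol.nfev),
            "status": int(sol.status),
        },
    )


def steady_state(params: ComXModelParams, x: float):
    """Closed-form fixed point for constant biomass ``x`` [g/L].

    Returns ``(a_ss, ea_ss)`` with ``a_ss = b*x*g/(e*f)`` and
    ``ea_ss = f*a_ss/g``.  Requires ``e*f > 0`` (otherwise ComX grows
    without bound and no finite steady state exists).
    """
    if x < 0:
        raise DomainError("biomass must be non-negative")
    if params.e * params.f <= 0:
        raise NoSteadyStateError(
            "no finite steady state: e*f must be positive"
        )
    a_ss = params.b * x * params.g / (params.e * params.f)
    ea_ss = params.f * a_ss / params.g
    return a_ss, ea_ss


@dataclass
class SensitivityEnvelope:
    """Pointwise min/max band of simulated ComX under parameter variation."""

    time: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    nominal: np.ndarray
    frac: float


def sensitivity_envelope(
    params: ComXModelParams,
    biomass,
    t_grid,
    frac: float = 0.08,
    ea0: float = 0.0,
) -> SensitivityEnvelope:
    """Band of ComX trajectories under +/- ``frac`` parameter variation.

    The free parameters (a0, b, d, e by default) are each scaled by the
    full factorial {1-frac, 1, 1+frac} (3^4 = 81 runs for the default
    split); fixed parameters are left untouched.  The band is the pointwise
    min/max over all runs and contains the nominal trajectory by
    construction.
    """
    if not 0 <= frac < 1:
        raise DomainError("frac must be in [0, 1)")
    t = np.ravel(np.asarray(t_grid, dtype=float))
    nominal = simulate(params, biomass, t, ea0=ea0).a_comx
    free = params.free_names
    lower = nominal.copy()
    upper = nominal.copy()
    if frac > 0:
        factors = (1.0 - frac, 1.0, 1.0 + frac)
        for combo in itertools.product(factors, repeat=len(free)):
            if all(c == 1.0 for c in combo):
                continue
            scaled = params.with_values(
                **{n: getattr(params, n) * c for n, c in zip(free, combo)}
            )
            a = simulate(scaled, biomass, t, ea0=ea0).a_comx
            np.minimum(lower, a, out=lower)
            np.maximum(upper, a, out=upper)
    return SensitivityEnvelope(
        time=t, lower=lower, upper=upper, nominal=nominal, frac=frac
    )
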