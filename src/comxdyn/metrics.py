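"""Batch-process performance calculus.

Yield coefficients, specific growth rate and specific productivity for a
batch cultivation, evaluated at the sampled time points where biomass or
product first exceed 90% of their maxima (no interpolation):

    Y_X/S = dm_X / dm_S            (at X >= 90%)
    Y_P/S = dm_P / dm_S            (at P >= 90%)
    Y_P/X = dm_P / mean(m_X1, m_X2)
    mu    = ln(m_X2/m_X1) / (t2 - t1),  mu_max over consecutive samples
    q     = dm_P / (mean(m_X1, m_X2) * dt)

plus the instantaneous specific-productivity curve q(t) = P'(t)/X(t) from
fitted smooth curves, paired with the fitted ComX activity and truncated at
the ComX maximum -- the basis of the productivity-versus-pheromone
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import DomainError, InsufficientDataError

_MG_PER_G = 1000.0


def t_at_fraction(time, value, frac: float):
    """Earliest sampled time at which ``value >= frac * max(value)``."""
    t = np.ravel(np.asarray(time, dtype=float))
    v = np.ravel(np.asarray(value, dtype=float))
    mask = np.isfinite(t) & np.isfinite(v)
    t, v = t[mask], v[mask]
    if len(t) == 0:
        raise InsufficientDataError("empty series")
    if not 0 < frac <= 1:
        raise DomainError("frac must be in (0, 1]")
    hit = np.nonzero(v >= frac * v.max())[0]
    return float(t[hit[0]])


def _value_at(series, column: str, t: float) -> float:
    """Observable value at a sampled time point (replicate mean)."""
    df = series.replicate_mean().data
    if column not in df.columns:
        raise InsufficientDataError(f"series has no {column!r} column")
    row = df[np.isclose(df["time_h"].to_numpy(dtype=float), t)]
    if row.empty:
        raise DomainError(f"time {t} h is not a sampled point")
    val = float(row[column].iloc[0])
    if not np.isfinite(val):
        raise DomainError(f"{column!r} missing at t={t} h")
    return val


def yield_biomass_substrate(series, t_ref: float) -> float:
    """Biomass-per-substrate yield Y_X/S [g/g] between t0 and ``t_ref``."""
    t0 = float(np.min(series.time))
    dx = _value_at(series, "cdw_g_L", t_ref) - _value_at(series, "cdw_g_L", t0)
    ds = _value_at(series, "glucose_g_L", t0) - _value_at(series, "glucose_g_L", t_ref)
    if not ds > 0:
        raise DomainError("no substrate consumed: yield undefined")
    return dx / ds


def yield_product_substrate(series, t_ref: float) -> float:
    """Product-per-substrate yield Y_P/S [g/g] between t0 and ``t_ref``.

    Surfactin is stored in mg/L and converted to g/L here.
    """
    t0 = float(np.min(series.time))
    dp = (_value_at(series, "surfactin_mg_L", t_ref)
          - _value_at(series, "surfactin_mg_L", t0)) / _MG_PER_G
    ds = _value_at(series, "glucose_g_L", t0) - _value_at(series, "glucose_g_L", t_ref)
    if not ds > 0:
        raise DomainError("no substrate consumed: yield undefined")
    return dp / ds


def yield_product_biomass(series, t_p: float, t_x: float) -> float:
    """Product-per-biomass yield Y_P/X [g/g].

    Product change over [t0, t_p], divided by the mean of the biomass at t0
    and at ``t_x``.
    """
    t0 = float(np.min(series.time))
    dp = (_value_at(series, "surfactin_mg_L", t_p)
          - _value_at(series, "surfactin_mg_L", t0)) / _MG_PER_G
    x1 = _value_at(series, "cdw_g_L", t0)
    x2 = _value_at(series, "cdw_g_L", t_x)
    mean_x = (x1 + x2) / 2.0
    if not mean_x > 0:
        raise DomainError("mean biomass must be > 0")
    return dp / mean_x


def growth_rate(x1: float, x2: float, t1: float, t2: float) -> float:
    """Specific growth rate mu = ln(x2/x1)/(t2 - t1) [1/h]."""
    if not (x1 > 0 and x2 > 0):
        raise DomainError("biomass values must be > 0")
    if not t2 > t1:
        raise DomainError("t2 must exceed t1")
    return float(np.log(x2 / x1) / (t2 - t1))


def max_growth_rate(time, x) -> float:
    """Maximum pairwise growth rate over consecutive sampled points."""
    t = np.ravel(np.asarray(time, dtype=float))
    xv = np.ravel(np.asarray(x, dtype=float))
    mask = np.isfinite(t) & np.isfinite(xv) & (xv > 0)
    t, xv = t[mask], xv[mask]
    if len(t) < 2:
        raise InsufficientDataError("need >= 2 positive biomass points")
    mus = np.diff(np.log(xv)) / np.diff(t)
    return float(np.max(mus))


def specific_productivity(dm_p: float, x1: float, x2: float, dt: float) -> float:
    """Interval specific productivity q = dm_P / (mean(x1, x2) * dt)."""
    if not dt > 0:
        raise DomainError("dt must be > 0")
    mean_x = (x1 + x2) / 2.0
    if not mean_x > 0:
        raise DomainError("mean biomass must be > 0")
    return dm_p / (mean_x * dt)


def overall_specific_productivity(series) -> float:
    """q_overall [g/(g*h)] over the whole process.

    Product change over [t0, t_P90] (mg converted to g), biomass averaged
    between t0 and t_X90, dt = t_P90 - t0.
    """
    mean = series.replicate_mean()
    t0 = float(np.min(mean.time))
    t_p90 = t_at_fraction(mean.time, mean.surfactin, 0.9)
    t_x90 = t_at_fraction(mean.time, mean.cdw, 0.9)
    dp = (_value_at(series, "surfactin_mg_L", t_p90)
          - _value_at(series, "surfactin_mg_L", t0)) / _MG_PER_G
    x1 = _value_at(series, "cdw_g_L", t0)
    x2 = _value_at(series, "cdw_g_L", t_x90)
    return specific_productivity(dp, x1, x2, t_p90 - t0)


@dataclass
class QComXCurve:
    """Instantaneous specific productivity paired with ComX activity.

    The grid is truncated at the time of maximum fitted ComX activity, the
    regime over which the productivity/pheromone relation is examined.
    ``q_surfactin`` is in g/(g*h).
    """

    t: np.ndarray
    comx: np.ndarray
    q_surfactin: np.ndarray
    q_max: float
    t_at_qmax: float
    comx_at_qmax: float
    truncated_at_comx_max: bool


def q_vs_comx(biomass_fit, surfactin_fit, comx_fit, t_grid,
              surfactin_unit: str = "mg/L") -> QComXCurve:
    """Instantaneous q(t) = P'(t)/X(t) from fitted curves, vs ComX(t).

    All three fits must cover ``t_grid``.  The grid is truncated at the
    ComX maximum; the returned curve records q_max and the ComX activity
    at which it occurs.
    """
    t = np.ravel(np.asarray(t_grid, dtype=float))
    x = np.asarray(biomass_fit.predict(t), dtype=float)
    if np.any(x <= 0):
        raise DomainError("biomass must be positive on the whole grid")
    dp = np.asarray(surfactin_fit.derivative(t), dtype=float)
    if surfactin_unit == "mg/L":
        dp = dp / _MG_PER_G
    elif surfactin_unit != "g/L":
        raise ValueError("surfactin_unit must be 'mg/L' or 'g/L'")
    comx = np.asarray(comx_fit.predict(t), dtype=float)
    i_max = int(np.argmax(comx))
    truncated = i_max < len(t) - 1
    sl = slice(0, i_max + 1)
    q = dp[sl] / x[sl]
    i_q = int(np.argmax(q))
    return QComXCurve(
        t=t[sl],
        comx=comx[sl],
        q_surfactin=q,
        q_max=float(q[i_q]),
        t_at_qmax=float(t[sl][i_q]),
        comx_at_qmax=float(comx[sl][i_q]),
        truncated_at_comx_max=truncated,
    )


@dataclass
class ProcessMetrics:
    """Per-cultivation batch performance summary."""

    y_xs: float
    y_ps: float
    y_px: float
    mu_max: float
    q_overall: float
    q_max: float
    t_x90: float
    t_p90: float
    x_max: float
    p_max: float
    comx_max: float
    comx_t_end: float

    def to_dict(self):
        return asdict(self)


def process_metrics(series) -> ProcessMetrics:
    """Compute the full performance summary for one cultivation.

    Replicates are averaged per sampling time before evaluating the >= 90%
    reference points; the interval q_max is the largest pairwise specific
    productivity over consecutive samples.
    """
    mean = series.replicate_mean()
    t = mean.time
    x = mean.cdw
    p = mean.surfactin
    comx = mean.comx_activity
    if x is None or p is None:
        raise InsufficientDataError("need biomass and surfactin columns")
    t_x90 = t_at_fraction(t, x, 0.9)
    t_p90 = t_at_fraction(t, p, 0.9)
    # pairwise interval q over consecutive samples
    dp = np.diff(p) / _MG_PER_G
    mean_x = (x[:-1] + x[1:]) / 2.0
    dt = np.diff(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        q_pair = np.where(mean_x > 0, dp / (mean_x * dt), np.nan)
    return ProcessMetrics(
        y_xs=yield_biomass_substrate(series, t_x90),
        y_ps=yield_product_substrate(series, t_p90),
        y_px=yield_product_biomass(series, t_p90, t_x90),
        mu_max=max_growth_rate(t, x),
        q_overall=overall_specific_productivity(series),
        q_max=float(np.nanmax(q_pair)),
        t_x90=t_x90,
        t_p90=t_p90,
        x_max=float(np.nanmax(x)),
        p_max=float(np.nanmax(p)),
        comx_max=float(np.nanmax(comx)) if comx is not None else float("nan"),
        comx_t_end=float(comx[-1]) if comx is not None else float("nan"),
    )
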