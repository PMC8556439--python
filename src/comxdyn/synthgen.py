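"""Seeded synthetic-data generator for cultivation and assay inputs.

Emulates 48-hour batch bioreactor time courses of a surfactin-producing
*Bacillus subtilis* cultivation sampled at regular intervals in biological
replicates: logistic biomass, yield-coupled glucose depletion, sigmoidal
surfactin accumulation, ComX activity generated by the kinetic model on the
true biomass curve plus additive Gaussian noise, and total endopeptidase
activity tracking cell density with multiplicative noise.  Every generator
is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import comx_model
from .assays import MillerAssayRecord
from .curvefit import SigmoidCurve
from .dataio import CultivationTimeSeries
from .exceptions import DomainError, InfeasibleTargetError


@dataclass
class SynthConfig:
    """Study-scale defaults for the synthetic reference process.

    Magnitudes mirror the 40 g/L-glucose reference cultivation: inoculation
    biomass 0.031 g/L (OD600 0.1 / 3.2), plateau 5.4 g/L, maximum specific
    growth rate 0.52 1/h, highest surfactin titre 1346.6 mg/L, biomass
    yield 0.15 g/g, and ~5 MU additive scatter on the bioassay readout.
    """

    x0: float = 0.031
    x_max: float = 5.4
    mu: float = 0.52
    t_end: float = 48.0
    sample_every: float = 2.0
    s0: float = 40.0
    y_xs: float = 0.15
    surfactin_max: float = 1346.6
    surfactin_t50: float = 20.0
    surfactin_tau: float = 4.0
    comx_params: comx_model.ComXModelParams = field(
        default_factory=comx_model.ComXModelParams
    )
    noise_sd_comx: float = 5.0
    noise_cv_other: float = 0.05
    ea_per_cdw: float = 15.0
    ea0: float = 0.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("x0", "x_max", "mu", "t_end", "sample_every", "s0",
                     "y_xs", "surfactin_max", "surfactin_tau", "ea_per_cdw"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")
        if self.x0 >= self.x_max:
            raise DomainError("x0 must be below x_max")
        if self.noise_sd_comx < 0 or self.noise_cv_other < 0:
            raise DomainError("noise levels must be >= 0")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")

    def biomass_curve(self) -> SigmoidCurve:
        """The generating logistic as a fitted-state sigmoid.

        X(t) = K / (1 + ((K - x0)/x0) * exp(-mu t)) is the four-parameter
        logistic with y0 = 0, a = K, tau = 1/mu and
        t0 = ln((K - x0)/x0) / mu, so X(0) = x0 exactly.
        """
        t0 = np.log((self.x_max - self.x0) / self.x0) / self.mu
        return SigmoidCurve.from_params(0.0, self.x_max, t0, 1.0 / self.mu)

    def surfactin_curve(self) -> SigmoidCurve:
        return SigmoidCurve.from_params(
            0.0, self.surfactin_max, self.surfactin_t50, self.surfactin_tau
        )

    def sample_times(self) -> np.ndarray:
        return np.arange(0.0, self.t_end + self.sample_every / 2,
                         self.sample_every)


@dataclass
class SynthTruth:
    """Noise-free generating curves and states behind a synthetic dataset."""

    times: np.ndarray
    biomass_curve: SigmoidCurve
    surfactin_curve: SigmoidCurve
    comx_params: comx_model.ComXModelParams
    ea0: float
    x_clean: np.ndarray
    glucose_clean: np.ndarray
    surfactin_clean: np.ndarray
    comx_clean: np.ndarray
    ea_csp_clean: np.ndarray
    ea_total_clean: np.ndarray
    glucose_depleted: bool

    def q_surfactin(self, t):
        """Analytic instantaneous specific productivity [g/(g*h)]."""
        t = np.asarray(t, dtype=float)
        return (self.surfactin_curve.derivative(t) / 1000.0
                / self.biomass_curve.predict(t))

    def to_dict(self) -> dict:
        d = {
            "biomass_curve": {n: getattr(self.biomass_curve, n + "_")
                              for n in ("y0", "a", "t0", "tau")},
            "surfactin_curve": {n: getattr(self.surfactin_curve, n + "_")
                                for n in ("y0", "a", "t0", "tau")},
            "comx_params": self.comx_params.values(),
            "ea0": self.ea0,
            "glucose_depleted": bool(self.glucose_depleted),
        }
        return d


def generate_cultivation(cfg: SynthConfig):
    """Generate one synthetic cultivation dataset.

    Returns ``(series, truth)``: a validated
    :class:`~comxdyn.dataio.CultivationTimeSeries` with ``n_replicates``
    noisy biological replicates on a common sampling grid, and the
    :class:`SynthTruth` generating object.  Identical configurations
    (including the seed) give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.sample_times()
    bio = cfg.biomass_curve()
    surf = cfg.surfactin_curve()
    x = bio.predict(t)
    glucose = np.maximum(cfg.s0 - (x - cfg.x0) / cfg.y_xs, 0.0)
    depleted = bool(np.any(glucose <= 0))
    p = surf.predict(t)
    traj = comx_model.simulate(cfg.comx_params, bio, t, ea0=cfg.ea0)
    ea_total = cfg.ea_per_cdw * x

    frames = []
    for rep in range(cfg.n_replicates):
        cv = cfg.noise_cv_other
        frames.append(pd.DataFrame({
            "time_h": t,
            "replicate": f"R{rep + 1}",
            "cdw_g_L": np.maximum(x * (1 + cv * rng.standard_normal(len(t))), 0.0),
            "glucose_g_L": np.maximum(
                glucose * (1 + cv * rng.standard_normal(len(t))), 0.0),
            "surfactin_mg_L": np.maximum(
                p * (1 + cv * rng.standard_normal(len(t))), 0.0),
            "comx_MU": traj.a_comx
            + cfg.noise_sd_comx * rng.standard_normal(len(t)),
            "ea_total": np.maximum(
                ea_total * (1 + cv * rng.standard_normal(len(t))), 0.0),
        }))
    series = CultivationTimeSeries(pd.concat(frames, ignore_index=True))
    truth = SynthTruth(
        times=t,
        biomass_curve=bio,
        surfactin_curve=surf,
        comx_params=cfg.comx_params,
        ea0=cfg.ea0,
        x_clean=x,
        glucose_clean=glucose,
        surfactin_clean=p,
        comx_clean=traj.a_comx,
        ea_csp_clean=traj.ea_csp,
        ea_total_clean=ea_total,
        glucose_depleted=depleted,
    )
    return series, truth


def generate_blanks(mean: float, sd: float, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` independent normal blank measurements [MU]."""
    if n < 1:
        raise DomainError("n must be >= 1")
    if sd < 0:
        raise DomainError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    return mean + sd * rng.standard_normal(n)


def generate_degradation_series(a0: float, rate: float, times,
                                noise_sd: float = 0.0,
                                seed: int = 0) -> pd.DataFrame:
    """Linear-decline incubation series: max(a0 - rate*t, 0) plus noise."""
    if rate < 0:
        raise DomainError("rate must be >= 0")
    t = np.ravel(np.asarray(times, dtype=float))
    rng = np.random.default_rng(seed)
    clean = np.maximum(a0 - rate * t, 0.0)
    comx = clean + noise_sd * rng.standard_normal(len(t))
    return pd.DataFrame({"time_h": t, "comx_MU": comx})


def generate_miller_raw(target_mu: float, od600: float = 0.5,
                        t_reaction: float = 30.0, v_sample: float = 0.1,
                        od550: float | None = None,
                        seed: int = 0) -> MillerAssayRecord:
    """Invert the Miller formula to raw absorbances hitting ``target_mu``.

    OD420 is solved exactly so that ``miller_units(record) == target_mu``;
    OD550 is drawn uniformly from [0.05, 0.3] when not given.  Targets that
    would require a negative OD420 are infeasible.
    """
    if od550 is None:
        od550 = float(np.random.default_rng(seed).uniform(0.05, 0.3))
    od420 = target_mu * t_reaction * v_sample * od600 / 1000.0 + 1.75 * od550
    if od420 < 0:
        raise InfeasibleTargetError(
            f"target {target_mu} MU implies negative OD420"
        )
    return MillerAssayRecord(
        od420=od420, od550=od550, od600=od600,
        t_reaction=t_reaction, v_sample=v_sample,
    )
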