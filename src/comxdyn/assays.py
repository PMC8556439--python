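"""Bioassay and enzyme-assay arithmetic.

Covers the beta-galactosidase reporter readout (Miller units), screening of
blank measurements and the resulting detection/quantification limits of the
ComX bioassay, the azocasein endopeptidase activity, and ComX degradation
rates from incubation series.

Miller units follow the classic normalisation

    MU = 1000 * (OD420 - 1.75 * OD550) / (t * v * OD600)

with the reaction time t in minutes and sample volume v in mL.  Detection
limits are the standard blank-based definitions LOD = mean + 3*SD and
LOQ = mean + 10*SD, computed after a single-pass exclusion of blanks whose
z-score (relative to the full set) reaches the threshold (default 2.0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError, InsufficientDataError


@dataclass(frozen=True)
class MillerAssayRecord:
    """Raw absorbances and conditions of one Miller assay reaction.

    ``t_reaction`` in minutes, ``v_sample`` in mL.
    """

    od420: float
    od550: float
    od600: float
    t_reaction: float
    v_sample: float

    def __post_init__(self):
        if not self.t_reaction > 0:
            raise DomainError("t_reaction must be > 0 min")
        if not self.v_sample > 0:
            raise DomainError("v_sample must be > 0 mL")
        if not self.od600 > 0:
            raise DomainError("od600 must be > 0")


@dataclass(frozen=True)
class BlankStatistics:
    """Mean/SD of bioassay blanks after outlier screening."""

    mean_blank: float
    sd_blank: float
    n_used: int
    n_excluded: int
    normality_p: float = float("nan")

    def __post_init__(self):
        if self.sd_blank < 0:
            raise DomainError("sd_blank must be >= 0")


@dataclass(frozen=True)
class DetectionLimits:
    """Limit of detection/quantification of the bioassay [MU]."""

    lod: float
    loq: float
    z_threshold: float = 2.0


def miller_units(rec: MillerAssayRecord) -> float:
    """Beta-galactosidase activity in Miller units.

    May be negative for blank-level noise; values are not clipped.
    """
    return (
        1000.0
        * (rec.od420 - 1.75 * rec.od550)
        / (rec.t_reaction * rec.v_sample * rec.od600)
    )


def blank_statistics(blanks, z_threshold: float = 2.0) -> BlankStatistics:
    """Screen blank measurements and return their mean/SD.

    A single pass removes values whose absolute z-score (computed from the
    mean and sample SD of the *full* set) reaches ``z_threshold``; the
    statistics are then recomputed from the remainder (sample SD, n-1
    denominator).  A Shapiro-Wilk normality p-value for the full set is
    reported, and a warning emitted if it falls below 0.05 -- normality is
    a reported gate, never an error.
    """
    x = np.ravel(np.asarray(blanks, dtype=float))
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 blank values, got {n}")
    p = float("nan")
    if np.ptp(x) > 0:
        p = float(stats.shapiro(x).pvalue)
        if p < 0.05:
            warnings.warn(
                f"blank values deviate from normality (Shapiro-Wilk p={p:.3g})",
                RuntimeWarning,
                stacklevel=2,
            )
    mean0 = float(np.mean(x))
    sd0 = float(np.std(x, ddof=1))
    if sd0 > 0 and np.isfinite(z_threshold):
        keep = np.abs(x - mean0) / sd0 < z_threshold
    else:
        keep = np.ones(n, dtype=bool)
    used = x[keep]
    mean = float(np.mean(used))
    sd = float(np.std(used, ddof=1)) if len(used) > 1 else 0.0
    return BlankStatistics(
        mean_blank=mean,
        sd_blank=sd,
        n_used=int(keep.sum()),
        n_excluded=int(n - keep.sum()),
        normality_p=p,
    )


def detection_limits(blank_stats: BlankStatistics,
                     z_threshold: float = 2.0) -> DetectionLimits:
    """LOD/LOQ from blank statistics: mean + 3*SD and mean + 10*SD."""
    return DetectionLimits(
        lod=blank_stats.mean_blank + 3.0 * blank_stats.sd_blank,
        loq=blank_stats.mean_blank + 10.0 * blank_stats.sd_blank,
        z_threshold=z_threshold,
    )


def endopeptidase_activity(a450_sample: float, a450_blank: float,
                           dilution: float = 1.0,
                           t_incubation: float = 1.0,
                           v_supernatant: float = 0.1) -> float:
    """Volumetric endopeptidase activity from the azocasein assay.

    Absorbance difference at 450 nm between sample and blank, scaled by the
    dilution factor, per hour of incubation and per mL of cell-free
    supernatant; units dA/(h*mL).  Defaults reflect the 100 uL / 1 h
    protocol.
    """
    if not t_incubation > 0:
        raise DomainError("t_incubation must be > 0 h")
    if not v_supernatant > 0:
        raise DomainError("v_supernatant must be > 0 mL")
    if dilution < 1:
        raise DomainError("dilution factor must be >= 1")
    return (a450_sample - a450_blank) * dilution / (t_incubation * v_supernatant)


def degradation_rate(time, comx, method: str = "regression") -> float:
    """ComX degradation rate [MU/h] from an incubation series.

    ``regression`` (default): negated slope of the ordinary least-squares
    line of activity vs time, so a declining series gives a positive rate.
    ``endpoints``: difference quotient between the first and last samples.
    """
    t = np.ravel(np.asarray(time, dtype=float))
    c = np.ravel(np.asarray(comx, dtype=float))
    if t.shape != c.shape:
        raise ValueError("time and comx must have the same length")
    if len(t) < 2:
        raise InsufficientDataError("need >= 2 points for a degradation rate")
    if np.any(np.diff(t) <= 0):
        raise DomainError("time must be strictly increasing")
    if method == "regression":
        slope = np.polyfit(t, c, 1)[0]
        return float(-slope)
    if method == "endpoints":
        return float((c[0] - c[-1]) / (t[-1] - t[0]))
    raise ValueError(f"unknown method {method!r}")


def percent_activity_loss(a_start: float, a_end: float) -> float:
    """Percent activity lost between two measurements: 100*(1 - end/start)."""
    if not a_start > 0:
        raise DomainError("a_start must be > 0")
    return 100.0 * (1.0 - a_end / a_start)
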