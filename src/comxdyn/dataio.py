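"""Cultivation time-series container, CSV I/O and unit conversions.

The common currency of the package is a tidy table of offline bioreactor
measurements: one row per (replicate, sampling time), columns for biomass
(OD600 and/or cell dry weight), glucose, ammonium, surfactin, ComX activity
in Miller units, and total endopeptidase activity.  Cell dry weight (CDW) is
derived from optical density through a linear correlation factor
(CDW = OD600 / factor, default factor 3.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError

#: Canonical CSV column names, in serialisation order.
CANONICAL_COLUMNS = (
    "time_h",
    "replicate",
    "od600",
    "cdw_g_L",
    "glucose_g_L",
    "ammonium_mg_L",
    "surfactin_mg_L",
    "comx_MU",
    "ea_total",
)

#: Measured observables (everything except the time/replicate keys).
OBSERVABLE_COLUMNS = tuple(
    c for c in CANONICAL_COLUMNS if c not in ("time_h", "replicate")
)

#: Columns that must be non-negative wherever present.
_NONNEGATIVE_COLUMNS = (
    "od600",
    "cdw_g_L",
    "glucose_g_L",
    "ammonium_mg_L",
    "surfactin_mg_L",
    "ea_total",
)


@dataclass(frozen=True)
class ConversionConfig:
    """Optical-density to cell-dry-weight conversion.

    CDW [g/L] = OD600 / ``od_cdw_factor``.  The factor carries an empirical
    standard deviation (``od_cdw_factor_sd``) which sets the tolerance used
    when checking consistency of jointly reported OD600 and CDW columns.
    """

    od_cdw_factor: float = 3.2
    od_cdw_factor_sd: float = 0.3

    def __post_init__(self):
        if not self.od_cdw_factor > 0:
            raise DomainError(
                f"od_cdw_factor must be > 0, got {self.od_cdw_factor}"
            )
        if self.od_cdw_factor_sd < 0:
            raise DomainError("od_cdw_factor_sd must be >= 0")

    @property
    def relative_tolerance(self) -> float:
        """Relative OD/CDW consistency tolerance (the factor's RSD)."""
        return self.od_cdw_factor_sd / self.od_cdw_factor


def cdw_from_od(od600, factor: float = 3.2):
    """Convert optical density at 600 nm to cell dry weight [g/L].

    Parameters
    ----------
    od600 : float or array-like
        Optical density, >= 0.
    factor : float
        Correlation factor (> 0); CDW = OD600 / factor.
    """
    if not factor > 0:
        raise DomainError(f"conversion factor must be > 0, got {factor}")
    od = np.asarray(od600, dtype=float)
    if np.any(od[np.isfinite(od)] < 0):
        raise DomainError("od600 must be non-negative")
    out = od / factor
    return float(out) if np.isscalar(od600) else out


@dataclass
class CultivationTimeSeries:
    """One cultivation's sampled observables over time.

    Wraps a tidy :class:`pandas.DataFrame` with the canonical columns of
    :data:`CANONICAL_COLUMNS` (unknown input columns are preserved).  Missing
    measurements are explicit NaN, never zeros.
    """

    data: pd.DataFrame
    conversion: ConversionConfig = field(default_factory=ConversionConfig)

    def __post_init__(self):
        df = self.data.copy()
        if "time_h" not in df.columns:
            raise ValidationError("time_h column is required")
        if "replicate" not in df.columns:
            df["replicate"] = "R1"
        df["time_h"] = df["time_h"].astype(float)
        present = [c for c in OBSERVABLE_COLUMNS if c in df.columns]
        if not present or df[present].isna().all().all():
            raise ValidationError("at least one observable column is required")
        if np.any(df["time_h"].to_numpy() < 0):
            raise ValidationError("time values must be non-negative")
        for rep, grp in df.groupby("replicate", sort=False):
            t = grp["time_h"].to_numpy()
            if len(np.unique(t)) != len(t):
                raise ValidationError(
                    f"duplicate time values within replicate {rep!r}"
                )
            if np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"time not strictly increasing within replicate {rep!r}"
                )
        for col in _NONNEGATIVE_COLUMNS:
            if col in df.columns:
                vals = df[col].to_numpy(dtype=float)
                bad = np.where(np.isfinite(vals) & (vals < 0))[0]
                if bad.size:
                    raise ValidationError(
                        f"negative value in column {col!r} at row {bad[0]}"
                    )
        self._check_od_cdw_consistency(df)
        self.data = df.reset_index(drop=True)

    def _check_od_cdw_consistency(self, df: pd.DataFrame) -> None:
        if "od600" not in df.columns or "cdw_g_L" not in df.columns:
            return
        od = df["od600"].to_numpy(dtype=float)
        cdw = df["cdw_g_L"].to_numpy(dtype=float)
        mask = np.isfinite(od) & np.isfinite(cdw)
        if not mask.any():
            return
        expected = od[mask] / self.conversion.od_cdw_factor
        tol = self.conversion.relative_tolerance * np.maximum(expected, 1e-12)
        off = np.abs(cdw[mask] - expected) > tol + 1e-9
        if off.any():
            row = int(np.where(mask)[0][np.argmax(off)])
            raise ValidationError(
                f"cdw_g_L inconsistent with od600/{self.conversion.od_cdw_factor} "
                f"beyond tolerance at row {row}"
            )

    # -- convenient column accessors -------------------------------------
    def _col(self, name):
        if name not in self.data.columns:
            return None
        return self.data[name].to_numpy(dtype=float)

    @property
    def time(self):
        return self.data["time_h"].to_numpy(dtype=float)

    @property
    def replicate(self):
        return self.data["replicate"].to_numpy()

    @property
    def od600(self):
        return self._col("od600")

    @property
    def cdw(self):
        return self._col("cdw_g_L")

    @property
    def glucose(self):
        return self._col("glucose_g_L")

    @property
    def ammonium(self):
        return self._col("ammonium_mg_L")

    @property
    def surfactin(self):
        return self._col("surfactin_mg_L")

    @property
    def comx_activity(self):
        return self._col("comx_MU")

    @property
    def ea_total(self):
        return self._col("ea_total")

    def replicates(self):
        """Replicate identifiers, in order of first appearance."""
        return list(dict.fromkeys(self.data["replicate"]))

    def for_replicate(self, rep) -> "CultivationTimeSeries":
        sub = self.data[self.data["replicate"] == rep]
        if sub.empty:
            raise KeyError(f"no replicate {rep!r}")
        return CultivationTimeSeries(sub, conversion=self.conversion)

    def replicate_mean(self) -> "CultivationTimeSeries":
        """Average observables over replicates at each sampling time."""
        num = [c for c in self.data.columns
               if c not in ("time_h", "replicate")
               and pd.api.types.is_numeric_dtype(self.data[c])]
        agg = self.data.groupby("time_h", sort=True)[num].mean().reset_index()
        agg["replicate"] = "mean"
        return CultivationTimeSeries(agg, conversion=self.conversion)

    def __len__(self):
        return len(self.data)


def read_timeseries(path, schema: ConversionConfig | None = None
                    ) -> CultivationTimeSeries:
    """Read a cultivation CSV into a validated :class:`CultivationTimeSeries`.

    Column headers are matched case-insensitively against the canonical names;
    unrecognised columns are preserved untouched.  If only ``od600`` is
    reported, ``cdw_g_L`` is derived through the conversion factor.  Empty
    cells become NaN.
    """
    schema = schema or ConversionConfig()
    df = pd.read_csv(path, float_precision="round_trip")
    lower = {c.lower(): c for c in CANONICAL_COLUMNS}
    df = df.rename(columns=lambda c: lower.get(str(c).strip().lower(), c))
    if "cdw_g_L" not in df.columns and "od600" in df.columns:
        df["cdw_g_L"] = cdw_from_od(
            df["od600"].to_numpy(dtype=float), schema.od_cdw_factor
        )
    return CultivationTimeSeries(df, conversion=schema)


def write_timeseries(series: CultivationTimeSeries, path) -> None:
    """Write a series to CSV with canonical column order and full precision.

    Floats are serialised via ``repr`` so a read/write round trip preserves
    every value bit-for-bit; missing values become empty cells.
    """
    df = series.data
    cols = [c for c in CANONICAL_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    out = df[cols].copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False)
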