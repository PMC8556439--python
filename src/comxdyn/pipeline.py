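"""End-to-end analysis pipeline: curves -> kinetics -> metrics -> assays.

Wires the package stages into the full cultivation analysis: fit smooth
curves to the observables, estimate the ComX kinetic parameters, compute
the sensitivity envelope, batch performance metrics, detection limits from
blanks, and the productivity-versus-ComX curve.  Every artifact written is
listed in a manifest with a content hash so a rerun with the same config
and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import assays, comx_model, curvefit, estimation, metrics, synthgen
from .dataio import ConversionConfig, read_timeseries, write_timeseries
from .exceptions import ComxdynError, ValidationError

log = logging.getLogger("comxdyn")


@dataclass
class PipelineConfig:
    """Validated configuration of a pipeline run.

    With ``input_csv`` unset, a synthetic cultivation is generated from
    ``synth`` (seeded); otherwise the CSV is read.  Optional blank and
    degradation CSVs feed the assay summaries.
    """

    outdir: str = "comxdyn_out"
    input_csv: str | None = None
    blanks_csv: str | None = None
    degradation_csv: str | None = None
    seed: int = 0
    ea0: float = 0.0
    envelope_frac: float = 0.08
    conversion: ConversionConfig = field(default_factory=ConversionConfig)
    synth: synthgen.SynthConfig = field(default_factory=synthgen.SynthConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError("pipeline config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "conversion" in kwargs:
            kwargs["conversion"] = ConversionConfig(**kwargs["conversion"])
        if "synth" in kwargs:
            synth_raw = dict(kwargs["synth"])
            if "comx_params" in synth_raw:
                synth_raw["comx_params"] = comx_model.ComXModelParams(
                    **synth_raw["comx_params"]
                )
            kwargs["synth"] = synthgen.SynthConfig(**synth_raw)
        cfg = cls(**kwargs)
        for key in ("input_csv", "blanks_csv", "degradation_csv"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise ComxdynError(f"{key} does not exist: {p}")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_yaml(obj, path: Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return the manifest (also written as JSON).

    On a stage failure, artifacts completed so far are retained and listed
    in the manifest before the error propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": [], "artifacts": {}}

    def record(stage: str, *paths: Path):
        manifest["stages"].append(stage)
        for p in paths:
            manifest["artifacts"][p.name] = _sha256(p)
        log.info("stage %s complete (%d artifacts)", stage, len(paths))

    def flush():
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        # -- stage: data ------------------------------------------------
        if config.input_csv is None:
            synth_cfg = synthgen.SynthConfig(
                **{**vars(config.synth), "seed": config.seed}
            )
            series, truth = synthgen.generate_cultivation(synth_cfg)
            csv_path = outdir / "cultivation.csv"
            write_timeseries(series, csv_path)
            _dump_yaml(truth.to_dict(), outdir / "truth.yaml")
            record("synth", csv_path, outdir / "truth.yaml")
        else:
            series = read_timeseries(config.input_csv, config.conversion)
            record("read")

        mean = series.replicate_mean()

        # -- stage: curve fits ------------------------------------------
        fits = {}
        for name, values in (("biomass", mean.cdw),
                             ("surfactin", mean.surfactin),
                             ("comx", mean.comx_activity)):
            if values is not None and np.isfinite(values).sum() >= 5:
                fits[name] = curvefit.fit_sigmoid4(mean.time, values)
        if "biomass" not in fits:
            raise ComxdynError("cannot fit biomass: too few CDW values")
        _dump_yaml(
            {name: {p: float(getattr(f, p + "_"))
                    for p in ("y0", "a", "t0", "tau")}
             | {"residual_sse": float(f.residual_sse_)}
             for name, f in fits.items()},
            outdir / "curve_fits.yaml",
        )
        record("curvefit", outdir / "curve_fits.yaml")

        # -- stage: kinetic parameter estimation ------------------------
        result = estimation.fit_comx_params(
            series, fits["biomass"], ea0=config.ea0,
            random_state=config.seed,
        )
        _dump_yaml(
            {
                "params": {k: float(v) for k, v in result.params.values().items()},
                "sse": float(result.sse),
                "n_obs": result.n_obs,
                "converged": result.converged,
                "at_bounds": result.at_bounds,
            },
            outdir / "comx_fit.yaml",
        )
        record("estimate", outdir / "comx_fit.yaml")

        # -- stage: simulation + sensitivity envelope -------------------
        t_grid = np.linspace(float(mean.time.min()), float(mean.time.max()), 241)
        traj = comx_model.simulate(result.params, fits["biomass"], t_grid,
                                   ea0=config.ea0)
        traj.to_frame().to_csv(outdir / "trajectory.csv", index=False)
        band = comx_model.sensitivity_envelope(
            result.params, fits["biomass"], t_grid,
            frac=config.envelope_frac, ea0=config.ea0,
        )
        import pandas as pd

        pd.DataFrame({
            "time_h": band.time, "comx_MU_lower": band.lower,
            "comx_MU_nominal": band.nominal, "comx_MU_upper": band.upper,
        }).to_csv(outdir / "envelope.csv", index=False)
        record("simulate", outdir / "trajectory.csv", outdir / "envelope.csv")

        # -- stage: process metrics -------------------------------------
        pm = metrics.process_metrics(series)
        _dump_yaml({k: float(v) for k, v in pm.to_dict().items()},
                   outdir / "metrics.yaml")
        record("metrics", outdir / "metrics.yaml")

        # -- stage: q vs ComX -------------------------------------------
        if "surfactin" in fits and "comx" in fits:
            curve = metrics.q_vs_comx(fits["biomass"], fits["surfactin"],
                                      fits["comx"], t_grid)
            pd.DataFrame({
                "time_h": curve.t, "comx_MU": curve.comx,
                "q_surfactin_g_per_g_h": curve.q_surfactin,
            }).to_csv(outdir / "q_vs_comx.csv", index=False)
            record("q_vs_comx", outdir / "q_vs_comx.csv")

        # -- stage: assays ----------------------------------------------
        if config.blanks_csv is not None:
            import pandas as pd

            blanks = pd.read_csv(config.blanks_csv)["comx_MU"].to_numpy()
            stats = assays.blank_statistics(blanks)
            limits = assays.detection_limits(stats)
            _dump_yaml(
                {
                    "mean_blank": stats.mean_blank,
                    "sd_blank": stats.sd_blank,
                    "n_used": stats.n_used,
                    "n_excluded": stats.n_excluded,
                    "normality_p": float(stats.normality_p),
                    "lod": limits.lod,
                    "loq": limits.loq,
                },
                outdir / "detection_limits.yaml",
            )
            record("detection_limits", outdir / "detection_limits.yaml")
        if config.degradation_csv is not None:
            import pandas as pd

            deg = pd.read_csv(config.degradation_csv)
            rate = assays.degradation_rate(deg["time_h"], deg["comx_MU"])
            _dump_yaml({"degradation_rate_MU_per_h": float(rate)},
                       outdir / "degradation.yaml")
            record("degradation", outdir / "degradation.yaml")
    finally:
        flush()
    return manifest
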