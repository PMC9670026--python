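"""Trace/manifest file formats, pipeline configuration and the pipeline driver.

Traces are plain CSV with a ``time_s,response_pm`` header; manifests are CSV
with the columns documented in :mod:`aggsense.synthetic`.  Pipeline
configuration is a strict (unknown keys rejected) pydantic schema, typically
loaded from YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .kinetics import InjectionProtocol, Sensorgram

__all__ = [
    "FormatError",
    "read_sensorgram",
    "write_sensorgram",
    "load_manifest_traces",
    "PipelineConfig",
    "run_pipeline",
]


class FormatError(ValueError):
    """Malformed trace or manifest file."""


def write_sensorgram(trace: Sensorgram, path: "str | Path") -> None:
    """Write a trace as ``time_s,response_pm`` CSV (6 significant figures)."""
    df = pd.DataFrame({"time_s": trace.time, "response_pm": trace.response})
    df.to_csv(path, index=False, float_format="%.6g")


def read_sensorgram(
    path: "str | Path", protocol: "InjectionProtocol | None" = None
) -> Sensorgram:
    """Read a ``time_s,response_pm`` CSV trace.

    ``protocol`` supplies the phase landmarks (defaults to the standard
    10/110/300 s protocol with the sample rate inferred from the file).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # empty file, parser errors
        raise FormatError(f"{path}: cannot parse trace CSV ({exc})") from exc
    missing = {"time_s", "response_pm"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df) < 3:
        raise FormatError(f"{path}: trace needs at least 3 rows")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +2: header line is 1, data starts at line 2
        raise FormatError(
            f"{path}: time not strictly increasing at line {int(bad[0]) + 3}"
        )
    if not np.all(np.isfinite(df["response_pm"].to_numpy(dtype=float))):
        raise FormatError(f"{path}: non-finite response values")
    if protocol is None:
        rate = 1.0 / float(t[1] - t[0])
        protocol = InjectionProtocol(t_end=float(t[-1]), sample_rate=rate)
    return Sensorgram(
        time=t,
        response=df["response_pm"].to_numpy(dtype=float),
        protocol=protocol,
        metadata={"path": str(path)},
    )


def load_manifest_traces(manifest: "pd.DataFrame | str | Path") -> pd.DataFrame:
    """Ensure a manifest has its traces attached under ``attrs['traces']``.

    Accepts a manifest DataFrame (possibly already carrying in-memory traces)
    or a path to ``manifest.csv``, in which case each trace CSV is read.
    """
    if not isinstance(manifest, pd.DataFrame):
        mpath = Path(manifest)
        df = pd.read_csv(mpath)
        traces = {}
        for _, row in df.iterrows():
            p = Path(row["path"])
            if not p.is_absolute():
                p = mpath.parent / p
            tr = read_sensorgram(p)
            tr.metadata.update(row.to_dict())
            traces[row["sample_id"]] = tr
        df.attrs["traces"] = traces
        return df
    if "traces" not in manifest.attrs:
        raise ValueError("manifest DataFrame carries no in-memory traces")
    return manifest


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sigma: float = 2.0
    bulk_jump: float = -10.0
    drift: float = 0.0


class FeatureConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    derivative_window: int = 11
    assoc_mask_s: float = 3.0


class CalibrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    exclusion_threshold_pm: float = 550.0
    lod_range_ug_per_ml: tuple[float, float] = (9.0, 21.0)


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: Literal["dissociation_only", "both_phases"] = "dissociation_only"
    hidden: int = 16
    epochs: int = 2000
    learning_rate: float = 0.01


class PipelineConfig(BaseModel):
    """Validated end-to-end pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    design: Literal["fig3_levels", "fig4_grid", "fig5_lowrange"] = "fig4_grid"
    ph: float = 3.8
    seed: int = 0
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    features: FeatureConfig = Field(default_factory=FeatureConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


def run_pipeline(config: PipelineConfig, out_dir: "str | Path") -> Path:
    """Run simulate -> features -> (calibrate | train/evaluate) for a design.

    Writes manifest, per-trace CSVs, ``features.csv`` and, depending on the
    design, ``calibration.json`` + ``control_predictions.csv`` (fig4_grid) or
    ``model.json`` + ``predictions.csv`` + ``evaluation.json``
    (fig5_lowrange).  Returns the run directory.
    """
    from . import calibration as calib_mod
    from . import features as feat_mod
    from . import nn as nn_mod
    from .synthetic import NoiseModel, generate_design

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    noise = NoiseModel(
        sigma=config.noise.sigma,
        bulk_jump=config.noise.bulk_jump,
        drift=config.noise.drift,
        seed=config.seed,
    )
    manifest = generate_design(config.design, noise=noise, out_dir=out / "traces",
                               ph=config.ph)
    manifest.to_csv(out / "manifest.csv", index=False)

    feats = feat_mod.extract_features(
        manifest, derivative_window=config.features.derivative_window
    )
    feats.to_csv(out / "features.csv", index=False)

    log: dict = {"design": config.design, "seed": config.seed,
                 "config": config.model_dump()}

    if config.design == "fig4_grid":
        model = calib_mod.calibrate_from_features(
            feats, manifest,
            exclusion_threshold=config.calibration.exclusion_threshold_pm,
            lod_range=config.calibration.lod_range_ug_per_ml,
        )
        (out / "calibration.json").write_text(json.dumps(model.to_dict(), indent=2))
        preds = calib_mod.predict_controls(model, feats, manifest)
        preds.to_csv(out / "control_predictions.csv", index=False)
        log["calibration"] = {"lod_ug_per_ml": model.lod, "loq_ug_per_ml": model.loq}
    elif config.design == "fig5_lowrange":
        reg, report, preds = nn_mod.train_and_evaluate(
            feats, manifest, mode=config.model.mode, seed=config.seed,
            hidden=config.model.hidden, epochs=config.model.epochs,
            learning_rate=config.model.learning_rate,
        )
        nn_mod.save_model(reg, out / "model.json")
        preds.to_csv(out / "predictions.csv", index=False)
        (out / "evaluation.json").write_text(json.dumps(report.to_dict(), indent=2))
        log["evaluation"] = report.to_dict()

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out
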