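"""Delimited-text and JSON artifact formats.

Frozen column conventions:

- measurement tables (CSV): ``time``, one column per output, optional
  ``sd_<output>`` columns with per-point standard deviations;
- input tables (CSV): ``time`` then one column per input channel;
- trajectory exports (CSV): ``time``, ``x_<state>``, ``w_<state>``,
  ``y_<output>``;
- AUC tables (CSV): ``component``, ``auc``, ``fraction``;
- run reports (JSON): config echo, software version, seed and a config hash
  so a report plus its input files reproduces the run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import AucTable
from .models import ConfigurationError, KnownInput, MeasurementSet, OdeModel
from .solver import DenSolution

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_input_table",
    "write_input_table",
    "write_trajectories",
    "write_auc_table",
    "write_report",
    "config_hash",
]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"file not found: {path}")
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ConfigurationError(f"{path.name}: missing required column 'time'")
    if not np.issubdtype(df["time"].dtype, np.number):
        raise ConfigurationError(f"{path.name}: column 'time' is not numeric")
    if not np.all(np.diff(df["time"].to_numpy()) > 0):
        raise ConfigurationError(f"{path.name}: column 'time' must be strictly increasing")
    return df


def read_measurements(path, output_labels=None) -> MeasurementSet:
    """Read a measurement CSV (time, outputs, optional sd_* columns).

    With ``output_labels`` the named columns are selected in that order and a
    missing column is reported by name; otherwise every non-time, non-sd
    column is an output.  When sd columns are absent the weighting defaults
    to identity.
    """
    df = _read_table(path)
    cols = [c for c in df.columns if c != "time" and not c.startswith("sd_")]
    if output_labels is not None:
        missing = [c for c in output_labels if c not in df.columns]
        if missing:
            raise ConfigurationError(
                f"{Path(path).name}: missing measurement column(s) {missing}")
        cols = list(output_labels)
    if not cols:
        raise ConfigurationError(f"{Path(path).name}: no output columns found")
    obs = df[cols].to_numpy(float)
    sd_cols = [f"sd_{c}" for c in cols]
    sds = None
    if all(c in df.columns for c in sd_cols):
        sds = df[sd_cols].to_numpy(float)
    elif any(c in df.columns for c in sd_cols):
        present = [c for c in sd_cols if c in df.columns]
        raise ConfigurationError(
            f"{Path(path).name}: partial sd columns {present}; provide all or none")
    return MeasurementSet(df["time"].to_numpy(float), obs, sds=sds)


def write_measurements(path, data: MeasurementSet, output_labels=None) -> None:
    m = data.n_outputs
    labels = list(output_labels) if output_labels else [f"y{i+1}" for i in range(m)]
    out = {"time": data.sample_times}
    for j, lab in enumerate(labels):
        out[lab] = data.observations[:, j]
    if data.sds is not None:
        for j, lab in enumerate(labels):
            out[f"sd_{lab}"] = data.sds[:, j]
    pd.DataFrame(out).to_csv(path, index=False)


def read_input_table(path, interpolation: str = "piecewise-linear") -> KnownInput:
    df = _read_table(path)
    cols = [c for c in df.columns if c != "time"]
    if not cols:
        raise ConfigurationError(f"{Path(path).name}: no input channel columns")
    return KnownInput(df["time"].to_numpy(float), df[cols].to_numpy(float),
                      interpolation=interpolation)


def write_input_table(path, input: KnownInput, labels=None) -> None:
    labels = list(labels) if labels else [f"u{i+1}" for i in range(input.n_inputs)]
    out = {"time": input.times}
    for j, lab in enumerate(labels):
        out[lab] = input.values[:, j]
    pd.DataFrame(out).to_csv(path, index=False)


def write_trajectories(path, solution: DenSolution, model: OdeModel) -> None:
    """Write time, x_hat, w_hat and y_hat on the solution's dense grid."""
    est = solution.state_estimate
    w = solution.hidden_input(est.times)
    out = {"time": est.times}
    for k, lab in enumerate(model.state_labels):
        out[f"x_{lab}"] = est.states[:, k]
    for k, lab in enumerate(model.state_labels):
        out[f"w_{lab}"] = w[:, k]
    for j, lab in enumerate(model.output_labels):
        out[f"y_{lab}"] = est.outputs[:, j]
    pd.DataFrame(out).to_csv(path, index=False)


def write_auc_table(path, auc: AucTable, labels=None) -> None:
    auc.as_frame(labels).to_csv(path, index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable config echo."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(path, report: dict) -> None:
    """Write a JSON run report; embeds the config hash alongside the echo."""
    report = dict(report)
    if "config" in report and "config_hash" not in report:
        report["config_hash"] = config_hash(report["config"])

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")
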