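"""CSV/JSON readers and writers shared by the CLI commands.

Formats:
* EMG CSV — header ``time_s,emg1,emg2``, 1-kHz rows, MVC-normalized values.
* Drive CSV — header ``time_s,drive1,drive2``.
* Trace CSV — header ``time_s,f1_hz,f2_hz``.
* Evaluation report — JSON validated against the shipped pydantic schema.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

logger = logging.getLogger(__name__)

__all__ = [
    "read_emg_csv",
    "write_drive_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_report_json",
    "EvaluationReport",
]


def _read_timed_csv(path, columns: tuple[str, ...], expected_dt: float | None, on_bad_dt: str):
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; header must be {list(columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(f"{path}: time not strictly increasing at data row {bad[0] + 2}")
    if expected_dt is not None and t.size >= 2:
        dt = float(np.median(np.diff(t)))
        if not np.isclose(dt, expected_dt, rtol=1e-3):
            msg = f"{path}: time step {dt:g} s differs from expected {expected_dt:g} s"
            if on_bad_dt == "fail":
                raise ValueError(msg)
            logger.warning(msg)
            if on_bad_dt == "resample":
                new_t = np.arange(t[0], t[-1] + expected_dt / 2, expected_dt)
                data = {"time_s": new_t}
                for c in columns[1:]:
                    data[c] = np.interp(new_t, t, df[c].to_numpy(dtype=float))
                df = pd.DataFrame(data)
    return df


def read_emg_csv(path, expected_dt: float | None = 0.001, on_bad_dt: str = "warn"):
    """Read a two-channel rectified-EMG stream.

    Returns ``(time_s, emg)`` with ``emg`` of shape (n, 2).  ``on_bad_dt``
    selects the policy when the sampling step deviates from 1 ms:
    ``"warn"`` (default), ``"resample"`` (linear), or ``"fail"``.
    """
    df = _read_timed_csv(path, ("time_s", "emg1", "emg2"), expected_dt, on_bad_dt)
    emg = df[["emg1", "emg2"]].to_numpy(dtype=float)
    if np.any(emg < 0):
        row = int(np.argwhere(np.any(emg < 0, axis=1))[0][0])
        raise ValueError(f"{path}: negative EMG amplitude at data row {row + 2}")
    return df["time_s"].to_numpy(dtype=float), emg


def write_drive_csv(path, time_s, drives) -> None:
    drives = np.asarray(drives)
    pd.DataFrame(
        {"time_s": time_s, "drive1": drives[:, 0], "drive2": drives[:, 1]}
    ).to_csv(path, index=False)


def write_trace_csv(path, trace) -> None:
    pd.DataFrame(
        {"time_s": trace.time_s, "f1_hz": trace.f1_hz, "f2_hz": trace.f2_hz}
    ).to_csv(path, index=False)


def read_trace_csv(path, expected_dt: float | None = 0.001, on_bad_dt: str = "warn"):
    from .formant_map import FormantTrace

    df = _read_timed_csv(path, ("time_s", "f1_hz", "f2_hz"), expected_dt, on_bad_dt)
    return FormantTrace(
        df["time_s"].to_numpy(dtype=float),
        df["f1_hz"].to_numpy(dtype=float),
        df["f2_hz"].to_numpy(dtype=float),
    )


class ListenerEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    listener: int = Field(ge=1)
    fraction_correct: float = Field(ge=0.0, le=1.0)
    kappa: float
    label: str


class EvaluationReport(BaseModel):
    """Schema of the ``evaluate`` command's JSON report."""

    model_config = ConfigDict(extra="forbid")
    n_trials: int = Field(ge=1)
    n_listeners: int = Field(ge=1)
    per_listener: list[ListenerEntry]
    fraction_correct_mean: float = Field(ge=0.0, le=1.0)
    kappa_mean: float
    kappa_sd: float = Field(ge=0.0)
    kappa_mean_label: str
    fleiss_kappa: float | None = None
    fleiss_label: str | None = None
    provenance: dict | None = None


def write_report_json(report: dict, path, provenance: dict | None = None) -> None:
    """Validate a session report against the schema and write it as JSON."""
    payload = dict(report)
    if provenance is not None:
        payload["provenance"] = provenance
    model = EvaluationReport.model_validate(payload)
    Path(path).write_text(
        json.dumps(model.model_dump(), indent=2, ensure_ascii=False), encoding="utf-8"
    )
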