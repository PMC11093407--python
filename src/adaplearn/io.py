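"""Readers and writers for sequence and session tables.

Two plain-CSV schemas are used throughout:

* **Sequence table** -- one row per observation of a generated sequence,
  columns ``task, sequence_id, t, x, h, cp`` with ``t`` 1-based, plus a
  JSON sidecar (same path, ``.json`` suffix) carrying the generating
  config and seed per sequence.
* **Session table** -- one row per (subject, sequence, observation),
  columns ``task, subject_id, sequence_id, t, x, v`` and optionally
  ``h, cp``.  This mirrors what a behavioral dataset would provide, so
  real sessions can be imported through the same path as simulated ones.

All files are UTF-8, comma-separated, '.' decimal, header required.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .agents import EstimateTrace
from .errors import DataError, ValidationError
from .seqgen import (MagnitudeGenConfig, ObservationSequence,
                     ProbabilityGenConfig)

__all__ = [
    "SessionTable",
    "write_sequences", "read_sequences",
    "write_sessions", "read_sessions",
    "write_normative_traces",
    "session_table_from_traces", "traces_from_session_table",
]

SESSION_COLUMNS = ["task", "subject_id", "sequence_id", "t", "x", "v"]
_TASKS = ("magnitude", "probability")


@dataclass
class SessionTable:
    """Validated long-format table of per-observation reports."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def subjects(self) -> List[str]:
        return sorted(self.df["subject_id"].unique())

    @property
    def sequences(self) -> List[str]:
        return sorted(self.df["sequence_id"].unique())


def _config_to_dict(config) -> dict:
    if config is None:
        return {}
    d = dataclasses.asdict(config)
    d["_type"] = type(config).__name__
    return d


def _config_from_dict(d: dict):
    d = dict(d)
    typ = d.pop("_type", None)
    if typ == "MagnitudeGenConfig":
        d["mean_support"] = tuple(d["mean_support"])
        return MagnitudeGenConfig(**d)
    if typ == "ProbabilityGenConfig":
        d["p_support"] = tuple(d["p_support"])
        return ProbabilityGenConfig(**d)
    return None


def write_sequences(seqs: Sequence[ObservationSequence], path) -> None:
    """Write sequences as CSV plus a JSON sidecar with configs and seeds."""
    path = Path(path)
    frames = []
    sidecar = []
    for s in seqs:
        frames.append(pd.DataFrame({
            "task": s.task, "sequence_id": s.sequence_id,
            "t": np.arange(1, s.n_obs + 1), "x": s.x, "h": s.h,
            "cp": s.cp.astype(int),
        }))
        sidecar.append({"sequence_id": s.sequence_id, "task": s.task,
                        "seed": s.seed, "config": _config_to_dict(s.config)})
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_sequences(path) -> List[ObservationSequence]:
    """Read a sequence table (and its sidecar, if present) back into objects."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"task", "sequence_id", "t", "x", "h", "cp"} - set(df.columns)
    if missing:
        raise DataError(f"sequence table missing columns: {sorted(missing)}")
    meta: Dict[str, dict] = {}
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = {m["sequence_id"]: m for m in json.loads(sidecar_path.read_text())}
    seqs = []
    for sid, g in df.groupby("sequence_id", sort=False):
        g = g.sort_values("t")
        m = meta.get(str(sid), {})
        seqs.append(ObservationSequence(
            task=str(g["task"].iloc[0]),
            x=g["x"].to_numpy(float),
            h=g["h"].to_numpy(float),
            cp=g["cp"].to_numpy().astype(bool),
            seed=m.get("seed"), sequence_id=str(sid),
            config=_config_from_dict(m.get("config", {})),
        ))
    return seqs


def write_normative_traces(traces, path) -> None:
    """Write observer traces as tidy CSV (one row per observation)."""
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "task": tr.task, "sequence_id": tr.sequence_id,
            "t": np.arange(1, tr.n_obs + 1), "v": tr.v, "u": tr.u,
            "omega": tr.omega, "alpha": tr.alpha,
        }))
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False,
                                                float_format="%.17g")


def session_table_from_traces(
    traces: Sequence[EstimateTrace],
    seqs_by_id: Mapping[str, ObservationSequence],
    metadata: Optional[dict] = None,
) -> SessionTable:
    """Assemble a session table from simulated traces and their sequences."""
    frames = []
    for tr in traces:
        seq = seqs_by_id[tr.sequence_id]
        frames.append(pd.DataFrame({
            "task": seq.task, "subject_id": tr.subject_id,
            "sequence_id": tr.sequence_id,
            "t": np.arange(1, seq.n_obs + 1),
            "x": seq.x, "v": tr.estimates,
            "h": seq.h, "cp": seq.cp.astype(int),
        }))
    return SessionTable(pd.concat(frames, ignore_index=True),
                        metadata=dict(metadata or {}))


def traces_from_session_table(table: SessionTable) -> List[EstimateTrace]:
    """Rebuild estimate traces (v_0 = 0.5 prepended) from a session table."""
    traces = []
    for (sub, sid), g in table.df.groupby(["subject_id", "sequence_id"],
                                          sort=False):
        g = g.sort_values("t")
        v = np.concatenate([[0.5], g["v"].to_numpy(float)])
        traces.append(EstimateTrace(v, subject_id=str(sub),
                                    sequence_id=str(sid)))
    return traces


def write_sessions(table: SessionTable, path) -> None:
    path = Path(path)
    table.df.to_csv(path, index=False, float_format="%.17g")
    if table.metadata:
        path.with_suffix(".json").write_text(
            json.dumps(table.metadata, indent=1, sort_keys=True))


def read_sessions(path) -> SessionTable:
    """Read and validate a session table; all failures reported at once."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    failures: List[str] = []

    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError([f"missing columns: {sorted(missing)}"])

    bad_task = ~df["task"].isin(_TASKS)
    for i in df.index[bad_task]:
        failures.append(f"row {i}: task {df.at[i, 'task']!r} not in {_TASKS}")
    for col in ("x", "v"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals > 1)
        for i in df.index[bad]:
            failures.append(f"row {i}: {col}={df.at[i, col]!r} outside [0, 1]")
    prob = df["task"] == "probability"
    nonbin = prob & ~df["x"].isin([0, 1, 0.0, 1.0])
    for i in df.index[nonbin]:
        failures.append(
            f"row {i}: probability-task x={df.at[i, 'x']!r} is not binary")
    for (sub, sid), g in df.groupby(["subject_id", "sequence_id"], sort=False):
        t = g.sort_values("t")["t"].to_numpy()
        if not np.array_equal(t, np.arange(1, len(t) + 1)):
            failures.append(
                f"subject {sub!r} sequence {sid!r}: t not contiguous from 1")
    if failures:
        raise ValidationError(failures)

    metadata = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
    return SessionTable(df, metadata=metadata)
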