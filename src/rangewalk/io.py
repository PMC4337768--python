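"""Shared I/O: trajectory CSV reading/writing, reports, run provenance."""

from __future__ import annotations

import json
import numpy as np
import pandas as pd
from pathlib import Path

from .trajstats import TrajectorySet

__all__ = ["read_trajectories", "write_trajectories", "write_report",
           "load_config"]


def read_trajectories(path) -> TrajectorySet:
    """Read a relocation CSV with header ``id,t,x,y`` (validated).

    Malformed rows and duplicate (id, t) records are rejected with line
    numbers (1-based, header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("id", "t", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for c in ("t", "x", "y"):
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any() or df[c].isna().any():
            lines = (df.index[bad | df[c].isna()] + 2).tolist()[:5]
            raise ValueError(f"{path}: non-numeric or missing {c!r} "
                             f"at lines {lines}")
        df[c] = pd.to_numeric(df[c])
    dup = df.duplicated(subset=["id", "t"], keep=False)
    if dup.any():
        lines = (df.index[df.duplicated(subset=['id', 't'])] + 2).tolist()[:5]
        raise ValueError(f"{path}: duplicate (id, t) records at lines {lines}")
    return TrajectorySet(df)


def write_trajectories(traj: TrajectorySet, path) -> None:
    traj.df.to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "as_dict"):
        return _jsonable(obj.as_dict())
    return obj


def write_report(results: dict, path) -> None:
    """Human-readable text + machine-readable JSON section, full precision.

    Re-running with identical inputs produces a byte-identical JSON
    section (keys sorted, repr-precision floats).
    """
    path = Path(path)
    payload = _jsonable(results)
    lines = ["# rangewalk report", ""]
    for k, v in payload.items():
        lines.append(f"{k}: {v}")
    lines += ["", "--- machine-readable ---",
              json.dumps(payload, sort_keys=True)]
    path.write_text("\n".join(lines) + "\n")


def load_config(path, allowed: set | None = None) -> dict:
    """Flat key-value config (YAML subset); unknown structure or keys
    rejected."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    if allowed is not None:
        unknown = sorted(set(cfg) - set(allowed))
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
    return cfg
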