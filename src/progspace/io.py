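"""Serialization: program ensembles as JSON-lines, config files, tables.

An ensemble file starts with a header object carrying the schema version
and task parameters, followed by one JSON object per program::

    {"schema": "progspace-ensemble", "version": 1, "params": {...}}
    {"M": 2, "labels": [-1, 1], "t_lose": [1, 0], "t_win": [0, 1],
     "id": "-+:10:01", "reward_rate": 0.3827, "flags": {"good": false}}

Round-trips are lossless including flags and rates; malformed records
fail with their line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .enumeration import Ensemble
from .programs import Program
from .task import TaskParams

__all__ = ["write_ensemble", "read_ensemble", "load_config", "ensemble_table"]

SCHEMA = "progspace-ensemble"
VERSION = 1


def write_ensemble(ensemble: Ensemble, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        header = {
            "schema": SCHEMA,
            "version": VERSION,
            "params": ensemble.params.to_dict(),
            "provenance": ensemble.provenance,
        }
        fh.write(json.dumps(header) + "\n")
        for i, p in enumerate(ensemble):
            rec = p.to_record()
            if ensemble.reward_rates is not None:
                rec["reward_rate"] = float(ensemble.reward_rates[i])
            if ensemble.flags:
                rec["flags"] = {k: bool(v[i]) for k, v in ensemble.flags.items()}
            fh.write(json.dumps(rec) + "\n")


def read_ensemble(path) -> Ensemble:
    path = Path(path)
    programs: list[Program] = []
    rates: list[float] = []
    flags: dict[str, list[bool]] = {}
    with path.open() as fh:
        try:
            header = json.loads(fh.readline())
        except json.JSONDecodeError as e:
            raise ValueError(f"{path}:1: malformed header: {e}") from e
        if header.get("schema") != SCHEMA:
            raise ValueError(f"{path}: not a {SCHEMA} file")
        if header.get("version") != VERSION:
            raise ValueError(
                f"{path}: unsupported schema version {header.get('version')!r}"
            )
        params = TaskParams.from_dict(header["params"])
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                p = Program.from_record(rec)
            except (json.JSONDecodeError, KeyError, ValueError) as e:
                raise ValueError(f"{path}:{lineno}: malformed record: {e}") from e
            programs.append(p)
            if "reward_rate" in rec:
                rates.append(rec["reward_rate"])
            for k, v in rec.get("flags", {}).items():
                flags.setdefault(k, []).append(bool(v))
    ens = Ensemble(
        programs=programs,
        params=params,
        provenance=header.get("provenance", "loaded"),
    )
    if len(rates) == len(programs) and rates:
        ens.reward_rates = np.array(rates)
    for k, v in flags.items():
        if len(v) == len(programs):
            ens.flags[k] = np.array(v, dtype=bool)
    return ens


def load_config(path) -> dict:
    """Key-value config (YAML); task parameters under ``mean_reward``,
    ``contrast``, ``hazard`` round-trip through TaskParams."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def ensemble_table(ensemble: Ensemble):
    """Evaluation table: one row per program (id, M, reward_rate, flags)."""
    import pandas as pd

    rows = []
    for i, p in enumerate(ensemble):
        row = {"id": p.canonical_id, "M": p.size}
        if ensemble.reward_rates is not None:
            row["reward_rate"] = float(ensemble.reward_rates[i])
        for k, v in ensemble.flags.items():
            row[k] = bool(v[i])
        rows.append(row)
    return pd.DataFrame(rows)
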