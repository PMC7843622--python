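"""Readers and writers for every schema the pipeline touches.

Every output file is self-describing: CSV files carry ``#`` comment
headers with the schema version and units, JSON outputs embed a
``schema`` field.  All readers validate and report the offending file,
line and column on mismatch.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .damage import DamageSummary, ScoringRules
from .dosimetry import DoseResult
from .geometry import DNAGeometry, SourceVolume
from .survival import ColonyRecord
from .track import KIND_CODES, KIND_NAMES, PhysicsModel, TrackResult

__all__ = [
    "SCHEMA_VERSION",
    "write_colony_csv",
    "read_colony_csv",
    "write_events_jsonl",
    "read_events_jsonl",
    "write_events_csv",
    "read_events_csv",
    "write_dose_json",
    "read_dose_json",
    "write_summary_csv",
    "read_summary_csv",
    "write_yaml",
    "read_geometry_yaml",
    "read_rules_yaml",
    "read_physics_yaml",
]

SCHEMA_VERSION = "1"

COLONY_COLUMNS = ["arm", "dose_gy", "cells_seeded", "colonies", "replicate"]
EVENT_COLUMNS = ["primary_id", "step", "kind", "x_nm", "y_nm", "z_nm", "energy_ev"]


def _header(schema: str, units: str) -> str:
    return f"# betaplus {schema} schema v{SCHEMA_VERSION}\n# {units}\n"


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def write_colony_csv(path: Union[str, Path], records: Sequence[ColonyRecord]) -> None:
    df = pd.DataFrame([asdict(r) for r in records], columns=COLONY_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_header("colony-records", "dose_gy in Gy; counts dimensionless"))
        df.to_csv(fh, index=False)


def read_colony_csv(path: Union[str, Path]) -> List[ColonyRecord]:
    df = pd.read_csv(path, comment="#")
    missing = set(COLONY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ColonyRecord(
                    arm=str(row["arm"]),
                    dose_gy=float(row["dose_gy"]),
                    cells_seeded=int(row["cells_seeded"]),
                    colonies=int(row["colonies"]),
                    replicate=int(row["replicate"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {i + 1}: {exc}") from None
    return records


def _track_event_rows(tracks: Iterable[TrackResult]):
    for tr in tracks:
        for step in range(len(tr.energies)):
            yield {
                "primary_id": tr.primary_id,
                "step": step,
                "kind": KIND_NAMES[int(tr.kinds[step])],
                "x_nm": float(tr.positions[step, 0]),
                "y_nm": float(tr.positions[step, 1]),
                "z_nm": float(tr.positions[step, 2]),
                "energy_ev": float(tr.energies[step]),
            }


def write_events_jsonl(path: Union[str, Path], tracks: Iterable[TrackResult]) -> None:
    """One deposition event per line, streamable at large campaign sizes."""
    with open(path, "w") as fh:
        for row in _track_event_rows(tracks):
            fh.write(json.dumps(row) + "\n")


def read_events_jsonl(path: Union[str, Path]):
    """Read an event stream; returns (positions, energies, primary_ids, kinds)."""
    pos, energy, pid, kind = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                row = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}:{lineno}: invalid JSON: {exc}") from None
            _validate_event_row(row, path, lineno)
            pos.append((row["x_nm"], row["y_nm"], row["z_nm"]))
            energy.append(row["energy_ev"])
            pid.append(row["primary_id"])
            kind.append(KIND_CODES[row["kind"]])
    return (
        np.array(pos, dtype=float).reshape(-1, 3),
        np.array(energy, dtype=float),
        np.array(pid, dtype=np.int64),
        np.array(kind, dtype=np.int8),
    )


def _validate_event_row(row: dict, path, lineno: int) -> None:
    missing = set(EVENT_COLUMNS) - set(row)
    if missing:
        raise SchemaError(f"{path}:{lineno}: missing fields {sorted(missing)}")
    if row["kind"] not in KIND_CODES:
        raise SchemaError(
            f"{path}:{lineno}: unknown kind {row['kind']!r} "
            f"(expected one of {sorted(KIND_CODES)})"
        )


def write_events_csv(path: Union[str, Path], tracks: Iterable[TrackResult]) -> None:
    df = pd.DataFrame(_track_event_rows(tracks), columns=EVENT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_header("deposition-events", "positions in nm; energy in eV"))
        df.to_csv(fh, index=False)


def read_events_csv(path: Union[str, Path]):
    df = pd.read_csv(path, comment="#")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["kind"].isin(KIND_CODES)
    if bad.any():
        i = int(np.flatnonzero(bad.values)[0])
        raise SchemaError(f"{path}: row {i + 1}: unknown kind {df['kind'].iloc[i]!r}")
    return (
        df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float),
        df["energy_ev"].to_numpy(dtype=float),
        df["primary_id"].to_numpy(dtype=np.int64),
        df["kind"].map(KIND_CODES).to_numpy(dtype=np.int8),
    )


def write_dose_json(path: Union[str, Path], result: DoseResult, metadata: dict = None) -> None:
    payload = {"schema": f"betaplus-dose-result-v{SCHEMA_VERSION}", **result.to_dict()}
    if metadata:
        payload["metadata"] = metadata
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_dose_json(path: Union[str, Path]) -> DoseResult:
    payload = json.loads(Path(path).read_text())
    try:
        return DoseResult(
            cumulated_activity=payload["cumulated_activity_decays"],
            dose_gy=payload["dose_gy"],
            initial_dose_rate_gy_s=payload["initial_dose_rate_gy_per_s"],
            mean_dose_rate_gy_s=payload["mean_dose_rate_gy_per_s"],
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing field {exc}") from None


SUMMARY_COLUMNS = [
    "species",
    "energy_ev",
    "seed",
    "n_primaries",
    "ssb_count",
    "dsb_count",
    "ssb_per_1e6",
    "dsb_per_1e6",
    "let_kev_um",
]


def write_summary_csv(path: Union[str, Path], summaries: Sequence[DamageSummary]) -> None:
    df = pd.DataFrame([s.to_dict() for s in summaries], columns=SUMMARY_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_header("damage-summary", "energy_ev in eV; frequencies per 1e6 primaries; LET in keV/um"))
        df.to_csv(fh, index=False)


def read_summary_csv(path: Union[str, Path]) -> List[DamageSummary]:
    df = pd.read_csv(path, comment="#")
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return [
        DamageSummary(
            species=str(r["species"]),
            energy_ev=float(r["energy_ev"]),
            seed=int(r["seed"]),
            n_primaries=int(r["n_primaries"]),
            ssb_count=int(r["ssb_count"]),
            dsb_count=int(r["dsb_count"]),
            mean_let_kev_um=float(r["let_kev_um"]),
        )
        for _, r in df.iterrows()
    ]


def write_yaml(path: Union[str, Path], obj) -> None:
    """Serialize a geometry / source / physics / rules object to YAML."""
    Path(path).write_text(yaml.safe_dump(obj.to_dict(), sort_keys=False))


def read_geometry_yaml(path: Union[str, Path]) -> DNAGeometry:
    return DNAGeometry.from_dict(yaml.safe_load(Path(path).read_text()))


def read_rules_yaml(path: Union[str, Path]) -> ScoringRules:
    return ScoringRules.from_dict(yaml.safe_load(Path(path).read_text()))


def read_physics_yaml(path: Union[str, Path]) -> PhysicsModel:
    return PhysicsModel.from_dict(yaml.safe_load(Path(path).read_text()))
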