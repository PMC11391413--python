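"""Readers and writers for titration shift tables, schedules and profiles.

Canonical on-disk formats are delimited text:

shift table (CSV/TSV)
    columns ``residue_id, residue_name, point_index, h_shift_ppm, n_shift_ppm``
schedule table (CSV/TSV)
    columns ``point_index, protein_total_uM, ligand_total_uM``
peak lists (whitespace-delimited, one file per spectrum)
    rows ``<residue_id> <residue_name> <h_shift> <n_shift>``; files are
    given in titration order and mapped onto the same internal model.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._exceptions import InvalidInputError
from .csp import ConcentrationSchedule, CSPProfile, ShiftRecord, TitrationSeries

__all__ = [
    "read_shift_table",
    "read_schedule",
    "read_titration",
    "read_peak_lists",
    "write_titration",
    "write_profile",
]

_SHIFT_COLS = ["residue_id", "residue_name", "point_index", "h_shift_ppm", "n_shift_ppm"]
_SCHED_COLS = ["point_index", "protein_total_uM", "ligand_total_uM"]


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    return df


def read_schedule(path) -> ConcentrationSchedule:
    df = _read_table(path, _SCHED_COLS).sort_values("point_index")
    if list(df["point_index"]) != list(range(len(df))):
        raise InvalidInputError(f"{path}: point_index must be 0..n-1 without gaps")
    return ConcentrationSchedule(
        points=tuple(zip(df["protein_total_uM"], df["ligand_total_uM"]))
    )


def read_shift_table(path) -> list[ShiftRecord]:
    df = _read_table(path, _SHIFT_COLS)
    return [
        ShiftRecord(
            residue_id=int(r.residue_id),
            residue_name=str(r.residue_name),
            point_index=int(r.point_index),
            h_shift=float(r.h_shift_ppm),
            n_shift=float(r.n_shift_ppm),
        )
        for r in df.itertuples()
    ]


def read_titration(shift_path, schedule_path, metadata: Mapping | None = None) -> TitrationSeries:
    """Load a titration series from a shift table plus a schedule table."""
    return TitrationSeries(
        schedule=read_schedule(schedule_path),
        records=tuple(read_shift_table(shift_path)),
        metadata=dict(metadata or {}),
    )


def read_peak_lists(paths: Sequence, schedule: ConcentrationSchedule,
                    metadata: Mapping | None = None) -> TitrationSeries:
    """Assemble a series from per-spectrum whitespace-delimited peak lists."""
    if len(paths) != schedule.n_points:
        raise InvalidInputError(
            f"{len(paths)} peak lists for a {schedule.n_points}-point schedule"
        )
    records = []
    for point, path in enumerate(paths):
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise InvalidInputError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            rid, name, h, n = fields
            records.append(
                ShiftRecord(
                    residue_id=int(rid),
                    residue_name=name,
                    point_index=point,
                    h_shift=float(h),
                    n_shift=float(n),
                )
            )
    return TitrationSeries(schedule=schedule, records=tuple(records),
                           metadata=dict(metadata or {}))


def write_titration(series: TitrationSeries, shift_path, schedule_path,
                    meta_path=None) -> None:
    """Write a series to the canonical shift-table + schedule CSV pair."""
    series.to_frame().to_csv(shift_path, index=False)
    series.schedule.to_frame().to_csv(schedule_path, index=False)
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(dict(series.metadata), indent=2, default=str))


def write_profile(profile: CSPProfile, path) -> None:
    """Export a CSP profile (per-residue curves, max CSP, selection state)."""
    profile.to_frame().to_csv(path, index=False)
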