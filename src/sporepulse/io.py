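"""Tidy delimited-text round trip for microcolony trace tables.

Two CSV tables describe a colony:

``traces.csv``
    one row per cell per frame: ``cell_id, parent_id, frame, time_min,
    length, mean_fluor_<channel>...``
``cells.csv``
    one row per cell: ``cell_id, parent_id, birth_frame, end_frame,
    fate, true_amplitude, true_pulse_time`` (the last two carry the
    generator's injected ground truth and may be empty for real data).

Floats are written at full ``repr`` precision so the round trip is
bit-exact.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .colony import CellRecord, Microcolony
from .errors import ParseError

__all__ = ["write_trace_tables", "read_trace_tables",
           "colony_to_tables", "colony_from_tables"]

TRACES_NAME = "traces.csv"
CELLS_NAME = "cells.csv"


def colony_to_tables(colony: Microcolony) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a colony into (traces, cells) tidy DataFrames."""
    trace_rows = []
    cell_rows = []
    channels = sorted({ch for c in colony for ch in c.mean_fluor})
    for cell in sorted(colony, key=lambda c: c.cell_id):
        cell_rows.append({
            "cell_id": cell.cell_id,
            "parent_id": cell.parent_id if cell.parent_id is not None else "",
            "birth_frame": cell.birth_frame,
            "end_frame": cell.end_frame,
            "fate": cell.fate,
            "true_amplitude": cell.true_amplitude,
            "true_pulse_time": cell.true_pulse_time,
        })
        for k, frame in enumerate(cell.frames):
            row = {
                "cell_id": cell.cell_id,
                "parent_id": cell.parent_id if cell.parent_id is not None else "",
                "frame": int(frame),
                "time_min": cell.time_min[k],
                "length": cell.length[k],
            }
            for ch in channels:
                row[f"mean_fluor_{ch}"] = cell.mean_fluor[ch][k]
            trace_rows.append(row)
    trace_cols = ["cell_id", "parent_id", "frame", "time_min", "length"] + [
        f"mean_fluor_{ch}" for ch in channels]
    cell_cols = ["cell_id", "parent_id", "birth_frame", "end_frame", "fate",
                 "true_amplitude", "true_pulse_time"]
    traces = pd.DataFrame(trace_rows, columns=trace_cols)
    cells = pd.DataFrame(cell_rows, columns=cell_cols)
    return traces, cells


def write_trace_tables(colony: Microcolony, path: str | Path) -> tuple[Path, Path]:
    """Write ``traces.csv`` and ``cells.csv`` under ``path`` (a directory)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    traces, cells = colony_to_tables(colony)
    tp, cp = path / TRACES_NAME, path / CELLS_NAME
    traces.to_csv(tp, index=False)
    cells.to_csv(cp, index=False)
    return tp, cp


def colony_from_tables(traces: pd.DataFrame, cells: pd.DataFrame) -> Microcolony:
    """Rebuild a :class:`Microcolony` from tidy tables, validating structure."""
    colony = Microcolony()
    known_ids = set(cells["cell_id"].astype(str))
    fluor_cols = [c for c in traces.columns if c.startswith("mean_fluor_")]
    grouped = dict(tuple(traces.groupby("cell_id", sort=True)))
    for rec in cells.to_dict("records"):
        cid = str(rec["cell_id"])
        parent = rec["parent_id"]
        parent = None if (parent is None or (isinstance(parent, float) and math.isnan(parent)) or str(parent) == "") else str(parent)
        if parent is not None and parent not in known_ids:
            raise ParseError(f"cell {cid!r}: parent {parent!r} missing from cells table")
        if cid not in grouped:
            raise ParseError(f"cell {cid!r}: no rows in traces table")
        g = grouped[cid].sort_values("frame")
        frames = g["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(frames[0], frames[-1] + 1)):
            raise ParseError(f"cell {cid!r}: non-contiguous frames")
        if int(frames[0]) != int(rec["birth_frame"]) or int(frames[-1]) != int(rec["end_frame"]):
            raise ParseError(f"cell {cid!r}: frame range disagrees with cells table")
        colony.add(CellRecord(
            cell_id=cid,
            parent_id=parent,
            birth_frame=int(rec["birth_frame"]),
            end_frame=int(rec["end_frame"]),
            fate=str(rec["fate"]),
            time_min=g["time_min"].to_numpy(dtype=float),
            length=g["length"].to_numpy(dtype=float),
            mean_fluor={c[len("mean_fluor_"):]: g[c].to_numpy(dtype=float)
                        for c in fluor_cols},
            true_amplitude=float(rec.get("true_amplitude", math.nan)),
            true_pulse_time=float(rec.get("true_pulse_time", math.nan)),
        ))
    return colony


def read_trace_tables(path: str | Path) -> Microcolony:
    """Read a colony written by :func:`write_trace_tables`."""
    path = Path(path)
    traces = pd.read_csv(path / TRACES_NAME, dtype={"cell_id": str, "parent_id": str},
                         keep_default_na=False, na_values=[""],
                         float_precision="round_trip")
    cells = pd.read_csv(path / CELLS_NAME, dtype={"cell_id": str, "parent_id": str},
                        keep_default_na=False, na_values=[""],
                        float_precision="round_trip")
    if len(cells) == 0:
        return Microcolony()
    return colony_from_tables(traces, cells)
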