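"""File I/O: capnogram CSV, breath-segment CSV, measurement-pair CSV.

Capnogram files are two-column CSV with header ``time_s,pco2_kpa`` (or
``pco2_mmhg``, converted on read); lines starting with ``#`` are comments.
All pressures are normalised to kPa in memory.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import MeasurementPair
from .capnogram import MMHG_TO_KPA, BreathSegment, CapnogramTrace
from .errors import TraceFormatError

__all__ = [
    "read_capnogram_csv",
    "write_capnogram_csv",
    "write_segments_csv",
    "read_pairs_csv",
    "write_pairs_csv",
]

_TIME_COL = "time_s"
_KPA_COL = "pco2_kpa"
_MMHG_COL = "pco2_mmhg"


def read_capnogram_csv(path: str | Path) -> CapnogramTrace:
    """Parse a capnogram CSV into a :class:`CapnogramTrace` (kPa internal).

    Raises :class:`TraceFormatError` with row numbers for malformed rows,
    missing columns, mixed units or a non-uniform time base.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise TraceFormatError(f"{path}: empty file")
    except (OSError, pd.errors.ParserError) as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc
    cols = set(df.columns)
    if _TIME_COL not in cols:
        raise TraceFormatError(f"{path}: missing column {_TIME_COL!r}")
    has_kpa, has_mmhg = _KPA_COL in cols, _MMHG_COL in cols
    if has_kpa and has_mmhg:
        raise TraceFormatError(
            f"{path}: mixed units - both {_KPA_COL!r} and {_MMHG_COL!r} present"
        )
    if not (has_kpa or has_mmhg):
        raise TraceFormatError(
            f"{path}: missing pressure column ({_KPA_COL!r} or {_MMHG_COL!r})"
        )
    pcol = _KPA_COL if has_kpa else _MMHG_COL
    times = pd.to_numeric(df[_TIME_COL], errors="coerce").to_numpy(dtype=float)
    pco2 = pd.to_numeric(df[pcol], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~(np.isfinite(times) & np.isfinite(pco2)))
    if bad.size:
        # +2: 1-based line numbers plus the header row
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise TraceFormatError(f"{path}: malformed rows at lines {lines}")
    if times.size < 2:
        raise TraceFormatError(f"{path}: needs at least two samples")
    steps = np.diff(times)
    if np.any(steps <= 0):
        i = int(np.flatnonzero(steps <= 0)[0])
        raise TraceFormatError(f"{path}: non-monotone time at line {i + 3}")
    dt = float(np.median(steps))
    if np.max(np.abs(steps - dt)) > 1e-6 * max(dt, 1.0):
        raise TraceFormatError(f"{path}: non-uniform sampling interval")
    if has_mmhg:
        pco2 = pco2 * MMHG_TO_KPA
    # rebuild an exactly uniform time base from the printed samples
    times = times[0] + np.arange(times.size) * dt
    return CapnogramTrace(
        times=times,
        pco2=np.clip(pco2, 0.0, None),
        sample_rate=1.0 / dt,
        meta={"source": str(path), "input_units": "mmhg" if has_mmhg else "kpa"},
    )


def write_capnogram_csv(
    trace: CapnogramTrace,
    path: str | Path,
    units: str = "kpa",
    comments: Sequence[str] = (),
) -> None:
    """Write a trace as CSV; ``units='mmhg'`` converts on output."""
    if units not in ("kpa", "mmhg"):
        raise ValueError("units must be 'kpa' or 'mmhg'")
    pco2 = trace.pco2 if units == "kpa" else trace.pco2 / MMHG_TO_KPA
    buf = _io.StringIO()
    for line in comments:
        buf.write(f"# {line}\n")
    buf.write(f"{_TIME_COL},{_KPA_COL if units == 'kpa' else _MMHG_COL}\n")
    for t, p in zip(trace.times, pco2):
        buf.write(f"{t:.9f},{p:.9f}\n")
    Path(path).write_text(buf.getvalue())


def write_segments_csv(segments: Sequence[BreathSegment], path: str | Path) -> None:
    """Write detected breath segments as CSV."""
    df = pd.DataFrame(
        {
            "index": [s.index for s in segments],
            "t_exp_start": [s.t_exp_start for s in segments],
            "t_exp_end": [s.t_exp_end for s in segments],
            "pet": [s.pet for s in segments],
            "valid": [s.valid for s in segments],
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_pairs_csv(path: str | Path) -> list[MeasurementPair]:
    """Read method-vs-reference pairs: subject_id,replicate,method_l,reference_l."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise TraceFormatError(f"{path}: empty file")
    required = {"subject_id", "method_l", "reference_l"}
    missing = required - set(df.columns)
    if missing:
        raise TraceFormatError(f"{path}: missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    pairs = []
    for i, row in df.iterrows():
        try:
            pairs.append(
                MeasurementPair(
                    subject_id=str(row["subject_id"]),
                    method_value=float(row["method_l"]),
                    reference_value=float(row["reference_l"]),
                    replicate=int(row["replicate"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise TraceFormatError(f"{path}: bad row at line {i + 2}: {exc}") from exc
    return pairs


def write_pairs_csv(pairs: Sequence[MeasurementPair], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in pairs],
            "replicate": [p.replicate for p in pairs],
            "method_l": [p.method_value for p in pairs],
            "reference_l": [p.reference_value for p in pairs],
        }
    )
    df.to_csv(path, index=False)
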