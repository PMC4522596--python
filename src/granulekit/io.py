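"""Readers and writers for the package's file formats.

Formats are deliberately plain: multi-frame grayscale TIFF for image
stacks, CSV for intensity traces and ROI definitions, JSON for summaries.
Trace CSVs carry the columns ``cell_id, frame, time_s, I_F, I_R, I_B,
phase`` with ``phase`` in {pre, post}; the bleach frame is the first
``post`` row. Coordinates are 0-based (row, col); ROI rectangles use
inclusive pixel bounds.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .frap import IntensityTrace

__all__ = [
    "read_stack",
    "write_stack",
    "read_traces",
    "write_traces",
    "traces_to_frame",
    "read_rois",
    "extract_traces_from_stack",
]

TRACE_COLUMNS = ["cell_id", "frame", "time_s", "I_F", "I_R", "I_B", "phase"]
ROI_COLUMNS = ["cell_id", "role", "row0", "col0", "row1", "col1"]


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Load a multi-frame grayscale TIFF as (frames, rows, cols).

    8- and 16-bit stacks load into their native integer dtype without
    rescaling; a single-frame image gains a leading frame axis. RGB /
    multi-channel files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"read_stack: no such file: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"read_stack: expected a 2-D/3-D grayscale stack, got shape {data.shape}")
    if data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:-1]):
        raise ValueError("read_stack: file looks RGB/multi-channel; convert to grayscale first")
    meta = {"n_frames": int(data.shape[0]), "shape": tuple(data.shape[1:]),
            "dtype": str(data.dtype)}
    return data, meta


def write_stack(path: str | Path, stack: np.ndarray, dtype: str = "uint16") -> None:
    """Write a stack as multi-frame grayscale TIFF (clipped and rounded)."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    info = np.iinfo(np.dtype(dtype))
    out = np.clip(np.rint(stack), info.min, info.max).astype(dtype)
    tifffile.imwrite(Path(path), out, photometric="minisblack")


def traces_to_frame(traces: list[IntensityTrace]) -> pd.DataFrame:
    """Serialize traces to the long trace-CSV schema."""
    rows = []
    for trace in traces:
        for k in range(len(trace.time)):
            rows.append({
                "cell_id": trace.cell_id,
                "frame": k,
                "time_s": trace.time[k],
                "I_F": trace.I_F[k],
                "I_R": trace.I_R[k],
                "I_B": trace.I_B[k],
                "phase": "pre" if k < trace.bleach_index else "post",
            })
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def write_traces(path: str | Path, traces: list[IntensityTrace]) -> None:
    traces_to_frame(traces).to_csv(Path(path), index=False)


def read_traces(path: str | Path) -> list[IntensityTrace]:
    """Read a trace CSV into per-cell :class:`IntensityTrace` objects.

    Rows may appear in any order; they are sorted by frame within each
    cell. Validation failures name the offending cell and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"read_traces: no such file: {path}")
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"read_traces: missing columns {missing} in {path.name}")
    traces = []
    for cell_id, group in table.groupby("cell_id", sort=True):
        group = group.sort_values("frame")
        time = group["time_s"].to_numpy(dtype=float)
        if len(time) > 1:
            dt = np.diff(time)
            if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError(f"read_traces: cell {cell_id!r}: non-uniform time_s spacing")
        phase = group["phase"].astype(str).str.lower().to_numpy()
        post = np.nonzero(phase == "post")[0]
        if post.size == 0 or post[0] == 0:
            raise ValueError(f"read_traces: cell {cell_id!r}: needs >= 1 'pre' row before the first 'post' row")
        traces.append(IntensityTrace(
            time=time,
            I_F=group["I_F"].to_numpy(dtype=float),
            I_R=group["I_R"].to_numpy(dtype=float),
            I_B=group["I_B"].to_numpy(dtype=float),
            bleach_index=int(post[0]),
            cell_id=str(cell_id),
        ))
    return traces


def read_rois(path: str | Path) -> pd.DataFrame:
    """Read rectangular ROI definitions.

    Columns: cell_id, role in {focus, reference, background}, and the
    inclusive pixel bounds row0, col0, row1, col1 (0-based).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"read_rois: no such file: {path}")
    table = pd.read_csv(path)
    missing = [c for c in ROI_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"read_rois: missing columns {missing} in {path.name}")
    bad = set(table["role"]) - {"focus", "reference", "background"}
    if bad:
        raise ValueError(f"read_rois: unknown roles {sorted(bad)}")
    return table


def extract_traces_from_stack(
    stack: np.ndarray,
    rois: pd.DataFrame,
    bleach_frame: int,
    frame_interval: float = 1.0,
) -> list[IntensityTrace]:
    """Mean-ROI intensity traces from a stack plus an ROI table.

    Every cell must define exactly one focus, one reference and one
    background ROI; means are taken over the inclusive rectangle per
    frame.
    """
    stack = np.asarray(stack, dtype=float)
    traces = []
    for cell_id, group in rois.groupby("cell_id", sort=True):
        channels = {}
        for role in ("focus", "reference", "background"):
            sel = group[group["role"] == role]
            if len(sel) != 1:
                raise ValueError(f"extract_traces_from_stack: cell {cell_id!r} needs exactly one {role} ROI")
            r0, c0, r1, c1 = (int(sel.iloc[0][c]) for c in ("row0", "col0", "row1", "col1"))
            if not (0 <= r0 <= r1 < stack.shape[1] and 0 <= c0 <= c1 < stack.shape[2]):
                raise ValueError(f"extract_traces_from_stack: {role} ROI of cell {cell_id!r} outside the image")
            channels[role] = stack[:, r0:r1 + 1, c0:c1 + 1].mean(axis=(1, 2))
        traces.append(IntensityTrace(
            time=np.arange(stack.shape[0]) * frame_interval,
            I_F=channels["focus"],
            I_R=channels["reference"],
            I_B=channels["background"],
            bleach_index=bleach_frame,
            cell_id=str(cell_id),
        ))
    return traces
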