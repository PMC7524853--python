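"""Disk formats: per-channel TIFF movies, tidy CSV tables, YAML configs.

Movies are written as one multi-page 16-bit TIFF per channel plus a
``metadata.yaml`` sidecar holding frame times, the sparse-channel frame
indices and the float->uint16 intensity scale per channel, so reading a
movie back reproduces the in-memory stack up to quantization.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import GroundTruthTrace
from .stack import FrameStack
from .trace import CellTrace

__all__ = [
    "write_movie",
    "read_movie",
    "write_traces",
    "read_traces",
    "write_ground_truth",
]


def write_movie(
    stack: FrameStack,
    out_dir: str | Path,
    labels: Optional[np.ndarray] = None,
    nuclear_labels: Optional[np.ndarray] = None,
) -> Path:
    """Write one 16-bit multi-page TIFF per channel plus metadata.yaml."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scales: dict[str, float] = {}
    expr_frames = np.flatnonzero(stack.expr_frame_mask()).tolist()
    for name, arr in stack.channels.items():
        data = np.nan_to_num(arr, nan=0.0)
        peak = float(data.max())
        scale = 60000.0 / peak if peak > 0 else 1.0
        scales[name] = scale
        tifffile.imwrite(
            out_dir / f"{name}.tif",
            np.clip(data * scale, 0, 65535).astype(np.uint16),
            photometric="minisblack",
        )
    if labels is not None:
        tifffile.imwrite(out_dir / "labels.tif", labels.astype(np.uint16))
    if nuclear_labels is not None:
        tifffile.imwrite(
            out_dir / "nuclear_labels.tif", nuclear_labels.astype(np.uint16)
        )
    meta = {
        "times_min": [float(t) for t in stack.times],
        "channels": sorted(stack.channels),
        "intensity_scale": {k: float(v) for k, v in scales.items()},
        "expr_marker_frames": expr_frames,
        "pixel_size_um": stack.pixel_size,
    }
    with open(out_dir / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    return out_dir


def read_movie(
    movie_dir: str | Path,
) -> tuple[FrameStack, Optional[np.ndarray], Optional[np.ndarray]]:
    """Read a movie directory written by :func:`write_movie`."""
    movie_dir = Path(movie_dir)
    with open(movie_dir / "metadata.yaml") as fh:
        meta = yaml.safe_load(fh)
    channels = {}
    for name in meta["channels"]:
        arr = tifffile.imread(movie_dir / f"{name}.tif").astype(np.float32)
        arr /= meta["intensity_scale"][name]
        channels[name] = arr
    if "expr_marker" in channels:
        acquired = np.zeros(channels["expr_marker"].shape[0], dtype=bool)
        acquired[meta.get("expr_marker_frames", [])] = True
        channels["expr_marker"][~acquired] = np.nan
    stack = FrameStack(
        channels=channels,
        times=np.asarray(meta["times_min"], dtype=float),
        pixel_size=meta.get("pixel_size_um"),
    )

    def maybe(name):
        p = movie_dir / name
        return tifffile.imread(p) if p.exists() else None

    return stack, maybe("labels.tif"), maybe("nuclear_labels.tif")


def write_traces(traces: Sequence[CellTrace], path: str | Path) -> Path:
    """Tidy per-frame CSV: one row per (track, frame)."""
    rows = []
    for tr in traces:
        for i, t in enumerate(tr.times):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "time_min": float(t),
                    "loc_index": float(tr.loc_index[i]),
                    "reporter": (
                        float(tr.reporter[i]) if tr.reporter is not None else np.nan
                    ),
                    "expr_marker": (
                        float(tr.expr_marker[i])
                        if tr.expr_marker is not None
                        else np.nan
                    ),
                    "strain": tr.strain,
                    "hexose": tr.hexose,
                    "alive": (
                        bool(tr.alive[i]) if tr.alive is not None else True
                    ),
                }
            )
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_traces(path: str | Path) -> list[CellTrace]:
    """Read a tidy trace CSV back into :class:`CellTrace` objects."""
    df = pd.read_csv(path)
    traces = []
    for track_id, grp in df.groupby("track_id"):
        grp = grp.sort_values("time_min")
        traces.append(
            CellTrace(
                track_id=int(track_id),
                times=grp["time_min"].to_numpy(),
                loc_index=grp["loc_index"].to_numpy(),
                reporter=grp["reporter"].to_numpy(),
                expr_marker=grp["expr_marker"].to_numpy(),
                strain=str(grp["strain"].iloc[0]),
                hexose=str(grp["hexose"].iloc[0]),
                alive=grp["alive"].to_numpy(dtype=bool),
            )
        )
    return traces


def write_ground_truth(
    truths: Sequence[GroundTruthTrace], out_dir: str | Path
) -> Path:
    """Ground-truth trace and pulse tables as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trace_rows, pulse_rows = [], []
    for tr in truths:
        for i, t in enumerate(tr.times):
            trace_rows.append(
                {
                    "cell_id": tr.cell_id,
                    "time_min": float(t),
                    "true_index": float(tr.true_index[i]),
                    "true_reporter": float(tr.true_reporter[i]),
                    "alive": bool(tr.alive[i]),
                }
            )
        for t, h in zip(tr.pulse_times, tr.pulse_heights):
            pulse_rows.append(
                {"cell_id": tr.cell_id, "time_min": float(t), "height": float(h)}
            )
    pd.DataFrame(trace_rows).to_csv(out_dir / "true_traces.csv", index=False)
    pd.DataFrame(
        pulse_rows, columns=["cell_id", "time_min", "height"]
    ).to_csv(out_dir / "true_pulses.csv", index=False)
    return out_dir
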