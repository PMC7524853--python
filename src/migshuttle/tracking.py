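"""Link per-frame cell regions into single-cell tracks.

Frame-to-frame linking is optimal bipartite matching on centroid distance
(Hungarian assignment), with a hard displacement gate.  Track building
chains the links, bridges short detection gaps with a proportionally
relaxed gate, and can require tracks to span the media shift so each cell
contributes both short- and long-term metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import logging

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .imaging import CellRegion
from .trace import CellTrace

__all__ = ["CellTrack", "link_frames", "build_tracks", "assemble_traces"]

log = logging.getLogger(__name__)


@dataclass
class CellTrack:
    """One cell's identity across frames: ordered (frame_index, label) pairs."""

    track_id: int
    entries: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [f for f, _ in self.entries]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.entries]

    @property
    def gap_count(self) -> int:
        frames = self.frames
        return int(sum(b - a - 1 for a, b in zip(frames, frames[1:])))

    def __len__(self) -> int:
        return len(self.entries)


def link_frames(
    regions_a: Sequence[CellRegion],
    regions_b: Sequence[CellRegion],
    max_displacement: float = 15.0,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """One-to-one assignment between two frames' regions.

    Minimizes total centroid distance over all one-to-one assignments
    (optimal bipartite matching), then rejects pairs farther apart than
    ``max_displacement``.  Returns ``(pairs, unmatched_a, unmatched_b)``
    where pairs hold indices into the two input lists.
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be > 0")
    if not regions_a or not regions_b:
        return [], list(range(len(regions_a))), list(range(len(regions_b)))
    ca = np.array([r.centroid for r in regions_a])
    cb = np.array([r.centroid for r in regions_b])
    cost = np.hypot(
        ca[:, None, 0] - cb[None, :, 0], ca[:, None, 1] - cb[None, :, 1]
    )
    # Forbidden pairs get a large-but-finite cost so the assignment solver
    # still runs; they are rejected afterwards.
    big = max_displacement * 1e6
    gated = np.where(cost <= max_displacement, cost, big)
    rows, cols = linear_sum_assignment(gated)
    pairs = [
        (int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] <= max_displacement
    ]
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    unmatched_a = [i for i in range(len(regions_a)) if i not in matched_a]
    unmatched_b = [j for j in range(len(regions_b)) if j not in matched_b]
    return pairs, unmatched_a, unmatched_b


def build_tracks(
    frames: Sequence[Sequence[CellRegion]],
    max_displacement: float = 15.0,
    max_gap: int = 1,
    min_length: int = 2,
) -> list[CellTrack]:
    """Chain pairwise links across the movie into tracks.

    ``frames`` must be ordered by time.  A track that misses up to
    ``max_gap`` consecutive frames can be re-acquired, with the displacement
    gate relaxed proportionally to the gap span.  Tracks shorter than
    ``min_length`` entries are discarded.  Each (frame, label) belongs to at
    most one track.
    """
    active: list[dict] = []  # {track, last_frame, centroid}
    finished: list[CellTrack] = []
    next_id = 0
    for f, regions in enumerate(frames):
        # Candidates: active tracks whose last frame is within max_gap + 1.
        candidates = [a for a in active if f - a["last_frame"] <= max_gap + 1]
        # Pseudo-regions carrying each candidate's last known centroid.
        pairs: list[tuple[int, int]] = []
        if candidates and regions:
            ca = np.array([a["centroid"] for a in candidates])
            cb = np.array([r.centroid for r in regions])
            cost = np.hypot(
                ca[:, None, 0] - cb[None, :, 0], ca[:, None, 1] - cb[None, :, 1]
            )
            spans = np.array([f - a["last_frame"] for a in candidates], dtype=float)
            gate = max_displacement * spans  # relaxed across gaps
            big = max_displacement * 1e6
            gated = np.where(cost <= gate[:, None], cost, big)
            rows, cols = linear_sum_assignment(gated)
            pairs = [
                (int(i), int(j))
                for i, j in zip(rows, cols)
                if cost[i, j] <= gate[i]
            ]
        matched_tracks = set()
        matched_regions = set()
        for i, j in pairs:
            cand = candidates[i]
            region = regions[j]
            cand["track"].entries.append((f, region.label))
            cand["last_frame"] = f
            cand["centroid"] = region.centroid
            matched_tracks.add(id(cand))
            matched_regions.add(j)
        # Retire tracks that can no longer be re-acquired.
        still_active = []
        for a in active:
            if id(a) in matched_tracks or f - a["last_frame"] <= max_gap:
                still_active.append(a)
            else:
                finished.append(a["track"])
        active = still_active
        # Unmatched regions found new tracks (births / first frame).
        for j, region in enumerate(regions):
            if j in matched_regions:
                continue
            track = CellTrack(track_id=next_id, entries=[(f, region.label)])
            next_id += 1
            active.append(
                {"track": track, "last_frame": f, "centroid": region.centroid}
            )
    finished.extend(a["track"] for a in active)
    tracks = [t for t in finished if len(t) >= min_length]
    tracks.sort(key=lambda t: (t.entries[0][0], t.entries[0][1]))
    for new_id, t in enumerate(tracks):
        t.track_id = new_id
    return tracks


def spans_shift(
    track: CellTrack, times: np.ndarray, t_after: float = 240.0
) -> bool:
    """True if the track covers both pre-shift frames and frames past ``t_after``.

    The default mirrors the dual-metric design: a cell must be present
    before the shift (for its basal level) and beyond 240 min (for the
    adapted-phase metrics).
    """
    frame_times = times[np.asarray(track.frames)]
    return bool(frame_times.min() < 0 and frame_times.max() > t_after)


def assemble_traces(
    tracks: Sequence[CellTrack],
    measurements: pd.DataFrame,
    times: np.ndarray,
    strain: str = "",
    hexose: str = "",
) -> list[CellTrace]:
    """Join tracks with the measurement table into per-cell time series.

    Produces one :class:`CellTrace` per track on the full movie time grid,
    with NaN at frames where the track has no (valid) measurement.  Tracks
    with zero valid measurements are dropped with a log entry.
    """
    times = np.asarray(times, dtype=float)
    keyed = measurements.set_index(["frame", "cell_label"])
    out: list[CellTrace] = []
    for track in tracks:
        idx = np.full(times.size, np.nan)
        rep = np.full(times.size, np.nan)
        expr = np.full(times.size, np.nan)
        n_valid = 0
        for f, label in track.entries:
            try:
                row = keyed.loc[(f, label)]
            except KeyError:
                continue
            if isinstance(row, pd.DataFrame):  # duplicate guard
                row = row.iloc[0]
            if not bool(row["valid"]):
                continue
            idx[f] = row["loc_index"]
            rep[f] = row["reporter"]
            expr[f] = row["expr_marker"]
            n_valid += 1
        if n_valid == 0:
            log.info("track %d has no valid measurements; dropped", track.track_id)
            continue
        out.append(
            CellTrace(
                track_id=track.track_id,
                times=times,
                loc_index=idx,
                reporter=rep,
                expr_marker=expr,
                strain=strain,
                hexose=hexose,
            )
        )
    return out
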