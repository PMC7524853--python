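"""Acquisition schedule for microfluidic time-lapse experiments.

The experiments this package models follow a media-shift protocol: cells grow
on a non-repressing carbon source (ethanol), are shifted to a hexose at t = 0,
and are imaged on a two-rate grid — sparse frames before the shift, dense
frames after it.  One fluorescence channel (the expression-level marker) is
acquired only on every *k*-th post-shift frame to limit photodamage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionSchedule", "make_schedule"]


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Frame times (minutes, relative to the media shift) of one movie.

    ``pre_shift_times`` runs from the start of the movie up to and including
    t = 0; ``post_shift_times`` runs from t = 0 to the end.  The shift frame
    t = 0 appears in both lists but only once in the merged ``times`` grid.
    ``sparse_channel_period`` is the acquisition period, in post-shift frames,
    of the sparsely imaged expression-marker channel.
    """

    pre_shift_times: np.ndarray
    post_shift_times: np.ndarray
    sparse_channel_period: int = 1
    times: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre_shift_times, dtype=float)
        post = np.asarray(self.post_shift_times, dtype=float)
        if pre.size and np.any(np.diff(pre) <= 0):
            raise ValueError("pre-shift times must be strictly increasing")
        if post.size and np.any(np.diff(post) <= 0):
            raise ValueError("post-shift times must be strictly increasing")
        if pre.size and pre[-1] > 0:
            raise ValueError("pre-shift times must be <= 0")
        if post.size and post[0] < 0:
            raise ValueError("post-shift times must be >= 0")
        if self.sparse_channel_period < 1:
            raise ValueError("sparse_channel_period must be >= 1")
        merged = np.unique(np.concatenate([pre, post]))
        object.__setattr__(self, "pre_shift_times", pre)
        object.__setattr__(self, "post_shift_times", post)
        object.__setattr__(self, "times", merged)

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def post_interval(self) -> float:
        """Sampling interval of the post-shift grid (minutes)."""
        if self.post_shift_times.size < 2:
            raise ValueError("need >= 2 post-shift frames for an interval")
        return float(np.diff(self.post_shift_times).min())

    def frame_index(self, time: float) -> int:
        """Index of ``time`` in the merged grid (exact match required)."""
        idx = int(np.searchsorted(self.times, time))
        if idx >= self.times.size or self.times[idx] != time:
            raise ValueError(f"time {time} is not on the acquisition grid")
        return idx

    @property
    def sparse_frame_mask(self) -> np.ndarray:
        """Boolean mask over the merged grid: frames with the sparse channel.

        The sparse channel is acquired on every ``sparse_channel_period``-th
        post-shift frame, counting from the shift frame itself.
        """
        mask = np.zeros(self.times.size, dtype=bool)
        sparse_times = self.post_shift_times[:: self.sparse_channel_period]
        for t in sparse_times:
            mask[self.frame_index(t)] = True
        return mask

    @property
    def post_shift_mask(self) -> np.ndarray:
        return self.times >= 0


def make_schedule(
    pre_interval: float = 30.0,
    post_interval: float = 5.0,
    t_min: float = -240.0,
    t_max: float = 720.0,
    sparse_period: int = 4,
) -> AcquisitionSchedule:
    """Build the two-rate acquisition grid.

    Defaults reproduce the reference protocol: frames every 30 min from
    −240 to 0 min, every 5 min from 0 to 720 min, and the expression-marker
    channel on every 4th post-shift frame.

    Parameters
    ----------
    pre_interval, post_interval
        Frame spacing before/after the media shift, minutes (> 0).
    t_min, t_max
        Movie start (< 0) and end (> 0), minutes relative to the shift.
    sparse_period
        Acquisition period of the sparse channel in post-shift frames.
    """
    if pre_interval <= 0 or post_interval <= 0:
        raise ValueError("acquisition intervals must be positive")
    if not (t_min < 0 < t_max):
        raise ValueError("schedule must span the shift: t_min < 0 < t_max")
    # Pre-shift grid anchored on the shift: 0, -pre_interval, ... down to t_min.
    n_pre = int(np.floor(-t_min / pre_interval))
    pre = -pre_interval * np.arange(n_pre, -1, -1, dtype=float)
    pre = pre[pre >= t_min]
    n_post = int(np.floor(t_max / post_interval))
    post = post_interval * np.arange(0, n_post + 1, dtype=float)
    return AcquisitionSchedule(pre, post, sparse_channel_period=sparse_period)
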