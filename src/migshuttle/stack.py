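"""Multi-channel time-lapse stack container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["FrameStack", "CHANNELS"]

#: Canonical channel names, in storage order.
CHANNELS = ("bf_above", "bf_below", "gfp", "nuc_marker", "reporter", "expr_marker")


@dataclass
class FrameStack:
    """A multi-channel movie with per-frame timestamps.

    ``channels`` maps channel name to a float array of shape (T, H, W).  The
    sparsely acquired expression-marker channel is stored dense with NaN
    frames where it was not imaged.  ``times`` are minutes relative to the
    media shift.
    """

    channels: dict[str, np.ndarray]
    times: np.ndarray
    pixel_size: Optional[float] = None  # µm / px
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be 1-D and strictly increasing")
        shape = None
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} must be (T, H, W)")
            if arr.shape[0] != self.times.size:
                raise ValueError(f"channel {name!r} frame count != len(times)")
            if shape is None:
                shape = arr.shape[1:]
            elif arr.shape[1:] != shape:
                raise ValueError("all channels must share (H, W)")
            self.channels[name] = arr

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def frame_shape(self) -> tuple[int, int]:
        arr = next(iter(self.channels.values()))
        return arr.shape[1], arr.shape[2]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} missing; have {sorted(self.channels)}"
            ) from None

    def expr_frame_mask(self) -> np.ndarray:
        """Frames on which the expression marker was acquired."""
        if "expr_marker" not in self.channels:
            return np.zeros(self.n_frames, dtype=bool)
        arr = self.channels["expr_marker"]
        return np.isfinite(arr).any(axis=(1, 2))
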