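"""Per-cell time-series container shared by the simulator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["CellTrace"]


@dataclass
class CellTrace:
    """One tracked cell's measured time series.

    ``loc_index`` is the Mig1 localization index (median nuclear / median
    whole-cell fluorescence − 1) per frame; missing or invalid measurements
    are NaN.  ``reporter`` is the promoter-reporter intensity (AU) and
    ``expr_marker`` the expression-level marker (AU, NaN on frames where the
    sparse channel was not acquired).
    """

    track_id: int
    times: np.ndarray  # minutes relative to the media shift
    loc_index: np.ndarray
    reporter: Optional[np.ndarray] = None
    expr_marker: Optional[np.ndarray] = None
    strain: str = ""
    hexose: str = ""
    alive: Optional[np.ndarray] = None  # per-frame viability flag
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.loc_index = np.asarray(self.loc_index, dtype=float)
        if self.times.shape != self.loc_index.shape:
            raise ValueError("times and loc_index must have equal length")
        for name in ("reporter", "expr_marker"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.times.shape:
                    raise ValueError(f"{name} length does not match times")
                setattr(self, name, arr)

    @property
    def expr_marker_level(self) -> float:
        """Cell-level expression-marker estimate: mean over acquired frames."""
        if self.expr_marker is None or not np.any(np.isfinite(self.expr_marker)):
            return float("nan")
        return float(np.nanmean(self.expr_marker))

    @property
    def is_alive(self) -> bool:
        """True unless the viability flag is down at any point."""
        return self.alive is None or bool(np.all(self.alive))

    def __len__(self) -> int:
        return int(self.times.size)
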