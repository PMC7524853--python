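"""Image analysis: brightfield division, segmentation, nuclei, localization.

The measurement chain per frame is

    divide_brightfield -> segment_cells -> identify_nucleus -> measure_cell

The localization index of a cell is defined from median fluorescence as

    index = median(GFP over nuclear mask) / median(GFP over whole cell) - 1

so 0 means spatially uniform Mig1-GFP, positive values nuclear enrichment,
and the index is invariant under global scaling of the GFP channel.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

from .stack import FrameStack

__all__ = [
    "CellRegion",
    "LocalizationMeasurement",
    "SegmentationParams",
    "divide_brightfield",
    "segment_cells",
    "identify_nucleus",
    "measure_cell",
    "measure_stack",
    "regions_from_labels",
]

log = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "frame",
    "time_min",
    "cell_label",
    "median_nuc",
    "median_total",
    "loc_index",
    "reporter",
    "expr_marker",
    "valid",
]


@dataclass
class CellRegion:
    """One segmented cell in one frame.

    Pixel sets are stored as coordinate arrays (row, col), 0-based.  The
    nuclear mask is empty until :func:`identify_nucleus` fills it and must
    then be a strict non-empty subset of the cell mask.
    """

    frame_index: int
    label: int
    rows: np.ndarray
    cols: np.ndarray
    nuc_rows: Optional[np.ndarray] = None
    nuc_cols: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        if self.rows.size == 0 or self.rows.size != self.cols.size:
            raise ValueError("cell mask must be a non-empty pixel set")
        if self.label <= 0:
            raise ValueError("labels must be positive integers")

    @property
    def area(self) -> int:
        return int(self.rows.size)

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())

    @property
    def has_nucleus(self) -> bool:
        return self.nuc_rows is not None and self.nuc_rows.size > 0

    def set_nucleus(self, rows: np.ndarray, cols: np.ndarray) -> None:
        rows = np.asarray(rows, dtype=np.intp)
        cols = np.asarray(cols, dtype=np.intp)
        own = set(zip(self.rows.tolist(), self.cols.tolist()))
        sub = set(zip(rows.tolist(), cols.tolist()))
        if not sub or not sub <= own or len(sub) >= len(own):
            raise ValueError(
                "nuclear mask must be a non-empty strict subset of the cell"
            )
        self.nuc_rows, self.nuc_cols = rows, cols

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


@dataclass(frozen=True)
class LocalizationMeasurement:
    """Per-cell, per-frame intensity readout."""

    frame_index: int
    time: float
    cell_label: int
    median_nuc: float
    median_total: float
    localization_index: float
    reporter_intensity: float = float("nan")
    expr_marker_intensity: float = float("nan")
    valid: bool = True


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the brightfield-ring segmentation.

    The divided image has background ~1 with a high-contrast ring along each
    cell outline; segmentation thresholds the smoothed |log| response, fills
    ring interiors, splits touching cells by watershed on the distance
    transform, and trims the ring half-width.
    """

    smooth_sigma: float = 2.0  # px
    min_threshold: float = 0.1  # |log ratio| floor
    ring_trim: int = 2  # px eroded after hole filling
    min_area: int = 80  # px
    max_area: int = 2500  # px
    min_solidity: float = 0.8
    split_min_distance: int = 8  # px between watershed seeds


def divide_brightfield(
    above: np.ndarray, below: np.ndarray, epsilon: Optional[float] = None
) -> np.ndarray:
    """Pixelwise ratio of above-focus to below-focus brightfield.

    Any multiplicative illumination field common to the two planes cancels,
    leaving the out-of-focus diffraction ring of each cell on a flat
    background.  ``epsilon`` guards the division; the default is
    ``1e-6 * median(below)``.
    """
    above = np.asarray(above, dtype=float)
    below = np.asarray(below, dtype=float)
    if above.shape != below.shape:
        raise ValueError("above/below focal planes must have the same shape")
    if epsilon is None:
        epsilon = 1e-6 * float(np.median(below))
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    return above / (below + epsilon)


def _remove_small(fg: np.ndarray, min_size: int) -> np.ndarray:
    lab, _ = ndi.label(fg)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[lab]


def segment_cells(
    divided: np.ndarray, params: SegmentationParams = SegmentationParams(),
    frame_index: int = 0,
) -> list[CellRegion]:
    """Segment cells from a divided brightfield image.

    Returns regions with masks only (no nuclei), labels 1..n ordered by
    centroid.  A blank frame yields an empty list.
    """
    divided = np.asarray(divided, dtype=float)
    if divided.size == 0:
        return []
    response = gaussian(
        np.abs(np.log(np.clip(divided, 1e-12, None))), sigma=params.smooth_sigma
    )
    spread = float(response.max() - response.min())
    if spread < params.min_threshold:
        return []
    try:
        thr = max(float(threshold_otsu(response)), params.min_threshold)
    except ValueError:  # constant image
        return []
    fg = response > thr
    fg = ndi.binary_closing(fg, structure=disk(2))
    fg = ndi.binary_fill_holes(fg)
    fg = _remove_small(fg, min_size=max(params.min_area // 2, 1))
    if params.ring_trim > 0:
        fg = ndi.binary_erosion(fg, disk(params.ring_trim))
    if not fg.any():
        return []

    # Split touching cells on the distance transform.
    dist = ndi.distance_transform_edt(fg)
    seed_mask = dist >= params.split_min_distance * 0.5
    markers, n_seeds = ndi.label(seed_mask)
    if n_seeds == 0:
        markers, _ = ndi.label(fg)
    labels = watershed(-dist, markers=markers, mask=fg)

    kept: list[tuple[np.ndarray, np.ndarray]] = []
    for prop in regionprops(labels):
        if not (params.min_area <= prop.area <= params.max_area):
            continue
        if prop.solidity < params.min_solidity:
            continue
        rr, cc = np.nonzero(labels == prop.label)
        kept.append((rr, cc))
    kept.sort(key=lambda m: (m[0].mean(), m[1].mean()))
    return [
        CellRegion(frame_index=frame_index, label=i, rows=rr, cols=cc)
        for i, (rr, cc) in enumerate(kept, start=1)
    ]


def regions_from_labels(
    label_image: np.ndarray,
    frame_index: int = 0,
    nuclear_labels: Optional[np.ndarray] = None,
) -> list[CellRegion]:
    """Build regions from a labelled mask (e.g. generator ground truth).

    If ``nuclear_labels`` is given (same labelling), nuclear masks are filled
    directly.
    """
    regions = []
    for lbl in np.unique(label_image):
        if lbl <= 0:
            continue
        rr, cc = np.nonzero(label_image == lbl)
        region = CellRegion(frame_index=frame_index, label=int(lbl), rows=rr, cols=cc)
        if nuclear_labels is not None:
            nr, nc = np.nonzero(nuclear_labels == lbl)
            if nr.size:
                region.set_nucleus(nr, nc)
        regions.append(region)
    return regions


def _grow_brightest_patch(
    region: CellRegion, values: np.ndarray, target: int
) -> tuple[np.ndarray, np.ndarray]:
    """Brightest contiguous patch of exactly ``target`` pixels in the cell.

    Greedy region growing from the brightest pixel, always absorbing the
    brightest 4-connected neighbour; ties break on (row, col) so the result
    is deterministic even for flat intensity.
    """
    coords = list(zip(region.rows.tolist(), region.cols.tolist()))
    value_of = dict(zip(coords, values.tolist()))
    start = max(coords, key=lambda rc: (value_of[rc], -rc[0], -rc[1]))
    selected = {start}
    frontier: list[tuple[float, int, int]] = []

    def push_neighbours(rc):
        r, c = rc
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if nb in value_of and nb not in selected:
                heapq.heappush(frontier, (-value_of[nb], nb[0], nb[1]))

    push_neighbours(start)
    while len(selected) < target and frontier:
        _, r, c = heapq.heappop(frontier)
        if (r, c) in selected:
            continue
        selected.add((r, c))
        push_neighbours((r, c))
    rr = np.array([r for r, _ in selected], dtype=np.intp)
    cc = np.array([c for _, c in selected], dtype=np.intp)
    return rr, cc


def identify_nucleus(
    region: CellRegion,
    nuc_marker: Optional[np.ndarray],
    fallback_fraction: float = 0.12,
    gfp: Optional[np.ndarray] = None,
) -> CellRegion:
    """Fill the region's nuclear mask from the nuclear-marker channel.

    The nucleus is the largest connected component of the Otsu-thresholded
    marker inside the cell.  If the marker is absent or flat — or the
    threshold would select the whole cell — the fallback takes the brightest
    contiguous ``fallback_fraction`` of the cell's GFP pixels (marker pixels
    if no GFP given), which has exactly ``round(fraction * area)`` pixels.
    """
    if not 0.0 < fallback_fraction < 0.5:
        raise ValueError("fallback_fraction must be in (0, 0.5)")
    target = max(1, min(int(round(fallback_fraction * region.area)), region.area - 1))

    def fallback() -> tuple[np.ndarray, np.ndarray]:
        channel = gfp if gfp is not None else nuc_marker
        if channel is None:
            raise ValueError("need a marker or GFP channel to find a nucleus")
        vals = np.asarray(channel, dtype=float)[region.rows, region.cols]
        return _grow_brightest_patch(region, vals, target)

    rr = cc = None
    if nuc_marker is not None:
        vals = np.asarray(nuc_marker, dtype=float)[region.rows, region.cols]
        spread = float(vals.max() - vals.min())
        flat = spread <= 1e-12 or spread < 0.05 * max(float(np.median(vals)), 1e-12)
        if not flat:
            thr = threshold_otsu(vals)
            inside = vals > thr
            if inside.any() and not inside.all():
                # Largest connected component of the thresholded marker.
                r0, c0 = region.rows.min(), region.cols.min()
                shape = (
                    region.rows.max() - r0 + 1,
                    region.cols.max() - c0 + 1,
                )
                sub = np.zeros(shape, dtype=bool)
                sub[region.rows[inside] - r0, region.cols[inside] - c0] = True
                lab = cc_label(sub, connectivity=1)
                sizes = np.bincount(lab.ravel())
                sizes[0] = 0
                keep = lab == sizes.argmax()
                rr, cc = np.nonzero(keep)
                rr, cc = rr + r0, cc + c0
                if rr.size >= region.area:
                    log.warning(
                        "nuclear mask fills cell %d; shrinking to fallback",
                        region.label,
                    )
                    rr = cc = None
    if rr is None:
        rr, cc = fallback()
    region.set_nucleus(rr, cc)
    return region


def measure_cell(
    region: CellRegion,
    gfp: np.ndarray,
    reporter: Optional[np.ndarray] = None,
    expr: Optional[np.ndarray] = None,
    time: float = 0.0,
) -> LocalizationMeasurement:
    """Localization index and reporter intensities for one cell.

    The index uses medians exactly as defined; reporter and expression
    channels use means over the whole cell mask (linear with expression).
    A non-positive whole-cell median flags the measurement invalid.
    """
    if not region.has_nucleus:
        raise ValueError("region has no nuclear mask; run identify_nucleus first")
    gfp = np.asarray(gfp, dtype=float)
    median_total = float(np.median(gfp[region.rows, region.cols]))
    median_nuc = float(np.median(gfp[region.nuc_rows, region.nuc_cols]))
    valid = median_total > 0
    index = median_nuc / median_total - 1.0 if valid else float("nan")

    def mean_over(channel):
        if channel is None:
            return float("nan")
        vals = np.asarray(channel, dtype=float)[region.rows, region.cols]
        return float(np.mean(vals)) if np.all(np.isfinite(vals)) else float("nan")

    return LocalizationMeasurement(
        frame_index=region.frame_index,
        time=time,
        cell_label=region.label,
        median_nuc=median_nuc,
        median_total=median_total,
        localization_index=index,
        reporter_intensity=mean_over(reporter),
        expr_marker_intensity=mean_over(expr),
        valid=valid,
    )


def measure_stack(
    stack: FrameStack,
    params: SegmentationParams = SegmentationParams(),
    fallback_fraction: float = 0.12,
    labels: Optional[np.ndarray] = None,
    nuclear_labels: Optional[np.ndarray] = None,
) -> tuple[pd.DataFrame, dict[int, list[CellRegion]]]:
    """Run divide -> segment -> nucleus -> measure over every frame.

    If ``labels`` (T, H, W integer masks) is given, segmentation is skipped
    and those masks are measured instead — the ground-truth path used for
    round-trip validation.  Per-frame failures are logged and skipped, never
    abort the stack.

    Returns the tidy measurement table and the per-frame regions (for
    tracking).
    """
    rows = []
    regions_by_frame: dict[int, list[CellRegion]] = {}
    expr_mask = stack.expr_frame_mask()
    gfp_stack = stack.channel("gfp")
    reporter_stack = stack.channels.get("reporter")
    expr_stack = stack.channels.get("expr_marker")
    nuc_stack = stack.channels.get("nuc_marker")

    for f in range(stack.n_frames):
        try:
            if labels is not None:
                nuc = nuclear_labels[f] if nuclear_labels is not None else None
                regions = regions_from_labels(labels[f], frame_index=f, nuclear_labels=nuc)
            else:
                divided = divide_brightfield(
                    stack.channel("bf_above")[f], stack.channel("bf_below")[f]
                )
                regions = segment_cells(divided, params, frame_index=f)
            gfp = gfp_stack[f]
            nuc_img = nuc_stack[f] if nuc_stack is not None else None
            for region in regions:
                if not region.has_nucleus:
                    identify_nucleus(
                        region, nuc_img, fallback_fraction=fallback_fraction, gfp=gfp
                    )
                m = measure_cell(
                    region,
                    gfp,
                    reporter_stack[f] if reporter_stack is not None else None,
                    expr_stack[f] if (expr_stack is not None and expr_mask[f]) else None,
                    time=float(stack.times[f]),
                )
                rows.append(
                    {
                        "frame": f,
                        "time_min": m.time,
                        "cell_label": m.cell_label,
                        "median_nuc": m.median_nuc,
                        "median_total": m.median_total,
                        "loc_index": m.localization_index,
                        "reporter": m.reporter_intensity,
                        "expr_marker": m.expr_marker_intensity,
                        "valid": m.valid,
                    }
                )
            regions_by_frame[f] = regions
        except Exception:  # pragma: no cover - defensive per-frame skip
            log.exception("frame %d failed; skipping", f)
            regions_by_frame[f] = []
    table = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return table, regions_by_frame
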