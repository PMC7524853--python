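"""Render ground-truth traces into synthetic multi-channel movies.

The renderer emulates the acquisition geometry of a microfluidic yeast
experiment: out-of-focus brightfield planes above and below focus (cells as
bright/dark diffraction rings of opposite polarity on a common illumination
field), a Mig1-GFP channel whose nuclear:cytoplasmic split encodes the
ground-truth localization index exactly, a nuclear-marker channel, the
promoter-reporter channel, and the sparsely acquired expression-level
marker.  At zero noise and zero blur the GFP rendering is exactly invertible:
measuring with the ground-truth masks returns the true index up to float
round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from .schedule import AcquisitionSchedule
from .simulate import GroundTruthTrace
from .stack import FrameStack

__all__ = ["SceneGeometry", "render_movie"]


@dataclass
class SceneGeometry:
    """Geometry and camera model of the rendered scene.

    ``illumination_gradient`` is the multiplicative factor reached in the
    far corner of the field (1 = flat); the same field multiplies both
    brightfield planes, so their ratio cancels it.  ``shot_gain`` scales
    intensity-dependent (Poisson-like) noise variance and ``read_noise`` is
    additive Gaussian noise in AU; zero both for noise-free frames.
    """

    image_size: tuple[int, int] = (256, 256)
    cell_radius_mean: float = 12.0
    cell_radius_sd: float = 1.5
    nuclear_area_fraction: float = 0.12
    cell_positions: Optional[np.ndarray] = None  # (n, 2) row, col
    drift_per_frame: float = 1.0  # px random-walk step SD
    drift_bound: float = 5.0  # px reflection box half-width
    psf_sigma: float = 0.0  # px
    background_level: float = 200.0  # brightfield counts
    illumination_gradient: float = 1.0
    ring_contrast: float = 0.35
    ring_width: float = 1.5  # px
    gfp_cyto_level: float = 100.0  # AU at index 0
    fluor_background: float = 20.0  # AU
    expr_background: float = 5.0  # AU
    shot_gain: float = 2.0
    read_noise: float = 2.0
    on_overlap: str = "regenerate"  # or "raise"

    def __post_init__(self) -> None:
        if not 0.0 < self.nuclear_area_fraction < 0.5:
            raise ValueError("nuclear_area_fraction must be in (0, 0.5)")
        if self.on_overlap not in ("regenerate", "raise"):
            raise ValueError("on_overlap must be 'regenerate' or 'raise'")


def _illumination_field(shape: tuple[int, int], gradient: float) -> np.ndarray:
    """Multiplicative field rising linearly from 1 to ``gradient`` corner-to-corner."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    ramp = (rr + cc) / max(h + w - 2, 1)
    return 1.0 + (gradient - 1.0) * ramp


def _place_cells(
    n: int,
    geometry: SceneGeometry,
    radii: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> np.ndarray:
    """Non-overlapping positions with room for drift and diffraction rings.

    Random sequential placement first (irregular, realistic layouts); if the
    requested density jams it, fall back to a jittered grid, which packs
    deterministically up to the geometric capacity of the field.
    """
    h, w = geometry.image_size
    margin = radii.max() + 3 * geometry.ring_width + geometry.drift_bound + 1
    clearance = 2 * geometry.drift_bound + 3 * geometry.ring_width + 2
    separation = float(2 * radii.max() + clearance)

    positions: list[tuple[float, float]] = []
    for i in range(n):
        for _ in range(max_tries):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            ok = all(
                np.hypot(r - pr, c - pc) >= radii[i] + radii[j] + clearance
                for j, (pr, pc) in enumerate(positions)
            )
            if ok:
                positions.append((r, c))
                break
        else:
            break
    if len(positions) == n:
        return np.asarray(positions)

    # Jittered grid fallback: pitch >= worst-case separation + jitter room.
    jitter = 2.0
    pitch = separation + 2 * jitter
    usable_h, usable_w = h - 2 * margin, w - 2 * margin
    rows = int(usable_h // pitch) + 1
    cols = int(usable_w // pitch) + 1
    if rows * cols < n:
        raise ValueError(
            f"could not place {n} non-overlapping cells in {geometry.image_size}"
        )
    sites = [
        (margin + i * pitch, margin + j * pitch)
        for i in range(rows)
        for j in range(cols)
    ]
    chosen = rng.permutation(len(sites))[:n]
    return np.asarray(
        [
            (
                sites[k][0] + rng.uniform(-jitter, jitter),
                sites[k][1] + rng.uniform(-jitter, jitter),
            )
            for k in chosen
        ]
    )


def render_movie(
    truths: Sequence[GroundTruthTrace],
    geometry: SceneGeometry,
    schedule: AcquisitionSchedule,
    rng: Optional[np.random.Generator] = None,
) -> tuple[FrameStack, np.ndarray, np.ndarray]:
    """Render traces into a movie plus ground-truth label stacks.

    Returns ``(stack, labels, nuclear_labels)`` where the label stacks are
    (T, H, W) uint16 with cell ``i`` carrying label ``i + 1`` in every frame
    it appears.  Dead cells stop drifting and freeze their intensities
    (their frozen index is already encoded in the ground truth).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(truths)
    h, w = geometry.image_size
    t_grid = schedule.times
    n_frames = t_grid.size
    for truth in truths:
        if truth.times.size != n_frames:
            raise ValueError("trace sampling does not match the schedule")

    radii = np.clip(
        rng.normal(geometry.cell_radius_mean, geometry.cell_radius_sd, size=n),
        4.0,
        None,
    )
    if geometry.cell_positions is not None:
        base = np.asarray(geometry.cell_positions, dtype=float)
        if base.shape != (n, 2):
            raise ValueError("cell_positions must be (n_cells, 2)")
        d = np.hypot(
            base[:, None, 0] - base[None, :, 0], base[:, None, 1] - base[None, :, 1]
        )
        np.fill_diagonal(d, np.inf)
        if np.any(d < radii[:, None] + radii[None, :]):
            if geometry.on_overlap == "raise":
                raise ValueError("provided cell positions overlap")
            base = _place_cells(n, geometry, radii, rng)
    else:
        base = _place_cells(n, geometry, radii, rng)

    # Bounded per-cell random-walk drift, frozen after death.
    offsets = np.zeros((n, 2))
    positions = np.zeros((n_frames, n, 2))
    for f in range(n_frames):
        if f > 0 and geometry.drift_per_frame > 0:
            for i, truth in enumerate(truths):
                if truth.alive[f]:
                    step = rng.normal(0.0, geometry.drift_per_frame, size=2)
                    prop = offsets[i] + step
                    bound = geometry.drift_bound
                    # Reflect into the [-bound, bound] box.
                    prop = np.where(prop > bound, 2 * bound - prop, prop)
                    prop = np.where(prop < -bound, -2 * bound - prop, prop)
                    offsets[i] = np.clip(prop, -bound, bound)
        positions[f] = base + offsets

    illum = _illumination_field((h, w), geometry.illumination_gradient)
    sparse = schedule.sparse_frame_mask
    nuc_radii = radii * np.sqrt(geometry.nuclear_area_fraction)

    channels = {
        name: np.zeros((n_frames, h, w), dtype=np.float32)
        for name in ("bf_above", "bf_below", "gfp", "nuc_marker", "reporter")
    }
    channels["expr_marker"] = np.full((n_frames, h, w), np.nan, dtype=np.float32)
    labels = np.zeros((n_frames, h, w), dtype=np.uint16)
    nuclear_labels = np.zeros((n_frames, h, w), dtype=np.uint16)

    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")

    for f in range(n_frames):
        bf_ring = np.zeros((h, w))
        gfp = np.full((h, w), geometry.fluor_background)
        nuc_ch = np.full((h, w), geometry.fluor_background)
        rep_ch = np.full((h, w), geometry.fluor_background)
        expr_ch = np.full((h, w), geometry.expr_background)

        for i, truth in enumerate(truths):
            r0, c0 = positions[f, i]
            rad = radii[i]
            lo_r = max(int(r0 - rad - 5 * geometry.ring_width), 0)
            hi_r = min(int(r0 + rad + 5 * geometry.ring_width) + 1, h)
            lo_c = max(int(c0 - rad - 5 * geometry.ring_width), 0)
            hi_c = min(int(c0 + rad + 5 * geometry.ring_width) + 1, w)
            d = np.hypot(
                yy[lo_r:hi_r, lo_c:hi_c] - r0, xx[lo_r:hi_r, lo_c:hi_c] - c0
            )
            ring = np.exp(-0.5 * ((d - rad) / geometry.ring_width) ** 2)
            bf_ring[lo_r:hi_r, lo_c:hi_c] += ring

            cell = d <= rad
            nuc = d <= nuc_radii[i]
            n_cell = int(cell.sum())
            n_nuc = int(nuc.sum())
            if n_cell == 0 or n_nuc == 0 or n_nuc >= n_cell:
                continue
            index = float(truth.true_index[f])
            # Fixed total cell-attributable fluorescence; the rendered
            # cytoplasm/nucleus values are chosen so that, background
            # included, median(nuc)/median(cell) - 1 equals the ground-truth
            # index exactly (nucleus < 50% of the cell, so the whole-cell
            # median is the cytoplasmic value).
            total = geometry.gfp_cyto_level * n_cell
            cyto_val = (total + geometry.fluor_background * n_cell) / (
                n_cell + index * n_nuc
            )
            nuc_val = cyto_val * (1.0 + index)
            patch = gfp[lo_r:hi_r, lo_c:hi_c]
            patch[cell] = cyto_val
            patch[nuc] = nuc_val

            nuc_ch[lo_r:hi_r, lo_c:hi_c][nuc] = geometry.fluor_background + 300.0
            rep_ch[lo_r:hi_r, lo_c:hi_c][cell] = (
                geometry.fluor_background + float(truth.true_reporter[f])
            )
            expr_ch[lo_r:hi_r, lo_c:hi_c][cell] = (
                geometry.expr_background + truth.expr_marker_level
            )
            labels[f, lo_r:hi_r, lo_c:hi_c][cell] = i + 1
            nuclear_labels[f, lo_r:hi_r, lo_c:hi_c][nuc] = i + 1

        bf_above = geometry.background_level * illum * (
            1.0 + geometry.ring_contrast * bf_ring
        )
        bf_below = geometry.background_level * illum * (
            1.0 - geometry.ring_contrast * np.clip(bf_ring, 0.0, 1.0)
        )
        # The illumination field multiplies every channel: brightfield and
        # excitation light share the same uneven optical path.  Brightfield
        # division cancels it exactly; fluorescence ratios within one cell
        # are nearly invariant because the field varies little across a
        # cell diameter.
        frame = {
            "bf_above": bf_above,
            "bf_below": np.clip(bf_below, 1e-3, None),
            "gfp": gfp * illum,
            "nuc_marker": nuc_ch * illum,
            "reporter": rep_ch * illum,
        }
        for name, img in frame.items():
            if geometry.psf_sigma > 0 and name not in ("bf_above", "bf_below"):
                img = ndi.gaussian_filter(img, geometry.psf_sigma)
            if geometry.shot_gain > 0 or geometry.read_noise > 0:
                sd = np.sqrt(
                    geometry.shot_gain * np.clip(img, 0.0, None)
                    + geometry.read_noise**2
                )
                img = img + rng.normal(0.0, 1.0, size=img.shape) * sd
            channels[name][f] = np.clip(img, 0.0, None)
        if sparse[f]:
            img = expr_ch * illum
            if geometry.shot_gain > 0 or geometry.read_noise > 0:
                sd = np.sqrt(
                    geometry.shot_gain * np.clip(img, 0.0, None)
                    + geometry.read_noise**2
                )
                img = img + rng.normal(0.0, 1.0, size=img.shape) * sd
            channels["expr_marker"][f] = np.clip(img, 0.0, None)

    stack = FrameStack(channels=channels, times=t_grid.copy())
    return stack, labels, nuclear_labels
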