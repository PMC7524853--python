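"""Validation benchmarks: every pipeline stage against its ground truth.

Each function regenerates its own synthetic inputs from a seed, runs the
pipeline stage under test, and returns the measured quantities as a flat
dict.  The test suite asserts the documented properties on these numbers;
the reproduction script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imaging import CellRegion, measure_cell, measure_stack
from .metrics import find_pulse_peaks
from .pipeline import ConditionSpec, RunConfig, metrics_for_traces, run_condition
from .presets import HEXOSES, STRAINS, ReporterParams, preset
from .render import SceneGeometry, render_movie
from .report import classify_condition, matrix_check
from .schedule import make_schedule
from .simulate import observe_traces, simulate_traces
from .stats import summarize_group
from .trace import CellTrace
from .tracking import build_tracks

__all__ = [
    "brute_force_pulse_peaks",
    "index_exactness",
    "illumination_invariance",
    "pulse_detector_vs_oracle",
    "parameter_recovery",
    "segmentation_tracking",
    "statistical_calibration",
    "qualitative_matrix",
]


# ----------------------------------------------------------------- oracles


def brute_force_pulse_peaks(
    values: np.ndarray, min_prominence: float, min_separation_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Reference pulse detector: prominence evaluated by definition.

    Independent O(n^2) implementation of the contract of
    :func:`migshuttle.metrics.find_pulse_peaks`: enumerate local maxima
    (plateau midpoints), compute each peak's topographic prominence by
    scanning to the nearest strictly higher sample on each side (series
    borders act as edges) and taking the deeper of the two intervening
    minima, then apply the prominence filter and the greedy
    highest-peak-first separation rule.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    maxima = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                maxima.append((i + j) // 2)  # plateau midpoint, left-biased
            i = j + 1
        else:
            i += 1
    peaks, proms = [], []
    for p in maxima:
        left_min = x[p]
        k = p - 1
        while k >= 0 and x[k] <= x[p]:
            left_min = min(left_min, x[k])
            k -= 1
        right_min = x[p]
        k = p + 1
        while k < n and x[k] <= x[p]:
            right_min = min(right_min, x[k])
            k += 1
        prom = x[p] - max(left_min, right_min)
        if prom >= min_prominence:
            peaks.append(p)
            proms.append(prom)
    order = sorted(range(len(peaks)), key=lambda k: (-x[peaks[k]], peaks[k]))
    kept: list[int] = []
    for k in order:
        if all(abs(peaks[k] - peaks[j]) >= min_separation_samples for j in kept):
            kept.append(k)
    kept.sort(key=lambda k: peaks[k])
    return (
        np.asarray([peaks[k] for k in kept], dtype=int),
        np.asarray([proms[k] for k in kept]),
    )


# ------------------------------------------------------------- benchmarks


def index_exactness(seed: int, n_masks: int = 1000) -> dict:
    """measure_cell vs direct median arithmetic on random constructed cells.

    Builds random cell/nucleus pixel sets with random intensities and
    compares the measured localization index against
    ``median(nuc)/median(cell) - 1`` computed directly from the raw pixel
    values.
    """
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for k in range(n_masks):
        n_pix = int(rng.integers(20, 400))
        n_nuc = int(rng.integers(1, max(2, n_pix // 2)))
        h = w = 40
        flat = rng.choice(h * w, size=n_pix, replace=False)
        rows, cols = np.divmod(flat, w)
        nuc_sel = rng.choice(n_pix, size=n_nuc, replace=False)
        img = np.zeros((h, w))
        values = rng.uniform(1.0, 500.0, size=n_pix)
        img[rows, cols] = values
        region = CellRegion(frame_index=0, label=1, rows=rows, cols=cols)
        region.set_nucleus(rows[nuc_sel], cols[nuc_sel])
        m = measure_cell(region, img)
        expected = float(np.median(values[nuc_sel]) / np.median(values) - 1.0)
        max_dev = max(max_dev, abs(m.localization_index - expected))
    return {"n_masks": n_masks, "max_abs_deviation": max_dev}


def _render_condition(seed: int, n_cells: int, gradient: float, noisy: bool,
                      image_size=(256, 256), t_max: float = 120.0,
                      post_interval: float = 5.0):
    schedule = make_schedule(30, post_interval, -60, t_max, 4)
    config = preset("wt", "glucose", n_cells=n_cells, seed=seed)
    truths = simulate_traces(config, schedule)
    geometry = SceneGeometry(
        image_size=image_size,
        illumination_gradient=gradient,
        shot_gain=2.0 if noisy else 0.0,
        read_noise=2.0 if noisy else 0.0,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    stack, labels, nuclear_labels = render_movie(truths, geometry, schedule, rng)
    return schedule, truths, stack, labels, nuclear_labels


def illumination_invariance(seed: int, n_cells: int = 10) -> dict:
    """Index shift caused by a 2x corner-to-corner illumination gradient.

    Renders the same noise-free scene flat and with the gradient applied to
    every channel, measures both with the ground-truth masks, and reports
    the largest per-measurement index difference plus the worst deviation
    from the ground-truth index.
    """
    results = {}
    tables = []
    for gradient in (1.0, 2.0):
        schedule, truths, stack, labels, nuclear_labels = _render_condition(
            seed, n_cells, gradient, noisy=False
        )
        table, _ = measure_stack(stack, labels=labels, nuclear_labels=nuclear_labels)
        tables.append(table.set_index(["frame", "cell_label"])["loc_index"])
    flat, graded = tables
    diff = (flat - graded).abs()
    results["n_measurements"] = int(diff.size)
    results["max_index_shift"] = float(diff.max())
    truth_err = []
    for (f, label), value in graded.items():
        truth_err.append(abs(value - truths[label - 1].true_index[f]))
    results["max_error_vs_truth"] = float(np.max(truth_err))
    return results


def pulse_detector_vs_oracle(seed: int, n_traces: int = 500) -> dict:
    """Pulse detector vs the brute-force prominence oracle on random traces.

    Traces mix white noise, smooth trends and Gaussian bumps (lengths up to
    200 samples); detections must agree exactly in peak positions and
    prominences.
    """
    rng = np.random.default_rng(seed)
    mismatches = 0
    total_peaks = 0
    for _ in range(n_traces):
        n = int(rng.integers(10, 201))
        t = np.arange(n, dtype=float)
        x = rng.normal(0, rng.uniform(0.02, 0.2), size=n)
        if rng.random() < 0.7:  # smooth trend
            x += rng.uniform(-1, 1) * np.sin(t / rng.uniform(5, 40))
        for _ in range(rng.integers(0, 6)):  # bumps
            c = rng.uniform(0, n)
            x += rng.uniform(0.1, 1.0) * np.exp(-0.5 * ((t - c) / rng.uniform(1, 5)) ** 2)
        min_prom = float(rng.uniform(0.05, 0.4))
        dist = int(rng.integers(1, 6))
        got_idx, got_prom = find_pulse_peaks(x, min_prom, dist)
        exp_idx, exp_prom = brute_force_pulse_peaks(x, min_prom, dist)
        total_peaks += exp_idx.size
        same = (
            got_idx.size == exp_idx.size
            and np.array_equal(got_idx, exp_idx)
            and np.allclose(got_prom, exp_prom, rtol=0, atol=1e-12)
        )
        if not same:
            mismatches += 1
    return {
        "n_traces": n_traces,
        "n_oracle_peaks": int(total_peaks),
        "n_mismatched_traces": mismatches,
    }


def recovery_benchmark_config(seed: int, n_cells: int = 200):
    """Generator condition used for parameter recovery.

    Wild-type-like biphasic dynamics with the plateau held at the basal
    level so pulse heights are measured against an unbiased baseline:
    A = 1.0 peaking at 30 min, pulses at 2/h of mean height 0.4 in the
    adapted phase, default noise.
    """
    return preset("wt", "glucose", n_cells=n_cells, seed=seed).with_(
        initial_amplitude=1.0, plateau_level=0.05, pulse_rate=2.0
    )


def parameter_recovery(seed: int, n_cells: int = 200) -> dict:
    """Recover generator parameters from observed traces (trace-only mode)."""
    schedule = make_schedule()
    config = recovery_benchmark_config(seed, n_cells)
    truths = simulate_traces(config, schedule)
    traces = observe_traces(truths, config, schedule)
    run = RunConfig()
    table, ms = metrics_for_traces(traces, run)

    lo, hi = 240.0, 480.0
    hours = (hi - lo) / 60.0
    det_rate = float(np.mean([m.pulse_rate((lo, hi)) for m in ms]))
    heights = [p.height for m in ms for p in m.pulses if lo <= p.time <= hi]
    true_rate = float(
        np.mean([np.sum((t.pulse_times >= lo) & (t.pulse_times <= hi)) for t in truths])
        / hours
    )

    # Reporter fold-change: derepressed (4x production) vs repressed group.
    rep_params = ReporterParams(
        repressed_rate=0.575,
        derepressed_rate=4 * 0.575,
        derepression_onset=60.0,
    )
    dep_cfg = config.with_(
        seed=seed + 1, reporter=rep_params, pulse_rate=0.0, n_cells=n_cells
    )
    repressed_cfg = config.with_(seed=seed + 2, pulse_rate=0.0, n_cells=n_cells)
    folds = []
    for cfg in (dep_cfg, repressed_cfg):
        tr = observe_traces(simulate_traces(cfg, schedule), cfg, schedule)
        t, _ = metrics_for_traces(tr, run)
        folds.append(float(t["expr_mean_long"].mean()))
    fold = folds[0] / folds[1]

    return {
        "n_cells": n_cells,
        "basal_true": config.basal_level,
        "basal_recovered": float(table["basal"].mean()),
        "basal_abs_error": float(abs(table["basal"].mean() - config.basal_level)),
        "t_peak_true_min": config.peak_time,
        "t_max_short_median_min": float(table["t_max_short"].median()),
        "pulse_rate_true_per_h": config.pulse_rate,
        "pulse_rate_realized_per_h": true_rate,
        "pulse_rate_detected_per_h": det_rate,
        "pulse_rate_rel_error_pct": float(
            100 * abs(det_rate - config.pulse_rate) / config.pulse_rate
        ),
        "pulse_height_true": config.pulse_height_mean,
        "pulse_height_recovered": float(np.mean(heights)),
        "pulse_height_abs_error": float(
            abs(np.mean(heights) - config.pulse_height_mean)
        ),
        "reporter_rate_ratio_true": 4.0,
        "reporter_fold_recovered": float(fold),
        "reporter_fold_rel_error_pct": float(100 * abs(fold - 4.0) / 4.0),
    }


def segmentation_tracking(seed: int, n_cells: int = 20) -> dict:
    """Detection recall, mask IoU and link accuracy on a rendered movie.

    Renders the full acquisition schedule at 256 x 256 px with default
    camera noise and per-cell drift, segments every frame from the divided
    brightfield, tracks, and scores against the ground-truth label stacks.
    A detection counts when it overlaps the true cell at IoU >= 0.5; a
    frame-to-frame link is correct when both its endpoints match the same
    ground-truth cell.
    """
    schedule = make_schedule()
    config = preset("wt", "glucose", n_cells=n_cells, seed=seed)
    truths = simulate_traces(config, schedule)
    geometry = SceneGeometry(image_size=(256, 256))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    stack, labels, _ = render_movie(truths, geometry, schedule, rng)
    table, regions = measure_stack(stack)

    def pixel_set(region):
        return set(zip(region.rows.tolist(), region.cols.tolist()))

    n_true = n_found = 0
    ious = []
    truth_of: list[dict[int, int]] = []  # per frame: detected label -> true label
    for f in range(stack.n_frames):
        mapping = {}
        dets = regions.get(f, [])
        det_sets = {r.label: pixel_set(r) for r in dets}
        for true_label in np.unique(labels[f]):
            if true_label == 0:
                continue
            n_true += 1
            rr, cc = np.nonzero(labels[f] == true_label)
            gt = set(zip(rr.tolist(), cc.tolist()))
            best_iou, best_label = 0.0, None
            for det_label, ds in det_sets.items():
                v = len(gt & ds) / len(gt | ds)
                if v > best_iou:
                    best_iou, best_label = v, det_label
            if best_iou >= 0.5:
                n_found += 1
                ious.append(best_iou)
                mapping[best_label] = int(true_label)
        truth_of.append(mapping)

    frames = [regions.get(f, []) for f in range(stack.n_frames)]
    tracks = build_tracks(frames, max_displacement=12.0)
    n_links = n_correct = 0
    for track in tracks:
        for (fa, la), (fb, lb) in zip(track.entries, track.entries[1:]):
            if fb - fa != 1:
                continue
            n_links += 1
            ta, tb = truth_of[fa].get(la), truth_of[fb].get(lb)
            if ta is not None and ta == tb:
                n_correct += 1
    return {
        "n_cells": n_cells,
        "n_frames": int(stack.n_frames),
        "recall": n_found / n_true,
        "mean_iou": float(np.mean(ious)),
        "n_links": n_links,
        "link_accuracy": n_correct / n_links if n_links else float("nan"),
    }


def statistical_calibration(
    seed: int, n_replicates: int = 1000, n_cells: int = 50
) -> dict:
    """Welch-test type-I error and t-CI coverage on null generator draws.

    Every replicate draws two independent groups from the same condition
    (the recovery benchmark) and compares their adapted-phase mean
    localization; coverage is scored against the condition's true expected
    ``mean_long``, obtained analytically from the noise-free model
    components (the log-normal jitters and the stationary pulse process
    have unit-mean multipliers, so the expectation is the deterministic
    trace plus the mean pulse mass).
    """
    from .metrics import long_term_mean
    from .simulate import initial_response_kernel

    schedule = make_schedule()
    base = recovery_benchmark_config(seed, n_cells)

    # Analytic E[mean_long]: deterministic component averaged over the
    # window grid plus expected pulse mass per sample.
    sel = (schedule.times >= 240) & (schedule.times <= 480)
    t_win = schedule.times[sel]
    b = base.basal_level
    det = b + base.initial_amplitude * initial_response_kernel(
        t_win, base.peak_time, base.decay_tau
    ) + (base.plateau_level - b) * (1 - np.exp(-t_win / base.decay_tau))
    from scipy.stats import norm

    sigma_g = base.pulse_width / (2 * np.sqrt(2 * np.log(2)))
    pulse_mass_per_min = (
        (base.pulse_rate / 60.0) * base.pulse_height_mean * sigma_g * np.sqrt(2 * np.pi)
    )
    # The stationary pulse process only runs from pulse_start, so the
    # expected bump mass at time t ramps in as the Gaussian CDF of
    # (t - pulse_start).
    ramp = norm.cdf((t_win - base.pulse_start) / sigma_g)
    true_mean = float(det.mean() + pulse_mass_per_min * ramp.mean())

    ss = np.random.SeedSequence([seed, 6])
    rejections = 0
    covered = 0
    for rep, child in enumerate(ss.spawn(n_replicates)):
        s1, s2, s3 = child.generate_state(3) % (2**31)
        groups = []
        for gseed in (int(s1), int(s2)):
            cfg = base.with_(seed=gseed)
            traces = observe_traces(simulate_traces(cfg, schedule), cfg, schedule)
            groups.append(np.array([long_term_mean(tr) for tr in traces]))
        summary = summarize_group(groups[0], groups[1])
        if summary.significant:
            rejections += 1
        lo, hi = summary.ci95
        if lo <= true_mean <= hi:
            covered += 1
    return {
        "n_replicates": n_replicates,
        "n_cells_per_group": n_cells,
        "true_mean_long": true_mean,
        "type_i_error": rejections / n_replicates,
        "ci95_coverage_pct": 100.0 * covered / n_replicates,
    }


def qualitative_matrix(seed: int, n_cells: int = 50) -> dict:
    """Full strain x hexose grid in trace-only mode vs the expected table."""
    run = RunConfig()
    metrics_by_condition = {}
    for si, strain in enumerate(STRAINS):
        for hi, hexose in enumerate(HEXOSES):
            spec = ConditionSpec(
                strain, hexose, n_cells=n_cells, seed=seed + 10 * si + hi
            )
            res = run_condition(spec, run)
            metrics_by_condition[(strain, hexose)] = res["metrics"]
    ref = float(metrics_by_condition[("wt", "glucose")]["expr_mean_long"].mean())
    classifications = [
        classify_condition(df, reference_expr_mean=ref)
        for df in metrics_by_condition.values()
    ]
    matrix, all_ok = matrix_check(classifications)
    return {
        "n_conditions": len(matrix),
        "n_agreeing": int(matrix["agrees"].sum()),
        "agreement_fraction": float(matrix["agrees"].mean()),
        "all_agree": bool(all_ok),
    }
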