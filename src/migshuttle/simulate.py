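"""Ground-truth single-cell Mig1 dynamics and reporter kinetics.

The generator encodes the biphasic localization response seen after a shift
from ethanol to a repressing hexose: a rapid initial nuclear-accumulation
peak (maximum within ~30 min) that decays over the following hours, an
adapted-phase plateau, and — in conditions with an active hexokinase-Snf1
axis — pulsatile nucleocytoplasmic shuttling.  All cell-to-cell variability
is multiplicative log-normal jitter on amplitude, pulse rate and pulse
height; all randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .presets import ReporterParams, SimulationConfig
from .schedule import AcquisitionSchedule
from .trace import CellTrace

__all__ = [
    "GroundTruthTrace",
    "initial_response_kernel",
    "simulate_traces",
    "simulate_reporter",
    "observe_traces",
]

#: Refractory gap between shuttling pulses, as a multiple of the pulse FWHM.
#: 1.5x the width keeps consecutive bumps resolvable as distinct local
#: maxima at the 5-min post-shift sampling interval.
REFRACTORY_WIDTHS = 1.5


@dataclass
class GroundTruthTrace:
    """Noise-free truth for one simulated cell.

    ``true_index`` and ``true_reporter`` are sampled on the acquisition grid;
    ``pulse_times``/``pulse_heights`` are the continuous-time pulse events.
    ``alive`` flags frames before toxicity-induced death (always True in
    non-toxic conditions).
    """

    cell_id: int
    times: np.ndarray
    true_index: np.ndarray
    pulse_times: np.ndarray
    pulse_heights: np.ndarray
    true_reporter: np.ndarray
    alive: np.ndarray
    expr_marker_level: float = float("nan")
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.true_index) != len(self.times):
            raise ValueError("true_index and times must have equal length")


def initial_response_kernel(
    t: np.ndarray, t_peak: float, decay_tau: float
) -> np.ndarray:
    """Gamma-shaped rise-and-decay, unit maximum at ``t_peak``.

    ``k(t) = (t/t_peak)**(t_peak/decay_tau) * exp((t_peak - t)/decay_tau)``
    for t >= 0, zero before.  The mode sits exactly at ``t_peak`` and the
    tail decays as ``exp(-t/decay_tau)``.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    a = t_peak / decay_tau
    out[pos] = (t[pos] / t_peak) ** a * np.exp((t_peak - t[pos]) / decay_tau)
    return out


def _lognormal_mult(rng: np.random.Generator, cv: float, size=None):
    """Log-normal multiplier(s) with mean 1 and the given CV."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _draw_pulse_times(
    rng: np.random.Generator,
    rate_per_hour: float,
    t_start: float,
    t_end: float,
    refractory: float,
) -> np.ndarray:
    """Pulse arrival times of a stationary renewal process on [t_start, t_end].

    Inter-arrival = refractory + Exp(mean_gap - refractory), so the mean gap
    is exactly ``60/rate_per_hour`` minutes; the first arrival is drawn from
    the equilibrium residual-life distribution, making the expected count in
    any window ``rate * window_length``.
    """
    if rate_per_hour <= 0 or t_end <= t_start:
        return np.empty(0)
    mean_gap = 60.0 / rate_per_hour
    exp_mean = max(mean_gap - refractory, 1e-6)
    c = min(refractory, mean_gap)

    def fresh_gap() -> float:
        return c + rng.exponential(exp_mean)

    # Equilibrium residual life of the gap distribution c + Exp(exp_mean):
    # with prob c/mean_gap uniform on [0, c], else c + Exp(exp_mean).
    if rng.random() < c / mean_gap:
        first = rng.uniform(0.0, c)
    else:
        first = fresh_gap()
    times = []
    t = t_start + first
    while t <= t_end:
        times.append(t)
        t += fresh_gap()
    return np.asarray(times)


def _gaussian_bumps(
    t: np.ndarray, centers: np.ndarray, heights: np.ndarray, fwhm: float
) -> np.ndarray:
    if centers.size == 0:
        return np.zeros_like(t)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    d = t[:, None] - centers[None, :]
    return (heights[None, :] * np.exp(-0.5 * (d / sigma) ** 2)).sum(axis=1)


def simulate_reporter(
    params: ReporterParams,
    schedule: AcquisitionSchedule,
    t_death: Optional[float] = None,
) -> np.ndarray:
    """Fluorescent-reporter level (AU) on the acquisition grid.

    Production is zero before the media shift, runs at ``repressed_rate``
    from t = 0 and switches to ``derepressed_rate`` at ``derepression_onset``.
    Product becomes fluorescent ``maturation_delay`` minutes after synthesis
    and the fluorescent pool decays at ``degradation_rate``; the solution is
    the exact superposition of first-order step responses.  If ``t_death`` is
    given the trajectory is frozen at its value at that time.
    """
    t = schedule.times
    k = params.degradation_rate
    # Rate steps of production-after-maturation: (time, rate increment).
    steps = [(params.maturation_delay, params.repressed_rate)]
    if params.derepression_onset is not None:
        steps.append(
            (
                params.derepression_onset + params.maturation_delay,
                params.derepressed_rate - params.repressed_rate,
            )
        )

    def level(tt: np.ndarray) -> np.ndarray:
        out = np.zeros_like(tt, dtype=float)
        for t0, dr in steps:
            active = tt > t0
            out[active] += (dr / k) * (1.0 - np.exp(-k * (tt[active] - t0)))
        return out

    out = level(t)
    if t_death is not None:
        frozen = float(level(np.asarray([t_death]))[0])
        out[t > t_death] = frozen
    return out


def simulate_traces(
    config: SimulationConfig,
    schedule: AcquisitionSchedule,
    rng: Optional[np.random.Generator] = None,
) -> list[GroundTruthTrace]:
    """Simulate noise-free ground-truth traces for ``config.n_cells`` cells.

    The localization index is ``basal`` before the shift and afterwards
    ``basal + A_c * kernel(t) + (L - basal) * (1 - exp(-t/decay_tau))`` plus
    the cell's shuttling pulses; per-cell ``A_c``, pulse rate and pulse
    heights carry log-normal jitter (CV ``jitter_cv``).  Reproducible for a
    fixed ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = schedule.times
    b = config.basal_level
    refractory = REFRACTORY_WIDTHS * config.pulse_width
    t_end = float(t[-1])

    traces: list[GroundTruthTrace] = []
    for cell_id in range(config.n_cells):
        responder = rng.random() < config.responder_fraction
        jitter_a, jitter_rate, jitter_h = _lognormal_mult(
            rng, config.jitter_cv, size=3
        )
        expr_level = float(
            config.expression_marker_median
            * np.exp(rng.normal(0.0, config.expression_marker_sigma))
        )
        # Dose-responsive rescue: pulse rate and plateau scale with the
        # (kinase-)expression level through a saturating Hill term.
        dose = 1.0
        if config.dose_response_k is not None:
            dose = expr_level / (expr_level + config.dose_response_k)

        amp = config.initial_amplitude * jitter_a if responder else 0.0
        rate = config.pulse_rate * jitter_rate * dose if responder else 0.0
        plateau = b + (config.plateau_level - b) * dose

        t_death = None
        if (
            config.death_expr_threshold is not None
            and expr_level > config.death_expr_threshold
        ):
            t_death = float(rng.uniform(60.0, 180.0))
        elif config.death_expr_threshold is None and config.death_fraction > 0:
            if rng.random() < config.death_fraction:
                t_death = float(rng.uniform(60.0, 180.0))

        pulse_times = _draw_pulse_times(
            rng, rate, config.pulse_start, t_end, refractory
        )
        n_pulses = pulse_times.size
        if n_pulses:
            mean_h = config.pulse_height_mean * jitter_h
            cv_h = (
                config.pulse_height_sd / config.pulse_height_mean
                if config.pulse_height_mean > 0
                else 0.0
            )
            heights = mean_h * _lognormal_mult(rng, cv_h, size=n_pulses)
        else:
            heights = np.empty(0)

        post = t >= 0
        index = np.full(t.shape, b, dtype=float)
        index[post] = (
            b
            + amp * initial_response_kernel(t[post], config.peak_time, config.decay_tau)
            + (plateau - b) * (1.0 - np.exp(-t[post] / config.decay_tau))
            + _gaussian_bumps(t[post], pulse_times, heights, config.pulse_width)
        )

        alive = np.ones(t.shape, dtype=bool)
        if t_death is not None:
            alive = t <= t_death
            # Dead cells freeze: hold the last live index value.
            last_live = index[alive][-1] if np.any(alive) else b
            index[~alive] = last_live
            keep = pulse_times <= t_death
            pulse_times, heights = pulse_times[keep], heights[keep]

        reporter = simulate_reporter(config.reporter, schedule, t_death=t_death)
        traces.append(
            GroundTruthTrace(
                cell_id=cell_id,
                times=t.copy(),
                true_index=index,
                pulse_times=pulse_times,
                pulse_heights=heights,
                true_reporter=reporter,
                alive=alive,
                expr_marker_level=expr_level,
                params={
                    "amplitude": amp,
                    "pulse_rate": rate,
                    "plateau": plateau,
                    "t_death": t_death,
                    "responder": responder,
                },
            )
        )
    return traces


def observe_traces(
    truths: Sequence[GroundTruthTrace],
    config: SimulationConfig,
    schedule: AcquisitionSchedule,
    rng: Optional[np.random.Generator] = None,
) -> list[CellTrace]:
    """Add measurement noise and channel sampling to ground-truth traces.

    This is the trace-only observation path: localization index plus
    ``noise_sd`` Gaussian noise, reporter plus ``reporter_noise_sd`` noise,
    and the expression marker (cell-constant truth plus 2% noise) only on
    the sparse-channel frames.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sparse = schedule.sparse_frame_mask
    out = []
    for truth in truths:
        n = truth.times.size
        idx = truth.true_index + rng.normal(0.0, config.noise_sd, size=n)
        rep = truth.true_reporter + rng.normal(
            0.0, config.reporter_noise_sd, size=n
        )
        expr = np.full(n, np.nan)
        if np.any(sparse):
            lvl = truth.expr_marker_level
            expr[sparse] = lvl * (
                1.0 + rng.normal(0.0, 0.02, size=int(sparse.sum()))
            )
        out.append(
            CellTrace(
                track_id=truth.cell_id,
                times=truth.times.copy(),
                loc_index=idx,
                reporter=rep,
                expr_marker=expr,
                strain=config.strain,
                hexose=config.hexose,
                alive=truth.alive.copy(),
                meta={"true_expr_level": truth.expr_marker_level},
            )
        )
    return out
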