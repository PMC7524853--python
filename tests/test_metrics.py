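import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migshuttle import (
    CellTrace,
    compute_basal,
    compute_trace_metrics,
    detect_pulses,
    expression_metrics,
    long_term_mean,
    make_schedule,
    mean_pulse_height,
    observe_traces,
    preset,
    short_term_metrics,
    simulate_traces,
)
from migshuttle.benchmarks import brute_force_pulse_peaks
from migshuttle.metrics import find_pulse_peaks


def trace_on_grid(values, t0=-45.0, dt=5.0, **kwargs):
    values = np.asarray(values, dtype=float)
    times = t0 + dt * np.arange(values.size)
    return CellTrace(track_id=0, times=times, loc_index=values, **kwargs)


def grid_trace(index_fn, schedule=None):
    if schedule is None:
        schedule = make_schedule()
    v = index_fn(schedule.times)
    return CellTrace(track_id=0, times=schedule.times, loc_index=v)


class TestWindows:
    def test_basal_is_preshift_mean(self):
        tr = trace_on_grid([0.1, 0.1, 0.1, 9.0, 9.0], t0=-15.0)
        assert compute_basal(tr) == pytest.approx(0.1)

    def test_basal_missing_without_preshift_frames(self):
        tr = trace_on_grid([1.0, 2.0, 3.0], t0=0.0)
        assert np.isnan(compute_basal(tr))

    def test_basal_recovery_monte_carlo(self):
        """b = 0.05, sigma = 0.02, 9 pre-shift frames, 200 cells."""
        schedule = make_schedule()
        cfg = preset("wt", "glucose", n_cells=200, seed=17).with_(noise_sd=0.02)
        traces = observe_traces(simulate_traces(cfg, schedule), cfg, schedule)
        basals = np.array([compute_basal(t) for t in traces])
        assert abs(basals.mean() - 0.05) < 0.01

    def test_short_term_peak_and_time(self):
        tr = grid_trace(
            lambda t: np.where(t == 30.0, 1.2, 0.2) * (t >= 0) + 0.1 * (t < 0)
        )
        mx, tmx, mean = short_term_metrics(tr)
        assert mx == 1.2 and tmx == 30.0
        assert mean < mx

    def test_monotone_decreasing_peaks_at_first_frame(self):
        tr = grid_trace(lambda t: np.where(t >= 0, 2.0 - 0.01 * t, 0.1))
        _, tmx, _ = short_term_metrics(tr)
        assert tmx == 0.0

    def test_short_term_needs_three_points(self):
        tr = trace_on_grid([0.1, 0.5, 0.4], t0=-5.0)  # only 2 in [0, 60]
        assert all(np.isnan(v) for v in short_term_metrics(tr))

    def test_long_term_constant(self):
        tr = grid_trace(lambda t: np.full(t.size, 0.4))
        assert long_term_mean(tr) == pytest.approx(0.4)

    def test_long_term_missing_below_coverage(self):
        tr = grid_trace(lambda t: np.full(t.size, 0.4))
        sel = (tr.times >= 240) & (tr.times <= 480)
        idx = np.flatnonzero(sel)
        tr.loc_index[idx[: int(0.6 * idx.size)]] = np.nan  # 40% coverage
        assert np.isnan(long_term_mean(tr))

    def test_window_metrics_ignore_outside_points(self):
        tr = grid_trace(lambda t: np.full(t.size, 0.3))
        tampered = grid_trace(lambda t: np.full(t.size, 0.3))
        outside = (tampered.times > 60) & (tampered.times < 240)
        tampered.loc_index[outside] = 50.0
        assert short_term_metrics(tr) == short_term_metrics(tampered)
        assert long_term_mean(tr) == long_term_mean(tampered)


class TestPulses:
    def gaussian_bumps(self, t, centers, heights, fwhm=15.0):
        s = fwhm / 2.355
        out = np.zeros_like(t, dtype=float)
        for c, h in zip(centers, heights):
            out += h * np.exp(-0.5 * ((t - c) / s) ** 2)
        return out

    def test_flat_trace_has_no_pulses(self):
        tr = grid_trace(lambda t: np.full(t.size, 0.2))
        assert detect_pulses(tr) == []

    def test_two_bump_heights_recovered(self):
        """Two bumps 60 min apart, heights 0.5/0.3 above a 0.1 basal."""
        tr = grid_trace(
            lambda t: 0.1 + self.gaussian_bumps(t, [240.0, 300.0], [0.5, 0.3])
        )
        pulses = detect_pulses(tr, min_prominence=0.1)
        assert len(pulses) == 2
        assert pulses[0].height == pytest.approx(0.5, abs=0.02)
        assert pulses[1].height == pytest.approx(0.3, abs=0.02)
        assert {p.time for p in pulses} == {240.0, 300.0}
        for p in pulses:
            assert p.width == pytest.approx(15.0, rel=0.4)

    def test_min_separation_drops_lower_neighbour(self):
        tr = grid_trace(
            lambda t: 0.0 + self.gaussian_bumps(t, [240.0, 250.0], [0.5, 0.4], fwhm=6)
        )
        near = detect_pulses(tr, min_prominence=0.05, min_separation=15.0)
        far = detect_pulses(tr, min_prominence=0.05, min_separation=5.0)
        assert len(near) == 1 and near[0].time == 240.0
        assert len(far) == 2

    def test_pulses_restricted_to_window(self):
        tr = grid_trace(
            lambda t: self.gaussian_bumps(t, [30.0, 300.0], [1.0, 0.5])
        )
        pulses = detect_pulses(tr, window=(60.0, 480.0), min_prominence=0.1)
        assert [p.time for p in pulses] == [300.0]

    def test_local_baseline_option_uses_prominence(self):
        tr = grid_trace(
            lambda t: 0.2 * (t >= 0) + self.gaussian_bumps(t, [300.0], [0.5])
        )
        from_basal = detect_pulses(tr, min_prominence=0.1)[0]
        local = detect_pulses(tr, min_prominence=0.1, height_baseline="local")[0]
        assert from_basal.height == pytest.approx(0.7, abs=0.02)  # plateau + bump
        assert local.height == pytest.approx(local.prominence)

    def test_raising_prominence_never_adds_pulses(self):
        rng = np.random.default_rng(0)
        schedule = make_schedule()
        for _ in range(20):
            tr = grid_trace(lambda t: rng.normal(0, 0.2, t.size), schedule)
            counts = [
                len(detect_pulses(tr, min_prominence=p))
                for p in (0.05, 0.1, 0.2, 0.4, 0.8)
            ]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_gap_interpolation_and_split(self):
        tr = grid_trace(lambda t: self.gaussian_bumps(t, [300.0], [0.6]))
        i300 = int(np.flatnonzero(tr.times == 300.0)[0])
        tr.loc_index[i300 - 1] = np.nan  # single-frame gap: interpolated
        assert len(detect_pulses(tr, min_prominence=0.1)) == 1

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 100_000),
        n=st.integers(5, 200),
        min_prom=st.floats(0.02, 0.5),
        dist=st.integers(1, 6),
    )
    def test_detector_matches_brute_force_oracle(self, seed, n, min_prom, dist):
        """Peak positions and prominences agree with the by-definition scan."""
        rng = np.random.default_rng(seed)
        t = np.arange(n, dtype=float)
        x = rng.normal(0, 0.1, n) + np.sin(t / max(rng.uniform(2, 30), 1e-3))
        got_i, got_p = find_pulse_peaks(x, min_prom, dist)
        exp_i, exp_p = brute_force_pulse_peaks(x, min_prom, dist)
        assert np.array_equal(got_i, exp_i)
        assert np.allclose(got_p, exp_p, atol=1e-12)

    def test_mean_pulse_height(self):
        tr = grid_trace(
            lambda t: 0.0 + self.gaussian_bumps(t, [250.0, 330.0], [0.5, 0.3])
        )
        pulses = detect_pulses(tr, min_prominence=0.1)
        assert mean_pulse_height(pulses) == pytest.approx(0.4, abs=0.02)
        assert np.isnan(mean_pulse_height([]))


class TestExpression:
    def reporter_trace(self, reporter):
        schedule = make_schedule()
        return CellTrace(
            track_id=0,
            times=schedule.times,
            loc_index=np.zeros(schedule.times.size),
            reporter=np.asarray(reporter, dtype=float),
        )

    def test_zero_reporter(self):
        schedule = make_schedule()
        tr = self.reporter_trace(np.zeros(schedule.times.size))
        mean_long, onset = expression_metrics(tr)
        assert mean_long == 0.0 and onset is None

    def test_constant_reporter_level(self):
        schedule = make_schedule()
        tr = self.reporter_trace(np.full(schedule.times.size, 5.0))
        mean_long, _ = expression_metrics(tr)
        assert mean_long == pytest.approx(5.0)

    def test_simulated_onset_detected_after_maturation(self):
        """Derepression at 60 min + 30 min maturation -> onset in [90, 120]."""
        schedule = make_schedule()
        cfg = preset("hxk2Δ", "glucose", n_cells=30, seed=21)
        cfg = cfg.with_(
            reporter=cfg.reporter.__class__(
                repressed_rate=0.0,
                derepressed_rate=cfg.reporter.derepressed_rate,
                maturation_delay=30.0,
                degradation_rate=cfg.reporter.degradation_rate,
                derepression_onset=60.0,
            )
        )
        traces = observe_traces(simulate_traces(cfg, schedule), cfg, schedule)
        onsets = [expression_metrics(t)[1] for t in traces]
        onsets = [o for o in onsets if o is not None]
        assert len(onsets) == len(traces)
        assert 90.0 <= np.median(onsets) <= 120.0


def test_compute_trace_metrics_bundles_consistently():
    schedule = make_schedule()
    cfg = preset("wt", "glucose", n_cells=5, seed=9)
    traces = observe_traces(simulate_traces(cfg, schedule), cfg, schedule)
    for tr in traces:
        m = compute_trace_metrics(tr)
        assert m.basal == pytest.approx(compute_basal(tr))
        assert m.max_short >= m.mean_short
        assert 0 <= m.t_max_short <= 60
        for p in m.pulses:
            assert 60 <= p.time <= 480
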