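import numpy as np
import pytest

from migshuttle import (
    ReporterParams,
    initial_response_kernel,
    make_schedule,
    observe_traces,
    preset,
    simulate_reporter,
    simulate_traces,
)


@pytest.fixture(scope="module")
def schedule():
    return make_schedule()


def flat_config(**kwargs):
    base = preset("wt", "glucose", n_cells=10, seed=3).with_(
        initial_amplitude=0.0,
        pulse_rate=0.0,
        plateau_level=0.05,
        noise_sd=0.0,
    )
    return base.with_(**kwargs)


def test_kernel_peaks_at_t_peak_with_unit_maximum():
    t = np.linspace(0, 600, 6001)
    k = initial_response_kernel(t, 30.0, 60.0)
    assert k.max() == pytest.approx(1.0, abs=1e-6)
    assert t[np.argmax(k)] == pytest.approx(30.0, abs=0.2)
    assert k[0] == 0.0
    assert k[-1] < 1e-3  # decayed


def test_degenerate_config_yields_flat_traces(schedule):
    traces = simulate_traces(flat_config(), schedule)
    for tr in traces:
        assert np.allclose(tr.true_index, 0.05)
        assert tr.pulse_times.size == 0


def test_fixed_seed_is_bit_reproducible(schedule):
    cfg = preset("wt", "glucose", n_cells=6, seed=11)
    a = simulate_traces(cfg, schedule)
    b = simulate_traces(cfg, schedule)
    for ta, tb in zip(a, b):
        assert np.array_equal(ta.true_index, tb.true_index)
        assert np.array_equal(ta.pulse_times, tb.pulse_times)
        assert np.array_equal(ta.true_reporter, tb.true_reporter)
    obs_a = observe_traces(a, cfg, schedule)
    obs_b = observe_traces(b, cfg, schedule)
    assert np.array_equal(obs_a[0].loc_index, obs_b[0].loc_index)


def test_pre_shift_index_is_basal(schedule):
    cfg = preset("wt", "glucose", n_cells=5, seed=2)
    for tr in simulate_traces(cfg, schedule):
        assert np.allclose(tr.true_index[tr.times < 0], cfg.basal_level)


def test_pulse_times_restricted_to_adapted_phase(schedule):
    cfg = preset("wt", "glucose", n_cells=40, seed=7)
    for tr in simulate_traces(cfg, schedule):
        if tr.pulse_times.size:
            assert tr.pulse_times.min() >= cfg.pulse_start
            assert tr.pulse_times.max() <= schedule.times[-1]
            assert np.all(np.diff(tr.pulse_times) >= 1.5 * cfg.pulse_width - 1e-9)


def test_realized_pulse_count_matches_rate(schedule):
    """Stationary pulse process: E[count in 240-480] = 2/h * 4 h = 8."""
    cfg = preset("wt", "glucose", n_cells=200, seed=19).with_(pulse_rate=2.0)
    counts = []
    for tr in simulate_traces(cfg, schedule):
        counts.append(np.sum((tr.pulse_times >= 240) & (tr.pulse_times <= 480)))
    counts = np.asarray(counts, dtype=float)
    se = counts.std(ddof=1) / np.sqrt(counts.size)
    assert abs(counts.mean() - 8.0) < 3 * se


def test_pulse_height_mean_matches_config(schedule):
    cfg = preset("wt", "glucose", n_cells=300, seed=23)
    heights = np.concatenate(
        [tr.pulse_heights for tr in simulate_traces(cfg, schedule)]
    )
    se = heights.std(ddof=1) / np.sqrt(heights.size)
    assert abs(heights.mean() - cfg.pulse_height_mean) < 3 * se


def test_responder_fraction_zero_silences_all_cells(schedule):
    cfg = preset("wt", "glucose", n_cells=10, seed=3).with_(
        responder_fraction=0.0, noise_sd=0.0, plateau_level=0.05
    )
    for tr in simulate_traces(cfg, schedule):
        assert np.allclose(tr.true_index, cfg.basal_level)


def test_toxicity_threshold_kills_high_expressers(schedule):
    cfg = preset("+HXK2", "mannose", n_cells=120, seed=13)
    traces = simulate_traces(cfg, schedule)
    dead = [tr for tr in traces if not tr.alive.all()]
    live = [tr for tr in traces if tr.alive.all()]
    assert dead and live
    assert min(tr.expr_marker_level for tr in dead) > max(
        0.0, cfg.death_expr_threshold
    )
    assert max(tr.expr_marker_level for tr in live) <= cfg.death_expr_threshold
    for tr in dead:
        # Frozen after death: constant index, no further pulses.
        frozen = tr.true_index[~tr.alive]
        assert np.allclose(frozen, frozen[0])
        t_death = tr.times[tr.alive].max()
        assert np.all(tr.pulse_times <= t_death)


class TestReporter:
    def test_never_derepressed_zero_leak_is_flat_zero(self, schedule):
        params = ReporterParams(repressed_rate=0.0, derepression_onset=None)
        assert np.allclose(simulate_reporter(params, schedule), 0.0)

    def test_maturation_delays_first_fluorescence(self, schedule):
        params = ReporterParams(
            repressed_rate=0.0,
            derepressed_rate=1.0,
            maturation_delay=30.0,
            derepression_onset=60.0,
        )
        out = simulate_reporter(params, schedule)
        assert np.all(out[schedule.times <= 90.0] == 0.0)
        assert np.all(out[schedule.times > 90.0] > 0.0)

    def test_steady_state_is_rate_over_degradation(self, schedule):
        params = ReporterParams(
            repressed_rate=2.0, degradation_rate=0.05, derepression_onset=None
        )
        out = simulate_reporter(params, schedule)
        assert out[-1] == pytest.approx(2.0 / 0.05, rel=1e-6)

    def test_death_freezes_reporter(self, schedule):
        params = ReporterParams(derepressed_rate=2.0, derepression_onset=0.0)
        out = simulate_reporter(params, schedule, t_death=120.0)
        after = out[schedule.times > 120.0]
        assert np.allclose(after, after[0])
        assert np.all(np.diff(out[schedule.times <= 120.0]) >= -1e-12)
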