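import numpy as np
import pandas as pd
import pytest

from migshuttle import (
    dose_response,
    fold_change,
    make_schedule,
    observe_traces,
    preset,
    simulate_traces,
    summarize_group,
    viability_filter,
)
from migshuttle.metrics import long_term_mean
from migshuttle.stats import benjamini_hochberg


class TestSummarizeGroup:
    def test_hand_computed_ci(self):
        """{1,2,3}: mean 2, sd 1, CI = 2 +/- t(0.975, 2) / sqrt(3)."""
        s = summarize_group([1.0, 2.0, 3.0])
        assert s.mean == 2.0 and s.sd == pytest.approx(1.0)
        half = 4.302652 * 1.0 / np.sqrt(3)
        assert s.ci95[0] == pytest.approx(2 - half, abs=1e-4)
        assert s.ci95[1] == pytest.approx(2 + half, abs=1e-4)
        assert np.isnan(s.p_vs_reference)

    def test_identical_constant_groups_not_significant(self):
        s = summarize_group([1, 1, 1, 1], [1, 1, 1, 1])
        assert not s.significant

    def test_single_value_has_no_ci(self):
        s = summarize_group([2.0])
        assert np.isnan(s.sd) and np.isnan(s.ci95[0])

    def test_welch_power_on_separated_generator_groups(self):
        """Mean difference >= 5 within-group SDs -> essentially always detected."""
        schedule = make_schedule()
        base = preset("wt", "glucose", n_cells=100, seed=0).with_(
            initial_amplitude=0.0, pulse_rate=0.0, noise_sd=0.05
        )
        detected = 0
        n_reps = 40
        for rep in range(n_reps):
            a_cfg = base.with_(seed=5000 + rep, plateau_level=0.05)
            # per-cell mean_long SE ~ 0.0072; shift the plateau by 5x that
            b_cfg = base.with_(seed=6000 + rep, plateau_level=0.05 + 0.036)
            a = [
                long_term_mean(t)
                for t in observe_traces(simulate_traces(a_cfg, schedule), a_cfg, schedule)
            ]
            b = [
                long_term_mean(t)
                for t in observe_traces(simulate_traces(b_cfg, schedule), b_cfg, schedule)
            ]
            if summarize_group(a, b).significant:
                detected += 1
        assert detected == n_reps

    def test_permutation_test_agrees_on_obvious_difference(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        b = rng.normal(3, 1, 40)
        s = summarize_group(a, b, test="permutation", n_permutations=500, rng=rng)
        assert s.significant


class TestFoldChange:
    def test_identity(self):
        assert fold_change(5.0, 5.0) == (1.0, "ratio")

    def test_eightfold(self):
        assert fold_change(8.0, 1.0) == (8.0, "ratio")

    def test_nonpositive_reference_reports_difference(self):
        value, kind = fold_change(3.0, 0.0)
        assert kind == "difference" and value == 3.0


class TestDoseResponse:
    def test_null_correlation_near_zero(self):
        rng = np.random.default_rng(1)
        expr = rng.lognormal(6, 0.5, 500)
        loc = rng.normal(0.2, 0.05, 500)
        points, rho, _ = dose_response(expr, loc)
        assert abs(rho) < 0.1
        assert len(points) >= 2

    def test_saturating_generator_relationship(self):
        """Kinase-rescue presets: localization rises with expression level."""
        schedule = make_schedule()
        cfg = preset("+HXK2", "fructose", n_cells=300, seed=3)
        traces = observe_traces(simulate_traces(cfg, schedule), cfg, schedule)
        expr = [t.expr_marker_level for t in traces]
        loc = [long_term_mean(t) for t in traces]
        points, rho, p = dose_response(expr, loc)
        # The saturating rescue term contributes ~0.054 index units of
        # between-cell spread vs ~0.037 from pulse/rate jitter and noise,
        # putting the expected rank correlation near 0.75.
        assert rho > 0.65 and p < 1e-6
        # binned means are monotone overall (first vs last bin)
        assert points[-1].mean_long_localization > points[0].mean_long_localization

    def test_too_few_cells_for_bins(self):
        rng = np.random.default_rng(2)
        points, rho, _ = dose_response(rng.uniform(0, 1, 8), rng.uniform(0, 1, 8),
                                       min_bin_n=10)
        assert points == []

    def test_tiny_input_rejected(self):
        with pytest.raises(ValueError):
            dose_response([1.0, 2.0], [0.1, 0.2])


class TestViabilityFilter:
    def frame(self, levels, alive):
        return pd.DataFrame({
            "expr_marker_level": levels,
            "alive": alive,
            "mean_long": np.linspace(0, 1, len(levels)),
        })

    def test_nothing_excluded_without_deaths(self):
        df = self.frame([100, 200, 300], [True, True, True])
        out, n, thr = viability_filter(df)
        assert n == 0 and len(out) == 3 and np.isnan(thr)

    def test_threshold_recovered_from_generator_deaths(self):
        """Cells die above X = 1000; the recovered midpoint is within 20%."""
        schedule = make_schedule()
        cfg = preset("+HXK2", "mannose", n_cells=150, seed=4)
        traces = observe_traces(simulate_traces(cfg, schedule), cfg, schedule)
        df = pd.DataFrame({
            "expr_marker_level": [t.expr_marker_level for t in traces],
            "alive": [t.is_alive for t in traces],
        })
        out, n_dead, thr = viability_filter(df)
        assert n_dead > 0
        assert out["alive"].all()
        assert abs(thr - cfg.death_expr_threshold) < 0.2 * cfg.death_expr_threshold

    def test_all_dead_yields_empty(self):
        df = self.frame([2000, 2500], [False, False])
        out, n, _ = viability_filter(df)
        assert len(out) == 0 and n == 2

    def test_explicit_threshold(self):
        df = self.frame([100, 900, 2000], [True, True, True])
        out, n, _ = viability_filter(df, expr_threshold=1000)
        assert n == 1 and len(out) == 2


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p) and np.all(adj <= 1.0)
    assert np.all(np.diff(adj[np.argsort(p)]) >= 0)
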