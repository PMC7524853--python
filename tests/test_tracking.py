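import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migshuttle import (
    CellRegion,
    assemble_traces,
    build_tracks,
    link_frames,
    measure_stack,
)
from migshuttle.tracking import spans_shift


def square_region(r, c, label, size=4, frame=0):
    rr, cc = np.meshgrid(np.arange(r, r + size), np.arange(c, c + size), indexing="ij")
    return CellRegion(frame_index=frame, label=label, rows=rr.ravel(), cols=cc.ravel())


def grid_frame(positions, frame=0):
    return [square_region(r, c, i + 1, frame=frame) for i, (r, c) in enumerate(positions)]


class TestLinkFrames:
    def test_identity_assignment(self):
        a = grid_frame([(0, 0), (20, 20), (40, 0)])
        pairs, ua, ub = link_frames(a, a, max_displacement=5)
        assert pairs == [(0, 0), (1, 1), (2, 2)]
        assert ua == [] and ub == []

    def test_uniform_drift_matched(self):
        a = grid_frame([(0, 0), (20, 20), (40, 0), (0, 40)])
        b = grid_frame([(r + 3, c + 2) for r, c in [(0, 0), (20, 20), (40, 0), (0, 40)]])
        pairs, ua, ub = link_frames(a, b, max_displacement=6)
        assert pairs == [(i, i) for i in range(4)]

    def test_disappearance_leaves_others_untouched(self):
        a = grid_frame([(0, 0), (20, 20), (40, 0)])
        b = grid_frame([(0, 0), (40, 0)])
        pairs, ua, ub = link_frames(a, b, max_displacement=5)
        assert (0, 0) in pairs and (2, 1) in pairs
        assert ua == [1] and ub == []

    def test_gate_rejects_long_jumps(self):
        a = grid_frame([(0, 0)])
        b = grid_frame([(30, 30)])
        pairs, ua, ub = link_frames(a, b, max_displacement=10)
        assert pairs == [] and ua == [0] and ub == [0]

    def test_empty_inputs(self):
        assert link_frames([], [], 5) == ([], [], [])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 5),
        m=st.integers(1, 5),
        seed=st.integers(0, 10_000),
    )
    def test_matching_is_globally_optimal(self, n, m, seed):
        """Assignment cost equals the exhaustive-permutation minimum."""
        rng = np.random.default_rng(seed)
        pa = rng.uniform(0, 60, size=(n, 2))
        pb = rng.uniform(0, 60, size=(m, 2))
        a = [square_region(int(r), int(c), i + 1) for i, (r, c) in enumerate(pa)]
        b = [square_region(int(r), int(c), i + 1) for i, (r, c) in enumerate(pb)]
        cost = np.array(
            [[np.hypot(*(np.subtract(x.centroid, y.centroid))) for y in b] for x in a]
        )
        gate = 80.0  # permissive: every pair allowed
        pairs, _, _ = link_frames(a, b, max_displacement=gate)
        got = sum(cost[i, j] for i, j in pairs)
        k = min(n, m)
        best = min(
            sum(cost[i, j] for i, j in zip(rows, perm))
            for rows in itertools.combinations(range(n), k)
            for perm in itertools.permutations(range(m), k)
        )
        assert got == pytest.approx(best, abs=1e-9)


class TestBuildTracks:
    def test_single_cell_spans_movie(self):
        frames = [[square_region(10, 10, 1, frame=f)] for f in range(6)]
        tracks = build_tracks(frames, max_displacement=5)
        assert len(tracks) == 1
        assert tracks[0].frames == list(range(6))
        assert tracks[0].gap_count == 0

    def test_gap_bridged_within_max_gap(self):
        frames = [[square_region(10, 10, 1, frame=f)] for f in range(6)]
        frames[3] = []  # one dropped detection
        tracks = build_tracks(frames, max_displacement=5, max_gap=1)
        assert len(tracks) == 1
        assert tracks[0].frames == [0, 1, 2, 4, 5]
        assert tracks[0].gap_count == 1

    def test_long_gap_splits_track(self):
        frames = [[square_region(10, 10, 1, frame=f)] for f in range(8)]
        frames[3] = frames[4] = []
        tracks = build_tracks(frames, max_displacement=5, max_gap=1)
        assert len(tracks) == 2

    def test_births_excluded_by_min_length(self):
        frames = [[square_region(10, 10, 1, frame=f)] for f in range(8)]
        for f in range(5, 8):  # a cell appearing mid-movie
            frames[f].append(square_region(40, 40, 2, frame=f))
        tracks = build_tracks(frames, max_displacement=5, min_length=8)
        assert len(tracks) == 1 and len(tracks[0]) == 8

    def test_region_in_at_most_one_track(self, rendered_movie):
        stack = rendered_movie["stack"]
        table, regions = measure_stack(stack)
        frames = [regions.get(f, []) for f in range(stack.n_frames)]
        tracks = build_tracks(frames, max_displacement=12)
        seen = set()
        for t in tracks:
            for entry in t.entries:
                assert entry not in seen
                seen.add(entry)
        assert len(tracks) <= max(len(fr) for fr in frames) + 5

    def test_spans_shift_filter(self):
        times = np.array([-30.0, 0.0, 100.0, 250.0])
        full = build_tracks([[square_region(5, 5, 1, frame=f)] for f in range(4)], 5)[0]
        assert spans_shift(full, times)
        late = build_tracks(
            [[], [square_region(5, 5, 1, frame=1)], [square_region(5, 5, 1, frame=2)],
             [square_region(5, 5, 1, frame=3)]], 5
        )[0]
        assert not spans_shift(late, times)


class TestAssembleTraces:
    def make_measurements(self, values):
        rows = [
            {
                "frame": f,
                "time_min": float(f),
                "cell_label": 1,
                "median_nuc": 1.0,
                "median_total": 1.0,
                "loc_index": v,
                "reporter": 2.0,
                "expr_marker": np.nan,
                "valid": True,
            }
            for f, v in enumerate(values)
        ]
        return pd.DataFrame(rows)

    def test_constant_index_trace(self):
        frames = [[square_region(10, 10, 1, frame=f)] for f in range(4)]
        tracks = build_tracks(frames, 5)
        traces = assemble_traces(
            tracks, self.make_measurements([0.5] * 4), np.arange(4.0)
        )
        assert len(traces) == 1
        assert np.allclose(traces[0].loc_index, 0.5)

    def test_invalid_measurements_become_missing(self):
        frames = [[square_region(10, 10, 1, frame=f)] for f in range(4)]
        tracks = build_tracks(frames, 5)
        meas = self.make_measurements([0.5, 0.6, 0.7, 0.8])
        meas.loc[2, "valid"] = False
        traces = assemble_traces(tracks, meas, np.arange(4.0))
        assert np.isnan(traces[0].loc_index[2])
        assert np.isfinite(traces[0].loc_index).sum() == 3

    def test_movie_traces_match_ground_truth(self, rendered_movie):
        """Assembled index traces track the generator truth (RMSE < 0.1)."""
        stack = rendered_movie["stack"]
        truths = rendered_movie["truths"]
        table, regions = measure_stack(stack)
        frames = [regions.get(f, []) for f in range(stack.n_frames)]
        tracks = build_tracks(frames, max_displacement=12)
        traces = assemble_traces(tracks, table, stack.times)
        assert len(traces) == len(truths)
        for tr in traces:
            rmse = min(
                np.sqrt(np.nanmean((tr.loc_index - t.true_index) ** 2))
                for t in truths
            )
            assert rmse < 0.1
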