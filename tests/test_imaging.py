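import numpy as np
import pytest

from migshuttle import (
    CellRegion,
    divide_brightfield,
    identify_nucleus,
    measure_cell,
    measure_stack,
    regions_from_labels,
    segment_cells,
)
from migshuttle.imaging import SegmentationParams
from migshuttle.stack import FrameStack


def disk_region(radius=10, center=(20, 20), label=1):
    yy, xx = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
    d = np.hypot(yy - center[0], xx - center[1])
    rr, cc = np.nonzero(d <= radius)
    return CellRegion(frame_index=0, label=label, rows=rr, cols=cc), d


class TestDivideBrightfield:
    def test_identical_planes_give_unity(self):
        img = np.random.default_rng(0).uniform(50, 200, (32, 32))
        out = divide_brightfield(img, img)
        assert np.allclose(out, 1.0, atol=1e-5)

    def test_doubled_plane_gives_two(self):
        img = np.full((16, 16), 100.0)
        assert np.allclose(divide_brightfield(2 * img, img), 2.0, atol=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            divide_brightfield(np.ones((4, 4)), np.ones((5, 5)))

    def test_multiplicative_gradient_cancels(self):
        rng = np.random.default_rng(1)
        above = rng.uniform(80, 250, (64, 64))
        below = rng.uniform(80, 250, (64, 64))
        yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        gradient = 1.0 + (yy + xx) / 126.0  # 1x -> 2x corner to corner
        plain = divide_brightfield(above, below, epsilon=1e-9)
        graded = divide_brightfield(above * gradient, below * gradient, epsilon=1e-9)
        assert np.max(np.abs(plain - graded)) < 1e-6


class TestMeasureCell:
    def test_uniform_gfp_has_zero_index(self):
        region, _ = disk_region()
        identify_nucleus(region, None, gfp=np.full((40, 40), 100.0))
        m = measure_cell(region, np.full((40, 40), 100.0))
        assert m.localization_index == 0.0

    def test_nuclear_enrichment_hand_case(self):
        """Nucleus at 300 AU, cytoplasm at 100 AU -> index exactly 2.0."""
        region, d = disk_region()
        gfp = np.full((40, 40), 100.0)
        gfp[d <= 4] = 300.0
        nrr, ncc = np.nonzero(d <= 4)
        region.set_nucleus(nrr, ncc)
        m = measure_cell(region, gfp)
        assert m.median_total == 100.0
        assert m.median_nuc == 300.0
        assert m.localization_index == 2.0

    def test_nuclear_export_hand_case(self):
        region, d = disk_region()
        gfp = np.full((40, 40), 100.0)
        gfp[d <= 4] = 50.0
        nrr, ncc = np.nonzero(d <= 4)
        region.set_nucleus(nrr, ncc)
        assert measure_cell(region, gfp).localization_index == -0.5

    def test_index_invariant_under_global_scaling(self):
        rng = np.random.default_rng(4)
        region, d = disk_region()
        gfp = rng.uniform(10, 500, (40, 40))
        nrr, ncc = np.nonzero(d <= 4)
        region.set_nucleus(nrr, ncc)
        base = measure_cell(region, gfp).localization_index
        for scale in (0.01, 3.7, 1200.0):
            scaled = measure_cell(region, gfp * scale).localization_index
            assert scaled == pytest.approx(base, abs=1e-12)

    def test_nonpositive_total_flags_invalid(self):
        region, d = disk_region()
        nrr, ncc = np.nonzero(d <= 4)
        region.set_nucleus(nrr, ncc)
        m = measure_cell(region, np.zeros((40, 40)))
        assert not m.valid


class TestIdentifyNucleus:
    def test_marker_disk_recovered_exactly(self):
        region, d = disk_region()
        marker = np.zeros((40, 40))
        marker[d <= 3.5] = 1.0  # ~12% of the cell area
        identify_nucleus(region, marker)
        got = set(zip(region.nuc_rows.tolist(), region.nuc_cols.tolist()))
        rr, cc = np.nonzero(d <= 3.5)
        assert got == set(zip(rr.tolist(), cc.tolist()))

    def test_flat_marker_falls_back_to_fraction(self):
        region, _ = disk_region()
        identify_nucleus(
            region,
            np.full((40, 40), 7.0),
            fallback_fraction=0.12,
            gfp=np.full((40, 40), 100.0),
        )
        assert region.nuc_rows.size == round(0.12 * region.area)

    def test_fallback_patch_is_brightest_and_contiguous(self):
        region, d = disk_region()
        gfp = np.full((40, 40), 100.0)
        gfp[d <= 4] = 400.0  # bright nucleus off the flat marker path
        identify_nucleus(region, None, fallback_fraction=0.12, gfp=gfp)
        vals = gfp[region.nuc_rows, region.nuc_cols]
        # the selected patch has exactly the target size and stays on the
        # bright disk (which is larger than the target here)
        assert vals.size == round(0.12 * region.area)
        assert np.all(vals == 400.0)

    def test_invalid_fraction_rejected(self):
        region, _ = disk_region()
        with pytest.raises(ValueError):
            identify_nucleus(region, None, fallback_fraction=0.7)


class TestSegmentCells:
    def test_blank_frame_yields_no_regions(self):
        assert segment_cells(np.ones((128, 128))) == []
        rng = np.random.default_rng(0)
        noisy = 1.0 + rng.normal(0, 0.01, (128, 128))
        assert segment_cells(noisy) == []

    def test_small_object_filtered_by_min_area(self):
        img = np.ones((96, 96))
        yy, xx = np.meshgrid(np.arange(96), np.arange(96), indexing="ij")
        ring = np.exp(-0.5 * ((np.hypot(yy - 48, xx - 48) - 4) / 1.5) ** 2)
        img *= 1 + 0.5 * ring  # a cell far below min_area
        assert segment_cells(img, SegmentationParams(min_area=200)) == []

    def test_synthetic_frame_detection(self, rendered_movie):
        stack, labels = rendered_movie["stack"], rendered_movie["labels"]
        divided = divide_brightfield(
            stack.channel("bf_above")[0], stack.channel("bf_below")[0]
        )
        detected = segment_cells(divided)
        truth = regions_from_labels(labels[0])
        assert len(detected) >= len(truth) - 1
        det_sets = [set(zip(r.rows.tolist(), r.cols.tolist())) for r in detected]
        for t in truth:
            ts = set(zip(t.rows.tolist(), t.cols.tolist()))
            best = max(len(ts & ds) / len(ts | ds) for ds in det_sets)
            assert best >= 0.7


class TestMeasureStack:
    def test_blank_movie_gives_empty_table(self):
        channels = {
            name: np.ones((3, 64, 64), dtype=float) * (100.0 if name.startswith("bf") else 5.0)
            for name in ("bf_above", "bf_below", "gfp", "nuc_marker", "reporter")
        }
        stack = FrameStack(channels=channels, times=np.array([-30.0, 0.0, 5.0]))
        table, regions = measure_stack(stack)
        assert table.empty
        assert all(len(v) == 0 for v in regions.values())

    def test_sparse_expression_channel_bookkeeping(self, rendered_movie):
        stack = rendered_movie["stack"]
        labels = rendered_movie["labels"]
        nuclear = rendered_movie["nuclear_labels"]
        schedule = rendered_movie["schedule"]
        table, _ = measure_stack(stack, labels=labels, nuclear_labels=nuclear)
        sparse = schedule.sparse_frame_mask
        for f, grp in table.groupby("frame"):
            if sparse[f]:
                assert grp["expr_marker"].notna().all()
            else:
                assert grp["expr_marker"].isna().all()

    def test_ground_truth_coverage(self, rendered_movie):
        """>= 95% of (frame, true cell) pairs yield a measurement."""
        stack = rendered_movie["stack"]
        table, _ = measure_stack(stack)
        n_truth = rendered_movie["labels"].shape[0] * len(rendered_movie["truths"])
        assert len(table) >= 0.95 * n_truth
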