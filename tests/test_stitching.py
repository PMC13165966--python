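"""Tests for mosaicking: topology, ROIs, matching, voting, alignment,
cropping, blending, and the per-plane driver."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdefov.simulate import Hologram, simulate_hologram
from mdefov.stitching import (
    MatchSet,
    MosaicLayout,
    ShiftEstimate,
    XCorrMatcher,
    auto_crop,
    blend,
    build_topology,
    estimate_pair_shift,
    extract_overlap_rois,
    feather_weights,
    global_align,
    match_rois,
    stitch_plane,
)


def matchset_from_displacements(disps, confidences=None):
    disps = np.asarray(disps, dtype=float)
    pts_b = np.tile(np.array([50.0, 50.0]), (len(disps), 1))
    pts_a = pts_b + disps
    conf = np.ones(len(disps)) if confidences is None else confidences
    return MatchSet(pts_a, pts_b, conf, "test")


class TestBuildTopology:
    def test_1x1_no_pairs(self):
        assert build_topology([(0, 0)]) == []

    def test_2x2_four_pairs(self):
        pairs = build_topology([(0, 0), (0, 1), (1, 0), (1, 1)])
        assert len(pairs) == 4

    def test_7x7_pair_count_oracle(self):
        cells = list(itertools.product(range(7), range(7)))
        pairs = build_topology(cells)
        # counting oracle: enumerate 4-neighbour pairs by brute force
        brute = {
            frozenset((a, b))
            for a in cells
            for b in cells
            if abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1
        }
        assert len(pairs) == 84 == 7 * 6 * 2
        assert {frozenset(p) for p in pairs} == brute

    def test_missing_cell_listed(self):
        with pytest.raises(ValueError, match=r"\(1, 1\)"):
            build_topology([(0, 0), (0, 1), (1, 0)])

    def test_accepts_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({"grid_row": [0, 0], "grid_col": [0, 1]})
        assert len(build_topology(df)) == 1


class TestExtractOverlapRois:
    def test_full_scale_strip_and_margin(self):
        # 3552 px tiles at 57.7% overlap: strip 2050 px, margin ~355 px
        tile = np.empty((3552, 3552), dtype=np.uint8)
        ba, bb = extract_overlap_rois(tile, tile, "h", 0.577, margin=0.10)
        assert ba == (0, 3552, 3552 - (2050 + 355), 3552)
        assert bb == (0, 3552, 0, 2050 + 355)

    def test_zero_margin_is_exact_strip(self):
        tile = np.empty((256, 256))
        ba, bb = extract_overlap_rois(tile, tile, "h", 0.5, margin=0.0)
        assert ba == (0, 256, 128, 256)
        assert bb == (0, 256, 0, 128)

    def test_full_overlap_clamps_to_tile(self):
        tile = np.empty((128, 128))
        ba, bb = extract_overlap_rois(tile, tile, "h", 1.0, margin=0.10)
        assert ba == (0, 128, 0, 128) == bb

    def test_vertical_direction(self):
        tile = np.empty((200, 100))
        ba, bb = extract_overlap_rois(tile, tile, "v", 0.5, margin=0.0)
        assert ba == (100, 200, 0, 100)
        assert bb == (0, 100, 0, 100)

    def test_equal_roi_sizes(self):
        tile = np.empty((256, 256))
        for ov in (0.3, 0.55, 0.9):
            ba, bb = extract_overlap_rois(tile, tile, "h", ov)
            assert (ba[1] - ba[0], ba[3] - ba[2]) == (bb[1] - bb[0], bb[3] - bb[2])

    def test_too_small_overlap_errors(self):
        tile = np.empty((256, 256))
        with pytest.raises(ValueError, match="narrower"):
            extract_overlap_rois(tile, tile, "h", 0.02)


@pytest.fixture(scope="module")
def textured_roi():
    rng = np.random.default_rng(0)
    from scipy import ndimage

    return 1.0 + ndimage.gaussian_filter(rng.normal(size=(192, 160)), 2)


class TestMatchRois:

    def test_identical_rois_zero_displacement(self, textured_roi):
        m = match_rois(textured_roi, textured_roi)
        assert len(m) >= 1
        est = estimate_pair_shift(m)
        assert (est.dy, est.dx) == (0, 0)

    def test_rolled_roi_recovers_shift(self, textured_roi):
        # roiB's window sits at (+7, -3) relative to roiA's
        roi_b = np.roll(textured_roi, (-7, 3), axis=(0, 1))
        m = match_rois(textured_roi, roi_b)
        est = estimate_pair_shift(m)
        assert (est.dy, est.dx) == (7, -3)

    def test_independent_noise_low_confidence(self):
        from mdefov.stitching import DEFAULT_CONFIDENCE_THRESHOLD

        rng = np.random.default_rng(1)
        roi_a = rng.normal(size=(128, 128))
        roi_b = rng.normal(size=(128, 128))
        m = match_rois(roi_a, roi_b)
        assert len(m) >= 1
        assert np.all(m.confidences < DEFAULT_CONFIDENCE_THRESHOLD)

    def test_constant_roi_empty_matchset(self):
        m = match_rois(np.ones((64, 64)), np.ones((64, 64)))
        assert len(m) == 0

    def test_confidences_in_unit_interval(self, textured_roi):
        m = match_rois(textured_roi, np.roll(textured_roi, 5, axis=1))
        assert np.all((m.confidences >= 0) & (m.confidences <= 1))


class TestEstimatePairShift:
    def test_unanimous_votes(self):
        m = matchset_from_displacements([(1505, 37)] * 10)
        est = estimate_pair_shift(m, pair=("a", "b"))
        assert (est.dx, est.dy) == (37, 1505)
        assert est.votes == 10
        assert est.support_fraction == 1.0

    def test_outliers_discarded_brute_force(self):
        inliers = [(3, 5)] * 6
        outliers = [(40, -22), (-31, 18), (55, 60), (-47, -12)]
        m = matchset_from_displacements(inliers + outliers)
        est = estimate_pair_shift(m)
        # brute-force oracle: median (3,5); every outlier > radius; votes = 6
        assert (est.dy, est.dx) == (3, 5)
        assert est.votes == 6
        assert est.support_fraction == 0.6

    def test_singleton(self):
        m = matchset_from_displacements([(0, 0)])
        est = estimate_pair_shift(m)
        assert (est.dx, est.dy) == (0, 0)
        assert est.votes == 1

    def test_empty_matchset_errors(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_pair_shift(MatchSet.empty())

    def test_tie_broken_toward_median(self):
        # two 2-vote bins at (0, 4) and (0, 8); median ~ (0, 5) -> pick (0, 4)
        m = matchset_from_displacements([(0, 4), (0, 4), (0, 8), (0, 8), (0, 5)])
        est = estimate_pair_shift(m)
        assert (est.dy, est.dx) == (0, 4)

    def test_outlier_robustness_30_percent(self):
        rng = np.random.default_rng(0)
        true = np.array([12, -7])
        n_ok = 0
        for _ in range(100):
            inl = np.tile(true, (14, 1))
            out = rng.uniform(-80, 80, size=(6, 2)).round()
            m = matchset_from_displacements(np.vstack([inl, out]))
            est = estimate_pair_shift(m)
            n_ok += (est.dy, est.dx) == tuple(true)
        assert n_ok == 100


class TestGlobalAlign:
    def test_two_tile_chain(self):
        s = ShiftEstimate(dx=1500, dy=0, votes=5, support_fraction=1.0,
                          pair=((0, 0), (0, 1)))
        layout = global_align([s], (100, 100))
        assert layout.positions[(0, 0)] == (0, 0)
        assert layout.positions[(0, 1)] == (0, 1500)

    def test_consistent_loop_zero_residual(self):
        shifts = [
            ShiftEstimate(100, 0, 1, 1.0, ((0, 0), (0, 1))),
            ShiftEstimate(100, 0, 1, 1.0, ((1, 0), (1, 1))),
            ShiftEstimate(0, 90, 1, 1.0, ((0, 0), (1, 0))),
            ShiftEstimate(0, 90, 1, 1.0, ((0, 1), (1, 1))),
        ]
        layout = global_align(shifts, (128, 128))
        assert layout.positions == {
            (0, 0): (0, 0), (0, 1): (0, 100), (1, 0): (90, 0), (1, 1): (90, 100),
        }

    def test_perturbed_loop_least_squares_oracle(self):
        # one constraint off by +2: LS spreads the residual around the loop
        shifts = [
            ShiftEstimate(100, 0, 1, 1.0, ((0, 0), (0, 1))),
            ShiftEstimate(102, 0, 1, 1.0, ((1, 0), (1, 1))),
            ShiftEstimate(0, 0, 1, 1.0, ((0, 0), (1, 0))),
            ShiftEstimate(0, 0, 1, 1.0, ((0, 1), (1, 1))),
        ]
        layout = global_align(shifts, (128, 128))

        def objective(pos):
            return sum(
                (pos[b][1] - pos[a][1] - s.dx) ** 2
                + (pos[b][0] - pos[a][0] - s.dy) ** 2
                for s in shifts
                for a, b in [s.pair]
            )

        ours = objective(layout.positions)
        # brute-force integer oracle over a window around the solution
        best = min(
            objective({(0, 0): (0, 0), (0, 1): (0, x1), (1, 0): (0, x2),
                       (1, 1): (0, x3)})
            for x1 in range(98, 104)
            for x2 in range(-3, 4)
            for x3 in range(98, 105)
        )
        assert ours == best

    def test_disconnected_graph_errors(self):
        shifts = [
            ShiftEstimate(10, 0, 1, 1.0, ((0, 0), (0, 1))),
            ShiftEstimate(10, 0, 1, 1.0, ((5, 5), (5, 6))),
        ]
        with pytest.raises(ValueError, match="disconnected"):
            global_align(shifts, (64, 64))

    def test_canvas_contains_all_tiles(self):
        s = ShiftEstimate(dx=-40, dy=-30, votes=1, support_fraction=1.0,
                          pair=((0, 0), (0, 1)))
        layout = global_align([s], (64, 64))
        assert layout.offset == (30, 40)
        assert layout.canvas_shape == (94, 104)
        assert layout.coverage.max() == 2


class TestAutoCrop:
    def test_full_coverage_unchanged(self):
        canvas = np.arange(12.0).reshape(3, 4)
        cropped, bounds = auto_crop(canvas, np.ones((3, 4)))
        np.testing.assert_array_equal(cropped, canvas)
        assert bounds == (0, 3, 0, 4)

    def test_uncovered_left_band_removed(self):
        coverage = np.ones((20, 30))
        coverage[:, :10] = 0
        canvas = np.random.default_rng(0).normal(size=(20, 30))
        cropped, bounds = auto_crop(canvas, coverage)
        assert bounds == (0, 20, 10, 30)
        np.testing.assert_array_equal(cropped, canvas[:, 10:])

    def test_empty_coverage_errors(self):
        with pytest.raises(ValueError, match="empty"):
            auto_crop(np.zeros((4, 4)), np.zeros((4, 4)))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_on_small_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((7, 8)) < 0.7
        if not mask.any():
            mask[3, 4] = True
        _, (r0, r1, c0, c1) = auto_crop(np.zeros(mask.shape), mask.astype(int))
        area = (r1 - r0) * (c1 - c0)
        assert mask[r0:r1, c0:c1].all()
        # brute force all rectangles
        best = 0
        for a in range(7):
            for b in range(a + 1, 8):
                for c in range(8):
                    for d in range(c + 1, 9):
                        if mask[a:b, c:d].all():
                            best = max(best, (b - a) * (d - c))
        assert area == best


class TestBlend:
    def test_single_tile_bit_exact(self):
        rng = np.random.default_rng(0)
        tile = rng.normal(size=(32, 32)) ** 2
        layout = MosaicLayout.build({(0, 0): (0, 0)}, (32, 32))
        out = blend({(0, 0): tile}, layout)
        np.testing.assert_array_equal(out, tile)

    def test_constant_tiles_stay_constant(self):
        layout = MosaicLayout.build({(0, 0): (0, 0), (0, 1): (0, 16)}, (32, 32))
        tiles = {(0, 0): np.full((32, 32), 3.0), (0, 1): np.full((32, 32), 3.0)}
        out = blend(tiles, layout)
        np.testing.assert_allclose(out, 3.0)

    def test_worked_weighted_average_example(self):
        # overlap pixel with values 2 and 4, weights 1 and 3 -> 3.5 exactly
        layout = MosaicLayout.build({"a": (0, 0), "b": (0, 0)}, (1, 1))
        out = blend(
            {"a": np.array([[2.0]]), "b": np.array([[4.0]])},
            layout,
            weight_profile={"a": np.array([[1.0]]), "b": np.array([[3.0]])},
        )
        assert out[0, 0] == 3.5

    def test_equal_weights_give_plain_mean(self):
        layout = MosaicLayout.build({"a": (0, 0), "b": (0, 0)}, (1, 1))
        out = blend(
            {"a": np.array([[2.0]]), "b": np.array([[4.0]])},
            layout,
            weight_profile=lambda shape: np.ones(shape),
        )
        np.testing.assert_allclose(out, 3.0)

    def test_convex_combination_bound(self):
        rng = np.random.default_rng(3)
        layout = MosaicLayout.build({(0, 0): (0, 0), (0, 1): (0, 20)}, (48, 48))
        tiles = {
            (0, 0): rng.uniform(0, 1, (48, 48)),
            (0, 1): rng.uniform(0, 1, (48, 48)),
        }
        out = blend(tiles, layout)
        overlap = out[:, 20:48]
        lo = np.minimum(tiles[(0, 0)][:, 20:], tiles[(0, 1)][:, :28])
        hi = np.maximum(tiles[(0, 0)][:, 20:], tiles[(0, 1)][:, :28])
        assert np.all(overlap >= lo - 1e-12)
        assert np.all(overlap <= hi + 1e-12)

    def test_feather_weights_positive_and_plateau(self):
        w = feather_weights((64, 64), ramp=8)
        assert w.min() > 0
        assert w.max() == 1.0
        assert w[32, 32] == 1.0
        assert w[0, 32] < w[4, 32] < w[8, 32]

    def test_weight_validation(self):
        layout = MosaicLayout.build({(0, 0): (0, 0)}, (8, 8))
        with pytest.raises(ValueError, match="weight"):
            blend({(0, 0): np.ones((8, 8))}, layout,
                  weight_profile=np.zeros((8, 8)))


class TestStitchPlane:
    def test_single_tile_identity(self):
        rng = np.random.default_rng(0)
        h = Hologram(rng.uniform(0.5, 1.0, (64, 64)), pitch=2e-6, z=1e-3)
        stitched, info = stitch_plane([h])
        np.testing.assert_array_equal(stitched.amplitude, h.amplitude)
        assert info.crop_bounds == (0, 64, 0, 64)

    def test_exact_shift_recovery_and_full_field_oracle(
        self, scan, scene, optics_cfg, scan_grid
    ):
        holograms, _ = scan
        obj, _ = scene
        step = scan_grid.step_px
        ref = optics_cfg.reference_index
        plane = [h for h in holograms if h.z_index == ref]
        stitched, info = stitch_plane(plane)
        # every estimated pair shift equals the manifest ground truth
        for (a, b), est in info.shifts.items():
            expected = (0, step) if a[0] == b[0] else (step, 0)
            assert (est.dy, est.dx) == expected, f"pair {a}-{b}"
        assert info.fallback_pairs == []
        # stitched plane equals the directly simulated full-field hologram
        full = simulate_hologram(obj, optics_cfg, optics_cfg.z_ref)
        r0, r1, c0, c1 = info.crop_bounds
        rms = np.sqrt(
            np.mean((stitched.amplitude - full.amplitude[r0:r1, c0:c1]) ** 2)
        )
        assert rms < 1e-6

    def test_stack_planes_share_crop(self, stitched_stack):
        stitched, infos = stitched_stack
        bounds = {info.crop_bounds for info in infos}
        assert len(bounds) == 1
        shapes = {s.shape for s in stitched}
        assert len(shapes) == 1
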