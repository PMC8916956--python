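"""Phase correlation, edge mosaicing, cross-cycle registration and assembly."""

import numpy as np
import pytest

from mcmini import stitchreg, synthgen
from mcmini.stitchreg import ShiftEstimate
from conftest import bruteforce_ncc_shift, gauge_removed_errors


def _texture(shape=(64, 64), seed=0, smooth=2.0):
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.normal(0, 1, shape), smooth)


class TestPhaseCorrelate:
    def test_identity_window_gives_zero_shift(self):
        img = _texture(seed=1)
        est = stitchreg.phase_correlate(img, img, max_shift=10)
        assert (round(est.dy), round(est.dx)) == (0, 0)
        assert est.confidence > 3

    def test_known_circular_shift_recovered(self):
        img = _texture(seed=2)
        mov = np.roll(img, (5, -3), axis=(0, 1))
        est = stitchreg.phase_correlate(img, mov, max_shift=10)
        assert est.dy == pytest.approx(5, abs=0.5)
        assert est.dx == pytest.approx(-3, abs=0.5)

    def test_matches_bruteforce_ncc_oracle(self):
        """Integer part agrees with exhaustive normalized cross-correlation."""
        for seed in range(8):
            img = _texture(seed=seed)
            rng = np.random.default_rng(seed + 100)
            shift = tuple(rng.integers(-8, 9, 2))
            mov = np.roll(img, shift, axis=(0, 1)) + rng.normal(0, 0.05, img.shape)
            est = stitchreg.phase_correlate(img, mov, max_shift=10)
            oracle, _ = bruteforce_ncc_shift(img, mov, 10, circular=True)
            assert (round(est.dy), round(est.dx)) == oracle

    def test_agrees_with_skimage_reference_implementation(self):
        """Independent library cross-check: integer shifts match
        skimage.registration.phase_cross_correlation on rolled textures."""
        from skimage.registration import phase_cross_correlation

        for seed in range(6):
            img = _texture(seed=seed + 30)
            rng = np.random.default_rng(seed)
            shift = tuple(rng.integers(-8, 9, 2))
            mov = np.roll(img, shift, axis=(0, 1))
            est = stitchreg.phase_correlate(img, mov, max_shift=10)
            ref_shift, _, _ = phase_cross_correlation(img, mov, normalization="phase")
            # skimage reports the shift to apply to mov to match ref (= -ours)
            assert (round(est.dy), round(est.dx)) == (-int(ref_shift[0]), -int(ref_shift[1]))

    def test_constant_window_guarded(self):
        est = stitchreg.phase_correlate(np.ones((32, 32)), np.ones((32, 32)), 5)
        assert (est.dy, est.dx, est.confidence) == (0.0, 0.0, 0.0)

    def test_noise_pairs_fall_below_calibrated_threshold(self):
        """Independent noise windows rarely exceed the 99th-percentile
        noise-calibrated confidence threshold."""
        rng = np.random.default_rng(0)
        strips = [rng.uniform(0, 100, (24, 64)) for _ in range(4)]
        thr = stitchreg.calibrate_confidence_threshold(strips, n_pairs=100, seed=1)
        n_above = 0
        for i in range(50):
            a = rng.normal(0, 1, (24, 64))
            b = rng.normal(0, 1, (24, 64))
            if stitchreg.phase_correlate(a, b, 10).confidence >= thr:
                n_above += 1
        assert n_above <= 3  # ~1% expected by construction

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            stitchreg.phase_correlate(np.ones((8, 8)), np.ones((8, 8)), 2)


class TestAlignCycle1Edges:
    def test_2x2_grid_has_four_edges(self):
        truth = synthgen.make_tissue_truth(40, (300, 300), seed=1)
        acq = synthgen.render_tiles(truth, 2, 2, overlap=0.12, seed=0)
        edges = stitchreg.align_cycle1_edges(acq)
        assert len(edges) == 4

    def test_zero_jitter_gives_zero_corrections(self):
        truth = synthgen.make_tissue_truth(60, (512, 512), seed=7, rim_blur_px=0.0)
        acq = synthgen.render_tiles(truth, 3, 3, overlap=0.1, seed=0)
        for e in stitchreg.align_cycle1_edges(acq):
            assert abs(e.dy) <= 0.5 and abs(e.dx) <= 0.5

    def test_jittered_corrections_match_true_origin_differences(self, jittered_acquisition):
        """Confident edges recover the true relative offsets; unreliable edges
        (flagged by low confidence) are the solver's job to discard."""
        acq = jittered_acquisition
        edges = stitchreg.align_cycle1_edges(acq)
        confident = [e for e in edges if e.confidence >= 3.0]
        assert len(confident) >= 9  # most of the 12 edges are usable
        for e in confident:
            a, b = e.pair
            ta = acq.true_origins[(0, *a)]
            tb = acq.true_origins[(0, *b)]
            na = acq.nominal_origins[a]
            nb = acq.nominal_origins[b]
            true_dy = (tb[0] - ta[0]) - (nb[0] - na[0])
            true_dx = (tb[1] - ta[1]) - (nb[1] - na[1])
            assert e.dy == pytest.approx(true_dy, abs=1.0)
            assert e.dx == pytest.approx(true_dx, abs=1.0)


class TestSolveGlobalPositions:
    def test_chain_positions_are_cumulative_sums(self):
        """Exact edge corrections along a 1x3 chain propagate additively."""
        truth = synthgen.make_tissue_truth(30, (150, 420), seed=3)
        acq = synthgen.render_tiles(truth, 1, 3, overlap=0.15, seed=0)
        edges = [
            ShiftEstimate(1.0, 2.0, 99.0, pair=((0, 0), (0, 1))),
            ShiftEstimate(-1.0, 3.0, 99.0, pair=((0, 1), (0, 2))),
        ]
        pos = stitchreg.solve_global_positions(edges, acq, confidence_threshold=2.0)
        n = acq.nominal_origins
        assert pos.origin(0, 0, 1) == (n[(0, 1)][0] + 1.0, n[(0, 1)][1] + 2.0)
        assert pos.origin(0, 0, 2) == (n[(0, 2)][0] + 0.0, n[(0, 2)][1] + 5.0)

    def test_recovers_jittered_origins_within_one_pixel_rmse(self, jittered_acquisition):
        acq = jittered_acquisition
        edges = stitchreg.align_cycle1_edges(acq)
        pos = stitchreg.solve_global_positions(edges, acq, seed=0)
        errs = gauge_removed_errors(pos, acq.true_origins, 0, (3, 3))
        rmse = float(np.sqrt((errs**2).sum(axis=1).mean()))
        assert rmse < 1.0

    def test_all_low_confidence_falls_back_to_nominal(self):
        truth = synthgen.make_tissue_truth(20, (300, 300), seed=1)
        acq = synthgen.render_tiles(truth, 2, 2, seed=0)
        edges = [
            ShiftEstimate(9.0, 9.0, 0.5, pair=((0, 0), (0, 1))),
        ]
        with pytest.warns(UserWarning, match="nominal"):
            pos = stitchreg.solve_global_positions(edges, acq, confidence_threshold=2.0)
        for (r, c), o in acq.nominal_origins.items():
            assert pos.origin(0, r, c) == (float(o[0]), float(o[1]))
            assert pos.provenance[(0, r, c)] == "nominal-fallback"

    def test_corrupted_edge_removed_by_confidence_filter(self):
        """One grossly wrong low-confidence edge must not daisy-chain into the
        last tile's position: the filter drops it and the tile falls back to
        a nominal offset from its neighbour."""
        truth = synthgen.make_tissue_truth(30, (150, 560), seed=3)
        acq = synthgen.render_tiles(truth, 1, 4, overlap=0.15, seed=0)
        edges = [
            ShiftEstimate(0.0, 0.0, 50.0, pair=((0, 0), (0, 1))),
            ShiftEstimate(0.0, 0.0, 50.0, pair=((0, 1), (0, 2))),
            ShiftEstimate(40.0, 40.0, 1.1, pair=((0, 2), (0, 3))),  # corrupted
        ]
        pos = stitchreg.solve_global_positions(edges, acq, confidence_threshold=2.0)
        nominal = acq.nominal_origins[(0, 3)]
        err = np.subtract(pos.origin(0, 0, 3), nominal)
        assert np.abs(err).max() < 5  # not the 40-px corruption
        assert pos.provenance[(0, 0, 3)] == "nominal-fallback"

    def test_translation_gauge_invariance(self, jittered_acquisition):
        """Solved positions are defined up to a global translation: the
        gauge-removed errors are what matters and they are small."""
        acq = jittered_acquisition
        edges = stitchreg.align_cycle1_edges(acq)
        pos = stitchreg.solve_global_positions(edges, acq, seed=0)
        errs = gauge_removed_errors(pos, acq.true_origins, 0, (3, 3))
        assert np.abs(errs).max() < 1.0


class TestRegisterCycle:
    def test_global_offset_recovered_per_tile(self, jittered_acquisition):
        acq = jittered_acquisition
        edges = stitchreg.align_cycle1_edges(acq)
        pos1 = stitchreg.solve_global_positions(edges, acq, seed=0)
        pos = stitchreg.register_cycle(acq, 1, pos1)
        gauge = np.array(
            [
                np.subtract(pos1.origin(0, r, c), acq.true_origins[(0, r, c)])
                for r in range(3)
                for c in range(3)
            ]
        ).mean(axis=0)
        for r in range(3):
            for c in range(3):
                err = np.subtract(pos.origin(1, r, c), acq.true_origins[(1, r, c)]) - gauge
                assert np.abs(err).max() < 1.0

    def test_identical_cycles_give_zero_shift(self):
        truth = synthgen.make_tissue_truth(40, (300, 300), seed=5, rim_blur_px=0.0)
        acq = synthgen.render_tiles(truth, 2, 2, cycles=2, seed=0)
        edges = stitchreg.align_cycle1_edges(acq)
        pos1 = stitchreg.solve_global_positions(edges, acq, seed=0)
        pos = stitchreg.register_cycle(acq, 1, pos1)
        for (r, c), nom in acq.nominal_origins.items():
            shift = np.subtract(pos.origin(1, r, c), nom)
            assert np.abs(shift).max() <= 0.5

    def test_blank_tile_uses_median_fallback_and_flag(self):
        truth = synthgen.make_tissue_truth(40, (300, 300), seed=5)
        acq = synthgen.render_tiles(truth, 2, 2, cycles=2, cycle_offset=(3, 3), seed=0)
        blank = acq.tile_at(1, 1, 1)
        blank.data[:] = 0
        edges = stitchreg.align_cycle1_edges(acq)
        pos1 = stitchreg.solve_global_positions(edges, acq, seed=0)
        pos = stitchreg.register_cycle(acq, 1, pos1)
        assert pos.provenance[(1, 1, 1)] == "registered-fallback"
        # fallback = nominal + median confident shift ≈ the true (3,3) offset
        err = np.subtract(pos.origin(1, 1, 1), acq.true_origins[(1, 1, 1)])
        assert np.abs(err).max() <= 1.0


class TestAssembleMosaic:
    def test_single_tile_mosaic_is_the_tile(self):
        truth = synthgen.make_tissue_truth(20, (128, 128), seed=0)
        acq = synthgen.render_tiles(truth, 1, 1, seed=0)
        pos = stitchreg.TilePositionSet({(0, 0, 0): (0.0, 0.0)}, {(0, 0, 0): "nominal"})
        mosaic = stitchreg.assemble_mosaic(acq, pos, "last-write-wins")
        np.testing.assert_array_equal(mosaic.data, acq.tiles[0].data)

    def test_zero_jitter_exact_reassembly(self):
        truth = synthgen.make_tissue_truth(60, (512, 512), seed=7, rim_blur_px=0.0)
        acq = synthgen.render_tiles(truth, 3, 3, overlap=0.1, seed=1)
        mosaic, _ = stitchreg.stitch_acquisition(acq)
        H, W = truth.height, truth.width
        np.testing.assert_array_equal(mosaic.data[:, :H, :W], truth.raster)

    def test_jittered_mosaic_close_to_truth(self, jittered_acquisition):
        acq = jittered_acquisition
        mosaic, pos = stitchreg.stitch_acquisition(acq, seed=0)
        truth = acq.truth
        # truth pixel t lands on the canvas at t + gauge - canvas_origin
        gauge = np.array(
            [
                np.subtract(pos.origin(0, r, c), acq.true_origins[(0, r, c)])
                for r in range(3)
                for c in range(3)
            ]
        ).mean(axis=0)
        y0 = min(int(round(v[0])) for v in pos.positions.values())
        x0 = min(int(round(v[1])) for v in pos.positions.values())
        sy = int(round(gauge[0])) - y0
        sx = int(round(gauge[1])) - x0
        H, W = truth.height - abs(sy) - 8, truth.width - abs(sx) - 8
        sl_m = (slice(max(0, sy), max(0, sy) + H), slice(max(0, sx), max(0, sx) + W))
        sl_t = (slice(max(0, -sy), max(0, -sy) + H), slice(max(0, -sx), max(0, -sx) + W))
        maes = []
        for name in truth.markers:  # match mosaic channels to truth by name
            plane = mosaic.channel(name)
            ti = truth.markers.index(name)
            maes.append(np.abs(plane[sl_m] - truth.raster[ti][sl_t]).mean())
        assert max(maes) < acq.noise_sd + 1.0

    def test_channel_order_and_names(self):
        truth = synthgen.make_tissue_truth(10, (256, 256), seed=0)
        acq = synthgen.render_tiles(truth, 2, 2, cycles=2, seed=0)
        mosaic, _ = stitchreg.stitch_acquisition(acq)
        assert mosaic.channel_names[0] == "DNA"
        assert "DNA_c2" in mosaic.channel_names
        assert len(mosaic.channel_names) == sum(len(c) for c in acq.cycle_channels)

    def test_pixel_budget_enforced(self):
        truth = synthgen.make_tissue_truth(10, (256, 256), seed=0)
        acq = synthgen.render_tiles(truth, 2, 2, seed=0)
        pos = stitchreg.TilePositionSet(
            {(0, t.grid_row, t.grid_col): tuple(map(float, t.nominal_origin)) for t in acq.tiles},
        )
        with pytest.raises(ValueError, match="budget"):
            stitchreg.assemble_mosaic(acq, pos, pixel_budget=1000)
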