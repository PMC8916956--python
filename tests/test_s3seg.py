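"""Seed detection, watershed nuclei, three cytoplasm methods, puncta, export."""

import numpy as np
import pytest
import tifffile
from scipy import ndimage

from mcmini import pixelclass, s3seg, synthgen
from mcmini.containers import LabelMask
from mcmini.s3seg import SeedSet
from conftest import object_f1, rasterize_disk


def _disk_image(centers, radius=6, shape=(96, 96), value=500.0):
    img = np.zeros(shape)
    for cy, cx in centers:
        img[rasterize_disk(*shape, cy, cx, radius)] = value
    return img


class TestDetectSeeds:
    def test_blank_map_gives_no_seeds(self):
        assert len(s3seg.detect_seeds(np.zeros((64, 64)), 12)) == 0

    def test_single_disk_single_seed_at_center(self):
        """Oracle: exhaustive maxima scan of the LoG-filtered map."""
        img = _disk_image([(40, 50)])
        pm = pixelclass.classical_probability_maps(img, 12)
        seeds = s3seg.detect_seeds(pm.center, 12)
        assert len(seeds) == 1
        resp = s3seg._log_response(pm.center, 12 / (2 * np.sqrt(2)))
        oracle = np.unravel_index(np.argmax(resp), resp.shape)
        assert tuple(seeds.coordinates[0]) == oracle
        assert abs(seeds.coordinates[0][0] - 40) <= 1
        assert abs(seeds.coordinates[0][1] - 50) <= 1

    def test_fifty_nuclei_matched_one_to_one(self):
        truth = synthgen.make_tissue_truth(50, (400, 400), seed=21, radius_range=(5, 8))
        pm = pixelclass.classical_probability_maps(truth.raster[0], 13)
        seeds = s3seg.detect_seeds(pm.center, 13)
        assert len(seeds) == 50
        taken = set()
        for c in truth.cells:
            d = np.hypot(
                seeds.coordinates[:, 0] - c.y, seeds.coordinates[:, 1] - c.x
            )
            i = int(d.argmin())
            assert d[i] <= c.radius and i not in taken
            taken.add(i)


class TestSegmentNuclei:
    def test_two_disks_recovered_with_high_iou(self):
        img = _disk_image([(30, 30), (60, 66)])
        pm = pixelclass.classical_probability_maps(img, 12)
        seeds = s3seg.detect_seeds(pm.center, 12)
        mask = s3seg.segment_nuclei(pm, seeds, img, "probability")
        assert mask.n_labels == 2
        for cy, cx in ((30, 30), (60, 66)):
            disk = rasterize_disk(96, 96, cy, cx, 6)
            lab = mask.labels[cy, cx]
            inter = (mask.labels[disk] == lab).sum()
            union = disk.sum() + (mask.labels == lab).sum() - inter
            assert inter / union >= 0.9

    def test_background_seed_removed_by_fp_filter(self):
        img = _disk_image([(30, 30)])
        pm = pixelclass.classical_probability_maps(img, 12)
        seeds = SeedSet(
            np.array([[30, 30], [70, 70]]), np.array([1.0, 0.5]), 4.0, 0.5
        )
        mask = s3seg.segment_nuclei(pm, seeds, img, "raw")
        assert mask.n_labels == 1
        assert mask.labels[70, 70] == 0

    def test_bit_identical_across_reruns(self, tissue_100):
        pm = pixelclass.classical_probability_maps(tissue_100.raster[0], 13)
        seeds = s3seg.detect_seeds(pm.center, 13)
        a = s3seg.segment_nuclei(pm, seeds, tissue_100.raster[0], "probability")
        b = s3seg.segment_nuclei(pm, seeds, tissue_100.raster[0], "probability")
        assert np.array_equal(a.labels, b.labels)

    def test_no_seeds_warns_and_returns_empty(self):
        pm = pixelclass.classical_probability_maps(np.zeros((32, 32)), 12)
        with pytest.warns(UserWarning, match="no seeds"):
            mask = s3seg.segment_nuclei(pm, s3seg.detect_seeds(pm.center, 12))
        assert mask.n_labels == 0

    def test_labels_renumbered_contiguously_by_scan_order(self):
        img = _disk_image([(70, 20), (20, 70)])
        pm = pixelclass.classical_probability_maps(img, 12)
        seeds = s3seg.detect_seeds(pm.center, 12)
        mask = s3seg.segment_nuclei(pm, seeds, img, "probability")
        # top-most region is label 1 regardless of seed order
        assert mask.labels[20, 70] == 1
        assert mask.labels[70, 20] == 2

    def test_quality_on_synthetic_tissue(self, tissue_100):
        rng = np.random.default_rng(0)
        noisy = tissue_100.raster[0] + rng.normal(0, 20, tissue_100.raster[0].shape).clip(0)
        pm = pixelclass.classical_probability_maps(noisy, 13)
        seeds = s3seg.detect_seeds(pm.center, 13)
        mask = s3seg.segment_nuclei(pm, seeds, noisy, "probability")
        assert object_f1(mask, tissue_100.cells, 0.5) >= 0.95


class TestCytoplasmMethods:
    @pytest.fixture()
    def nuclei(self):
        img = _disk_image([(40, 30), (40, 60)], radius=5)
        labels = np.zeros((96, 96), dtype=np.int32)
        labels[rasterize_disk(96, 96, 40, 30, 5)] = 1
        labels[rasterize_disk(96, 96, 40, 60, 5)] = 2
        return LabelMask(labels, "nucleus"), img

    def test_zero_ring_radius_gives_empty_cytoplasm(self, nuclei):
        mask, _ = nuclei
        assert s3seg.segment_cytoplasm_ring(mask, 0).n_labels == 0

    def test_annulus_area_matches_bruteforce_distance_scan(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[rasterize_disk(64, 64, 32, 32, 5)] = 1
        cyto = s3seg.segment_cytoplasm_ring(LabelMask(labels, "nucleus"), 3)
        dist = ndimage.distance_transform_edt(labels == 0)
        expected = ((dist > 0) & (dist <= 3) & (labels == 0)).sum()
        assert (cyto.labels == 1).sum() == expected

    def test_close_nuclei_rings_disjoint_and_nearest(self):
        """Rings of two nearby nuclei never overlap and each cytoplasm pixel
        is strictly nearer to its own nucleus (brute-force check)."""
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[rasterize_disk(64, 64, 32, 25.3, 4)] = 1
        labels[rasterize_disk(64, 64, 32, 37.8, 4)] = 2
        cyto = s3seg.segment_cytoplasm_ring(LabelMask(labels, "nucleus"), 5)
        d1 = ndimage.distance_transform_edt(labels != 1)
        d2 = ndimage.distance_transform_edt(labels != 2)
        for lab, own, other in ((1, d1, d2), (2, d2, d1)):
            pix = cyto.labels == lab
            assert np.all(own[pix] <= other[pix])
            assert np.all(own[pix] < other[pix] + 1e-9)

    def test_edt_equals_ring_under_all_bright_mask(self, nuclei):
        mask, _ = nuclei
        bright = np.full((96, 96), 100.0)
        ring = s3seg.segment_cytoplasm_ring(mask, 4)
        edt = s3seg.segment_cytoplasm_edt(mask, bright, 4)
        np.testing.assert_array_equal(ring.labels, edt.labels)

    def test_edt_dark_mask_gives_empty_cytoplasm(self, nuclei):
        mask, _ = nuclei
        with pytest.warns(UserWarning, match="empty"):
            cyto = s3seg.segment_cytoplasm_edt(mask, np.zeros((96, 96)), 4)
        assert cyto.n_labels == 0

    def test_edt_respects_half_tissue_mask(self, nuclei):
        mask, _ = nuclei
        chan = np.zeros((96, 96))
        chan[:, :48] = 100.0
        cyto = s3seg.segment_cytoplasm_edt(mask, chan, 4)
        assert np.all(cyto.labels[:, 48:] == 0)

    def test_gwdt_beta_zero_equals_edt(self, nuclei):
        mask, _ = nuclei
        bright = np.full((96, 96), 100.0)
        edt = s3seg.segment_cytoplasm_edt(mask, bright, 6)
        gw = s3seg.segment_cytoplasm_gwdt(mask, bright, alpha=1, beta=0, max_distance=6)
        np.testing.assert_array_equal(gw.labels, edt.labels)

    def test_gwdt_uniform_image_boundary_is_equidistant(self):
        """With uniform intensity the watershed boundary between two equal
        nuclei matches the brute-force nearest-nucleus partition within 1 px."""
        labels = np.zeros((64, 96), dtype=np.int32)
        labels[rasterize_disk(64, 96, 32, 30, 5)] = 1
        labels[rasterize_disk(64, 96, 32, 66, 5)] = 2
        raw = np.full((64, 96), 80.0)
        gw = s3seg.segment_cytoplasm_gwdt(
            LabelMask(labels, "nucleus"), raw, alpha=1, beta=1, max_distance=14
        )
        d1 = ndimage.distance_transform_edt(labels != 1)
        d2 = ndimage.distance_transform_edt(labels != 2)
        wrong = ((gw.labels == 1) & (d1 > d2 + 1.5)) | ((gw.labels == 2) & (d2 > d1 + 1.5))
        assert wrong.sum() == 0

    def test_gwdt_alpha_zero_boundary_follows_intensity_valley(self):
        """With alpha=0 the relief is inverted intensity, so the boundary
        between two bright cells sits in the dark separating valley."""
        raw = np.zeros((48, 96))
        raw[:, :44] = 200.0
        raw[:, 52:] = 200.0
        raw[:, 44:52] = 40.0  # valley off-center relative to the nuclei below
        labels = np.zeros((48, 96), dtype=np.int32)
        labels[rasterize_disk(48, 96, 24, 20, 5)] = 1
        labels[rasterize_disk(48, 96, 24, 70, 5)] = 2
        gw = s3seg.segment_cytoplasm_gwdt(
            LabelMask(labels, "nucleus"), raw, alpha=0, beta=1, max_distance=60
        )
        from skimage.segmentation import find_boundaries

        both = np.isin(gw.labels, (1, 2))
        boundary = find_boundaries(gw.labels, mode="inner") & both
        interior_median = np.median(raw[both & ~boundary])
        assert np.median(raw[boundary]) <= interior_median

    def test_partition_and_label_correspondence(self, tissue_100):
        pm = pixelclass.classical_probability_maps(tissue_100.raster[0], 13)
        seeds = s3seg.detect_seeds(pm.center, 13)
        nuc = s3seg.segment_nuclei(pm, seeds, tissue_100.raster[0], "probability")
        for cyto in (
            s3seg.segment_cytoplasm_ring(nuc, 3),
            s3seg.segment_cytoplasm_edt(nuc, tissue_100.raster[0], 3),
            s3seg.segment_cytoplasm_gwdt(nuc, tissue_100.raster[0], max_distance=3),
        ):
            overlap = (nuc.labels > 0) & (cyto.labels > 0)
            assert not overlap.any()  # nucleus ∩ cytoplasm = ∅
            assert cyto.label_set() <= nuc.label_set()
            cell = s3seg.combine_cell_mask(nuc, cyto)
            assert np.array_equal(
                cell.labels > 0, (nuc.labels > 0) | (cyto.labels > 0)
            )

    def test_invalid_gwdt_weights_rejected(self, nuclei):
        mask, img = nuclei
        with pytest.raises(ValueError):
            s3seg.segment_cytoplasm_gwdt(mask, img, alpha=0, beta=0)


class TestDetectPuncta:
    def test_blank_image_gives_no_spots(self):
        assert len(s3seg.detect_puncta(np.zeros((64, 64)))) == 0

    def test_planted_spots_recovered(self):
        img = np.zeros((100, 100))
        spots = [(10, 10), (10, 50), (30, 80), (50, 20), (60, 60), (80, 40), (90, 90)]
        for y, x in spots:
            img[y, x] = 100.0
        found = s3seg.detect_puncta(img, spot_sigma=1.5, relative_threshold=0.3)
        assert len(found) == 7
        for y, x in spots:
            d = np.abs(found.coordinates - [y, x]).sum(axis=1).min()
            assert d <= 1

    def test_higher_threshold_detects_subset(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (80, 80))
        for y, x, v in ((20, 20, 50), (40, 60, 20), (60, 30, 8)):
            img[y, x] += v
        low = s3seg.detect_puncta(img, 1.5, 0.1)
        high = s3seg.detect_puncta(img, 1.5, 0.5)
        low_set = {tuple(c) for c in low.coordinates}
        high_set = {tuple(c) for c in high.coordinates}
        assert high_set <= low_set

    def test_sigma_bound(self):
        with pytest.raises(ValueError):
            s3seg.detect_puncta(np.zeros((32, 32)), spot_sigma=0.2)


class TestExportMasks:
    def test_round_trip_bit_identical(self, tmp_path):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[rasterize_disk(40, 40, 20, 20, 5)] = 1
        raw = np.random.default_rng(0).uniform(0, 9, (40, 40))
        written = s3seg.export_masks({"nuclei": LabelMask(labels, "nucleus")}, raw, tmp_path)
        back = tifffile.imread(written["nuclei"])
        np.testing.assert_array_equal(back, labels.astype(np.uint32))
        assert back.dtype == np.uint32

    def test_outline_pixel_count_matches_boundary_scan(self, tmp_path):
        """Oracle: a label pixel is boundary iff one of its 4-neighbours is
        outside the label."""
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[rasterize_disk(40, 40, 20, 20, 5)] = 1
        expected = 0
        for y in range(40):
            for x in range(40):
                if labels[y, x] != 1:
                    continue
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    yy, xx = y + dy, x + dx
                    if not (0 <= yy < 40 and 0 <= xx < 40) or labels[yy, xx] != 1:
                        expected += 1
                        break
        s3seg.export_masks({"m": LabelMask(labels, "nucleus")}, np.zeros((40, 40)), tmp_path)
        overlay = tifffile.imread(tmp_path / "m_overlay.tif")
        assert overlay[0].sum() == expected

    def test_empty_mask_gives_zero_outline(self, tmp_path):
        s3seg.export_masks(
            {"e": LabelMask(np.zeros((16, 16), dtype=np.int32), "nucleus")},
            np.zeros((16, 16)),
            tmp_path,
        )
        assert tifffile.imread(tmp_path / "e_overlay.tif")[0].sum() == 0
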