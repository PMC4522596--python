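"""Segmentation, circularity and particle-analysis tests."""

import math

import numpy as np
import pytest
import skimage.draw

from granulekit.morphometry import (
    LabelImage,
    circularity,
    count_size_timeseries,
    detect_fusions,
    foci_to_cytoplasm_ratio,
    measure_objects,
    measure_table,
    segment_granules,
)
from granulekit.synthetic import GranuleFieldConfig, simulate_granule_field


class TestCircularityFormula:
    def test_analytic_disk_is_one(self):
        r = 7.3
        assert circularity(math.pi * r**2, 2 * math.pi * r) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("area, perimeter, expected", [
        (4.0, 8.0, math.pi / 4),            # unit square scaled: 4πs²/(4s)²
        (100.0, 202.0, 4 * math.pi * 100 / 202**2),  # 1 x 100 px bar, ~0.031
    ])
    def test_hand_computed_shapes(self, area, perimeter, expected):
        assert circularity(area, perimeter) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            circularity(0.0, 10.0)
        with pytest.raises(ValueError):
            circularity(10.0, 0.0)


class TestMeasureObjects:
    @pytest.mark.parametrize("radius", [20, 35])
    def test_rasterized_disk_circularity_converges(self, radius):
        img = np.zeros((120, 120))
        rr, cc = skimage.draw.disk((60, 60), radius)
        img[rr, cc] = 1
        labels = LabelImage(labels=img.astype(int))
        (obj,) = measure_objects(labels)
        assert obj.circularity == pytest.approx(1.0, abs=0.05)
        assert obj.centroid == (pytest.approx(60.0, abs=0.5), pytest.approx(60.0, abs=0.5))

    def test_elongation_decreases_circularity(self):
        # ellipses of equal area, increasing axis ratio
        circs = []
        for a, b in [(30, 30), (45, 20), (60, 15), (90, 10)]:
            img = np.zeros((220, 220), dtype=int)
            rr, cc = skimage.draw.ellipse(110, 110, b, a)
            img[rr, cc] = 1
            (obj,) = measure_objects(LabelImage(labels=img))
            circs.append(obj.circularity)
        assert all(x > y for x, y in zip(circs, circs[1:]))

    def test_pixel_size_scaling(self):
        img = np.zeros((60, 60), dtype=int)
        rr, cc = skimage.draw.disk((30, 30), 10)
        img[rr, cc] = 1
        (obj,) = measure_objects(LabelImage(labels=img, pixel_size=0.13))
        assert obj.area_um2 == pytest.approx(obj.area_px * 0.13**2)
        assert obj.perimeter_um == pytest.approx(obj.perimeter_px * 0.13)

    def test_shape_mismatch_rejected(self):
        labels = LabelImage(labels=np.zeros((10, 10), dtype=int))
        with pytest.raises(ValueError, match="shape"):
            measure_objects(labels, np.zeros((5, 5)))


class TestSegmentation:
    def test_blank_image_no_objects(self):
        seg = segment_granules(np.zeros((64, 64)), threshold_method="manual", manual_threshold=0.5)
        assert seg.n_objects == 0

    def test_two_disjoint_disks(self):
        img = np.zeros((80, 80))
        for center in ((20, 20), (60, 60)):
            rr, cc = skimage.draw.disk(center, 8)
            img[rr, cc] = 100
        seg = segment_granules(img)
        assert seg.n_objects == 2

    def test_manual_method_requires_threshold(self):
        with pytest.raises(ValueError, match="manual_threshold"):
            segment_granules(np.zeros((16, 16)), threshold_method="manual")

    def test_synthetic_field_count_and_centroids(self):
        # 12 well-separated disks at SNR 10 (granule-over-cytoplasm 500/50)
        cfg = GranuleFieldConfig(n_granules=12, noise_sd=50.0, seed=21)
        field = simulate_granule_field(cfg)
        seg = segment_granules(field.image, mask=field.cell_mask)
        assert seg.n_objects == 12
        got = {(round(o.centroid[0]), round(o.centroid[1])) for o in measure_objects(seg)}
        for _, row in field.truth.iterrows():
            nearest = min(np.hypot(r - row.center_row, c - row.center_col) for r, c in got)
            assert nearest <= 1.0

    def test_size_window_filters(self):
        img = np.zeros((80, 80))
        rr, cc = skimage.draw.disk((20, 20), 3)
        img[rr, cc] = 100
        rr, cc = skimage.draw.disk((60, 60), 12)
        img[rr, cc] = 100
        seg = segment_granules(img, min_area=100)
        assert seg.n_objects == 1

    def test_summed_areas_equal_threshold_foreground(self):
        field = simulate_granule_field(GranuleFieldConfig(n_granules=7, seed=4, noise_sd=0.0))
        thr = 500.0  # between cytoplasm (300) and granule (800)
        seg = segment_granules(field.image, threshold_method="manual", manual_threshold=thr)
        total = sum(o.area_px for o in measure_objects(seg))
        assert total == np.count_nonzero(field.image > thr)


class TestFociToCytoplasmRatio:
    def _masks(self):
        cell = np.zeros((40, 40), dtype=bool)
        cell[5:35, 5:35] = True
        foci = np.zeros_like(cell)
        foci[15:20, 15:20] = True
        return cell, foci

    def test_uniform_cell_ratio_one(self):
        cell, foci = self._masks()
        assert foci_to_cytoplasm_ratio(np.full((40, 40), 77.0), cell, foci) == pytest.approx(1.0)

    def test_hand_computed_ratios(self):
        cell, foci = self._masks()
        img = np.where(foci, 200.0, 100.0)
        assert foci_to_cytoplasm_ratio(img, cell, foci, background_level=0.0) == pytest.approx(2.0)
        assert foci_to_cytoplasm_ratio(img, cell, foci, background_level=50.0) == pytest.approx(3.0)

    def test_gain_invariance_with_scaled_background(self):
        cell, foci = self._masks()
        img = np.where(foci, 200.0, 100.0)
        base = foci_to_cytoplasm_ratio(img, cell, foci, background_level=50.0)
        scaled = foci_to_cytoplasm_ratio(3.7 * img, cell, foci, background_level=3.7 * 50.0)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_errors(self):
        cell, foci = self._masks()
        img = np.full((40, 40), 100.0)
        with pytest.raises(ValueError, match="within the cell"):
            foci_to_cytoplasm_ratio(img, np.zeros_like(cell), foci)
        with pytest.raises(ValueError, match="empty foci"):
            foci_to_cytoplasm_ratio(img, cell, np.zeros_like(foci))
        with pytest.raises(ValueError, match="nonpositive"):
            foci_to_cytoplasm_ratio(img, cell, foci, background_level=200.0)


def _disk_frame(centers, radius=8, shape=(100, 100), value=100.0):
    img = np.zeros(shape)
    for center in centers:
        rr, cc = skimage.draw.disk(center, radius, shape=shape)
        img[rr, cc] = value
    return img


class TestCountSizeTimeseries:
    def test_static_stack_constant_counts(self):
        frame = _disk_frame([(30, 30), (70, 70)])
        stack = np.stack([frame] * 4)
        cells = np.ones((100, 100), dtype=int)
        table = count_size_timeseries(stack, cells, threshold_method="manual", manual_threshold=50.0)
        per_cell = table[table.cell_id == 1]
        assert (per_cell.granule_count == 2).all()

    def test_fusion_conserves_total_area(self):
        pre = _disk_frame([(50, 35), (50, 65)], radius=10)
        merged = np.zeros((100, 100))
        rr, cc = skimage.draw.disk((50, 50), 10 * math.sqrt(2))  # same total area
        merged[rr, cc] = 100.0
        stack = np.stack([pre, merged])
        cells = np.ones((100, 100), dtype=int)
        table = count_size_timeseries(stack, cells, threshold_method="manual", manual_threshold=50.0)
        per_cell = table[table.cell_id == 1].set_index("frame")
        assert per_cell.loc[0, "granule_count"] == 2
        assert per_cell.loc[1, "granule_count"] == 1
        assert per_cell.loc[1, "mean_area_um2"] == pytest.approx(
            2 * per_cell.loc[0, "mean_area_um2"], rel=0.05)
        assert per_cell.loc[1, "total_area_um2"] == pytest.approx(
            per_cell.loc[0, "total_area_um2"], rel=0.05)

    def test_zero_granule_frame_reports_missing_mean(self):
        stack = np.stack([_disk_frame([(30, 30)]), np.zeros((100, 100))])
        cells = np.ones((100, 100), dtype=int)
        table = count_size_timeseries(stack, cells, threshold_method="manual", manual_threshold=50.0)
        empty = table[(table.frame == 1) & (table.cell_id == 1)].iloc[0]
        assert empty.granule_count == 0
        assert np.isnan(empty.mean_area_um2)

    def test_no_cells_rejected(self):
        with pytest.raises(ValueError, match="no cells"):
            count_size_timeseries(np.zeros((1, 20, 20)), np.zeros((20, 20), dtype=int))


class TestDetectFusions:
    def _labels(self, frame):
        import skimage.measure

        return LabelImage(labels=skimage.measure.label(frame > 50))

    def test_static_objects_no_events(self):
        frame = _disk_frame([(30, 30), (70, 70)])
        assert detect_fusions([self._labels(frame)] * 3) == []

    def test_two_disk_merge_detected_once(self):
        pre = _disk_frame([(50, 40), (50, 60)], radius=9)
        merged = np.zeros((100, 100))
        rr, cc = skimage.draw.disk((50, 50), 9 * math.sqrt(2))
        merged[rr, cc] = 100.0
        events = detect_fusions([self._labels(pre), self._labels(merged)],
                                max_displacement=12.0)
        assert len(events) == 1
        assert events[0].frame == 1
        assert len(events[0].parent_labels) == 2

    def test_near_miss_without_merge_no_event(self):
        # objects approach but never overlap; displacement above threshold
        a = _disk_frame([(50, 20), (50, 80)])
        b = _disk_frame([(50, 35), (50, 65)])
        events = detect_fusions([self._labels(a), self._labels(b)], max_displacement=5.0)
        assert events == []
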