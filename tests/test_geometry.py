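"""Partition line, arch curves, tooth extraction, gating, ACH measurement."""
from __future__ import annotations

import numpy as np
import pytest

from achkit import (
    BinaryMask,
    Calibration,
    DegenerateGeometryError,
    DimensionError,
    Landmark,
    LandmarkClass,
    LandmarkSource,
    MaskLabel,
    PipelineConfig,
    Point2D,
)
from achkit.geometry import (
    ARCH_LOWER,
    ARCH_UPPER,
    ArchCurve,
    PartitionLine,
    classify_severity,
    extract_tooth_instances,
    fit_arch_curve,
    fit_partition_line,
    measure_tooth_ach,
    merge_teeth_masks,
    partition_landmarks,
    process_radiograph,
    render_overlay,
    tooth_crosses_curves,
)
from achkit.oracle import NoiseParams, oracle_detect
from achkit.phantom import PhantomSpec, generate_phantom
from conftest import make_rect_tooth
from oracles import exact_polyfit, exhaustive_crossing, ols_line


def pts(*pairs):
    return [Point2D(float(x), float(y)) for x, y in pairs]


def lm(x, y, cls, conf=1.0):
    return Landmark(Point2D(float(x), float(y)), cls, conf, LandmarkSource.FUSED)


def const_curve(y, arch=ARCH_UPPER, cls=LandmarkClass.ABCL, support=(0.0, 100.0)):
    return ArchCurve(arch, cls, (float(y), 0.0), 1, support)


class TestPartitionLine:
    def test_collinear_horizontal(self):
        line = fit_partition_line(pts((0, 10), (10, 10), (20, 10)))
        assert line.slope == pytest.approx(0.0, abs=1e-12)
        assert line.intercept == pytest.approx(10.0)

    def test_two_symmetric_clusters_bisected(self):
        line = fit_partition_line(pts((0, 0), (10, 0), (20, 0), (0, 20), (10, 20), (20, 20)))
        assert line.slope == pytest.approx(0.0, abs=1e-12)
        assert line.intercept == pytest.approx(10.0)

    @pytest.mark.parametrize("points", [[(5, 5)], [(3, 1), (3, 9)], []])
    def test_degenerate_geometry_rejected(self, points):
        with pytest.raises(DegenerateGeometryError):
            fit_partition_line(pts(*points))

    def test_matches_closed_form_ols_on_random_points(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            raw = [(float(x), float(y)) for x, y in
                   zip(rng.uniform(0, 100, 15), rng.uniform(0, 100, 15))]
            line = fit_partition_line(pts(*raw))
            slope, intercept = ols_line(raw)
            assert line.slope == pytest.approx(slope, rel=1e-9, abs=1e-9)
            assert line.intercept == pytest.approx(intercept, rel=1e-9, abs=1e-9)

    def test_accepts_mask_input(self):
        grid = np.zeros((30, 30), dtype=bool)
        grid[10, 5:25] = True
        line = fit_partition_line(BinaryMask(grid, MaskLabel.ABCL))
        assert line.y_at(15.0) == pytest.approx(10.0)


class TestPartitionLandmarks:
    @pytest.mark.parametrize("y, expect_upper", [(3, True), (17, False), (10, True)])
    def test_split_with_tie_to_upper(self, y, expect_upper):
        line = PartitionLine(0.0, 10.0)
        upper, lower = partition_landmarks([lm(5, y, LandmarkClass.CEJ)], line)
        assert (len(upper), len(lower)) == ((1, 0) if expect_upper else (0, 1))

    def test_union_preserved(self):
        line = PartitionLine(0.1, 5.0)
        landmarks = [lm(x, y, LandmarkClass.ABCL) for x, y in
                     zip(range(10), [2, 8, 1, 20, 5, 9, 30, 0, 4, 15])]
        upper, lower = partition_landmarks(landmarks, line)
        assert sorted(upper + lower, key=id) == sorted(landmarks, key=id)


class TestArchCurve:
    def test_exact_line(self):
        curve = fit_arch_curve(pts((0, 0), (1, 1), (2, 2)), ARCH_UPPER, LandmarkClass.CEJ, 1)
        assert curve.coeffs == pytest.approx([0.0, 1.0], abs=1e-10)

    def test_exact_parabola(self):
        curve = fit_arch_curve(pts((0, 0), (1, 1), (2, 4), (3, 9)), ARCH_UPPER, LandmarkClass.CEJ, 2)
        assert curve.coeffs == pytest.approx([0.0, 0.0, 1.0], abs=1e-9)

    def test_degree_reduced_when_points_scarce(self):
        curve = fit_arch_curve(pts((0, 5), (4, 5)), ARCH_LOWER, LandmarkClass.ABCL, 2)
        assert curve.degree == 1
        assert curve.coeffs == pytest.approx([5.0, 0.0], abs=1e-10)
        # interpolating case reproduces inputs exactly
        assert curve(0.0) == pytest.approx(5.0) and curve(4.0) == pytest.approx(5.0)

    def test_degenerate_x_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_arch_curve(pts((2, 1), (2, 9)), ARCH_UPPER, LandmarkClass.CEJ, 2)

    def test_matches_exact_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            degree = int(rng.integers(1, 5))
            n = int(rng.integers(degree + 1, 51))
            x = rng.uniform(0, 20, n)
            x[: degree + 1] += np.arange(degree + 1)  # guarantee distinct x
            y = rng.uniform(-50, 50, n)
            curve = fit_arch_curve(pts(*zip(x, y)), ARCH_UPPER, LandmarkClass.ABCL, degree)
            expected = exact_polyfit(x, y, degree)
            scale = max(1.0, max(abs(c) for c in expected))
            assert np.allclose(curve.coeffs, expected, rtol=1e-8, atol=1e-8 * scale)


class TestToothExtraction:
    def test_all_background_gives_empty(self):
        mask = BinaryMask(np.zeros((50, 50), dtype=bool), MaskLabel.TEETH)
        assert extract_tooth_instances(mask, 200) == []

    def test_two_squares_counted_and_ordered(self):
        grid = np.zeros((60, 90), dtype=bool)
        grid[10:30, 50:70] = True  # right square first in memory
        grid[10:30, 5:25] = True
        teeth = extract_tooth_instances(BinaryMask(grid, MaskLabel.TEETH), 200)
        assert [t.area_px for t in teeth] == [400, 400]
        assert [t.tooth_id for t in teeth] == [0, 1]
        assert teeth[0].x_min == 5 and teeth[1].x_min == 50

    def test_small_component_filtered(self):
        grid = np.zeros((40, 40), dtype=bool)
        grid[5:15, 5:15] = True  # area 100
        assert extract_tooth_instances(BinaryMask(grid, MaskLabel.TEETH), 200) == []

    def test_diagonally_touching_blobs_are_one_component(self):
        grid = np.zeros((40, 40), dtype=bool)
        grid[5:15, 5:15] = True
        grid[15:25, 15:25] = True  # touches only at the corner
        teeth = extract_tooth_instances(BinaryMask(grid, MaskLabel.TEETH), 150)
        assert len(teeth) == 1 and teeth[0].area_px == 200

    def test_outline_pixels_have_background_4_neighbour(self):
        grid = np.zeros((40, 40), dtype=bool)
        grid[10:30, 8:28] = True
        (tooth,) = extract_tooth_instances(BinaryMask(grid, MaskLabel.TEETH), 10)
        padded = np.pad(grid, 1)
        for x, y in tooth.outline:
            neighbours = [padded[y, x + 1], padded[y + 2, x + 1], padded[y + 1, x], padded[y + 1, x + 2]]
            assert not all(neighbours)
        # and interior pixels are not outline
        assert len(tooth.outline) == 2 * 20 + 2 * 18

    def test_rejects_non_teeth_mask(self):
        with pytest.raises(ValueError, match="teeth"):
            extract_tooth_instances(BinaryMask(np.ones((5, 5), bool), MaskLabel.ABCL), 1)


class TestMergeMasks:
    def test_identity_idempotence_additivity(self):
        grid_a = np.zeros((20, 20), dtype=bool)
        grid_a[2:6, 2:6] = True
        grid_b = np.zeros((20, 20), dtype=bool)
        grid_b[10:14, 10:14] = True
        a = BinaryMask(grid_a, MaskLabel.TEETH)
        b = BinaryMask(grid_b, MaskLabel.TEETH)
        empty = BinaryMask(np.zeros((20, 20), bool), MaskLabel.TEETH)
        assert merge_teeth_masks(a, empty) == a
        assert merge_teeth_masks(a, a) == a
        merged = merge_teeth_masks(a, b)
        assert merged.grid.sum() == grid_a.sum() + grid_b.sum()

    def test_shape_mismatch_raises(self):
        a = BinaryMask(np.zeros((10, 10), bool), MaskLabel.TEETH)
        b = BinaryMask(np.zeros((10, 12), bool), MaskLabel.TEETH)
        with pytest.raises(DimensionError):
            merge_teeth_masks(a, b)


class TestCrossingGate:
    def setup_method(self):
        self.tooth = make_rect_tooth(0, 10, 5, 15)

    def test_both_curves_inside_tooth_cross(self):
        assert tooth_crosses_curves(self.tooth, const_curve(12), const_curve(8, cls=LandmarkClass.CEJ))

    def test_curve_outside_tooth_fails(self):
        assert not tooth_crosses_curves(
            self.tooth, const_curve(12), const_curve(20, cls=LandmarkClass.CEJ)
        )

    def test_single_crossing_is_not_enough(self):
        assert not tooth_crosses_curves(
            self.tooth, const_curve(12), const_curve(40, cls=LandmarkClass.CEJ)
        )

    def test_support_limits_the_test(self):
        off_support = ArchCurve(ARCH_UPPER, LandmarkClass.ABCL, (12.0, 0.0), 1, (50.0, 90.0))
        assert not tooth_crosses_curves(self.tooth, off_support, const_curve(8, cls=LandmarkClass.CEJ))

    def test_matches_exhaustive_pixel_scan_on_random_blobs(self):
        from achkit.geometry import _crosses_one_curve

        rng = np.random.default_rng(23)
        for _ in range(40):
            grid = np.zeros((40, 40), dtype=bool)
            x0, y0 = rng.integers(0, 20, 2)
            w, h = rng.integers(4, 18, 2)
            grid[y0:y0 + h, x0:x0 + w] = True
            (tooth,) = extract_tooth_instances(BinaryMask(grid, MaskLabel.TEETH), 1)
            coeffs = (float(rng.uniform(-5, 45)), float(rng.uniform(-1, 1)),
                      float(rng.uniform(-0.05, 0.05)))
            curve = ArchCurve(ARCH_UPPER, LandmarkClass.ABCL, coeffs, 2,
                              (float(rng.uniform(0, 15)), float(rng.uniform(20, 40))))
            tol = 1.0
            got = _crosses_one_curve(tooth, curve, tol)
            expected = exhaustive_crossing(
                [tuple(p) for p in tooth.pixels],
                [tuple(p) for p in tooth.outline],
                curve, curve.support, tol,
            )
            assert got == expected


class TestSeverity:
    @pytest.mark.parametrize(
        "ach_mm, rule, expected",
        [(4.99, "ge", False), (5.0, "ge", True), (5.0, "gt", False), (5.01, "gt", True)],
    )
    def test_threshold_conventions(self, ach_mm, rule, expected):
        assert classify_severity(ach_mm, 5.0, rule) is expected

    def test_rules_disagree_only_at_threshold(self):
        for v in np.linspace(0, 10, 101):
            ge, gt = classify_severity(v, 5.0, "ge"), classify_severity(v, 5.0, "gt")
            assert (ge == gt) or v == 5.0

    def test_negative_ach_rejected(self):
        with pytest.raises(ValueError):
            classify_severity(-0.1, 5.0)


class TestMeasureToothAch:
    def test_vertical_pair_gives_expected_mm(self, config):
        tooth = make_rect_tooth(100, 160, 180, 400, shape=(450, 300))
        landmarks = [lm(100, 200, LandmarkClass.CEJ), lm(100, 250, LandmarkClass.ABCL)]
        (m,) = measure_tooth_ach(tooth, landmarks, Calibration(0.1), config)
        assert m.ach_px == pytest.approx(50.0)
        assert m.ach_mm == pytest.approx(5.0)
        assert m.severe is True and m.site == "left"

    def test_pythagorean_distance(self):
        config = PipelineConfig(mm_per_px=1.0)
        tooth = make_rect_tooth(0, 30, 0, 60)
        landmarks = [lm(0, 0, LandmarkClass.CEJ), lm(3, 4, LandmarkClass.ABCL)]
        measurements = measure_tooth_ach(tooth, landmarks, Calibration(1.0), config)
        assert measurements[0].ach_px == pytest.approx(5.0)
        assert measurements[0].ach_mm == pytest.approx(5.0)

    def test_side_without_abcl_emits_nothing(self, config):
        tooth = make_rect_tooth(10, 50, 10, 70)
        landmarks = [lm(10, 30, LandmarkClass.CEJ)]  # no ABCL anywhere
        assert measure_tooth_ach(tooth, landmarks, Calibration(0.1), config) == []

    def test_both_sides_measured_when_both_flanks_have_pairs(self, config):
        tooth = make_rect_tooth(10, 150, 10, 70, shape=(100, 200))
        landmarks = [
            lm(10, 30, LandmarkClass.CEJ), lm(10, 50, LandmarkClass.ABCL),
            lm(150, 30, LandmarkClass.CEJ), lm(150, 55, LandmarkClass.ABCL),
        ]
        measurements = measure_tooth_ach(tooth, landmarks, Calibration(0.1), config)
        assert [m.site for m in measurements] == ["left", "right"]
        assert measurements[1].ach_px == pytest.approx(25.0)

    def test_on_flank_landmark_beats_far_spurious_one(self, config):
        tooth = make_rect_tooth(10, 150, 40, 99, shape=(100, 200))
        true_cej = lm(10, 50, LandmarkClass.CEJ)
        spurious = lm(11, 2, LandmarkClass.CEJ)  # in window, far from the tooth
        landmarks = [spurious, true_cej, lm(10, 80, LandmarkClass.ABCL)]
        (m,) = measure_tooth_ach(tooth, landmarks, Calibration(0.1), config)
        assert m.cej == true_cej.point


class TestProcessRadiograph:
    def test_all_inputs_empty_degrades_gracefully(self, config):
        empty_teeth = BinaryMask(np.zeros((50, 50), bool), MaskLabel.TEETH)
        empty_abcl = BinaryMask(np.zeros((50, 50), bool), MaskLabel.ABCL)
        result = process_radiograph([], [], empty_teeth, empty_teeth, empty_abcl,
                                    config.calibration, config)
        assert result.measurements == [] and result.partition_line is None

    def test_mask_shape_mismatch_raises(self, config):
        t1 = BinaryMask(np.zeros((50, 50), bool), MaskLabel.TEETH)
        t2 = BinaryMask(np.zeros((50, 60), bool), MaskLabel.TEETH)
        abcl = BinaryMask(np.zeros((50, 50), bool), MaskLabel.ABCL)
        with pytest.raises(DimensionError):
            process_radiograph([], [], t1, t2, abcl, config.calibration, config)

    def test_deleting_one_tooth_cej_is_local(self, config):
        """Removing one tooth's CEJ detections drops only that tooth."""
        spec = PhantomSpec(seed=4)
        _, truth = generate_phantom(spec)
        bundle = oracle_detect(truth, NoiseParams(seed=4))
        target = truth.teeth[2]

        def drop_cej(landmarks):
            return [
                l for l in landmarks
                if not (l.cls == LandmarkClass.CEJ
                        and target.x_min - 1 <= l.point.x <= target.x_max + 1
                        and target.y_min - 1 <= l.point.y <= target.y_max + 1)
            ]

        full = process_radiograph(bundle.landmarks_a, bundle.landmarks_b, bundle.teeth_mask_1,
                                  bundle.teeth_mask_2, bundle.abcl_mask,
                                  config.calibration, config)
        ablated = process_radiograph(drop_cej(bundle.landmarks_a), drop_cej(bundle.landmarks_b),
                                     bundle.teeth_mask_1, bundle.teeth_mask_2, bundle.abcl_mask,
                                     config.calibration, config)
        full_keys = {(m.tooth_id, m.site): m.ach_mm for m in full.measurements}
        ablated_keys = {(m.tooth_id, m.site): m.ach_mm for m in ablated.measurements}
        assert all(k[0] != target.tooth_id for k in ablated_keys)
        for k, v in ablated_keys.items():
            assert v == pytest.approx(full_keys[k], abs=1e-9)
        assert set(full_keys) - set(ablated_keys) == {
            (target.tooth_id, "left"), (target.tooth_id, "right")
        }

    def test_gate_soundness_on_phantoms(self, config):
        """Every tooth that emitted measurements satisfies the crossing gate."""
        from conftest import run_phantom_pipeline

        truth, result = run_phantom_pipeline(9, NoiseParams(jitter_sigma_px=2.0, seed=9))
        teeth_by_id = {t.tooth_id: t for t in result.teeth}
        for m in result.measurements:
            tooth = teeth_by_id[m.tooth_id]
            abcl_curve = result.curves[(tooth.arch, LandmarkClass.ABCL)]
            cej_curve = result.curves[(tooth.arch, LandmarkClass.CEJ)]
            assert tooth_crosses_curves(tooth, abcl_curve, cej_curve,
                                        config.crossing_tolerance_px)


class TestRenderOverlay:
    def _measurement(self):
        from achkit import AchMeasurement

        return AchMeasurement("img", 0, "left", Point2D(10, 10), Point2D(10, 40), 30.0, 3.0, False)

    def test_no_measurements_is_plain_rgb_conversion(self):
        rng = np.random.default_rng(2)
        image = rng.integers(0, 255, size=(40, 60), dtype=np.uint8)
        out = render_overlay(image, [])
        assert out.shape == (40, 60, 3)
        assert np.array_equal(out, np.stack([image] * 3, axis=-1))

    def test_measurement_changes_pixels_and_is_deterministic(self):
        image = np.zeros((60, 60), dtype=np.uint8)
        out1 = render_overlay(image, [self._measurement()])
        out2 = render_overlay(image, [self._measurement()])
        assert out1.shape == (60, 60, 3)
        assert np.array_equal(out1, out2)
        assert np.any(out1 != 0)

    def test_severe_and_non_severe_visually_distinct(self):
        from achkit import AchMeasurement

        image = np.zeros((60, 60), dtype=np.uint8)
        severe = AchMeasurement("img", 0, "left", Point2D(10, 10), Point2D(10, 40), 30, 6.0, True)
        colors_severe = set(map(tuple, render_overlay(image, [severe]).reshape(-1, 3)))
        colors_mild = set(map(tuple, render_overlay(image, [self._measurement()]).reshape(-1, 3)))
        assert colors_severe != colors_mild
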