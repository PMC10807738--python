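"""Wedge detection, grey→mmAl calibration, subchondral circle placement."""

import numpy as np
import pytest

from kneequant.calibration import (CalibrationCurve, WedgeError, WedgeSpec,
                                   build_calibration, calibrate_wedge,
                                   circle_mask, detect_wedge,
                                   measure_intensities,
                                   place_subchondral_circles)
from kneequant.geometry import build_framework
from kneequant.phantom import PHANTOM_SUITE, generate_phantom


def synthetic_wedge(greys=(1000, 2000, 3000, 4000, 5000), band_w=20, h=60,
                    pad=10, noise=0.0, seed=0):
    """Image with vertical wedge bands of the given greys plus padding."""
    n = len(greys)
    img = np.full((h + 2 * pad, n * band_w + 2 * pad), 100.0)
    for i, g in enumerate(greys):
        img[pad:pad + h, pad + i * band_w:pad + (i + 1) * band_w] = g
    if noise:
        img = img + np.random.default_rng(seed).normal(0, noise, img.shape)
    spec = WedgeSpec(thicknesses=tuple(range(1, n + 1)),
                     roi=(pad, pad, n * band_w, h))
    return img, spec


class TestDetectWedge:
    def test_noiseless_band_means_exact(self):
        img, spec = synthetic_wedge()
        masks = detect_wedge(img, spec)
        assert len(masks) == 5
        for mask, g in zip(masks, (1000, 2000, 3000, 4000, 5000)):
            assert img[mask].mean() == pytest.approx(g, abs=1.0)

    def test_noisy_assignment_matches_ground_truth(self):
        """σ=20 grey noise: >99% of eroded-mask pixels keep their true band."""
        img, spec = synthetic_wedge(noise=20.0, seed=5)
        clean, _ = synthetic_wedge()
        masks = detect_wedge(img, spec)
        total = correct = 0
        for mask, g in zip(masks, (1000, 2000, 3000, 4000, 5000)):
            total += mask.sum()
            correct += (np.abs(clean[mask] - g) < 1).sum()
        assert correct / total > 0.99

    def test_roi_outside_image_rejected(self):
        img, _ = synthetic_wedge()
        bad = WedgeSpec(thicknesses=(1, 2), roi=(0, 0, img.shape[1] + 5, 10))
        with pytest.raises(WedgeError, match="outside image"):
            detect_wedge(img, bad)

    def test_too_few_bands_raises(self):
        img = np.full((80, 120), 1000.0)  # one flat band, 5 expected
        spec = WedgeSpec(thicknesses=(1, 2, 3, 4, 5), roi=(10, 10, 100, 60))
        with pytest.raises(WedgeError):
            detect_wedge(img, spec)


class TestCalibrationCurve:
    def test_linear_interpolation_between_knots(self):
        c = CalibrationCurve(grey=[100.0, 200.0], mmal=[1.0, 2.0])
        assert c(150.0) == pytest.approx(1.5)

    def test_knot_identity(self):
        c = CalibrationCurve(grey=[100.0, 200.0], mmal=[1.0, 2.0])
        assert c(100.0) == 1.0
        assert c(200.0) == 2.0

    def test_clamped_extrapolation_flagged(self):
        c = CalibrationCurve(grey=[100.0, 200.0], mmal=[1.0, 2.0])
        assert c(250.0) == pytest.approx(2.0)
        assert c.extrapolates(250.0)
        assert not c.extrapolates(150.0)

    def test_monotone_evaluation(self):
        c = CalibrationCurve(grey=[100.0, 180.0, 260.0], mmal=[1.0, 2.0, 4.0])
        g = np.linspace(50, 300, 101)
        v = c(g)
        assert np.all(np.diff(v) >= 0)

    def test_non_monotone_knots_rejected(self):
        with pytest.raises(WedgeError, match="not strictly increasing"):
            CalibrationCurve(grey=[200.0, 100.0], mmal=[1.0, 2.0])

    def test_build_from_masks(self):
        img, spec = synthetic_wedge()
        curve = build_calibration(detect_wedge(img, spec), img, spec)
        assert curve(1500.0) == pytest.approx(1.5, abs=1e-3)


class TestWedgeSpec:
    def test_needs_increasing_thicknesses(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            WedgeSpec(thicknesses=(2.0, 1.0), roi=(0, 0, 10, 10))

    def test_needs_two_steps(self):
        with pytest.raises(ValueError, match="at least 2"):
            WedgeSpec(thicknesses=(1.0,), roi=(0, 0, 10, 10))


@pytest.fixture(scope="module")
def flat_framework():
    p = PHANTOM_SUITE["parallel"]
    return p, build_framework(generate_phantom(p)[1])


class TestSubchondralPlacement:
    def test_closed_form_positions_on_flat_phantom(self, flat_framework):
        """Horizontal L3 at y=300, AB=340: diameter 17 px, tibial centers at
        y = 308.5, spaced 17 px inward from the outer perpendicular."""
        p, fw = flat_framework
        circles = place_subchondral_circles(fw, "lateral", "tibia")
        assert len(circles) == 4
        d = fw.ab / 20.0
        outer_x = p.x_lateral - 2 / 15 * fw.ab  # lateral stations run medially
        for k, c in enumerate(circles):
            assert 2 * c.radius == pytest.approx(d)
            assert c.center[1] == pytest.approx(p.tibial_y + d / 2)
            assert c.center[0] == pytest.approx(outer_x - k * d)

    def test_tangency_to_joint_line(self, flat_framework):
        _p, fw = flat_framework
        for bone, line in (("tibia", fw.l3), ("femur", fw.l2)):
            for comp in ("medial", "lateral"):
                for c in place_subchondral_circles(fw, comp, bone):
                    gap = float(line.distance(c.center)[0]) - c.radius
                    assert abs(gap) < 1e-6

    def test_bone_side_contract(self, flat_framework):
        """Tibial circles strictly below L3, femoral strictly above L2."""
        p, fw = flat_framework
        for comp in ("medial", "lateral"):
            for c in place_subchondral_circles(fw, comp, "tibia"):
                assert c.center[1] > p.tibial_y
            for c in place_subchondral_circles(fw, comp, "femur"):
                assert c.center[1] < p.tibial_y - p.gap_center

    def test_circles_within_group_do_not_overlap(self, flat_framework):
        _p, fw = flat_framework
        for bone in ("tibia", "femur"):
            for comp in ("medial", "lateral"):
                cs = place_subchondral_circles(fw, comp, bone)
                for i in range(4):
                    for j in range(i + 1, 4):
                        dist = np.linalg.norm(cs[i].center - cs[j].center)
                        assert dist >= cs[i].radius + cs[j].radius - 1e-9


class TestMeasureIntensities:
    def test_uniform_image_maps_through_curve(self, flat_framework):
        _p, fw = flat_framework
        img = np.full((512, 512), 1500.0)
        calib = CalibrationCurve(grey=[1000.0, 2000.0], mmal=[2.0, 4.0])
        res = measure_intensities(img, fw, calib)
        for key, v in res.group_means.items():
            assert v == pytest.approx(3.0), key

    def test_distinct_bone_greys_resolved(self, flat_framework):
        p, fw = flat_framework
        img = np.full((512, 512), 0.0)
        img[:300, :] = 2000.0   # femoral side grey
        img[300:, :] = 1000.0   # tibial side grey
        calib = CalibrationCurve(grey=[500.0, 1000.0, 2000.0], mmal=[0.0, 2.0, 4.0])
        res = measure_intensities(img, fw, calib)
        assert res.value("tibia", "medial") == pytest.approx(2.0)
        assert res.value("tibia", "lateral") == pytest.approx(2.0)
        assert res.value("femur", "medial") == pytest.approx(4.0)
        assert res.value("femur", "lateral") == pytest.approx(4.0)

    def test_affine_photometric_invariance(self):
        """Applying a·g + b to image AND wedge leaves every mmAl unchanged."""
        p = PHANTOM_SUITE["parallel"]
        img, ls, _gt = generate_phantom(p)
        fw = build_framework(ls)
        spec = p.wedge_spec()
        base = measure_intensities(img.astype(float), fw,
                                   calibrate_wedge(img.astype(float), spec))
        shifted = 1.7 * img.astype(float) + 321.0
        res = measure_intensities(shifted, fw, calibrate_wedge(shifted, spec))
        for key in base.group_means:
            assert res.group_means[key] == pytest.approx(
                base.group_means[key], abs=1e-6)


def test_circle_mask_center_in_rule():
    mask = circle_mask((20, 20), np.array([10.0, 10.0]), 3.0)
    yy, xx = np.nonzero(mask)
    assert np.all((xx - 10.0) ** 2 + (yy - 10.0) ** 2 <= 9.0 + 1e-9)
    assert mask.sum() == 29  # 3px-radius disk on the integer grid
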