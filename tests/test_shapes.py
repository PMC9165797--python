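"""Grain outline construction: limits, symmetry, validity, determinism."""

import math

import numpy as np
import pytest

import pollenmorph as pm
from pollenmorph.errors import ContourError
from pollenmorph.shapes import curvature_bounds, perpendicular_extent

from conftest import make_truth


def sweep_extent(vertices: np.ndarray, step_deg: float = 0.05) -> float:
    """Dense angular-sweep oracle for the maximum Feret extent."""
    best = 0.0
    for ang in np.arange(0.0, 180.0, step_deg):
        d = (math.cos(math.radians(ang)), math.sin(math.radians(ang)))
        proj = vertices @ np.asarray(d)
        best = max(best, proj.max() - proj.min())
    return best


class TestAmbLimits:
    def test_sharp_equilateral_triangle_limit(self):
        """curvature=0, vanishing apex rounding -> equilateral triangle whose
        protocol E equals the side length (dense-sweep oracle)."""
        truth = make_truth(curvature=0.0, apex_rounding=0.004, e_true=19.0)
        contour = pm.build_contour(truth, n_vertices=900)
        e = pm.protocol_equatorial(contour)
        assert e == pytest.approx(19.0, rel=5e-3)
        # for the sharp triangle the side equals the maximum Feret extent
        assert pm.max_feret(contour) == pytest.approx(19.0, rel=5e-3)
        assert sweep_extent(contour.vertices, 0.1) == pytest.approx(
            pm.max_feret(contour), rel=1e-4)
        # nearly sharp triangle compactness approaches pi*sqrt(3)/9
        f = pm.core_features(contour)
        assert f["compactness"] == pytest.approx(math.pi * math.sqrt(3) / 9,
                                                 rel=2e-2)

    def test_convex_sides_give_solidity_one(self):
        truth = make_truth(curvature=0.20, apex_rounding=0.15)
        f = pm.core_features(pm.build_contour(truth))
        assert f["convex_hull"] == pytest.approx(1.0, abs=1e-4)

    def test_concave_sides_are_nonconvex(self):
        """Midside points lie strictly inside the convex hull: solidity < 1."""
        truth = make_truth(curvature=-0.08, apex_rounding=0.15)
        f = pm.core_features(pm.build_contour(truth))
        assert f["convex_hull"] < 0.99

    @pytest.mark.parametrize("curvature", [-0.49, -0.3, 0.3, 0.49])
    def test_extreme_curvature_rejected(self, curvature):
        truth = make_truth(curvature=curvature, apex_rounding=0.3)
        with pytest.raises(ContourError):
            pm.build_contour(truth)

    def test_curvature_outside_half_rejected(self):
        with pytest.raises(ContourError):
            pm.build_contour(make_truth(curvature=0.6))

    def test_nonpositive_apex_rounding_rejected(self):
        with pytest.raises(ContourError):
            pm.build_contour(make_truth(apex_rounding=0.0))

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ContourError):
            pm.build_contour(make_truth(), n_vertices=23)


class TestContourInvariants:
    @pytest.mark.parametrize("preset", ["leptospermum", "kunzea"])
    def test_sampled_contours_are_valid(self, preset):
        """Every sampled contour (incl. degraded, both views) is a simple
        polygon with positive area and >= 24 vertices."""
        profile = pm.get_preset(preset).with_(degraded_fraction=0.3)
        for truth in pm.sample_truths(profile, 60, view_mix=0.5, seed=3):
            contour = pm.build_contour(truth)
            contour.validate()
            assert contour.signed_area() > 0

    def test_three_fold_rotation_leaves_core_features(self):
        """Rotating a polar contour by 2*pi/3 changes every core feature by
        less than 0.1%."""
        truth = make_truth(irregularity=0.03, seed=42)
        contour = pm.build_contour(truth)
        rotated = contour.transformed(rotate=2.0 * math.pi / 3.0)
        f0 = pm.core_features(contour)
        f1 = pm.core_features(rotated)
        for name in pm.CORE_FEATURE_NAMES:
            assert f1[name] == pytest.approx(f0[name], rel=1e-3), name

    def test_protocol_e_anchoring(self):
        """The built polar contour reproduces e_true through the measurement
        protocol within 0.5%."""
        for seed in (1, 2, 3):
            truth = make_truth(e_true=17.3, irregularity=0.05, seed=seed)
            contour = pm.build_contour(truth)
            assert pm.protocol_equatorial(contour) == pytest.approx(
                17.3, rel=5e-3)

    def test_equatorial_dimensions(self):
        truth = make_truth(view="equatorial", e_true=19.0, p_true=12.98,
                           aperture_angles=(math.pi / 2, 3 * math.pi / 2))
        contour = pm.build_contour(truth)
        assert pm.protocol_polar(contour) == pytest.approx(12.98, rel=1e-3)
        assert pm.protocol_equatorial(contour) == pytest.approx(19.0, rel=1e-3)

    def test_build_is_deterministic(self):
        t = make_truth(irregularity=0.04, seed=5)
        a = pm.build_contour(t)
        b = pm.build_contour(t)
        np.testing.assert_array_equal(a.vertices, b.vertices)


class TestMonotoneOffset:
    def test_offset_nondecreasing_in_curvature(self):
        """mean(MFD - protocol E) does not decrease over the curvature grid
        (convex-sided ambs deviate more, as observed between the genera)."""
        offsets = []
        for curvature in (-0.2, -0.1, 0.0, 0.1, 0.2):
            truth = make_truth(curvature=curvature, apex_rounding=0.06,
                               irregularity=0.0, e_true=19.0)
            contour = pm.build_contour(truth, n_vertices=900)
            offsets.append(pm.max_feret(contour) - pm.protocol_equatorial(contour))
        for a, b in zip(offsets, offsets[1:]):
            assert b >= a - 0.02


def test_curvature_bounds_bracket_construction():
    lo, hi = curvature_bounds(0.30, 3)
    assert lo < 0 < hi
    for c in (lo, hi):
        pm.build_contour(make_truth(curvature=c, apex_rounding=0.30))


def test_perpendicular_extent_matches_definition():
    rng = np.random.default_rng(0)
    v = rng.normal(size=(30, 2))
    ang = 0.7
    d = np.array([-math.sin(ang), math.cos(ang)])
    assert perpendicular_extent(v, ang) == pytest.approx(
        (v @ d).max() - (v @ d).min())
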