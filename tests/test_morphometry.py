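"""Core shape features against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pollenmorph as pm
from pollenmorph.errors import ContourError, FeatureError
from pollenmorph.morphometry import GRATICULE_QUANTUM

from conftest import make_truth, random_star_polygon, regular_polygon

SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def equilateral(side: float) -> np.ndarray:
    h = side * math.sqrt(3) / 2.0
    return np.array([[0.0, 0.0], [side, 0.0], [side / 2.0, h]])


def brute_force_max_feret(v: np.ndarray) -> float:
    d2 = ((v[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
    return math.sqrt(d2.max())


def sweep_min_feret(v: np.ndarray, step_deg: float = 0.01) -> float:
    best = math.inf
    for ang in np.arange(0.0, 180.0, step_deg):
        d = np.array([math.cos(math.radians(ang)), math.sin(math.radians(ang))])
        proj = v @ d
        best = min(best, proj.max() - proj.min())
    return best


class TestAreaPerimeter:
    def test_unit_square(self):
        assert pm.area_perimeter(SQUARE) == pytest.approx((1.0, 4.0))

    def test_equilateral_triangle_side_2(self):
        area, perim = pm.area_perimeter(equilateral(2.0))
        assert area == pytest.approx(math.sqrt(3))
        assert perim == pytest.approx(6.0)

    def test_360gon_approximates_circle(self):
        area, perim = pm.area_perimeter(regular_polygon(360))
        assert area == pytest.approx(math.pi, rel=1e-3)
        assert perim == pytest.approx(2 * math.pi, rel=1e-3)

    def test_self_intersection_rejected(self):
        bowtie = pm.Contour.__new__(pm.Contour)  # bypass orientation fix
        bowtie.vertices = np.array([[0, 0], [1, 1], [1, 0], [0, 1.0]])
        bowtie.grain_id = bowtie.taxon = bowtie.view = None
        bowtie.aperture_angles = None
        with pytest.raises(ContourError):
            pm.area_perimeter(bowtie)


class TestFeretDiameters:
    def test_square_diagonal(self):
        assert pm.max_feret(SQUARE) == pytest.approx(math.sqrt(2))
        assert pm.min_feret(SQUARE) == pytest.approx(1.0)

    def test_equilateral_triangle(self):
        tri = equilateral(3.0)
        assert pm.max_feret(tri) == pytest.approx(3.0)
        assert pm.min_feret(tri) == pytest.approx(3.0 * math.sqrt(3) / 2.0)

    def test_max_feret_matches_bruteforce_on_random_polygons(self):
        """Exactly the pairwise-distance maximum on 120 random polygons."""
        rng = np.random.default_rng(7)
        for _ in range(120):
            v = random_star_polygon(rng, n=int(rng.integers(5, 40)))
            assert pm.max_feret(v) == pytest.approx(
                brute_force_max_feret(v), abs=1e-9)

    def test_min_feret_matches_sweep_on_random_convex_polygons(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            pts = rng.normal(size=(int(rng.integers(6, 25)), 2))
            from scipy.spatial import ConvexHull
            hull = pts[ConvexHull(pts).vertices]
            assert pm.min_feret(hull) == pytest.approx(
                sweep_min_feret(hull), rel=1e-3)


class TestCoreFeatures:
    def test_circle_identities(self):
        f = pm.core_features(regular_polygon(720, radius=2.0))
        assert f["compactness"] == pytest.approx(1.0, rel=1e-4)
        assert f["heywood"] == pytest.approx(1.0, rel=1e-4)
        assert f["hydraulic_radius"] == pytest.approx(1.0, rel=1e-4)  # r/2
        assert f["elongation"] == pytest.approx(1.0, rel=1e-3)
        assert f["convex_hull"] == pytest.approx(1.0, abs=1e-6)
        assert f["max_feret"] == pytest.approx(4.0, rel=1e-4)

    def test_unit_square_closed_forms(self):
        f = pm.core_features(SQUARE)
        assert f["compactness"] == pytest.approx(math.pi / 4.0)
        assert f["heywood"] == pytest.approx(2.0 / math.sqrt(math.pi))
        assert f["hydraulic_radius"] == pytest.approx(0.25)
        assert f["elongation"] == pytest.approx(math.sqrt(2))
        assert f["convex_hull"] == pytest.approx(1.0)

    def test_sharp_triangle_compactness(self):
        f = pm.core_features(equilateral(2.0))
        assert f["compactness"] == pytest.approx(math.pi * math.sqrt(3) / 9.0)

    def test_compactness_heywood_identity(self):
        """compactness * heywood^2 == 1 by definition, on arbitrary shapes."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            f = pm.core_features(random_star_polygon(rng))
            assert f["compactness"] * f["heywood"] ** 2 == pytest.approx(
                1.0, abs=1e-9)

    @given(st.floats(min_value=0.1, max_value=10.0),
           st.floats(min_value=0.0, max_value=2 * math.pi))
    @settings(max_examples=25, deadline=None)
    def test_scale_and_rotation_covariance(self, k, ang):
        """Scaling by k multiplies area by k^2 and lengths by k; rigid
        rotation changes nothing (1e-6 relative)."""
        rng = np.random.default_rng(5)
        v = random_star_polygon(rng, 18)
        f0 = pm.core_features(v)
        rot = np.array([[math.cos(ang), math.sin(ang)],
                        [-math.sin(ang), math.cos(ang)]])
        f1 = pm.core_features(k * (v @ rot))
        assert f1["area"] == pytest.approx(k**2 * f0["area"], rel=1e-6)
        for name in ("max_feret", "hydraulic_radius"):
            assert f1[name] == pytest.approx(k * f0[name], rel=1e-6)
        for name in ("compactness", "heywood", "elongation", "convex_hull"):
            assert f1[name] == pytest.approx(f0[name], rel=1e-6)

    def test_zero_area_rejected(self):
        with pytest.raises((FeatureError, ContourError)):
            pm.core_features(np.array([[0, 0], [1, 0], [2, 0.0]]))


class TestMeasurementProtocol:
    def test_circle_any_aperture_gives_diameter(self):
        circle = regular_polygon(720, radius=9.5)
        for ang in (0.0, 1.0, 2.5):
            assert pm.protocol_equatorial(circle, [ang]) == pytest.approx(
                19.0, rel=1e-4)

    def test_triangle_apertures_at_vertices(self):
        """E perpendicular to a vertex direction equals the side length for
        an equilateral triangle (also its max Feret)."""
        tri = equilateral(2.0)
        centroid = tri.mean(axis=0)
        angles = [math.atan2(*(v - centroid)[::-1]) for v in tri]
        v = tri - centroid
        e = pm.protocol_equatorial(v, angles, aperture_rule="max")
        assert e == pytest.approx(2.0, rel=1e-9)
        assert e == pytest.approx(pm.max_feret(v))

    def test_protocol_e_never_exceeds_max_feret(self):
        rng = np.random.default_rng(19)
        profile = pm.get_preset("leptospermum")
        for truth in pm.sample_truths(profile, 40, 1.0, seed=23):
            c = pm.build_contour(truth)
            for rule in ("first", "max"):
                e = pm.protocol_equatorial(c, aperture_rule=rule)
                assert e <= pm.max_feret(c) + 1e-9

    def test_max_rule_at_least_first_rule(self):
        truth = make_truth(irregularity=0.05, seed=9)
        c = pm.build_contour(truth)
        assert pm.protocol_equatorial(c, aperture_rule="max") >= \
            pm.protocol_equatorial(c, aperture_rule="first")

    def test_graticule_quantization(self):
        """Rounding to the nearest half of a 0.625 μm division."""
        assert GRATICULE_QUANTUM == pytest.approx(0.3125)
        oracle = lambda x: round(x / 0.3125) * 0.3125
        circle = regular_polygon(1440, radius=12.99 / 2.0)
        measured = pm.protocol_equatorial(circle, [0.3], rounding="graticule")
        assert measured == pytest.approx(oracle(12.99))
        # 12.99/0.3125 = 41.57 -> 42 divisions -> 13.125
        assert measured == pytest.approx(13.125)

    def test_polar_diameter_requires_equatorial_view(self):
        truth = make_truth()
        contour = pm.build_contour(truth)
        with pytest.raises(FeatureError):
            pm.protocol_polar(contour)

    def test_no_apertures_rejected(self):
        with pytest.raises(FeatureError):
            pm.protocol_equatorial(SQUARE, [])

    def test_measure_record_equatorial(self):
        truth = make_truth(view="equatorial", e_true=16.0, p_true=11.0,
                           aperture_angles=(math.pi / 2, 3 * math.pi / 2))
        rec = pm.measure_record(pm.build_contour(truth))
        assert rec.p_protocol == pytest.approx(11.0, rel=1e-3)
        assert rec.e_protocol <= rec.max_feret + 1e-9
        assert rec.p_protocol < rec.e_protocol
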