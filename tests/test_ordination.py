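"""Summary statistics, PCA and HPD regions."""

import math

import numpy as np
import pandas as pd
import pytest

import pollenmorph as pm
from pollenmorph.errors import FeatureError


class TestSummarize:
    def test_hand_computed_example(self):
        s = pm.summarize([1.0, 3.0])
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(math.sqrt(2))
        assert s.range_1sd == pytest.approx((2 - math.sqrt(2), 2 + math.sqrt(2)))
        assert s.range_2sd == pytest.approx((2 - 2 * math.sqrt(2),
                                             2 + 2 * math.sqrt(2)))
        assert (s.min, s.max) == (1.0, 3.0)

    def test_constant_list_collapses(self):
        s = pm.summarize([5.0, 5.0, 5.0])
        assert s.sd == 0.0
        assert s.range_1sd == (5.0, 5.0)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            pm.summarize([1.0])

    def test_preset_calibration(self):
        """490 draws from the leptospermum preset summarize to the published
        E mean within 2 standard errors."""
        truths = pm.sample_truths(pm.get_preset("leptospermum"), 490, 1.0,
                                  seed=77)
        s = pm.summarize([t.e_true for t in truths])
        assert abs(s.mean - 19.08) < 2 * 1.28 / math.sqrt(490)


class TestPCA:
    def test_perfectly_correlated_features(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = pm.pca(df)
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_features_share_variance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(10000, 4)),
                          columns=list("abcd"))
        res = pm.pca(df)
        assert np.allclose(res.variance_explained, 0.25, atol=0.02)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(60, 5)) * [1, 2, 3, 4, 5],
                          columns=list("abcde"))
        res = pm.pca(df, scale=True)
        X = df.to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recon - Z).max() < 1e-8

    def test_variance_sums_to_one_and_sorted(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(100, 6)))
        res = pm.pca(df)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_sign_convention(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(80, 4)))
        res = pm.pca(df)
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"alive": [1.0, 2.0, 3.0], "dead": [7.0, 7.0, 7.0]})
        with pytest.raises(FeatureError, match="dead"):
            pm.pca(df, scale=True)

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            pm.pca(df)


class TestHPDRegion:
    def test_bivariate_normal_area_matches_chi2(self):
        """For a standard bivariate normal, the 95% HPD region is the disk of
        radius^2 = chi2_2(0.95), area pi * 5.991 ~ 18.8."""
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((100_000, 2))
        region = pm.hpd_region_2d(pts, mass=0.95)
        assert region.total_area == pytest.approx(math.pi * 5.991, rel=0.10)

    def test_mass_nesting(self):
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((20_000, 2))
        r95 = pm.hpd_region_2d(pts, mass=0.95)
        r99 = pm.hpd_region_2d(pts, mass=0.99)
        assert r99.density_level <= r95.density_level
        assert r99.total_area >= r95.total_area
        assert r99.contains_region(r95)

    def test_two_clusters_two_polygons(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((2000, 2))
        b = rng.standard_normal((2000, 2)) + [30.0, 0.0]
        region = pm.hpd_region_2d(np.vstack([a, b]), mass=0.9)
        assert len(region.polygons) >= 2

    def test_degenerate_inputs_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            pm.hpd_region_2d(rng.standard_normal((20, 2)), mass=0.95)
        x = np.linspace(0, 1, 100)
        with pytest.raises(ValueError):
            pm.hpd_region_2d(np.column_stack([x, 2 * x]), mass=0.95)
        with pytest.raises(ValueError):
            pm.hpd_region_2d(rng.standard_normal((100, 2)), mass=1.0)


class TestCohortOrdination:
    def test_hpd_overlap_partial_not_nested(self, polar_cohort):
        """The two genus 95% HPD envelopes on PC1-PC2 overlap partially but
        neither contains the other."""
        from shapely.geometry import Polygon
        from shapely.ops import unary_union

        kept = polar_cohort["kept"]
        res = pm.pca(kept[list(pm.CORE_FEATURE_NAMES)])
        scores = res.scores.iloc[:, :2].to_numpy()
        shapes = {}
        for taxon in ("leptospermum", "kunzea"):
            pts = scores[(kept["taxon"] == taxon).to_numpy()]
            region = pm.hpd_region_2d(pts, mass=0.95)
            shapes[taxon] = unary_union([Polygon(p) for p in region.polygons])
        inter = shapes["leptospermum"].intersection(shapes["kunzea"])
        assert inter.area > 0
        assert not shapes["leptospermum"].contains(shapes["kunzea"])
        assert not shapes["kunzea"].contains(shapes["leptospermum"])

    def test_leading_loadings_include_discriminants(self, polar_cohort):
        """PC1 loads substantially on max Feret diameter, compactness,
        solidity and Heywood circularity."""
        kept = polar_cohort["kept"]
        res = pm.pca(kept[list(pm.CORE_FEATURE_NAMES)])
        pc1 = res.loadings["PC1"].abs()
        for name in ("max_feret", "compactness", "convex_hull", "heywood"):
            assert pc1[name] > 0.2
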