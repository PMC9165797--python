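"""Shared fixtures: calibrated synthetic cohorts and reference shapes.

The two cohort fixtures mirror the study design at desk scale (the study's
~3:1 genus imbalance at 4000 grains instead of 23702) and are session-scoped
because simulating and measuring 4000 grains dominates the suite's runtime.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import pollenmorph as pm

COHORT_COUNTS = {"leptospermum": 3000, "kunzea": 1000}


def make_truth(**kwargs) -> pm.GrainTruth:
    """A GrainTruth with sane defaults, overridable per test."""
    defaults = dict(
        grain_id="g-0", taxon="test", view="polar", e_true=19.0, p_true=13.0,
        curvature=-0.05, aperture_angles=(math.pi / 2, math.pi / 2 + 2 * math.pi / 3,
                                          math.pi / 2 + 4 * math.pi / 3),
        apocolpium=False, texture_amplitude=0.08, degraded=False, seed=7,
        apex_rounding=0.30, apex_enlargement=0.0, irregularity=0.0,
        texture_scale=0.8,
    )
    defaults.update(kwargs)
    return pm.GrainTruth(**defaults)


def regular_polygon(n: int, radius: float = 1.0) -> np.ndarray:
    ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return radius * np.column_stack([np.cos(ang), np.sin(ang)])


def random_star_polygon(rng: np.random.Generator, n: int = 24) -> np.ndarray:
    """Random simple (star-shaped) polygon."""
    ang = np.sort(rng.uniform(0.0, 2 * np.pi, n))
    radii = rng.uniform(0.5, 2.0, n)
    return np.column_stack([radii * np.cos(ang), radii * np.sin(ang)])


@pytest.fixture(scope="session")
def polar_cohort():
    """QC'd polar-view calibrated cohort with measurements (t-style)."""
    config = pm.CohortConfig(profiles=dict(COHORT_COUNTS), view_mix=1.0,
                             seed=101)
    features = pm.build_feature_table(config, with_measurements=True)
    kept, report = pm.compactness_filter(features)
    return {"features": features, "kept": kept, "report": report}


@pytest.fixture(scope="session")
def both_cohort():
    """Mixed-view cohort, two-thirds polar, with QC applied."""
    config = pm.CohortConfig(profiles=dict(COHORT_COUNTS), view_mix=2.0 / 3.0,
                             seed=202)
    features = pm.build_feature_table(config, with_measurements=True)
    kept, report = pm.compactness_filter(features)
    return {"features": features, "kept": kept, "report": report}


def _run_cv(kept: pd.DataFrame, feature_set: str, view_set: str,
            seed: int) -> pm.CVReport:
    sub = pm.feature_subset(kept, feature_set, view_set)
    cols = (list(pm.CORE_FEATURE_NAMES) if feature_set == "core7"
            else list(pm.FEATURE_COLUMNS))
    return pm.svm_cv(sub[cols], sub["taxon"],
                     pm.CVConfig(n_iter=99, feature_set=feature_set,
                                 view_set=view_set, seed=seed))


@pytest.fixture(scope="session")
def cv_all50_polar(polar_cohort) -> pm.CVReport:
    """99-iteration all-50-feature SVM on the polar cohort."""
    return _run_cv(polar_cohort["kept"], "all50", "polar_only", seed=11)


@pytest.fixture(scope="session")
def cv_grid_both(both_cohort):
    """The four feature-set x view-set SVM experiments on one cohort."""
    kept = both_cohort["kept"]
    return {
        (fs, vs): _run_cv(kept, fs, vs, seed=13)
        for fs in ("all50", "core7")
        for vs in ("polar_only", "both")
    }
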