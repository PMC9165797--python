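"""End-to-end pipeline driver mirroring the study workflow:
simulate (capture) -> measure -> QC filter -> view split -> ordination -> SVM.

``run_pipeline`` writes every stage's declared outputs into a run directory
and a run-metadata JSON recording the configuration, derived per-stage seeds
and package versions; runs are deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .classify import CVConfig, CVReport, feature_subset, svm_cv
from .cohort import CohortConfig, FEATURE_COLUMNS, build_feature_table
from .errors import PipelineError
from .morphometry import CORE_FEATURE_NAMES
from .ordination import hpd_region_2d, pca, summarize
from .qc import DEFAULT_THRESHOLD, compactness_filter, split_views

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs; round-trips through YAML/JSON."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    qc_threshold: float = DEFAULT_THRESHOLD
    cv_experiments: List[Dict] = field(default_factory=lambda: [
        {"feature_set": "all50", "view_set": "polar_only"},
        {"feature_set": "core7", "view_set": "both"},
    ])
    n_iter: int = 99
    train_frac: float = 0.8
    hpd_mass: float = 0.95

    def to_dict(self) -> dict:
        return {
            "cohort": {
                "profiles": dict(self.cohort.profiles),
                "view_mix": self.cohort.view_mix,
                "seed": self.cohort.seed,
                "pixel_size": self.cohort.pixel_size,
                "n_vertices": self.cohort.n_vertices,
            },
            "qc_threshold": self.qc_threshold,
            "cv_experiments": list(self.cv_experiments),
            "n_iter": self.n_iter,
            "train_frac": self.train_frac,
            "hpd_mass": self.hpd_mass,
        }


@dataclass
class PipelineResult:
    features: pd.DataFrame
    kept: pd.DataFrame
    qc_report: object
    ordination: object
    cv_reports: Dict[str, CVReport]
    size_stats: Dict[str, object]
    run_dir: Optional[Path]


def _stage(name):
    """Wrap stage errors with the stage name for clean failures."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig,
                 out_dir=None) -> PipelineResult:
    """Run simulate -> features -> QC -> split -> PCA/HPD -> SVM end to end."""
    from . import io as pmio

    run_dir = None
    if out_dir is not None:
        run_dir = Path(out_dir)
        run_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.cohort.seed)
    stage_seeds = {name: int(rng.integers(0, 2**31))
                   for name in ("cv", "hpd")}

    with _stage("simulate"):
        features = build_feature_table(config.cohort, with_measurements=True)
    if run_dir is not None:
        pmio.write_feature_csv(features, run_dir / "features.csv")

    with _stage("qc"):
        kept, qc_report = compactness_filter(features, config.qc_threshold)
    if run_dir is not None:
        (run_dir / "qc_report.json").write_text(
            json.dumps(qc_report.to_dict(), indent=2))

    with _stage("split_views"):
        polar, equatorial = split_views(kept, mode="truth")

    with _stage("ordination"):
        ord_table = polar if len(polar) >= 2 else kept
        ordination = pca(ord_table[list(CORE_FEATURE_NAMES)], scale=True)
        hpd_regions = {}
        scores = ordination.scores.iloc[:, :2].to_numpy()
        for taxon in sorted(ord_table["taxon"].unique()):
            pts = scores[(ord_table["taxon"] == taxon).to_numpy()]
            if len(pts) >= 50:
                hpd_regions[taxon] = hpd_region_2d(pts, mass=config.hpd_mass)
    if run_dir is not None:
        ordination.scores.to_csv(run_dir / "pca_scores.csv")
        ordination.loadings.to_csv(run_dir / "pca_loadings.csv")
        pd.Series(ordination.variance_explained,
                  index=ordination.scores.columns,
                  name="variance_explained").to_csv(run_dir / "pca_variance.csv")
        if hpd_regions:
            pmio.hpd_to_geojson(hpd_regions, run_dir / "hpd_regions.geojson")

    with _stage("size_stats"):
        size_stats = {
            taxon: summarize(polar.loc[polar["taxon"] == taxon, "e_protocol"])
            for taxon in sorted(polar["taxon"].unique())
            if (polar["taxon"] == taxon).sum() >= 2 and "e_protocol" in polar
        }
    if run_dir is not None and size_stats:
        (run_dir / "size_stats.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in size_stats.items()}, indent=2))

    cv_reports: Dict[str, CVReport] = {}
    with _stage("svm_cv"):
        if kept["taxon"].nunique() < 2:
            raise PipelineError(
                "stage 'svm_cv' failed: cross-validation needs two taxa, got "
                f"{sorted(kept['taxon'].unique())}"
            )
        for exp in config.cv_experiments:
            cv_config = CVConfig(
                n_iter=config.n_iter, train_frac=config.train_frac,
                feature_set=exp["feature_set"], view_set=exp["view_set"],
                seed=stage_seeds["cv"],
            )
            sub = feature_subset(kept, cv_config.feature_set,
                                 cv_config.view_set)
            cols = (list(CORE_FEATURE_NAMES) if cv_config.feature_set == "core7"
                    else list(FEATURE_COLUMNS))
            report = svm_cv(sub[cols], sub["taxon"], cv_config)
            cv_reports[f"{exp['feature_set']}/{exp['view_set']}"] = report
    if run_dir is not None:
        (run_dir / "cv_reports.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in cv_reports.items()}, indent=2))

    if run_dir is not None:
        config_json = json.dumps(config.to_dict(), sort_keys=True)
        meta = {
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "stage_seeds": stage_seeds,
            "package_version": _pkg_version,
            "python": platform.python_version(),
        }
        (run_dir / "run_meta.json").write_text(json.dumps(meta, indent=2))

    return PipelineResult(
        features=features, kept=kept, qc_report=qc_report,
        ordination=ordination, cv_reports=cv_reports,
        size_stats=size_stats, run_dir=run_dir,
    )
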