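"""Cohort simulation: one-call drivers that mirror the study design
(capture -> measure) on synthetic grains.

A cohort is defined by a mapping of taxon profiles to grain counts, a
polar:equatorial view mix and a seed. ``iter_cohort`` streams
(truth, contour, image) triples so feature extraction never holds the whole
image set in memory; ``build_feature_table`` produces the frozen 50-feature
table (7 core + texture_01..43) plus identity columns; ``simulate_cohort``
additionally writes a manifest CSV with the ground-truth labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import PipelineError
from .morphometry import CORE_FEATURE_NAMES, core_features, max_feret, protocol_equatorial
from .profiles import TaxonProfile, get_preset
from .render import GrainImage, render_image
from .sampling import GrainTruth, sample_truths
from .shapes import Contour, build_contour
from .texture import TEXTURE_FEATURE_NAMES, texture_features

__all__ = [
    "CohortConfig",
    "TEXTURE_COLUMNS",
    "FEATURE_COLUMNS",
    "iter_cohort",
    "build_feature_table",
    "simulate_cohort",
]

#: frozen feature-CSV column order: texture features are published by index
TEXTURE_COLUMNS = tuple(f"texture_{i:02d}" for i in range(1, 44))
FEATURE_COLUMNS = tuple(CORE_FEATURE_NAMES) + TEXTURE_COLUMNS
#: mapping from frozen CSV column to this package's descriptive texture name
TEXTURE_COLUMN_MEANING = dict(zip(TEXTURE_COLUMNS, TEXTURE_FEATURE_NAMES))

_MANIFEST_COLUMNS = (
    "grain_id", "taxon", "view", "e_true", "p_true", "curvature",
    "n_apertures", "apocolpium", "texture_amplitude", "degraded", "seed",
)


@dataclass
class CohortConfig:
    """Configuration of a simulated two-genus (or n-taxon) cohort."""

    profiles: Dict[str, int] = field(
        default_factory=lambda: {"leptospermum": 3000, "kunzea": 1000}
    )
    view_mix: float = 1.0  # proportion of grains in polar view
    seed: int = 0
    pixel_size: float = 0.25  # μm per pixel
    n_vertices: int = 600
    custom_profiles: Dict[str, TaxonProfile] = field(default_factory=dict)

    def resolve_profile(self, name: str) -> TaxonProfile:
        if name in self.custom_profiles:
            return self.custom_profiles[name]
        return get_preset(name)

    def validate(self) -> None:
        if not self.profiles:
            raise PipelineError("cohort config names no profiles")
        for name, n in self.profiles.items():
            if n < 0:
                raise PipelineError(f"profile {name!r}: count must be >= 0")
            self.resolve_profile(name).validate()
        if not 0 <= self.view_mix <= 1:
            raise PipelineError("view_mix must lie in [0, 1]")


def _profile_seeds(config: CohortConfig) -> Dict[str, int]:
    """Derive one independent sub-seed per profile from the cohort seed."""
    rng = np.random.default_rng(config.seed)
    return {name: int(rng.integers(0, 2**31))
            for name in sorted(config.profiles)}


def iter_cohort(config: CohortConfig,
                render: bool = True) -> Iterator[Tuple[GrainTruth, Contour, Optional[GrainImage]]]:
    """Stream (truth, contour, image) for every grain of the cohort.

    Deterministic given ``config.seed``; grains are emitted profile by
    profile in sorted-name order. With ``render=False`` the image slot is
    ``None`` (contour-only workflows).
    """
    config.validate()
    seeds = _profile_seeds(config)
    for name in sorted(config.profiles):
        n = config.profiles[name]
        if n == 0:
            continue
        profile = config.resolve_profile(name)
        truths = sample_truths(profile, n, config.view_mix, seeds[name],
                               id_prefix=name)
        for truth in truths:
            contour = build_contour(truth, config.n_vertices)
            image = render_image(contour, truth, config.pixel_size) if render else None
            yield truth, contour, image


def truth_manifest(truths: List[GrainTruth]) -> pd.DataFrame:
    """Ground-truth manifest table (one row per grain)."""
    rows = []
    for t in truths:
        rows.append({
            "grain_id": t.grain_id,
            "taxon": t.taxon,
            "view": t.view,
            "e_true": t.e_true,
            "p_true": t.p_true,
            "curvature": t.curvature,
            "n_apertures": len(t.aperture_angles),
            "apocolpium": t.apocolpium,
            "texture_amplitude": t.texture_amplitude,
            "degraded": t.degraded,
            "seed": t.seed,
        })
    df = pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)
    if df["grain_id"].duplicated().any():
        dupes = df.loc[df["grain_id"].duplicated(), "grain_id"].tolist()
        raise PipelineError(f"duplicate grain_ids in manifest: {dupes[:5]}")
    return df


def build_feature_table(config: CohortConfig,
                        with_measurements: bool = False) -> pd.DataFrame:
    """Simulate the cohort and extract the full 50-feature table.

    Columns: grain_id, taxon, view, the 7 core features, texture_01..43 and,
    if ``with_measurements``, the manual-protocol E (graticule-rounded) and
    the MFD-vs-E offset. Images are rendered one at a time and discarded.
    """
    rows = []
    for truth, contour, image in iter_cohort(config, render=True):
        row = {"grain_id": truth.grain_id, "taxon": truth.taxon,
               "view": truth.view}
        row.update(core_features(contour))
        tex = texture_features(image)
        row.update({col: tex[name] for col, name
                    in TEXTURE_COLUMN_MEANING.items()})
        if with_measurements:
            e = protocol_equatorial(contour, rounding="graticule")
            row["e_protocol"] = e
            row["mfd_minus_e"] = max_feret(contour) - protocol_equatorial(contour)
        rows.append(row)
    cols = ["grain_id", "taxon", "view", *FEATURE_COLUMNS]
    if with_measurements:
        cols += ["e_protocol", "mfd_minus_e"]
    return pd.DataFrame(rows, columns=cols)


def simulate_cohort(config: CohortConfig, out_dir=None,
                    render: bool = True) -> dict:
    """Run the full cohort simulation; optionally persist to ``out_dir``.

    Returns a dict with the manifest DataFrame, the list of contours, and
    (when rendered) the feature table. When ``out_dir`` is given, writes
    ``manifest.csv``, ``contours.jsonl`` and ``features.csv`` there.
    """
    from . import io as pmio  # local import to avoid a cycle

    truths, contours, rows = [], [], []
    for truth, contour, image in iter_cohort(config, render=render):
        truths.append(truth)
        contours.append(contour)
        if render:
            row = {"grain_id": truth.grain_id, "taxon": truth.taxon,
                   "view": truth.view}
            row.update(core_features(contour))
            tex = texture_features(image)
            row.update({col: tex[name] for col, name
                        in TEXTURE_COLUMN_MEANING.items()})
            rows.append(row)
    manifest = truth_manifest(truths)
    features = None
    if render:
        features = pd.DataFrame(
            rows, columns=["grain_id", "taxon", "view", *FEATURE_COLUMNS]
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(out / "manifest.csv", index=False)
        pmio.write_contours_jsonl(contours, out / "contours.jsonl")
        if features is not None:
            pmio.write_feature_csv(features, out / "features.csv")
    return {"manifest": manifest, "contours": contours, "features": features}
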