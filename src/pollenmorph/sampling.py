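"""Sampling of per-grain ground truth from a taxon profile."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .errors import ProfileError
from .profiles import TaxonProfile
from .shapes import curvature_bounds

__all__ = ["GrainTruth", "sample_truths"]

_TWO_PI = 2.0 * math.pi
_MIN_DIAMETER = 5.0  # μm; size distributions are truncated below this


@dataclass(frozen=True)
class GrainTruth:
    """Realized ground truth for a single simulated grain."""

    grain_id: str
    taxon: str
    view: str  # "polar" | "equatorial"
    e_true: float  # μm, protocol equatorial diameter
    p_true: float  # μm, polar diameter (drawn for all grains)
    curvature: float  # amb-side sagitta / side length
    aperture_angles: tuple  # radians, one per aperture
    apocolpium: bool
    texture_amplitude: float
    degraded: bool
    seed: int
    apex_rounding: float = 0.30
    apex_enlargement: float = 0.0
    irregularity: float = 0.015
    texture_scale: float = 0.8


def sample_truths(
    profile: TaxonProfile,
    n: int,
    view_mix: float = 1.0,
    seed: Optional[int] = None,
    id_prefix: Optional[str] = None,
) -> List[GrainTruth]:
    """Draw ``n`` grain truths from a profile, fully reproducible from ``seed``.

    ``view_mix`` is the proportion of grains in polar view (each grain's view
    is an independent Bernoulli draw). E is Normal(e_mean, e_sd) truncated at
    > 5 μm; P is truncated to (5 μm, E) so grains are oblate. Aperture counts,
    apocolpia, texture amplitudes and degraded flags follow the profile.
    """
    profile.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= view_mix <= 1.0:
        raise ValueError("view_mix must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else profile.name

    counts = sorted(profile.aperture_probs)
    probs = np.array([profile.aperture_probs[c] for c in counts], dtype=float)
    c_lo, c_hi = curvature_bounds(profile.apex_rounding, 3)

    truths: List[GrainTruth] = []
    for i in range(n):
        view = "polar" if rng.random() < view_mix else "equatorial"
        e = _trunc_normal(rng, profile.e_mean, profile.e_sd, _MIN_DIAMETER)
        p = _trunc_normal(rng, profile.p_mean, profile.p_sd, _MIN_DIAMETER,
                          upper=e)
        curvature = float(
            np.clip(rng.normal(profile.curvature_mean, profile.curvature_sd),
                    c_lo, c_hi)
        )
        k = int(rng.choice(counts, p=probs))
        # clip 2- and 4-aperturate curvature bounds separately
        if k != 3 and view == "polar" and k >= 3:
            b_lo, b_hi = curvature_bounds(profile.apex_rounding, k)
            curvature = float(np.clip(curvature, b_lo, b_hi))
        theta0 = rng.uniform(0.0, _TWO_PI / k)
        angles = tuple(
            (math.pi / 2.0 + theta0 + _TWO_PI * j / k) % _TWO_PI
            for j in range(k)
        )
        apocolpium = bool(rng.random() < profile.parasyncolpate_prob)
        amp = max(0.0, float(rng.normal(profile.texture_amplitude,
                                        profile.texture_amplitude_sd)))
        degraded = bool(rng.random() < profile.degraded_fraction)
        grain_seed = int(rng.integers(0, 2**31))
        truths.append(
            GrainTruth(
                grain_id=f"{prefix}-{i:05d}",
                taxon=profile.name,
                view=view,
                e_true=float(e),
                p_true=float(p),
                curvature=curvature,
                aperture_angles=angles,
                apocolpium=apocolpium,
                texture_amplitude=amp,
                degraded=degraded,
                seed=grain_seed,
                apex_rounding=profile.apex_rounding,
                apex_enlargement=profile.apex_enlargement,
                irregularity=profile.irregularity,
                texture_scale=profile.texture_scale,
            )
        )
    return truths


def _trunc_normal(rng, mean, sd, lower, upper=None, max_tries=1000) -> float:
    """Rejection-sample Normal(mean, sd) restricted to (lower, upper)."""
    if sd == 0:
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if x > lower and (upper is None or x < upper):
            return x
    raise ProfileError(
        f"size distribution Normal({mean}, {sd}) incompatible with bounds "
        f"({lower}, {upper})"
    )
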