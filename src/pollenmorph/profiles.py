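"""Distributional recipes for pollen taxa.

A :class:`TaxonProfile` captures everything the synthetic generator needs to
emulate one genus or morphotype: the equatorial (E) and polar (P) diameter
distributions measured under the light microscope, the amb-side curvature
(concave / straight / convex outline in polar view), apex rounding, aperture
count probabilities, exine texture contrast (scabrate vs psilate), and the
fraction of degraded (poorly focused) grains.

Size parameters for the two genus presets are the published light-microscope
measurements: *Leptospermum scoparium* s.l. E = 19.08 ± 1.28 μm (n = 490),
P = 12.98 ± 1.66 μm; *Kunzea* spp. E = 16.30 ± 0.95 μm (n = 318),
P = 11.28 ± 2.33 μm. Curvature, texture contrast and boundary irregularity
are not quantified by light microscopy; the preset values are calibration
choices (see docs/methods.md) fixed so that the downstream morphometric
contrasts (compactness/solidity separation, scabrate-vs-psilate intensity
contrast, MFD-vs-E offset band) are realistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping

from .errors import ProfileError

__all__ = [
    "TaxonProfile",
    "GENUS_PRESETS",
    "MORPHOTYPE_PRESETS",
    "get_preset",
    "list_presets",
]

#: Default probabilities of 2-, 3- and 4-aperturate grains
#: ("tricolporate ... very rarely di- or tetracolporate").
DEFAULT_APERTURE_PROBS: Mapping[int, float] = {2: 0.005, 3: 0.99, 4: 0.005}


@dataclass(frozen=True)
class TaxonProfile:
    """Distributional recipe for one genus or morphotype.

    Parameters
    ----------
    e_mean, e_sd : float
        Equatorial diameter distribution in μm (measured in polar view).
    p_mean, p_sd : float
        Polar diameter distribution in μm (measured in equatorial view).
    curvature_mean, curvature_sd : float
        Amb-side curvature: the sagitta of each side arc as a fraction of the
        side length. Negative is concave, zero straight, positive convex.
    apex_rounding : float
        Apex fillet radius as a fraction of the amb circumradius, in (0, 0.5].
    apex_enlargement : float
        Relative radial enlargement of the apices (>= 0).
    aperture_probs : mapping
        Probability of each aperture count in {2, 3, 4}; must sum to 1.
    parasyncolpate_prob : float
        Probability of a small apocolpium (polar island) being visible.
    texture_amplitude : float
        Mean relative s.d. of the interior speckle intensity (scabrate > psilate).
    texture_amplitude_sd : float
        Grain-to-grain s.d. of the texture amplitude.
    texture_scale : float
        Speckle correlation length in μm.
    irregularity : float
        Relative amplitude of smooth low-order radial boundary irregularity.
    degraded_fraction : float
        Probability that a grain is degraded (poor focus / ragged outline).
    """

    name: str
    e_mean: float
    e_sd: float
    p_mean: float
    p_sd: float
    curvature_mean: float = 0.0
    curvature_sd: float = 0.015
    apex_rounding: float = 0.30
    apex_enlargement: float = 0.0
    aperture_probs: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_APERTURE_PROBS)
    )
    parasyncolpate_prob: float = 0.0
    texture_amplitude: float = 0.06
    texture_amplitude_sd: float = 0.0
    texture_scale: float = 0.8
    irregularity: float = 0.015
    degraded_fraction: float = 0.048

    def validate(self) -> None:
        """Raise :class:`ProfileError` naming the first invalid field."""
        if not self.name:
            raise ProfileError("name: must be a non-empty label")
        for fname in ("e_sd", "p_sd"):
            if getattr(self, fname) <= 0:
                raise ProfileError(f"{fname}: must be > 0")
        for fname in ("e_mean", "p_mean", "texture_scale"):
            if getattr(self, fname) <= 0:
                raise ProfileError(f"{fname}: must be > 0")
        if not -0.5 < self.curvature_mean < 0.5:
            raise ProfileError("curvature_mean: must lie in (-0.5, 0.5)")
        if self.curvature_sd < 0:
            raise ProfileError("curvature_sd: must be >= 0")
        if not 0 < self.apex_rounding <= 0.5:
            raise ProfileError("apex_rounding: must lie in (0, 0.5]")
        if self.apex_enlargement < 0:
            raise ProfileError("apex_enlargement: must be >= 0")
        probs = dict(self.aperture_probs)
        if set(probs) - {2, 3, 4}:
            raise ProfileError("aperture_probs: keys must be in {2, 3, 4}")
        if any(p < 0 for p in probs.values()):
            raise ProfileError("aperture_probs: probabilities must be >= 0")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ProfileError("aperture_probs: must sum to 1 within 1e-9")
        if not 0 <= self.parasyncolpate_prob <= 1:
            raise ProfileError("parasyncolpate_prob: must lie in [0, 1]")
        if self.texture_amplitude < 0:
            raise ProfileError("texture_amplitude: must be >= 0")
        if self.texture_amplitude_sd < 0:
            raise ProfileError("texture_amplitude_sd: must be >= 0")
        if self.irregularity < 0:
            raise ProfileError("irregularity: must be >= 0")
        if not 0 <= self.degraded_fraction <= 1:
            raise ProfileError("degraded_fraction: must lie in [0, 1]")

    def with_(self, **kwargs) -> "TaxonProfile":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


# -- genus presets -----------------------------------------------------------
# Size: published LM measurements. Curvature: Leptospermum amb "often concave",
# Kunzea "slightly concave or straight, to slightly convex". Texture:
# Leptospermum scabrate (flecked under LM), Kunzea psilate. Apocolpia: Kunzea
# "more often ... slightly parasyncolpate". degraded_fraction 0.048 matches the
# study's discard rate (1190 of 24892 captures). Calibrated (non-size) values
# are documented in docs/methods.md.

LEPTOSPERMUM = TaxonProfile(
    name="leptospermum",
    e_mean=19.08,
    e_sd=1.28,
    p_mean=12.98,
    p_sd=1.66,
    curvature_mean=-0.055,
    curvature_sd=0.014,
    apex_rounding=0.30,
    apex_enlargement=0.02,
    parasyncolpate_prob=0.02,
    texture_amplitude=0.120,
    texture_amplitude_sd=0.042,
    texture_scale=0.8,
    irregularity=0.036,
    degraded_fraction=0.048,
)

KUNZEA = TaxonProfile(
    name="kunzea",
    e_mean=16.30,
    e_sd=0.95,
    p_mean=11.28,
    p_sd=2.33,
    curvature_mean=0.012,
    curvature_sd=0.014,
    apex_rounding=0.30,
    apex_enlargement=0.0,
    parasyncolpate_prob=0.50,
    texture_amplitude=0.040,
    texture_amplitude_sd=0.032,
    texture_scale=0.8,
    irregularity=0.058,
    degraded_fraction=0.048,
)

GENUS_PRESETS: Dict[str, TaxonProfile] = {
    "leptospermum": LEPTOSPERMUM,
    "kunzea": KUNZEA,
}

# -- morphotype / species presets --------------------------------------------
# E/P averages and ranges from the visual-observation tables; the s.d. is
# approximated as range/4 (the ranges span roughly +/- 2 s.d.). Shape and
# texture fields inherit the genus preset.


def _morph(base: TaxonProfile, name: str, e_avg, e_rng, p_avg, p_rng,
           **kwargs) -> TaxonProfile:
    return base.with_(
        name=name,
        e_mean=e_avg,
        e_sd=max((e_rng[1] - e_rng[0]) / 4.0, 0.05),
        p_mean=p_avg,
        p_sd=max((p_rng[1] - p_rng[0]) / 4.0, 0.05),
        **kwargs,
    )


MORPHOTYPE_PRESETS: Dict[str, TaxonProfile] = {
    p.name: p
    for p in [
        # Leptospermum scoparium s.l. morphotypes
        _morph(LEPTOSPERMUM, "otaipango", 19.2, (17.0, 20.8), 14.4, (12.1, 16.0),
               curvature_mean=-0.01),
        _morph(LEPTOSPERMUM, "papa", 19.0, (15.9, 20.9), 11.6, (10.6, 13.0)),
        _morph(LEPTOSPERMUM, "wellington", 17.9, (15.7, 20.4), 11.5, (10.3, 12.6)),
        _morph(LEPTOSPERMUM, "northern_south_island", 19.1, (18.0, 20.9), 14.2, (13.1, 15.3)),
        _morph(LEPTOSPERMUM, "southern_south_island", 19.1, (18.4, 21.6), 14.1, (12.9, 16.4)),
        _morph(LEPTOSPERMUM, "three_kings", 20.0, (18.2, 21.3), 10.3, (9.3, 12.1),
               curvature_mean=-0.01),
        _morph(LEPTOSPERMUM, "east_cape", 18.1, (16.0, 20.7), 11.6, (10.0, 13.1),
               curvature_mean=-0.06),
        _morph(LEPTOSPERMUM, "flat_silver", 19.0, (16.9, 20.3), 13.4, (12.7, 14.1),
               curvature_mean=-0.06),
        _morph(LEPTOSPERMUM, "surville_cliffs", 20.6, (18.2, 22.1), 13.6, (13.1, 15.1),
               curvature_mean=-0.07),
        _morph(LEPTOSPERMUM, "central_volcanic_plateau", 18.5, (16.6, 20.1), 13.0, (11.1, 14.3)),
        _morph(LEPTOSPERMUM, "incanum", 19.4, (17.3, 21.9), 16.0, (13.5, 17.5)),
        _morph(LEPTOSPERMUM, "south_island_mountain", 19.8, (17.9, 22.2), 14.0, (12.6, 15.8)),
        _morph(LEPTOSPERMUM, "waikato_peat_bog", 18.6, (16.5, 20.1), 13.4, (12.7, 14.3),
               aperture_probs={2: 0.005, 3: 0.965, 4: 0.03}),
        _morph(LEPTOSPERMUM, "auckland", 18.8, (16.0, 22.4), 11.7, (10.7, 13.1)),
        _morph(LEPTOSPERMUM, "coromandel_swamp", 18.3, (17.1, 20.3), 14.3, (12.8, 16.1),
               aperture_probs={2: 0.005, 3: 0.965, 4: 0.03}),
        # Kunzea species
        _morph(KUNZEA, "k_toelkenii", 17.8, (15.2, 20.0), 10.0, (9.4, 10.6),
               curvature_mean=-0.02, apex_enlargement=0.02),
        _morph(KUNZEA, "k_linearis", 16.9, (16.3, 17.5), 10.5, (10.0, 10.6),
               curvature_mean=-0.02),
        _morph(KUNZEA, "k_amathicola", 16.8, (15.6, 18.1), 9.6, (8.8, 11.3),
               curvature_mean=-0.02),
        _morph(KUNZEA, "k_triregensis", 16.7, (15.2, 17.6), 9.1, (8.8, 10.0),
               curvature_mean=0.03),
        _morph(KUNZEA, "k_tenuicaulis", 16.1, (15.0, 16.9), 9.6, (8.8, 10.6),
               curvature_mean=0.0),
        _morph(KUNZEA, "k_robusta", 16.0, (15.0, 17.5), 9.9, (9.4, 10.6),
               curvature_mean=-0.02),
        _morph(KUNZEA, "k_ericoides", 16.6, (14.4, 18.1), 10.2, (9.4, 11.3),
               curvature_mean=-0.02),
        _morph(KUNZEA, "k_sinclairii", 16.2, (15.2, 17.6), 9.7, (8.8, 10.0),
               curvature_mean=-0.04),
        _morph(KUNZEA, "k_salterae", 15.4, (14.4, 16.8), 9.8, (9.4, 10.6),
               curvature_mean=0.0),
        _morph(KUNZEA, "k_serotina", 15.0, (13.8, 16.3), 9.4, (8.8, 10.6),
               curvature_mean=-0.02),
    ]
}

_ALL_PRESETS: Dict[str, TaxonProfile] = {**GENUS_PRESETS, **MORPHOTYPE_PRESETS}


def get_preset(name: str) -> TaxonProfile:
    """Return a shipped profile by name (genus or morphotype)."""
    try:
        return _ALL_PRESETS[name]
    except KeyError:
        raise ProfileError(
            f"unknown preset {name!r}; available: {sorted(_ALL_PRESETS)}"
        ) from None


def list_presets() -> list:
    """Names of all shipped presets."""
    return sorted(_ALL_PRESETS)
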