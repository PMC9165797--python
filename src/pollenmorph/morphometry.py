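"""Shape morphometry: the 7 core Classifynder-style features and the manual
light-microscope measurement protocol (E and P).

Core feature definitions (fixed; the instrument's own definitions are
unpublished, these follow standard particle-shape usage):

- ``area``             polygon area (shoelace), μm²
- ``max_feret``        maximum Feret diameter: max projection extent over all
                       directions = maximum pairwise vertex distance, μm
- ``elongation``       max Feret / min Feret (>= 1)
- ``compactness``      4π·area / perimeter² (circle = 1; ragged outline << 1)
- ``convex_hull``      solidity: area / convex-hull area (convex shape = 1)
- ``heywood``          Heywood circularity: perimeter / perimeter of the
                       equal-area circle = perimeter / (2·sqrt(π·area)) (>= 1)
- ``hydraulic_radius`` area / perimeter, μm

By these definitions compactness × heywood² = 1 identically.

The manual protocol mirrors measurement through an eyepiece graticule: E is
the maximum extent perpendicular to a line from the grain centre through an
aperture midpoint (maximized over apertures); P is the extent along the polar
axis of an equatorial-view grain. One graticule division is 0.625 μm and
readings are to the nearest half division, so graticule rounding quantizes to
multiples of 0.3125 μm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull

from .errors import ContourError, FeatureError
from .shapes import Contour, direction_extent, perpendicular_extent

__all__ = [
    "CORE_FEATURE_NAMES",
    "GRATICULE_QUANTUM",
    "MeasurementRecord",
    "area_perimeter",
    "max_feret",
    "min_feret",
    "core_features",
    "protocol_equatorial",
    "protocol_polar",
    "measure_record",
]

#: fixed order of the 7 core features in feature vectors and CSVs
CORE_FEATURE_NAMES = (
    "area",
    "max_feret",
    "elongation",
    "compactness",
    "convex_hull",
    "heywood",
    "hydraulic_radius",
)

#: half of one 0.625 μm eyepiece graticule division
GRATICULE_QUANTUM = 0.3125


@dataclass(frozen=True)
class MeasurementRecord:
    """Manual-protocol measurements for one grain."""

    grain_id: Optional[str]
    e_protocol: float  # μm (E)
    p_protocol: Optional[float]  # μm (P); absent for polar-view grains
    max_feret: float  # μm (MFD)
    rounding: str  # "none" | "graticule"


def _vertices(contour) -> np.ndarray:
    if isinstance(contour, Contour):
        return contour.vertices
    v = np.asarray(contour, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ContourError("expected a Contour or an (n, 2) vertex array")
    return v


def area_perimeter(contour) -> Tuple[float, float]:
    """Shoelace area (absolute) and perimeter of a simple polygon."""
    v = _vertices(contour)
    if len(v) < 3:
        raise ContourError("polygon needs >= 3 vertices")
    if isinstance(contour, Contour):
        if not contour.as_polygon().is_simple:
            raise ContourError("self-intersecting polygon")
    x, y = v[:, 0], v[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    perim = float(np.linalg.norm(np.diff(np.vstack([v, v[:1]]), axis=0), axis=1).sum())
    return area, perim


def _hull_points(v: np.ndarray) -> np.ndarray:
    if len(v) < 3:
        return v
    try:
        hull = ConvexHull(v)
    except Exception as exc:  # degenerate (collinear) input
        raise ContourError(f"convex hull failed: {exc}") from exc
    return v[hull.vertices]


def max_feret(contour) -> float:
    """Maximum Feret diameter = maximum pairwise vertex distance."""
    v = _vertices(contour)
    if len(v) < 3:
        raise ContourError("polygon needs >= 3 vertices")
    h = _hull_points(v)
    d2 = ((h[:, None, :] - h[None, :, :]) ** 2).sum(axis=2)
    return float(math.sqrt(d2.max()))


def min_feret(contour) -> float:
    """Minimum Feret diameter (minimum width over directions).

    Exact for polygons: the minimum width of the convex hull is attained with
    one side of the hull flush against a caliper jaw, so it is the minimum
    over hull edges of the farthest vertex distance to the edge line.
    """
    v = _vertices(contour)
    h = _hull_points(v)
    n = len(h)
    if n < 3:
        raise ContourError("degenerate polygon")
    best = math.inf
    for i in range(n):
        p, q = h[i], h[(i + 1) % n]
        edge = q - p
        norm = np.linalg.norm(edge)
        if norm < 1e-12:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        width = float(np.abs((h - p) @ normal).max())
        best = min(best, width)
    return best


def core_features(contour) -> dict:
    """The 7 core shape/size features of a contour, as an ordered dict."""
    area, perim = area_perimeter(contour)
    if area <= 0:
        raise FeatureError("zero-area contour")
    v = _vertices(contour)
    hull = _hull_points(v)
    hull_area, _ = area_perimeter(hull)
    mf = max_feret(contour)
    mnf = min_feret(contour)
    return {
        "area": area,
        "max_feret": mf,
        "elongation": mf / mnf,
        "compactness": 4.0 * math.pi * area / perim**2,
        "convex_hull": area / hull_area,
        "heywood": perim / (2.0 * math.sqrt(math.pi * area)),
        "hydraulic_radius": area / perim,
    }


def _quantize(x: float, rounding: str) -> float:
    if rounding == "graticule":
        return round(x / GRATICULE_QUANTUM) * GRATICULE_QUANTUM
    if rounding == "none":
        return x
    raise ValueError(f"unknown rounding mode {rounding!r}")


def protocol_equatorial(contour, aperture_angles=None, rounding: str = "none",
                        aperture_rule: str = "first") -> float:
    """Manual-protocol equatorial diameter E.

    E is the maximum dimension of the outline along a line at right angles to
    the line from the grain centre through the midpoint of one aperture. With
    ``aperture_rule="first"`` (default) the measurement uses the first listed
    aperture, mirroring a palynologist reading against a single aperture; with
    ``"max"`` the maximum over all apertures is returned. Either way E <= the
    maximum Feret diameter.
    """
    v = _vertices(contour)
    if aperture_angles is None and isinstance(contour, Contour):
        aperture_angles = contour.aperture_angles
    angles = np.atleast_1d(aperture_angles) if aperture_angles is not None else None
    if angles is None or angles.size == 0:
        raise FeatureError("protocol E requires at least one aperture angle")
    if aperture_rule == "first":
        e = perpendicular_extent(v, float(angles[0]))
    elif aperture_rule == "max":
        e = max(perpendicular_extent(v, float(a)) for a in angles)
    else:
        raise ValueError(f"unknown aperture_rule {aperture_rule!r}")
    return _quantize(e, rounding)


def protocol_polar(contour, view: Optional[str] = None,
                   rounding: str = "none") -> float:
    """Manual-protocol polar diameter P (equatorial-view grains only).

    P is the extent along the grain's polar axis — in an equatorial view the
    colpi converge on the poles, so the axis is read from the first aperture
    angle. Without aperture metadata the minimum Feret extent (short axis of
    the flattened oval) is used instead.
    """
    if view is None and isinstance(contour, Contour):
        view = contour.view
    if view != "equatorial":
        raise FeatureError("polar diameter can be measured only in equatorial views")
    angles = getattr(contour, "aperture_angles", None)
    if angles is not None and len(np.atleast_1d(angles)) > 0:
        a = float(np.atleast_1d(angles)[0])
        p = direction_extent(_vertices(contour), (math.cos(a), math.sin(a)))
    else:
        p = min_feret(contour)
    return _quantize(p, rounding)


def measure_record(contour, rounding: str = "none") -> MeasurementRecord:
    """Full manual measurement of one contour (E, P if equatorial, MFD)."""
    e = protocol_equatorial(contour, rounding=rounding)
    p = None
    if isinstance(contour, Contour) and contour.view == "equatorial":
        p = protocol_polar(contour, rounding=rounding)
    return MeasurementRecord(
        grain_id=getattr(contour, "grain_id", None),
        e_protocol=e,
        p_protocol=p,
        max_feret=max_feret(contour),
        rounding=rounding,
    )
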