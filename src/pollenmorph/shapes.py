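"""Grain outline construction.

Polar-view pollen grains of *Leptospermum* and *Kunzea* are triangular
(angulaperturate): the amb is modelled as a k-fold symmetric polygon
(k = aperture count, normally 3) whose sides are circular arcs with
sagitta = curvature x side length (negative sagitta = concave side) and whose
apices are circular fillets of radius apex_rounding x circumradius, tangent to
the adjacent side arcs. Equatorial-view grains are flattened ovals with width
e_true and height p_true. A smooth low-order random radial field models
biological boundary irregularity; degraded (poor-focus) grains additionally
receive a high-frequency ragged boundary that inflates the perimeter and hence
depresses compactness below the QC threshold.

All contours are in micrometres, origin at the grain centroid, vertices
ordered counter-clockwise, implicitly closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import shapely.geometry as sgeom

from .errors import ContourError

__all__ = ["Contour", "build_contour", "curvature_bounds"]

#: total relative s.d. of the high-frequency boundary raggedness added to
#: degraded grains (calibrated so measured compactness < 0.55 w.p. >= 0.9).
DEGRADED_BOUNDARY_SD = 0.055
#: harmonic range of the degraded raggedness field.
_DEGRADED_HARMONICS = (16, 40)
#: harmonic range of the healthy-grain irregularity field.
_IRREGULARITY_HARMONICS = (2, 8)
#: equatorial-view grains lie on their side and roll into oblique poses, so
#: their apparent outline carries extra pose-driven noise (added in
#: quadrature, the same for every taxon) on top of the wall irregularity
EQUATORIAL_POSE_IRREGULARITY = 0.05

_TWO_PI = 2.0 * math.pi


@dataclass
class Contour:
    """A grain's closed outline in μm, origin at the grain centroid.

    ``vertices`` is an (n, 2) array ordered counter-clockwise; the polygon is
    implicitly closed (last vertex connects back to the first).
    """

    vertices: np.ndarray
    grain_id: Optional[str] = None
    taxon: Optional[str] = None
    view: Optional[str] = None
    aperture_angles: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ContourError("vertices must be an (n, 2) array")
        if _signed_area(self.vertices) < 0:
            self.vertices = self.vertices[::-1].copy()
        if self.aperture_angles is not None:
            self.aperture_angles = np.asarray(self.aperture_angles, dtype=float)

    # -- geometry helpers ----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def signed_area(self) -> float:
        return _signed_area(self.vertices)

    def centroid(self) -> np.ndarray:
        return _polygon_centroid(self.vertices)

    def as_polygon(self) -> sgeom.Polygon:
        return sgeom.Polygon(self.vertices)

    def validate(self) -> None:
        """Check the contour invariants, raising :class:`ContourError`."""
        if self.n_vertices < 24:
            raise ContourError(f"contour has {self.n_vertices} < 24 vertices")
        area = self.signed_area()
        if area <= 0:
            raise ContourError("contour encloses non-positive area")
        if not self.as_polygon().is_simple:
            raise ContourError("contour is self-intersecting")

    def transformed(self, *, rotate: float = 0.0, scale: float = 1.0) -> "Contour":
        """Rigidly rotated (radians, about the centroid) and/or scaled copy."""
        v = self.vertices - self.centroid()
        if rotate:
            c, s = math.cos(rotate), math.sin(rotate)
            v = v @ np.array([[c, s], [-s, c]])
        v = v * scale
        ap = None
        if self.aperture_angles is not None:
            ap = (self.aperture_angles + rotate) % _TWO_PI
        return Contour(v, grain_id=self.grain_id, taxon=self.taxon,
                       view=self.view, aperture_angles=ap)


# -- low-level polygon utilities ----------------------------------------------

def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polygon_centroid(v: np.ndarray) -> np.ndarray:
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return v.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def direction_extent(vertices: np.ndarray, direction: Sequence[float]) -> float:
    """Feret extent of a polygon along a unit direction."""
    proj = vertices @ np.asarray(direction, dtype=float)
    return float(proj.max() - proj.min())


def perpendicular_extent(vertices: np.ndarray, angle: float) -> float:
    """Extent along the direction perpendicular to ``angle`` (radians)."""
    d = (-math.sin(angle), math.cos(angle))
    return direction_extent(vertices, d)


def resample_closed(vertices: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` points uniformly by arc length."""
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ContourError("degenerate (zero-length) contour")
    target = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


# -- rounded-amb construction --------------------------------------------------

def _wrap_pi(a: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    a = (a + math.pi) % _TWO_PI - math.pi
    return math.pi if a == -math.pi else a


def _arc_points(center, radius, p0, p1, n) -> np.ndarray:
    """Sample the short arc of the circle (center, radius) from p0 to p1."""
    a0 = math.atan2(p0[1] - center[1], p0[0] - center[0])
    a1 = math.atan2(p1[1] - center[1], p1[0] - center[0])
    delta = _wrap_pi(a1 - a0)
    ang = a0 + delta * np.linspace(0.0, 1.0, n)
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )


def _rounded_amb(k: int, curvature: float, apex_rounding: float,
                 points_per_side: int = 80) -> np.ndarray:
    """Canonical k-fold rounded amb with circumradius 1, first apex at +y.

    Sides are circular arcs with sagitta = curvature x side length; apices are
    fillet arcs of radius ``apex_rounding`` tangent to the adjacent sides.
    """
    if k < 3:
        raise ContourError("rounded amb requires >= 3 apertures")
    if not -0.5 < curvature < 0.5:
        raise ContourError(
            f"curvature {curvature:.3f} outside (-0.5, 0.5): shape degenerates"
        )
    if apex_rounding <= 0:
        raise ContourError("apex_rounding must be > 0")

    ck, sk = math.cos(math.pi / k), math.sin(math.pi / k)
    inradius = ck
    side = 2.0 * sk
    rho = apex_rounding
    sag = curvature * side

    theta_v = math.pi / 2.0 + _TWO_PI * np.arange(k) / k  # vertex angles, CCW

    if abs(sag) < 1e-9:
        t = (inradius - rho) / ck
        side_geom = ("straight", None, None)
    else:
        r_arc = side * side / (8.0 * abs(sag)) + abs(sag) / 2.0
        m = inradius + sag - math.copysign(r_arc, sag)
        if sag > 0:
            if rho >= r_arc:
                raise ContourError(
                    "apex fillet radius exceeds convex side-arc radius"
                )
            d = r_arc - rho
            disc = d * d - m * m * sk * sk
            if disc <= 0:
                raise ContourError("apex fillet does not fit convex amb")
            t = m * ck + math.sqrt(disc)
        else:
            d = r_arc + rho
            disc = d * d - m * m * sk * sk
            if disc <= 0:
                raise ContourError("apex fillet does not fit concave amb")
            t = m * ck - math.sqrt(disc)
        side_geom = ("arc", r_arc, m)
    if t <= 1e-6:
        raise ContourError(
            "amb curvature/apex rounding combination is degenerate "
            f"(curvature={curvature:.3f}, apex_rounding={apex_rounding:.3f})"
        )

    fillet_centers = t * np.column_stack([np.cos(theta_v), np.sin(theta_v)])

    def tangent_point(j_side: int, c_fillet: np.ndarray) -> np.ndarray:
        psi = theta_v[j_side] + math.pi / k  # mid-side direction
        u = np.array([math.cos(psi), math.sin(psi)])
        kind, r_arc, m = side_geom
        if kind == "straight":
            return c_fillet + rho * u
        o = m * u
        w = c_fillet - o
        return o + r_arc * w / np.linalg.norm(w)

    pieces = []
    n_apex = max(8, points_per_side // 2)
    for j in range(k):
        # apex fillet at vertex j: from the tangent with side j-1 to side j
        c = fillet_centers[j]
        t_in = tangent_point((j - 1) % k, c)
        t_out = tangent_point(j, c)
        pieces.append(_arc_points(c, rho, t_in, t_out, n_apex)[:-1])
        # side j: from this apex's tangent to the next apex's tangent
        t_next = tangent_point(j, fillet_centers[(j + 1) % k])
        kind, r_arc, m = side_geom
        if kind == "straight":
            frac = np.linspace(0.0, 1.0, points_per_side)[:-1, None]
            pieces.append(t_out[None, :] * (1 - frac) + t_next[None, :] * frac)
        else:
            psi = theta_v[j] + math.pi / k
            o = m * np.array([math.cos(psi), math.sin(psi)])
            pieces.append(_arc_points(o, r_arc, t_out, t_next, points_per_side)[:-1])
    verts = np.vstack(pieces)
    if _signed_area(verts) <= 0 or not sgeom.Polygon(verts).is_simple:
        raise ContourError(
            "amb curvature/apex rounding combination is degenerate "
            f"(curvature={curvature:.3f}, apex_rounding={apex_rounding:.3f})"
        )
    return verts


@lru_cache(maxsize=None)
def curvature_bounds(apex_rounding: float, k: int = 3) -> tuple:
    """Feasible (lo, hi) amb curvature for a given apex rounding.

    Found by bisection on the success of the fillet construction; used to clip
    sampled per-grain curvatures so that every grain has a valid outline.
    """

    def ok(c: float) -> bool:
        try:
            v = _rounded_amb(k, c, apex_rounding)
        except ContourError:
            return False
        return sgeom.Polygon(v).is_simple

    lo_bad, lo_good = -0.499, 0.0
    for _ in range(40):
        mid = 0.5 * (lo_bad + lo_good)
        if ok(mid):
            lo_good = mid
        else:
            lo_bad = mid
    hi_good, hi_bad = 0.0, 0.499
    for _ in range(40):
        mid = 0.5 * (hi_good + hi_bad)
        if ok(mid):
            hi_good = mid
        else:
            hi_bad = mid
    # keep a safety margin away from the exact degeneracy
    return (0.9 * lo_good, 0.9 * hi_good)


# -- random boundary fields ------------------------------------------------------

def _radial_field(theta: np.ndarray, rng: np.random.Generator,
                  harmonics: tuple, total_sd: float,
                  spectrum: str = "red") -> np.ndarray:
    """Zero-mean random radial perturbation field evaluated at ``theta``.

    ``spectrum='red'`` weights harmonic h by 1/h (smooth, low order);
    ``'flat'`` weights all harmonics equally (ragged, high frequency).
    """
    h_lo, h_hi = harmonics
    hs = np.arange(h_lo, h_hi + 1)
    w = 1.0 / hs if spectrum == "red" else np.ones_like(hs, dtype=float)
    # each harmonic contributes (a^2+b^2)/2 with a,b ~ N(0, sigma_h^2)
    sigma = total_sd * w / math.sqrt(float((w * w).sum()))
    a = rng.normal(0.0, sigma)
    b = rng.normal(0.0, sigma)
    ang = np.outer(theta, hs)
    return np.cos(ang) @ a + np.sin(ang) @ b


def _apply_radial(vertices: np.ndarray, factor_of_theta) -> np.ndarray:
    theta = np.arctan2(vertices[:, 1], vertices[:, 0])
    r = np.linalg.norm(vertices, axis=1)
    r2 = r * factor_of_theta(theta)
    return np.column_stack([r2 * np.cos(theta), r2 * np.sin(theta)])


def _apex_bump(theta: np.ndarray, k: int, theta0: float,
               enlargement: float) -> np.ndarray:
    """Smooth radial enlargement peaked at the k apex angles."""
    return 1.0 + enlargement * (0.5 + 0.5 * np.cos(k * (theta - theta0))) ** 4


# -- public construction --------------------------------------------------------

def build_contour(truth, n_vertices: int = 600) -> Contour:
    """Build a grain outline from a :class:`~pollenmorph.sampling.GrainTruth`.

    Polar view: k-fold rounded amb scaled so the measurement-protocol
    equatorial diameter equals ``e_true``. Equatorial view: flattened oval of
    width ``e_true`` and height ``p_true``. Boundary irregularity and (for
    degraded grains) high-frequency raggedness are reproducible from
    ``truth.seed``.
    """
    if n_vertices < 24:
        raise ContourError("n_vertices must be >= 24")
    rng = np.random.default_rng(truth.seed)
    ap = np.asarray(truth.aperture_angles, dtype=float)
    if ap.size < 1:
        raise ContourError("truth has no aperture angles")
    k = ap.size
    theta0 = float(ap[0]) - math.pi / 2.0

    if truth.view == "polar":
        if k >= 3:
            verts = _rounded_amb(k, truth.curvature, truth.apex_rounding)
        else:
            # dicolporate: gently flattened oval, apertures at the short axis
            ang = np.linspace(0.0, _TWO_PI, 360, endpoint=False)
            verts = np.column_stack([np.cos(ang), 0.85 * np.sin(ang)])
        verts = resample_closed(verts, n_vertices)
        if truth.apex_enlargement > 0 and k >= 3:
            verts = _apply_radial(
                verts, lambda th: _apex_bump(th, k, math.pi / 2.0,
                                             truth.apex_enlargement))
    elif truth.view == "equatorial":
        ang = np.linspace(0.0, _TWO_PI, n_vertices, endpoint=False)
        verts = np.column_stack([np.cos(ang), np.sin(ang)])
    else:
        raise ContourError(f"unknown view {truth.view!r}")

    irregularity = truth.irregularity
    if truth.view == "equatorial":
        irregularity = math.hypot(irregularity, EQUATORIAL_POSE_IRREGULARITY)
    if irregularity > 0:
        verts = _apply_radial(
            verts,
            lambda th: 1.0 + _radial_field(th, rng, _IRREGULARITY_HARMONICS,
                                           irregularity, "red"),
        )
    if truth.degraded:
        verts = _apply_radial(
            verts,
            lambda th: 1.0 + _radial_field(th, rng, _DEGRADED_HARMONICS,
                                           DEGRADED_BOUNDARY_SD, "flat"),
        )

    if truth.view == "equatorial":
        # exact width (E) and height (P) in the canonical frame
        verts[:, 0] *= truth.e_true / (verts[:, 0].max() - verts[:, 0].min())
        verts[:, 1] *= truth.p_true / (verts[:, 1].max() - verts[:, 1].min())

    # rotate into the sampled orientation
    c, s = math.cos(theta0), math.sin(theta0)
    verts = verts @ np.array([[c, s], [-s, c]])
    verts = verts - _polygon_centroid(verts)

    if truth.view == "polar":
        # scale so the protocol equatorial diameter (first-aperture rule, as
        # in morphometry.protocol_equatorial) equals e_true exactly
        e_now = perpendicular_extent(verts, float(ap[0]))
        verts = verts * (truth.e_true / e_now)

    return Contour(
        verts,
        grain_id=truth.grain_id,
        taxon=truth.taxon,
        view=truth.view,
        aperture_angles=ap,
    )
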