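"""Summary statistics, standardized PCA and 2-D highest-posterior-density
regions of ordination scores.

``summarize`` gives the genus-level size statistics used in the size rule
(mean, sample s.d., 1-s.d. and 2-s.d. ranges). ``pca`` is a correlation-matrix
PCA by default (features are standardized before eigendecomposition — the
defensible choice given mixed units of μm², μm and dimensionless ratios) with
a deterministic sign convention. ``hpd_region_2d`` estimates the smallest
region containing a given probability mass of a 2-D point cloud via a binned
Gaussian kernel density (Scott's bandwidth) and returns its contour polygons,
as used to draw population envelopes in ordination space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage import measure as skmeasure

from .errors import FeatureError

__all__ = ["SummaryStats", "OrdinationResult", "HPDRegion",
           "summarize", "pca", "hpd_region_2d"]


@dataclass(frozen=True)
class SummaryStats:
    """Sample statistics of a size measurement (μm)."""

    n: int
    mean: float
    sd: float
    range_1sd: Tuple[float, float]
    range_2sd: Tuple[float, float]
    min: float
    max: float

    def to_dict(self) -> dict:
        return {
            "n": self.n, "mean": self.mean, "sd": self.sd,
            "range_1sd": list(self.range_1sd), "range_2sd": list(self.range_2sd),
            "min": self.min, "max": self.max,
        }


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, sample s.d. (n-1 denominator) and 1/2-s.d. ranges of a sample."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("summarize requires at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return SummaryStats(
        n=int(x.size),
        mean=mean,
        sd=sd,
        range_1sd=(mean - sd, mean + sd),
        range_2sd=(mean - 2 * sd, mean + 2 * sd),
        min=float(x.min()),
        max=float(x.max()),
    )


@dataclass
class OrdinationResult:
    """PCA scores, loadings and per-axis variance-explained proportions."""

    scores: pd.DataFrame  # grain x axis
    loadings: pd.DataFrame  # feature x axis
    variance_explained: np.ndarray  # proportion per axis, sums to 1

    @property
    def n_axes(self) -> int:
        return len(self.variance_explained)


def pca(features: pd.DataFrame, scale: bool = True) -> OrdinationResult:
    """Principal component analysis of a grain x feature table.

    Columns are centred and, with ``scale=True`` (default), divided by their
    sample s.d. (correlation PCA). Axes are ordered by decreasing variance;
    the sign of each axis is fixed so its largest-magnitude loading is
    positive. Scores reconstruct the centred/scaled data via the loadings.
    """
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("pca requires at least 2 grains and 2 features")
    if not np.isfinite(X).all():
        raise ValueError("pca input contains missing or non-finite values")
    mu = X.mean(axis=0)
    Xc = X - mu
    if scale:
        sd = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(sd <= 0)
        if dead.size:
            names = [str(features.columns[i]) for i in dead]
            raise FeatureError(
                f"zero-variance column(s) with scale=True: {names}"
            )
        Xc = Xc / sd
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    ratio = var / var.sum()
    # deterministic sign: largest-magnitude loading of each axis is positive
    for j in range(vt.shape[0]):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    axes = [f"PC{j + 1}" for j in range(len(s))]
    scores = pd.DataFrame(u * s, index=features.index, columns=axes)
    loadings = pd.DataFrame(vt.T, index=features.columns, columns=axes)
    return OrdinationResult(scores=scores, loadings=loadings,
                            variance_explained=ratio)


@dataclass
class HPDRegion:
    """Smallest density super-level set holding ``mass`` probability."""

    mass: float
    polygons: List[np.ndarray]  # closed (n, 2) vertex arrays in score space
    total_area: float
    density_level: float

    def contains_region(self, other: "HPDRegion", tol: float = 1e-6) -> bool:
        """True if this region's polygons cover the other's."""
        mine = unary_union([Polygon(p) for p in self.polygons]).buffer(tol)
        theirs = unary_union([Polygon(p) for p in other.polygons])
        return mine.contains(theirs)


def _scott_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    return float(x.std(ddof=1)) * n ** (-1.0 / 6.0)


def hpd_region_2d(scores, mass: float = 0.95, grid: int = 201,
                  bandwidth: Optional[Tuple[float, float]] = None) -> HPDRegion:
    """2-D highest-posterior-density region of a point cloud.

    A Gaussian kernel density is estimated on a ``grid`` x ``grid`` raster
    (binned KDE: 2-D histogram smoothed by a Gaussian of Scott's-rule
    bandwidth per axis, overridable via ``bandwidth``). The region is the
    smallest density super-level set containing at least ``mass`` of the
    estimated probability; its boundary is returned as one or more closed
    polygons.
    """
    pts = np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be an (n, 2) array")
    n = len(pts)
    if n < 50:
        raise ValueError("hpd_region_2d requires at least 50 points")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    hx = bandwidth[0] if bandwidth else _scott_bandwidth(pts[:, 0])
    hy = bandwidth[1] if bandwidth else _scott_bandwidth(pts[:, 1])
    if hx <= 0 or hy <= 0:
        raise ValueError("degenerate (zero-spread) points")
    # correlation check guards against exactly collinear input
    if abs(np.corrcoef(pts[:, 0], pts[:, 1])[0, 1]) > 1.0 - 1e-12:
        raise ValueError("degenerate (collinear) points")

    pad = 4.0
    x0, x1 = pts[:, 0].min() - pad * hx, pts[:, 0].max() + pad * hx
    y0, y1 = pts[:, 1].min() - pad * hy, pts[:, 1].max() + pad * hy
    hist, xedges, yedges = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=grid, range=[[x0, x1], [y0, y1]]
    )
    dx = xedges[1] - xedges[0]
    dy = yedges[1] - yedges[0]
    density = ndimage.gaussian_filter(hist, sigma=(hx / dx, hy / dy),
                                      mode="constant")
    density /= n * dx * dy  # now integrates to ~1 over the grid

    # smallest super-level set holding >= mass
    flat = np.sort(density.ravel())[::-1]
    cum = np.cumsum(flat) * dx * dy
    k = int(np.searchsorted(cum, mass))
    level = float(flat[min(k, len(flat) - 1)])

    # pad with a zero ring so all contours close
    padded = np.zeros((grid + 2, grid + 2))
    padded[1:-1, 1:-1] = density
    contours = skmeasure.find_contours(padded, level)
    polygons: List[np.ndarray] = []
    xc = 0.5 * (xedges[:-1] + xedges[1:])
    yc = 0.5 * (yedges[:-1] + yedges[1:])
    total = 0.0
    for c in contours:
        # padded array indices -> density indices -> coordinates
        xi = np.interp(c[:, 0] - 1.0, np.arange(grid), xc)
        yi = np.interp(c[:, 1] - 1.0, np.arange(grid), yc)
        poly = np.column_stack([xi, yi])
        if len(poly) < 4:
            continue
        shapely_poly = Polygon(poly)
        if not shapely_poly.is_valid or shapely_poly.area <= 0:
            continue
        polygons.append(poly)
    if not polygons:
        raise ValueError("no closed HPD contour found (mass too extreme?)")
    # union area: robust to overlapping or nested contour polygons
    total = unary_union([Polygon(p) for p in polygons]).area
    return HPDRegion(mass=mass, polygons=polygons, total_area=float(total),
                     density_level=level)
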