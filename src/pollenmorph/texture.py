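"""The 43 texture-and-extra-shape features computed from the grain raster.

The automated instrument reports 43 parameters beyond the 7 core shape/size
ones; their exact definitions are unpublished, so this module defines its own
fixed, documented, rotation-invariant set of 43 (count and order frozen for
reproducibility):

====================  =====================================================
feature               definition
====================  =====================================================
int_mean/sd/skew/kurt interior intensity moments (rim excluded)
grad_mean, grad_sd    Sobel gradient-magnitude statistics in the interior
hist_entropy          Shannon entropy of the 32-bin interior histogram (bits)
glcm_*_d1, glcm_*_d3  grey-level co-occurrence contrast, homogeneity, energy
                      and correlation at pixel offsets 1 and 3, averaged over
                      the four offset angles (32 grey levels, interior only)
fourier_01..08        radial Fourier descriptors of the mask boundary:
                      |FFT harmonic h| / |DC|, h = 1..8
log_sd_05/10/20       Laplacian-of-Gaussian response s.d. at 0.5/1.0/2.0 μm
lbp_00..09            rotation-invariant uniform LBP histogram (P=8, R=1)
hu_1..hu_7            signed-log Hu moment invariants of the mask
====================  =====================================================

All values are dimensionless; every feature is invariant under rigid rotation
up to raster resampling error (~2%).
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np
from scipy import ndimage
from scipy import stats as sstats
from skimage import measure as skmeasure
from skimage.feature import graycomatrix, local_binary_pattern

from .errors import FeatureError
from .render import GrainImage

__all__ = ["TEXTURE_FEATURE_NAMES", "N_TEXTURE_FEATURES", "texture_features"]

_GLCM_STATS = ("contrast", "homogeneity", "energy", "correlation")

TEXTURE_FEATURE_NAMES = tuple(
    ["int_mean", "int_sd", "int_skew", "int_kurt", "grad_mean", "grad_sd",
     "hist_entropy"]
    + [f"glcm_{s}_d{d}" for d in (1, 3) for s in _GLCM_STATS]
    + [f"fourier_{h:02d}" for h in range(1, 9)]
    + ["log_sd_05", "log_sd_10", "log_sd_20"]
    + [f"lbp_{b:02d}" for b in range(10)]
    + [f"hu_{i}" for i in range(1, 8)]
)
N_TEXTURE_FEATURES = len(TEXTURE_FEATURE_NAMES)
assert N_TEXTURE_FEATURES == 43

#: interior = mask eroded by this many pixels, to exclude the bright rim
_RIM_EROSION_PX = 3
_N_GREY_LEVELS = 32
_MIN_MASK_PX = 50


def _interior_mask(mask: np.ndarray) -> np.ndarray:
    interior = ndimage.binary_erosion(mask, iterations=_RIM_EROSION_PX)
    if interior.sum() < _MIN_MASK_PX:
        raise FeatureError(
            f"grain interior below {_MIN_MASK_PX} px: texture features unstable"
        )
    return interior


def _intensity_moments(values: np.ndarray) -> Dict[str, float]:
    sd = float(values.std())
    if sd < 1e-12:
        skew = kurt = 0.0
    else:
        skew = float(sstats.skew(values))
        kurt = float(sstats.kurtosis(values))
    return {"int_mean": float(values.mean()), "int_sd": sd,
            "int_skew": skew, "int_kurt": kurt}


def _gradient_stats(pixels: np.ndarray, interior: np.ndarray) -> Dict[str, float]:
    gx = ndimage.sobel(pixels, axis=1)
    gy = ndimage.sobel(pixels, axis=0)
    mag = np.hypot(gx, gy)[interior]
    return {"grad_mean": float(mag.mean()), "grad_sd": float(mag.std())}


def _entropy(values: np.ndarray) -> float:
    hist, _ = np.histogram(values, bins=_N_GREY_LEVELS, range=(0.0, 1.0))
    p = hist.astype(float)
    p = p[p > 0]
    p /= p.sum()
    return float(-(p * np.log2(p)).sum())


def _quantize(pixels: np.ndarray, interior: np.ndarray) -> np.ndarray:
    """Interior intensities quantized to 1.._N_GREY_LEVELS; 0 = background."""
    q = np.zeros(pixels.shape, dtype=np.uint8)
    levels = np.clip(
        (pixels[interior] * _N_GREY_LEVELS).astype(int), 0, _N_GREY_LEVELS - 1
    )
    q[interior] = levels + 1
    return q


def _glcm_stats(q: np.ndarray) -> Dict[str, float]:
    """Angle-averaged GLCM statistics at offsets 1 and 3 px, background excluded."""
    angles = (0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4)
    glcm = graycomatrix(q, distances=(1, 3), angles=angles,
                        levels=_N_GREY_LEVELS + 1, symmetric=True)
    out: Dict[str, float] = {}
    idx = np.arange(1, _N_GREY_LEVELS + 1, dtype=float)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    for d_i, d in enumerate((1, 3)):
        acc = {s: 0.0 for s in _GLCM_STATS}
        for a_i in range(len(angles)):
            m = glcm[1:, 1:, d_i, a_i].astype(float)  # drop background row/col
            tot = m.sum()
            if tot <= 0:
                continue
            p = m / tot
            acc["contrast"] += float((p * (ii - jj) ** 2).sum())
            acc["homogeneity"] += float((p / (1.0 + (ii - jj) ** 2)).sum())
            acc["energy"] += float(np.sqrt((p * p).sum()))
            mu_i = float((p * ii).sum())
            mu_j = float((p * jj).sum())
            var_i = float((p * (ii - mu_i) ** 2).sum())
            var_j = float((p * (jj - mu_j) ** 2).sum())
            if var_i > 1e-12 and var_j > 1e-12:
                cov = float((p * (ii - mu_i) * (jj - mu_j)).sum())
                acc["correlation"] += cov / math.sqrt(var_i * var_j)
        for s in _GLCM_STATS:
            out[f"glcm_{s}_d{d}"] = acc[s] / len(angles)
    return out


def _fourier_descriptors(mask: np.ndarray, n_harmonics: int = 8) -> Dict[str, float]:
    """Radial Fourier descriptors |c_h|/|c_0| of the mask boundary."""
    contours = skmeasure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise FeatureError("mask has no boundary")
    boundary = max(contours, key=len)
    centroid = boundary.mean(axis=0)
    r = np.linalg.norm(boundary - centroid, axis=1)
    # uniform resampling along the boundary index to a fixed length
    n = 256
    r_u = np.interp(np.linspace(0, len(r) - 1, n), np.arange(len(r)), r)
    spec = np.abs(np.fft.rfft(r_u))
    dc = spec[0] if spec[0] > 0 else 1.0
    return {f"fourier_{h:02d}": float(spec[h] / dc)
            for h in range(1, n_harmonics + 1)}


def _log_stats(pixels: np.ndarray, interior: np.ndarray,
               pixel_size: float) -> Dict[str, float]:
    out = {}
    for name, sigma_um in (("log_sd_05", 0.5), ("log_sd_10", 1.0),
                           ("log_sd_20", 2.0)):
        resp = ndimage.gaussian_laplace(pixels, sigma_um / pixel_size)
        out[name] = float(resp[interior].std())
    return out


def _lbp_histogram(pixels: np.ndarray, interior: np.ndarray) -> Dict[str, float]:
    # LBP on an 8-bit quantization: float inputs make tiny numeric
    # differences flip bits non-reproducibly
    q8 = np.clip(pixels * 255.0, 0, 255).astype(np.uint8)
    lbp = local_binary_pattern(q8, P=8, R=1, method="uniform")
    hist, _ = np.histogram(lbp[interior], bins=10, range=(0, 10))
    hist = hist / max(hist.sum(), 1)
    return {f"lbp_{b:02d}": float(hist[b]) for b in range(10)}


def _hu_moments(mask: np.ndarray) -> Dict[str, float]:
    mu = skmeasure.moments_central(mask.astype(float))
    nu = skmeasure.moments_normalized(mu)
    hu = skmeasure.moments_hu(nu)
    # signed log transform keeps the invariants on a comparable scale
    vals = -np.sign(hu) * np.log10(np.abs(hu) + 1e-30)
    return {f"hu_{i + 1}": float(vals[i]) for i in range(7)}


def texture_features(image: GrainImage) -> Dict[str, float]:
    """Compute the fixed 43-feature texture/extra-shape set for one grain.

    Returns a dict keyed and ordered by :data:`TEXTURE_FEATURE_NAMES`.
    Raises :class:`FeatureError` if the grain interior is smaller than 50 px.
    """
    mask = image.mask.astype(bool)
    if mask.sum() < _MIN_MASK_PX:
        raise FeatureError(f"mask smaller than {_MIN_MASK_PX} px")
    interior = _interior_mask(mask)
    pixels = image.pixels.astype(float)
    inside = pixels[interior]

    feats: Dict[str, float] = {}
    feats.update(_intensity_moments(inside))
    feats.update(_gradient_stats(pixels, interior))
    feats["hist_entropy"] = _entropy(inside)
    feats.update(_glcm_stats(_quantize(pixels, interior)))
    feats.update(_fourier_descriptors(mask))
    feats.update(_log_stats(pixels, interior, image.pixel_size))
    feats.update(_lbp_histogram(pixels, interior))
    feats.update(_hu_moments(mask))
    return {name: feats[name] for name in TEXTURE_FEATURE_NAMES}
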