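"""Shape-normalized radial intensity profiling and related quantitation.

A cell's morphology is reduced to a circular coordinate by mapping each
pixel inside the mask to a normalized radius

    r = d_centroid / (d_centroid + d_edge)     in [0, 1)

where ``d_centroid`` is the Euclidean distance to the mask's center of
mass and ``d_edge`` the distance to the closest background pixel (from a
Euclidean distance transform).  The mask is then split into ``n_bins``
concentric bins (bin 1 centroid-proximal) and the mean intensity per bin
reported together with the whole-cell mean.  Also provided: the furthest-
migrated-cell normalization m/d and a calibrated F:G densitometry ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RMIProfile",
    "MigrationMeasure",
    "DensitometryRatio",
    "normalized_radius",
    "radial_mean_intensity",
    "migration_normalize",
    "fg_ratio",
]


@dataclass(frozen=True)
class RMIProfile:
    bin_means: tuple          # length n_bins, bin 1 first (centroid-proximal)
    whole_cell_mean: float
    n_pixels_per_bin: tuple

    @property
    def n_bins(self) -> int:
        return len(self.bin_means)


@dataclass(frozen=True)
class MigrationMeasure:
    m: float
    d: float

    @property
    def normalized(self) -> float:
        return self.m / self.d


@dataclass(frozen=True)
class DensitometryRatio:
    f_signal: float
    g_signal: float
    slope: float
    intercept: float
    fg_ratio: float


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("mask is empty")
    n_components = ndimage.label(mask)[1]
    if n_components > 1:
        raise ValueError(
            f"mask has {n_components} connected components; one cell per call")
    return mask


def normalized_radius(mask: np.ndarray) -> np.ndarray:
    """Per-pixel normalized centroid-to-edge radius over a single-cell mask.

    Pixels outside the mask get NaN.  A pixel with d_centroid + d_edge = 0
    (degenerate single-pixel mask) is assigned r = 0.
    """
    mask = _check_mask(mask)
    cy, cx = ndimage.center_of_mass(mask)
    yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    d_centroid = np.hypot(yy - cy, xx - cx)
    # distance to the closest background pixel, computed on the mask
    d_edge = ndimage.distance_transform_edt(mask)
    total = d_centroid + d_edge
    r = np.full(mask.shape, np.nan)
    inside = mask & (total > 0)
    r[inside] = d_centroid[inside] / total[inside]
    r[mask & (total == 0)] = 0.0
    return r


def radial_mean_intensity(image: np.ndarray, mask: np.ndarray,
                          n_bins: int = 5) -> RMIProfile:
    """Mean intensity in ``n_bins`` shape-normalized concentric bins.

    Pixel with radius r falls in bin ceil(r * n_bins) (bin 1 for r = 0);
    bins are half-open on r with the outermost right-closed at 1, so the
    bins partition the mask and pixel counts conserve its area.
    """
    image = np.asarray(image, dtype=float)
    mask = _check_mask(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    r = normalized_radius(mask)
    rv = r[mask]
    iv = image[mask]
    bins = np.minimum(np.ceil(rv * n_bins).astype(int), n_bins)
    bins[bins < 1] = 1
    means, counts = [], []
    for b in range(1, n_bins + 1):
        sel = bins == b
        counts.append(int(sel.sum()))
        means.append(float(iv[sel].mean()) if sel.any() else float("nan"))
    return RMIProfile(bin_means=tuple(means),
                      whole_cell_mean=float(iv.mean()),
                      n_pixels_per_bin=tuple(counts))


def migration_normalize(m: float, d: float) -> MigrationMeasure:
    """Distance of the furthest migrated cell normalized to a landmark."""
    if d <= 0:
        raise ValueError(f"reference distance d must be > 0, got {d}")
    if m < 0:
        raise ValueError(f"migration distance m must be >= 0, got {m}")
    return MigrationMeasure(m=float(m), d=float(d))


def fg_ratio(f_band: float, g_band: float, standards) -> DensitometryRatio:
    """Calibrated filamentous:monomeric actin ratio from band densitometry.

    ``standards`` is a sequence of (known_load, signal) pairs from the
    total-load dilution series; a least-squares line signal = a*load + b
    converts band signals to load units before forming the F/G ratio.
    """
    standards = np.asarray(standards, dtype=float)
    if standards.ndim != 2 or standards.shape[0] < 2:
        raise ValueError("need at least 2 calibration standards")
    loads, signals = standards[:, 0], standards[:, 1]
    if np.unique(loads).size < 2:
        raise ValueError("calibration standards must span distinct loads")
    slope, intercept = np.polyfit(loads, signals, 1)
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    f_load = (f_band - intercept) / slope
    g_load = (g_band - intercept) / slope
    if f_load <= 0 or g_load <= 0:
        raise ValueError(
            "converted band load non-positive; check background subtraction "
            "or detector saturation")
    return DensitometryRatio(f_signal=float(f_band), g_signal=float(g_band),
                             slope=float(slope), intercept=float(intercept),
                             fg_ratio=float(f_load / g_load))
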