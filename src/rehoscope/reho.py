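"""Regional homogeneity: voxelwise Kendall's coefficient of concordance.

For each in-mask voxel, the time series of the voxel and its nearest
neighbors (default 27: the voxel plus its 26 face/edge/corner neighbors) are
ranked over time, and Kendall's W is computed from the rank sums

    W = sum_i (R_i - Rbar)^2 / [ (1/12) k^2 (n^3 - n) ]

with R_i the rank sum of time point i across the k series and
Rbar = (n + 1) k / 2.  No tie-correction term enters the denominator; ties
are resolved upstream by midranks, accepting a slight downward bias of W
under ties.  At mask edges the neighborhood shrinks to the in-mask subset
and the actual series count k is used (and recorded per voxel), so boundary
cortex is not discarded.

Individual W maps are normalized by the whole-brain (mask-mean) W and then
spatially smoothed with a Gaussian kernel of given FWHM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.stats

from .errors import GeometryError
from .io import BoldSeries, BrainMask, check_geometry

#: conversion between Gaussian FWHM and standard deviation
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ReHoMap:
    """3D Kendall's-W map with its mask and per-voxel neighbor count."""

    data: np.ndarray
    normalized: bool
    mask: BrainMask
    k_used: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        """Voxels where W is defined (in mask with at least 2 series)."""
        return self.mask.data & (self.k_used >= 2)


def neighborhood_footprint(neighborhood: int = 27) -> np.ndarray:
    """3x3x3 boolean footprint for a 7-, 19- or 27-voxel cluster."""
    if neighborhood not in (7, 19, 27):
        raise ValueError("neighborhood must be 7, 19 or 27")
    order = {7: 1, 19: 2, 27: 3}[neighborhood]
    return ndi.generate_binary_structure(3, order)


def rank_time_series(series: np.ndarray) -> tuple[np.ndarray, bool]:
    """Rank one time series (1..n, midranks on ties).

    Returns ``(ranks, degenerate)`` where ``degenerate`` marks an all-tie
    (constant) series.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or series.size < 2:
        raise ValueError("series must be a 1D vector with n >= 2")
    if not np.isfinite(series).all():
        raise ValueError("non-finite values in time series")
    ranks = scipy.stats.rankdata(series, method="average")
    degenerate = bool(np.ptp(series) == 0)
    return ranks, degenerate


def kendalls_w(ranks: np.ndarray) -> float:
    """Kendall's W from an n x k matrix of within-series ranks.

    Column j holds the time ranks of series j.  W is 1 under perfect
    concordance and ~1/k under independence; the value is clipped to [0, 1]
    only against floating-point excursion.
    """
    ranks = np.asarray(ranks, dtype=np.float64)
    if ranks.ndim != 2:
        raise ValueError("ranks must be an n x k matrix")
    n, k = ranks.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 and k >= 2, got n={n}, k={k}")
    row_sums = ranks.sum(axis=1)
    rbar = k * (n + 1) / 2.0
    s = float(((row_sums - rbar) ** 2).sum())
    denom = (k * k * (n ** 3 - n)) / 12.0
    w = s / denom
    return float(min(max(w, 0.0), 1.0))


def reho_map(bold: BoldSeries, mask: BrainMask, neighborhood: int = 27) -> ReHoMap:
    """Voxelwise Kendall's W over the in-mask neighborhood cluster.

    For every mask voxel, W is computed over the in-mask subset of the
    voxel-plus-neighbors cluster with k set to the actual in-mask count
    (recorded in ``k_used``).  Voxels with fewer than 2 in-mask series get 0.
    """
    check_geometry(bold.shape, bold.affine, mask.shape, mask.affine,
                   what="BOLD vs mask")
    n = bold.n_volumes
    if n < 2:
        raise GeometryError("need at least 2 time points")
    foot = neighborhood_footprint(neighborhood).astype(np.float64)

    # within-voxel time ranks (midranks on ties)
    ranks = scipy.stats.rankdata(bold.data, method="average", axis=-1)

    maskf = mask.data.astype(np.float64)
    counts = ndi.correlate(maskf, foot, mode="constant", cval=0.0)
    k_used = np.where(mask.data, np.rint(counts).astype(np.int64), 0)

    # neighborhood rank sums for every time point in one pass
    ranks *= maskf[..., None]
    rank_sums = ndi.correlate(ranks, foot[..., None], mode="constant", cval=0.0)

    # sum_i (R_i - Rbar)^2 = sum_i R_i^2 - n * Rbar^2 because midranks keep
    # every column sum at n(n+1)/2, hence mean_i R_i = k (n+1)/2 exactly
    rbar = k_used * (n + 1) / 2.0
    s = np.einsum("xyzt,xyzt->xyz", rank_sums, rank_sums) - n * rbar ** 2
    np.maximum(s, 0.0, out=s)

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = (k_used.astype(np.float64) ** 2) * (n ** 3 - n) / 12.0
        w = np.where(k_used >= 2, s / np.where(denom > 0, denom, 1.0), 0.0)
    np.clip(w, 0.0, 1.0, out=w)
    w[~mask.data] = 0.0
    return ReHoMap(data=w, normalized=False, mask=mask, k_used=k_used)


def normalize_reho(m: ReHoMap) -> ReHoMap:
    """Divide every in-mask W by the mask-mean W.

    The denominator averages only voxels with a defined W (``k_used >= 2``)
    so degenerate zeros do not deflate the mean; after normalization the
    mean over those voxels is 1.
    """
    if m.normalized:
        raise ValueError("map is already normalized")
    valid = m.valid
    if not valid.any():
        raise ValueError("no voxels with a defined W")
    mean_w = float(m.data[valid].mean())
    if mean_w <= 0:
        raise ValueError(f"mask-mean W must be positive, got {mean_w}")
    out = np.where(m.mask.data, m.data / mean_w, 0.0)
    return ReHoMap(data=out, normalized=True, mask=m.mask, k_used=m.k_used)


def smooth_map(data: np.ndarray, fwhm_mm: float,
               voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    """Separable Gaussian smoothing with per-axis sigma = FWHM/2.3548/voxel.

    ``fwhm_mm = 0`` is the identity.  Boundaries use edge replication so a
    constant map stays constant.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    data = np.asarray(data, dtype=np.float64)
    if fwhm_mm == 0:
        return data.copy()
    sigma = [fwhm_mm * FWHM_TO_SIGMA / float(v) for v in voxel_size_mm]
    return ndi.gaussian_filter(data, sigma=sigma, mode="nearest")


def smooth_reho(m: ReHoMap, fwhm_mm: float) -> ReHoMap:
    """Smooth a (typically normalized) ReHo map in place of its data."""
    out = smooth_map(m.data, fwhm_mm, m.mask.voxel_size_mm)
    out[~m.mask.data] = 0.0
    return ReHoMap(data=out, normalized=m.normalized, mask=m.mask, k_used=m.k_used)
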