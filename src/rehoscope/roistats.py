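"""ROI-level statistics: mean-ReHo extraction, brain-behavior correlations
with Bonferroni control, the gray-matter index, covariance-controlled group
re-analysis, and the mean-signal sanity map.

"Bivariate correlation" is Pearson throughout (a Spearman option exists for
rank-based sensitivity checks).  Bonferroni families default to the number
of ROIs tested per behavioral variable.  The gray-matter index of an ROI is
its gray-matter volume divided by the subject's total gray-matter volume,
both from continuous probability maps (sum x voxel volume); pass
``binarize=True`` for hard segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import DegenerateDataError, DesignError, GeometryError
from .io import BoldSeries
from .reho import ReHoMap


@dataclass
class CorrelationResult:
    roi: str
    variable: str
    r: float
    p: float
    n: int
    adjusted_alpha: float
    significant: bool
    partial_on: str | None = None


def extract_roi_means(maps: list[ReHoMap] | list[np.ndarray],
                      roi: np.ndarray) -> np.ndarray:
    """Per-subject mean of each map over the ROI voxels."""
    roi = np.asarray(roi).astype(bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    out = np.empty(len(maps))
    for i, m in enumerate(maps):
        data = m.data if isinstance(m, ReHoMap) else np.asarray(m)
        if data.shape != roi.shape:
            raise GeometryError("map and ROI shapes differ")
        out[i] = float(data[roi].mean())
    return out


def pearson_correlation(x: np.ndarray, y: np.ndarray,
                        method: str = "pearson") -> tuple[float, float, int]:
    """Correlation with a two-tailed p from the t transform (n - 2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input to correlation")
    if method == "pearson":
        r, p = scipy.stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = scipy.stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p), n


def bonferroni_gate(p_values, family_size: int, alpha: float = 0.05) -> list[bool]:
    """Significance flags at the Bonferroni-adjusted level alpha/family."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    cut = alpha / family_size
    return [bool(p < cut) for p in p_values]


def total_gm_volume(gm_map: np.ndarray, voxel_volume_mm3: float,
                    binarize: bool = False) -> float:
    """Whole-map gray-matter volume in mm^3."""
    gm = np.asarray(gm_map, dtype=np.float64)
    if binarize:
        gm = (gm >= 0.5).astype(np.float64)
    return float(gm.sum() * voxel_volume_mm3)


def gm_index(gm_map: np.ndarray, roi: np.ndarray,
             whole_brain_gm_volume_mm3: float, voxel_volume_mm3: float,
             binarize: bool = False) -> float:
    """ROI gray-matter volume as a fraction of total gray-matter volume."""
    if whole_brain_gm_volume_mm3 <= 0:
        raise ValueError("whole-brain gray-matter volume must be positive")
    gm = np.asarray(gm_map, dtype=np.float64)
    roi = np.asarray(roi).astype(bool)
    if gm.shape != roi.shape:
        raise GeometryError("gray-matter map and ROI shapes differ")
    if binarize:
        gm = (gm >= 0.5).astype(np.float64)
    roi_vol = float(gm[roi].sum() * voxel_volume_mm3)
    return roi_vol / whole_brain_gm_volume_mm3


def ancova_group_effect(y: np.ndarray, group: np.ndarray,
                        covariate: np.ndarray) -> tuple[float, float]:
    """F test for the group term in ``y ~ 1 + group + covariate``.

    Compares the residual sum of squares of the covariate-only model against
    the full model; the F statistic has (1, N - 3) degrees of freedom.
    Degenerate fits (y constant, or the covariate already explaining y
    exactly) report F = 0.
    """
    y = np.asarray(y, dtype=np.float64)
    group = np.asarray(group, dtype=np.float64)
    covariate = np.asarray(covariate, dtype=np.float64)
    n = y.size
    if group.shape != (n,) or covariate.shape != (n,):
        raise ValueError("y, group and covariate must have equal length")
    levels = np.unique(group)
    if levels.size != 2 or min((group == g).sum() for g in levels) < 2:
        raise DesignError("need two groups with at least 2 subjects each")
    x_full = np.column_stack([np.ones(n), group, covariate - covariate.mean()])
    # the group term must stay estimable; a degenerate (e.g. zero-variance)
    # covariate is fine and reduces to the one-way comparison
    nuisance = x_full[:, [0, 2]]
    g_resid = group - nuisance @ np.linalg.lstsq(nuisance, group, rcond=None)[0]
    if float(g_resid @ g_resid) <= 1e-10 * n:
        raise DesignError("covariate is collinear with the group indicator")
    x_red = x_full[:, [0, 2]]

    def rss(x: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r)

    rss_f = rss(x_full)
    rss_r = rss(x_red)
    # rank-based residual df: N - 3 for any non-degenerate covariate, and
    # exactly the one-way df when the covariate column is degenerate
    df = n - int(np.linalg.matrix_rank(x_full))
    scale = float(y.var() * n) or 1.0
    if rss_f <= 1e-12 * scale:
        # the full model (or the covariate alone) fits y exactly
        return 0.0, 1.0
    f_stat = max(rss_r - rss_f, 0.0) / (rss_f / df)
    p = float(scipy.stats.f.sf(f_stat, 1, df))
    return float(f_stat), p


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        z: np.ndarray) -> tuple[float, float]:
    """Correlation of x and y after removing a linear effect of z from each.

    Both vectors are regressed on [intercept, z]; the Pearson correlation of
    the residuals is reported with a two-tailed p from the t transform with
    n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    n = x.size
    if y.shape != (n,) or z.shape != (n,):
        raise ValueError("x, y and z must have equal length")
    if n < 4:
        raise ValueError("need n >= 4")
    design = np.column_stack([np.ones(n), z])

    def residualize(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input to partial correlation")
    rx = residualize(x)
    ry = residualize(y)
    scale_x = float(np.abs(x - x.mean()).max()) or 1.0
    scale_y = float(np.abs(y - y.mean()).max()) or 1.0
    if np.abs(rx).max() <= 1e-10 * scale_x or np.abs(ry).max() <= 1e-10 * scale_y:
        # one side is an exact linear function of z: nothing left to correlate
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    r_clamped = min(max(r, -0.9999999999), 0.9999999999)
    t_stat = r_clamped * np.sqrt(df / (1.0 - r_clamped ** 2))
    p = float(2.0 * scipy.stats.t.sf(abs(t_stat), df))
    return r, p


def mean_t2star_map(bolds: list[BoldSeries], volume_index: int = 19) -> np.ndarray:
    """Voxelwise mean of one raw volume across subjects (signal-loss check).

    Default index 19 selects the twentieth volume (0-based indexing).
    """
    if not bolds:
        raise ValueError("need at least one subject")
    shape = bolds[0].shape
    affine = bolds[0].affine
    acc = np.zeros(shape)
    for b in bolds:
        if b.shape != shape or not np.allclose(b.affine, affine, atol=1e-4):
            raise GeometryError("subjects disagree in geometry")
        if volume_index >= b.n_volumes:
            raise ValueError(
                f"volume index {volume_index} out of range for subject "
                f"{b.subject_id!r} with T={b.n_volumes}")
        acc += b.data[..., volume_index]
    return acc / len(bolds)


def two_sample_scalar_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t with a two-tailed p (df = nx + ny - 2)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need n >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return 0.0, 1.0
    if np.ptp(np.concatenate([x - x.mean(), y - y.mean()])) == 0:
        raise DegenerateDataError("zero pooled variance")
    t_stat, p = scipy.stats.ttest_ind(x, y, equal_var=True)
    return float(t_stat), float(p)
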