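"""Voxelwise two-group GLM with covariates, and supra-threshold clustering.

The group comparison is an ordinary least-squares fit of
``y = b0 + b1 * group + covariates`` at every in-mask voxel; the reported
statistic is t = b1 / se(b1) with N - 2 - p degrees of freedom.  Covariates
are mean-centered before fitting (numerical conditioning; no effect on t).
Testing is two-sided throughout: voxels with |t| above the two-tailed
critical value at the chosen voxel-level p are labeled into connected
components separately per sign, so clusters of opposite sign never merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.stats

from .errors import DesignError, GeometryError
from .io import BrainMask, SubjectRecord, check_geometry
from .reho import ReHoMap


@dataclass
class GroupDesign:
    """Subject order, group coding (patient=1, control=0) and covariates."""

    subjects: list[str]
    group_indicator: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.group_indicator = np.asarray(self.group_indicator, dtype=np.float64)
        n = len(self.subjects)
        if self.group_indicator.shape != (n,):
            raise DesignError("group indicator length must match subjects")
        levels = np.unique(self.group_indicator)
        if levels.size != 2:
            raise DesignError("both groups must be non-empty")
        if self.covariates is None:
            self.covariates = np.empty((n, 0))
        self.covariates = np.asarray(self.covariates, dtype=np.float64)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        if self.covariates.shape[0] != n:
            raise DesignError("covariate rows must match subjects")

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def design_matrix(self) -> np.ndarray:
        """[intercept, group, mean-centered covariates].

        The group column must not be collinear with the nuisance columns
        (its effect would be inestimable); degenerate covariates such as an
        identically-zero column are tolerated — they change the counted
        degrees of freedom but not the group t (fits use pseudo-inverses).
        """
        n = len(self.subjects)
        cov = self.covariates - self.covariates.mean(axis=0, keepdims=True)
        x = np.column_stack([np.ones(n), self.group_indicator, cov])
        nuisance = np.column_stack([x[:, 0:1], cov])
        resid = x[:, 1] - nuisance @ np.linalg.lstsq(nuisance, x[:, 1],
                                                     rcond=None)[0]
        if float(resid @ resid) <= 1e-10 * n:
            raise DesignError("group indicator is collinear with the "
                              "intercept/covariates")
        return x


def build_group_design(records: list[SubjectRecord],
                       covariate_names: list[str] | None = None) -> GroupDesign:
    """Design from subject records; covariates are record attributes by name."""
    covariate_names = covariate_names or []
    cov = np.array([[getattr(r, name) for name in covariate_names]
                    for r in records]) if covariate_names else None
    return GroupDesign(
        subjects=[r.subject_id for r in records],
        group_indicator=np.array([1.0 if r.is_patient else 0.0 for r in records]),
        covariates=cov,
        covariate_names=list(covariate_names),
    )


@dataclass
class StatMap:
    """Voxelwise t statistics with their degrees of freedom."""

    t: np.ndarray
    df: int
    mask: BrainMask

    def __post_init__(self) -> None:
        if self.df < 1:
            raise DesignError(f"degrees of freedom must be >= 1, got {self.df}")


@dataclass
class ClusterTable:
    """Supra-threshold connected components of a statistic map.

    ``table`` has one row per cluster (sorted by extent, descending) and
    ``masks`` maps cluster_id to its boolean voxel mask.
    """

    table: pd.DataFrame
    masks: dict[int, np.ndarray]
    voxel_volume_mm3: float
    t_threshold: float

    def __len__(self) -> int:
        return len(self.table)


_COLUMNS = ["cluster_id", "sign", "n_voxels", "volume_mm3", "peak_t",
            "peak_x_mm", "peak_y_mm", "peak_z_mm"]


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D adjacency footprint: 6 (faces), 18 (+edges) or 26 (+corners)."""
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndi.generate_binary_structure(3, order)


def fit_voxelwise_glm(maps: list[ReHoMap] | list[np.ndarray],
                      design: GroupDesign,
                      mask: BrainMask | None = None) -> StatMap:
    """OLS group-difference t at every in-mask voxel.

    ``maps`` must be ordered exactly as ``design.subjects``.  With no
    covariates the result equals the classical pooled-variance two-sample t.
    """
    if mask is None:
        first = maps[0]
        if not isinstance(first, ReHoMap):
            raise ValueError("pass a mask when maps are plain arrays")
        mask = first.mask
    arrays = []
    for m in maps:
        data = m.data if isinstance(m, ReHoMap) else np.asarray(m, dtype=np.float64)
        if isinstance(m, ReHoMap):
            check_geometry(data.shape, m.mask.affine, mask.shape, mask.affine,
                           what="ReHo map vs mask")
        elif data.shape != mask.shape:
            raise GeometryError("map shape does not match mask")
        arrays.append(data)
    n = len(arrays)
    if n != len(design.subjects):
        raise DesignError("number of maps must match design subjects")

    x = design.design_matrix()
    # rank-based df: equals N - 2 - p for any non-degenerate design, and
    # keeps t exact when a covariate column is itself degenerate
    df = n - int(np.linalg.matrix_rank(x))
    if df < 1:
        raise DesignError(f"not enough subjects: N={n}, "
                          f"parameters={x.shape[1]}")

    inmask = mask.data
    y = np.stack([a[inmask] for a in arrays])  # (N, V)
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df
    xtx_inv = np.linalg.pinv(x.T @ x)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = np.where(se > 0, beta[1] / np.where(se > 0, se, 1.0), 0.0)

    t_map = np.zeros(mask.shape)
    t_map[inmask] = t_vals
    return StatMap(t=t_map, df=df, mask=mask)


def label_clusters(stat: StatMap, voxel_p: float,
                   connectivity: int = 18) -> ClusterTable:
    """Connected supra-threshold clusters at the two-tailed voxel threshold.

    Positive and negative excursions are labeled separately under the given
    connectivity; the table is sorted by extent, descending.  An empty
    supra-threshold set yields an empty table.
    """
    if not (0 < voxel_p < 1):
        raise ValueError("voxel_p must lie in (0, 1)")
    t_crit = float(scipy.stats.t.ppf(1.0 - voxel_p / 2.0, stat.df))
    struct = connectivity_structure(connectivity)
    vox_vol = stat.mask.voxel_volume_mm3
    affine = stat.mask.affine

    entries = []
    cluster_masks: dict[int, np.ndarray] = {}
    raw = []
    for sign, supra in (("pos", stat.t > t_crit), ("neg", stat.t < -t_crit)):
        supra = supra & stat.mask.data
        labels, n_lab = ndi.label(supra, structure=struct)
        for lab in range(1, n_lab + 1):
            m = labels == lab
            size = int(m.sum())
            t_in = stat.t[m]
            peak_pos = np.abs(t_in).argmax()
            peak_t = float(t_in[peak_pos])
            idx = np.argwhere(m)[peak_pos]
            world = affine @ np.append(idx, 1.0)
            raw.append((sign, size, peak_t, world[:3], m))

    raw.sort(key=lambda r: (-r[1], -abs(r[2])))
    for cid, (sign, size, peak_t, world, m) in enumerate(raw, start=1):
        entries.append({
            "cluster_id": cid, "sign": sign, "n_voxels": size,
            "volume_mm3": size * vox_vol, "peak_t": peak_t,
            "peak_x_mm": float(world[0]), "peak_y_mm": float(world[1]),
            "peak_z_mm": float(world[2]),
        })
        cluster_masks[cid] = m
    table = pd.DataFrame(entries, columns=_COLUMNS)
    return ClusterTable(table=table, masks=cluster_masks,
                        voxel_volume_mm3=vox_vol, t_threshold=t_crit)
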