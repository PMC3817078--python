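"""End-to-end orchestration: preprocess -> ReHo -> group GLM -> Monte-Carlo
cluster correction -> ROI statistics, plus the on-disk run layout and the
human-readable report.

:func:`analyze_cohort` works on in-memory objects (what the tests and the
simulation study use); :func:`run_pipeline` wraps it with cohort-directory
I/O, output files and a run manifest.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import PipelineError
from .inference import (ClusterTable, StatMap, build_group_design,
                        fit_voxelwise_glm, label_clusters)
from .io import (BoldSeries, BrainMask, PipelineConfig, SubjectRecord,
                 check_geometry, read_bold, read_map, read_mask,
                 read_subject_table, save_config, write_map)
from .montecarlo import (NullExtentDistribution, apply_cluster_correction,
                         estimate_smoothness_fwhm, extent_threshold,
                         simulate_null_extents)
from .preprocess import preprocess_bold, screen_head_motion
from .reho import ReHoMap, normalize_reho, reho_map, smooth_reho
from .roistats import (CorrelationResult, ancova_group_effect, bonferroni_gate,
                       extract_roi_means, gm_index, partial_correlation,
                       pearson_correlation, total_gm_volume,
                       two_sample_scalar_test)

log = logging.getLogger(__name__)

BEHAVIORAL_VARIABLES = ("bis_total", "bis_attentional", "bis_motor",
                        "bis_nonplan", "duration_use", "age_first_use")
#: variables defined for patients only
PATIENT_ONLY_VARIABLES = ("duration_use", "age_first_use")


@dataclass
class AnalysisResult:
    """Everything one cohort analysis produces, in memory."""

    stat_map: StatMap
    null_dist: NullExtentDistribution
    t_threshold: float
    extent_threshold_voxels: int
    extent_threshold_mm3: float
    fwhm_used_mm: tuple[float, float, float]
    clusters: ClusterTable
    surviving: ClusterTable
    roi_masks: dict[str, np.ndarray]
    roi_means: pd.DataFrame
    gm_index_table: pd.DataFrame | None
    correlations: pd.DataFrame
    ancova: pd.DataFrame | None
    excluded_subjects: list[str]
    records: list[SubjectRecord]
    reho_maps: list[ReHoMap] = field(repr=False, default_factory=list)


def compute_subject_reho(bold: BoldSeries, mask: BrainMask,
                         config: PipelineConfig) -> ReHoMap:
    """One subject: temporal preprocessing, KCC map, normalization, smoothing."""
    pre = preprocess_bold(bold, config)
    raw = reho_map(pre, mask, neighborhood=config.neighborhood)
    norm = normalize_reho(raw)
    return smooth_reho(norm, config.fwhm_mm)


def _correlation_rows(roi_masks: dict[str, np.ndarray],
                      roi_means: pd.DataFrame,
                      records: list[SubjectRecord],
                      gm_idx: pd.DataFrame | None,
                      alpha: float) -> list[CorrelationResult]:
    family = max(len(roi_masks), 1)
    adj = alpha / family
    rows: list[CorrelationResult] = []
    by_group = {
        "patient": [i for i, r in enumerate(records) if r.is_patient],
        "control": [i for i, r in enumerate(records) if not r.is_patient],
    }
    for variable in BEHAVIORAL_VARIABLES:
        groups = ("patient",) if variable in PATIENT_ONLY_VARIABLES \
            else ("patient", "control")
        for group in groups:
            idx = by_group[group]
            vals = [getattr(records[i], variable) for i in idx]
            if any(v is None for v in vals):
                continue
            y = np.asarray(vals, dtype=float)
            for roi in roi_masks:
                x = roi_means.loc[[records[i].subject_id for i in idx], roi].values
                try:
                    r, p, n = pearson_correlation(x, y)
                except ValueError:
                    continue
                rows.append(CorrelationResult(
                    roi=roi, variable=f"{variable}[{group}]", r=r, p=p, n=n,
                    adjusted_alpha=adj,
                    significant=bonferroni_gate([p], family, alpha)[0]))
                if gm_idx is not None:
                    z = gm_idx.loc[[records[i].subject_id for i in idx],
                                   roi].values
                    try:
                        rp, pp = partial_correlation(x, y, z)
                    except ValueError:
                        continue
                    rows.append(CorrelationResult(
                        roi=roi, variable=f"{variable}[{group}]", r=rp, p=pp,
                        n=n, adjusted_alpha=adj,
                        significant=bonferroni_gate([pp], family, alpha)[0],
                        partial_on="gm_index"))
    return rows


def analyze_cohort(bolds: list[BoldSeries], records: list[SubjectRecord],
                   mask: BrainMask, config: PipelineConfig,
                   gm_maps: list[np.ndarray] | None = None,
                   reho_maps: list[ReHoMap] | None = None) -> AnalysisResult:
    """Run the full group analysis on an in-memory cohort.

    ``reho_maps`` may supply precomputed per-subject maps (same order as
    ``records``) to skip the per-subject stage.
    """
    config.validate(tr=bolds[0].tr if bolds else None)
    if len(records) != len(bolds) and reho_maps is None:
        raise PipelineError("one BOLD series per subject record is required")

    # motion screening on tabulated maxima
    limits = (config.motion_limit_mm, config.motion_limit_deg)
    keep: list[int] = []
    excluded: list[str] = []
    for i, rec in enumerate(records):
        res = screen_head_motion(rec.motion_shift, rec.motion_rotation,
                                 limits, subject_id=rec.subject_id)
        if res.excluded:
            excluded.append(rec.subject_id)
        else:
            keep.append(i)
    if not keep:
        raise PipelineError("no subjects remaining after motion screening")
    if excluded:
        log.info("motion screening excluded %d subject(s): %s",
                 len(excluded), ", ".join(excluded))
    records = [records[i] for i in keep]
    if bolds:
        bolds = [bolds[i] for i in keep]
    if gm_maps is not None:
        gm_maps = [gm_maps[i] for i in keep]

    # per-subject ReHo maps
    if reho_maps is None:
        maps = [compute_subject_reho(b, mask, config) for b in bolds]
    else:
        maps = [reho_maps[i] for i in keep]

    # voxelwise GLM with head-motion covariates
    design = build_group_design(records,
                                ["motion_shift", "motion_rotation"])
    stat = fit_voxelwise_glm(maps, design, mask=mask)

    # Monte-Carlo extent threshold
    if config.smoothness == "estimated":
        fwhm_used = estimate_smoothness_fwhm(maps, design.group_indicator, mask)
        if all(f == 0 for f in fwhm_used):
            fwhm_used = (config.fwhm_mm,) * 3
    else:
        fwhm_used = (config.fwhm_mm,) * 3
    dist = simulate_null_extents(mask, fwhm_used, config.voxel_p,
                                 config.n_sims,
                                 connectivity=config.connectivity,
                                 seed=config.seed)
    c_min = extent_threshold(dist, config.alpha)

    clusters = label_clusters(stat, config.voxel_p,
                              connectivity=config.connectivity)
    surviving = apply_cluster_correction(clusters, c_min)
    log.info("df=%d, |t|>%.4f, extent threshold %d voxels (%.0f mm^3), "
             "connectivity %d: %d/%d clusters survive",
             stat.df, clusters.t_threshold, c_min,
             c_min * mask.voxel_volume_mm3, config.connectivity,
             len(surviving), len(clusters))

    roi_masks = {
        f"cluster_{int(row.cluster_id):02d}_{row.sign}": surviving.masks[
            int(row.cluster_id)]
        for row in surviving.table.itertuples()
    }

    ids = [r.subject_id for r in records]
    roi_means = pd.DataFrame(
        {name: extract_roi_means(maps, m) for name, m in roi_masks.items()},
        index=ids)

    gm_idx = None
    if gm_maps is not None and roi_masks:
        vox_vol = mask.voxel_volume_mm3
        data = {}
        for name, roi in roi_masks.items():
            col = []
            for gm in gm_maps:
                total = total_gm_volume(gm, vox_vol)
                col.append(gm_index(gm, roi, total, vox_vol))
            data[name] = col
        gm_idx = pd.DataFrame(data, index=ids)

    corr_rows = _correlation_rows(roi_masks, roi_means, records, gm_idx,
                                  config.alpha)
    correlations = pd.DataFrame([dataclasses.asdict(r) for r in corr_rows])

    ancova = None
    if gm_idx is not None:
        group = design.group_indicator
        rows = []
        for name in roi_masks:
            y = roi_means[name].values
            t_unc, p_unc = two_sample_scalar_test(y[group == 1], y[group == 0])
            f_ctrl, p_ctrl = ancova_group_effect(y, group, gm_idx[name].values)
            rows.append({
                "roi": name, "t_uncontrolled": t_unc,
                "p_uncontrolled": p_unc, "f_uncontrolled": t_unc ** 2,
                "f_gm_controlled": f_ctrl, "p_gm_controlled": p_ctrl,
            })
        ancova = pd.DataFrame(rows)

    return AnalysisResult(
        stat_map=stat, null_dist=dist, t_threshold=clusters.t_threshold,
        extent_threshold_voxels=c_min,
        extent_threshold_mm3=c_min * mask.voxel_volume_mm3,
        fwhm_used_mm=tuple(fwhm_used), clusters=clusters, surviving=surviving,
        roi_masks=roi_masks, roi_means=roi_means, gm_index_table=gm_idx,
        correlations=correlations, ancova=ancova,
        excluded_subjects=excluded, records=records, reho_maps=maps)


@dataclass
class RunManifest:
    """Provenance of one on-disk run."""

    config: dict
    seed: int
    version: str
    started: str
    finished: str
    cohort_dir: str
    outputs: dict[str, str]
    excluded_subjects: list[str]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _write_report(path: Path, result: AnalysisResult,
                  config: PipelineConfig, n_subjects: int) -> None:
    lines = [
        "# Regional homogeneity group analysis",
        "",
        f"- subjects analyzed: {n_subjects} "
        f"(excluded for motion: {len(result.excluded_subjects)})",
        f"- degrees of freedom: {result.stat_map.df}",
        f"- voxel threshold: p < {config.voxel_p} two-tailed, "
        f"|t| > {result.t_threshold:.4f}",
        f"- smoothness used for the null fields (FWHM, mm): "
        f"{tuple(round(f, 2) for f in result.fwhm_used_mm)} "
        f"({config.smoothness})",
        f"- corrected alpha {config.alpha}: minimum cluster extent "
        f"{result.extent_threshold_voxels} voxels "
        f"({result.extent_threshold_mm3:.0f} mm^3) from "
        f"{config.n_sims} simulations, connectivity {config.connectivity}",
        "",
        "## Surviving clusters",
        "",
        result.surviving.table.to_string(index=False)
        if len(result.surviving) else "(none)",
        "",
        "## Brain-behavior correlations",
        "",
        result.correlations.to_string(index=False)
        if len(result.correlations) else "(no surviving ROIs)",
    ]
    if result.ancova is not None and len(result.ancova):
        lines += ["", "## Group effect with and without gray-matter control",
                  "", result.ancova.to_string(index=False)]
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig, cohort_dir: str | Path,
                 out_dir: str | Path,
                 config_path: str | Path | None = None) -> RunManifest:
    """Disk-to-disk run over a cohort directory.

    Expects ``subjects.tsv``, ``mask.nii.gz`` and per subject
    ``<subject_id>_bold.nii.gz`` (optionally ``<subject_id>_gm.nii.gz``)
    inside ``cohort_dir``.
    """
    started = datetime.datetime.now().isoformat(timespec="seconds")
    cohort_dir = Path(cohort_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = read_subject_table(cohort_dir / "subjects.tsv")
    mask = read_mask(cohort_dir / "mask.nii.gz")
    bolds = []
    gm_maps: list[np.ndarray] | None = []
    for rec in records:
        bold_path = cohort_dir / f"{rec.subject_id}_bold.nii.gz"
        if not bold_path.exists():
            raise PipelineError(f"stage load: missing BOLD for {rec.subject_id}")
        bold = read_bold(bold_path, tr=config.tr, subject_id=rec.subject_id)
        check_geometry(bold.shape, bold.affine, mask.shape, mask.affine,
                       what=f"{rec.subject_id} vs mask")
        bolds.append(bold)
        gm_path = cohort_dir / f"{rec.subject_id}_gm.nii.gz"
        if gm_maps is not None and gm_path.exists():
            gm, gm_aff = read_map(gm_path)
            check_geometry(gm.shape, gm_aff, mask.shape, mask.affine,
                           what=f"{rec.subject_id} GM vs mask")
            gm_maps.append(gm)
        else:
            gm_maps = None

    result = analyze_cohort(bolds, records, mask, config, gm_maps=gm_maps)

    outputs: dict[str, str] = {}

    def _emit(name: str, path: Path) -> Path:
        outputs[name] = str(path)
        return path

    write_map(_emit("t_map", out / "tmap.nii.gz"), result.stat_map.t,
              mask.affine)
    result.clusters.table.to_csv(
        _emit("clusters", out / "clusters.tsv"), sep="\t", index=False)
    result.surviving.table.to_csv(
        _emit("surviving_clusters", out / "surviving_clusters.tsv"),
        sep="\t", index=False)
    ext = pd.DataFrame({"max_extent_voxels": result.null_dist.max_extents})
    ext.to_csv(_emit("null_extents", out / "null_extents.tsv"),
               sep="\t", index=False)
    result.roi_means.to_csv(_emit("roi_means", out / "roi_means.tsv"),
                            sep="\t", index_label="subject_id")
    result.correlations.to_csv(
        _emit("correlations", out / "correlations.tsv"), sep="\t", index=False)
    if result.gm_index_table is not None:
        result.gm_index_table.to_csv(
            _emit("gm_index", out / "gm_index.tsv"), sep="\t",
            index_label="subject_id")
    if result.ancova is not None:
        result.ancova.to_csv(_emit("ancova", out / "ancova.tsv"),
                             sep="\t", index=False)
    for name, roi in result.roi_masks.items():
        write_map(_emit(f"roi_{name}", out / f"roi_{name}.nii.gz"),
                  roi.astype(np.float32), mask.affine)
    _write_report(_emit("report", out / "report.md"), result, config,
                  len(result.records))

    snapshot = _emit("config_snapshot", out / "config_snapshot.yaml")
    if config_path is not None:
        snapshot.write_bytes(Path(config_path).read_bytes())
    else:
        save_config(config, snapshot)

    manifest = RunManifest(
        config=config.to_dict(), seed=config.seed, version=__version__,
        started=started,
        finished=datetime.datetime.now().isoformat(timespec="seconds"),
        cohort_dir=str(cohort_dir), outputs=outputs,
        excluded_subjects=result.excluded_subjects)
    manifest.save(out / "manifest.json")
    for p in outputs.values():
        if not Path(p).exists():
            raise PipelineError(f"declared output missing: {p}")
    return manifest
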