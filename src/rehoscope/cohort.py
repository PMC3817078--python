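"""Synthetic two-group resting-state cohort with planted effects.

The generator emulates the structure of a case-control ReHo study: two
groups of subjects, 4D BOLD noise with controllable local temporal
coherence, designated ROIs where coherence is reduced in the patient group,
behavioral scores with planted correlations to each subject's realized ROI
coherence, and gray-matter probability maps with a patient volume deficit in
exactly one ROI.

Coherence follows a shared-signal (equicorrelated) model: inside a region
with coupling rho, every voxel's series is

    x_j(t) = sqrt(rho) * s(t) + sqrt(1 - rho) * e_j(t)

with s and e_j unit-variance white Gaussian noise, so any two voxels of the
region have Pearson correlation rho and the expected Kendall's W of a
k-voxel cluster has the closed form ((k-1) * r_s + 1) / k with
r_s = (6/pi) asin(rho/2) (the Gaussian rank-correlation identity).  A linear
drift and a >0.1 Hz sinusoid are added so temporal preprocessing has
something to remove; both are eliminated exactly by detrending and the
0.01-0.08 Hz band-pass.

Head motion enters only as tabulated summary covariates (|N(0.123, 0.016)|
mm translation, |N(0.0017, 0.0006)| degree rotation, the scale of a
compliant adult cohort), not as image corruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import (BoldSeries, BrainMask, SubjectRecord, write_bold, write_map,
                 write_mask, write_subject_table)

# group means / SDs used to put planted scores on the instrument's scale:
# (attentional, motor, nonplanning) subscales and the 30-120 total
_BIS_SCALE = {
    "patient": {
        "bis_total": (71.6, 4.6), "bis_attentional": (18.3, 2.95),
        "bis_motor": (30.5, 2.74), "bis_nonplan": (22.9, 1.96),
    },
    "control": {
        "bis_total": (57.1, 5.2), "bis_attentional": (15.6, 1.63),
        "bis_motor": (22.1, 3.38), "bis_nonplan": (19.6, 2.71),
    },
}
_BIS_BOUNDS = {
    "bis_total": (30, 120), "bis_attentional": (8, 32),
    "bis_motor": (11, 44), "bis_nonplan": (11, 44),
}


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned voxel-index block [start, stop) on each axis."""

    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))

    def mask(self, grid: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(grid, dtype=bool)
        out[self.slices()] = True
        return out

    @property
    def n_voxels(self) -> int:
        return int(np.prod([b - a for a, b in zip(self.start, self.stop)]))


def _default_rois() -> dict[str, RoiBox]:
    # two well-separated 4x4x4 blocks standing in for medial OFC and left
    # dorsal striatum on the 24^3 grid; together ~1% of the volume, the
    # scale of a focal deficit relative to whole-brain gray matter
    return {
        "mofc": RoiBox((4, 10, 3), (8, 14, 7)),
        "dorsal_striatum": RoiBox((16, 10, 15), (20, 14, 19)),
    }


def _default_behav_corr() -> dict[str, tuple[str, float]]:
    # variable -> (driving ROI, target Pearson r with realized coherence);
    # magnitudes follow the correlation structure the pipeline must recover
    return {
        "bis_total": ("mofc", -0.46),
        "bis_attentional": ("dorsal_striatum", -0.58),
        "duration_use": ("dorsal_striatum", -0.41),
        "age_first_use": ("dorsal_striatum", 0.42),
    }


@dataclass
class SimulationSpec:
    """Ground-truth description of one synthetic cohort."""

    n_per_group: int = 30
    grid: tuple[int, int, int] = (24, 24, 24)
    n_volumes: int = 240
    tr: float = 2.0
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    rois: dict[str, RoiBox] = field(default_factory=_default_rois)
    coherence_control: dict[str, float] = field(
        default_factory=lambda: {"mofc": 0.35, "dorsal_striatum": 0.35})
    coherence_patient: dict[str, float] = field(
        default_factory=lambda: {"mofc": 0.22, "dorsal_striatum": 0.22})
    background_coherence: float = 0.10
    coherence_jitter_sd: float = 0.06
    behav_corr: dict[str, tuple[str, float]] = field(
        default_factory=_default_behav_corr)
    gm_deficit_roi: str = "mofc"
    gm_deficit_frac: float = 0.15
    gm_mediates: bool = False
    motion_shift_mean: float = 0.123
    motion_shift_sd: float = 0.016
    motion_rot_mean: float = 0.0017
    motion_rot_sd: float = 0.0006
    drift_amplitude: float = 1.0
    cardio_freq_hz: float = 0.15
    cardio_amplitude: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        occupancy = np.zeros(self.grid, dtype=int)
        for name, box in self.rois.items():
            if any(a < 0 for a in box.start) or any(
                    b > g for b, g in zip(box.stop, self.grid)):
                raise ValueError(f"ROI {name!r} extends outside the grid")
            if box.n_voxels < 1:
                raise ValueError(f"ROI {name!r} is empty")
            occupancy[box.slices()] += 1
        if (occupancy > 1).any():
            raise ValueError("ROIs must be disjoint")
        for name in self.rois:
            for coh in (self.coherence_control, self.coherence_patient):
                if name not in coh:
                    raise ValueError(f"no coherence value for ROI {name!r}")
                if not (0 <= coh[name] < 1):
                    raise ValueError("coherence must lie in [0, 1)")
        if not (0 <= self.background_coherence < 1):
            raise ValueError("background coherence must lie in [0, 1)")
        for var, (roi, r) in self.behav_corr.items():
            if roi not in self.rois:
                raise ValueError(f"behav_corr for {var!r} names unknown ROI {roi!r}")
            if abs(r) > 1:
                raise ValueError("behavioral correlations must satisfy |r| <= 1")
        if self.gm_deficit_roi not in self.rois:
            raise ValueError(f"gm_deficit_roi {self.gm_deficit_roi!r} unknown")
        if not (0 <= self.gm_deficit_frac < 1):
            raise ValueError("gm_deficit_frac must lie in [0, 1)")

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff

    def group_coherence(self, group: str) -> dict[str, float]:
        if group == "patient":
            return dict(self.coherence_patient)
        if group == "control":
            return dict(self.coherence_control)
        raise ValueError(f"no coherence values for group {group!r}")


@dataclass
class Cohort:
    """Everything :func:`simulate_cohort` knows about one realized cohort."""

    spec: SimulationSpec
    records: list[SubjectRecord]
    realized_coherence: dict[str, np.ndarray]  # roi -> per-subject rho
    mask: BrainMask
    bolds: list[BoldSeries] | None = None
    gm_maps: list[np.ndarray] | None = None

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def group_indicator(self) -> np.ndarray:
        return np.array([1 if r.is_patient else 0 for r in self.records])


def expected_kcc(rho: float, k: int = 27) -> float:
    """Closed-form expected Kendall's W of an equicorrelated Gaussian cluster."""
    r_s = (6.0 / np.pi) * np.arcsin(rho / 2.0)
    return ((k - 1) * r_s + 1.0) / k


def simulate_subject(spec: SimulationSpec, group: str, subject_seed: int,
                     coherences: dict[str, float] | None = None,
                     subject_id: str = "") -> tuple[BoldSeries, float, float]:
    """Simulate one subject's BOLD run plus motion summary statistics.

    ``coherences`` overrides the group's per-ROI coupling (used by
    :func:`simulate_cohort` to give each subject an individual realization).
    Output is a pure function of ``(spec, group, subject_seed, coherences)``.
    """
    spec.validate()
    rho_by_roi = spec.group_coherence(group)
    if coherences:
        rho_by_roi.update(coherences)
    rng = np.random.default_rng(subject_seed)
    t_len = spec.n_volumes

    data = rng.standard_normal(spec.grid + (t_len,))
    rho_bg = spec.background_coherence
    s_bg = rng.standard_normal(t_len)
    data *= np.sqrt(1.0 - rho_bg)
    data += np.sqrt(rho_bg) * s_bg

    for name in sorted(spec.rois):
        box = spec.rois[name]
        rho = float(np.clip(rho_by_roi[name], 0.0, 0.95))
        shape = tuple(b - a for a, b in zip(box.start, box.stop))
        s_roi = rng.standard_normal(t_len)
        eps = rng.standard_normal(shape + (t_len,))
        data[box.slices()] = np.sqrt(1.0 - rho) * eps + np.sqrt(rho) * s_roi

    # nuisance structure removed by preprocessing: a linear drift and a
    # high-frequency (>0.1 Hz) physiological-style sinusoid
    t = np.arange(t_len)
    drift = rng.normal(0.0, spec.drift_amplitude) * (2.0 * t / max(t_len - 1, 1) - 1.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    cardio = spec.cardio_amplitude * np.sin(
        2.0 * np.pi * spec.cardio_freq_hz * t * spec.tr + phase)
    data += drift + cardio

    shift = float(abs(rng.normal(spec.motion_shift_mean, spec.motion_shift_sd)))
    rot = float(abs(rng.normal(spec.motion_rot_mean, spec.motion_rot_sd)))
    bold = BoldSeries(data=data, affine=spec.affine(), tr=spec.tr,
                      subject_id=subject_id or f"sub-{subject_seed}")
    return bold, shift, rot


def _planted_scores(rng: np.random.Generator, spec: SimulationSpec,
                    realized: dict[str, np.ndarray], group: str,
                    idx: np.ndarray, variable: str) -> np.ndarray:
    """Standardized scores with the target correlation to realized coherence."""
    target = spec.behav_corr.get(variable)
    n = idx.size
    noise = rng.standard_normal(n)
    if target is None:
        return noise
    roi, r = target
    rho = realized[roi][idx]
    sd = rho.std()
    if sd == 0 or n < 3:
        return noise
    z = (rho - rho.mean()) / sd
    return r * z + np.sqrt(max(1.0 - r * r, 0.0)) * noise


def simulate_cohort(spec: SimulationSpec, generate_bold: bool = True,
                    generate_gm: bool = True) -> Cohort:
    """Simulate a full two-group cohort.

    Per-subject ROI coherences are the group value plus Gaussian jitter
    (``coherence_jitter_sd``); behavioral variables are linear functions of
    the realized coherence of their driving ROI plus noise calibrated to the
    target correlation.  Patient gray-matter maps are reduced by
    ``gm_deficit_frac`` inside ``gm_deficit_roi`` only.  With
    ``gm_mediates=True`` the patient coherence deficit in that ROI is driven
    by the same per-subject gray-matter factor, so the functional group
    difference is fully mediated by structure.

    ``generate_bold`` / ``generate_gm`` skip the image synthesis for callers
    that only need the table and realized ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_group
    groups = ["patient"] * n + ["control"] * n
    ids = [f"sub-p{i + 1:02d}" for i in range(n)] + \
          [f"sub-c{i + 1:02d}" for i in range(n)]
    n_total = 2 * n
    is_patient = np.array([g == "patient" for g in groups])

    # per-subject gray-matter factor; under mediation it also drives the
    # coherence deficit in the deficit ROI.  The 0.10 within-group SD against
    # the default 0.15 deficit puts the group difference near t ~ -5 at
    # n=2x30, a realistic separation for a regional volume deficit
    u = rng.standard_normal(n_total)
    gm_factor = 1.0 - spec.gm_deficit_frac * is_patient + 0.10 * u
    gm_factor = np.clip(gm_factor, 0.05, 1.5)

    realized: dict[str, np.ndarray] = {}
    for name in sorted(spec.rois):
        rho_c = spec.coherence_control[name]
        rho_p = spec.coherence_patient[name]
        base = np.where(is_patient, rho_p, rho_c)
        if spec.gm_mediates and name == spec.gm_deficit_roi and spec.gm_deficit_frac > 0:
            slope = (rho_c - rho_p) / spec.gm_deficit_frac
            rho = rho_c - slope * (1.0 - gm_factor) + rng.normal(0.0, 0.01, n_total)
        else:
            rho = base + rng.normal(0.0, spec.coherence_jitter_sd, n_total)
        realized[name] = np.clip(rho, 0.0, 0.95)

    # behavioral scores per group, tied to realized coherence
    scores: dict[str, np.ndarray] = {}
    for var in ("bis_total", "bis_attentional", "bis_motor", "bis_nonplan"):
        col = np.zeros(n_total)
        for group in ("patient", "control"):
            idx = np.flatnonzero(is_patient if group == "patient" else ~is_patient)
            raw = _planted_scores(rng, spec, realized, group, idx, var)
            mean, sd = _BIS_SCALE[group][var]
            lo, hi = _BIS_BOUNDS[var]
            col[idx] = np.clip(np.rint(mean + sd * raw), lo, hi)
        scores[var] = col
    # the instrument's total can never fall below a subscale
    sub_max = np.max([scores[v] for v in
                      ("bis_attentional", "bis_motor", "bis_nonplan")], axis=0)
    scores["bis_total"] = np.maximum(scores["bis_total"], sub_max)

    pat_idx = np.flatnonzero(is_patient)
    duration = np.clip(5.1 + 1.8 * _planted_scores(
        rng, spec, realized, "patient", pat_idx, "duration_use"), 0.5, 10.0)
    age_first = np.clip(19.9 + 4.3 * _planted_scores(
        rng, spec, realized, "patient", pat_idx, "age_first_use"), 12.0, 32.0)

    subject_seeds = rng.integers(0, 2 ** 31 - 1, size=n_total)

    bolds: list[BoldSeries] | None = [] if generate_bold else None
    shifts = np.empty(n_total)
    rots = np.empty(n_total)
    for i in range(n_total):
        coh = {name: float(realized[name][i]) for name in spec.rois}
        if generate_bold:
            bold, shift, rot = simulate_subject(
                spec, groups[i], int(subject_seeds[i]), coherences=coh,
                subject_id=ids[i])
            bolds.append(bold)
        else:
            sub_rng = np.random.default_rng(int(subject_seeds[i]))
            shift = float(abs(sub_rng.normal(spec.motion_shift_mean,
                                             spec.motion_shift_sd)))
            rot = float(abs(sub_rng.normal(spec.motion_rot_mean,
                                           spec.motion_rot_sd)))
        shifts[i], rots[i] = shift, rot

    gm_maps: list[np.ndarray] | None = None
    if generate_gm:
        gm_maps = []
        deficit_slices = spec.rois[spec.gm_deficit_roi].slices()
        for i in range(n_total):
            gm = np.clip(0.55 + 0.04 * u[i]
                         + 0.03 * rng.standard_normal(spec.grid), 0.05, 0.95)
            gm[deficit_slices] *= gm_factor[i]
            gm_maps.append(gm)

    records: list[SubjectRecord] = []
    pat_counter = 0
    for i in range(n_total):
        if is_patient[i]:
            dur = float(duration[pat_counter])
            age = float(age_first[pat_counter])
            pat_counter += 1
        else:
            dur = age = None
        records.append(SubjectRecord(
            subject_id=ids[i], group=groups[i],
            motion_shift=shifts[i], motion_rotation=rots[i],
            bis_total=int(scores["bis_total"][i]),
            bis_attentional=int(scores["bis_attentional"][i]),
            bis_motor=int(scores["bis_motor"][i]),
            bis_nonplan=int(scores["bis_nonplan"][i]),
            duration_use=dur, age_first_use=age,
        ))

    mask = BrainMask(data=np.ones(spec.grid, dtype=bool), affine=spec.affine())
    return Cohort(spec=spec, records=records, realized_coherence=realized,
                  mask=mask, bolds=bolds, gm_maps=gm_maps)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort to disk: BOLD + GM NIfTIs, mask, and subjects.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mask(out / "mask.nii.gz", cohort.mask)
    write_subject_table(cohort.records, out / "subjects.tsv")
    affine = cohort.spec.affine()
    if cohort.bolds is not None:
        for bold in cohort.bolds:
            write_bold(out / f"{bold.subject_id}_bold.nii.gz", bold)
    if cohort.gm_maps is not None:
        for rec, gm in zip(cohort.records, cohort.gm_maps):
            write_map(out / f"{rec.subject_id}_gm.nii.gz", gm, affine)


def spec_from_dict(d: dict) -> SimulationSpec:
    """Build a :class:`SimulationSpec` from a plain (YAML-friendly) mapping.

    ROIs are given as ``name: [x0, x1, y0, y1, z0, z1]`` half-open index
    bounds; behavioral targets as ``variable: [roi, r]``.
    """
    d = dict(d)
    if "rois" in d:
        d["rois"] = {
            name: RoiBox((int(b[0]), int(b[2]), int(b[4])),
                         (int(b[1]), int(b[3]), int(b[5])))
            for name, b in d["rois"].items()
        }
    if "behav_corr" in d:
        d["behav_corr"] = {k: (str(v[0]), float(v[1]))
                           for k, v in d["behav_corr"].items()}
    for key in ("grid", "voxel_size_mm"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationSpec(**d)


def replace_seed(spec: SimulationSpec, seed: int) -> SimulationSpec:
    """Copy of ``spec`` with a new seed (for replicate cohorts)."""
    return replace(spec, seed=int(seed))
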