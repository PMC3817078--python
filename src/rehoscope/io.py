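"""Reading and writing of pipeline artifacts.

All on-disk images are NIfTI-1 (statistic and ReHo maps as 32-bit float,
masks as 8-bit unsigned), subject tables are tab-separated text with a header
row, and run configurations are YAML.  Voxel indices are 0-based throughout;
world coordinates (mm) come only from the affine.  Images that enter the same
pipeline stage must agree in shape and affine — a mismatch is an error, never
a silent resample.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, GeometryError

log = logging.getLogger(__name__)

GROUP_LABELS = ("patient", "control")

#: absolute tolerance for declaring two affines equal
AFFINE_ATOL = 1e-4

_REQUIRED_SUBJECT_COLUMNS = (
    "subject_id",
    "group",
    "motion_shift",
    "motion_rotation",
    "bis_total",
    "bis_attentional",
    "bis_motor",
    "bis_nonplan",
)
_OPTIONAL_SUBJECT_COLUMNS = ("duration_use", "age_first_use")


@dataclass
class BoldSeries:
    """One subject's 4D BOLD run (X x Y x Z x T) with voxel geometry and TR."""

    data: np.ndarray
    affine: np.ndarray
    tr: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise GeometryError(
                f"BOLD series must be 4D, got {self.data.ndim}D "
                f"(subject {self.subject_id!r})"
            )
        if self.data.shape[3] < 2:
            raise GeometryError("BOLD series needs at least 2 time points")
        if not np.isfinite(self.data).all():
            raise ValueError(
                f"non-finite values in BOLD data (subject {self.subject_id!r})"
            )
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise GeometryError("affine is not invertible")
        if not (self.tr > 0):
            raise ConfigError(f"TR must be positive, got {self.tr}")
        self.tr = float(self.tr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        """Copy of this series with new time-series data, same geometry/TR."""
        return BoldSeries(data=data, affine=self.affine.copy(), tr=self.tr,
                          subject_id=self.subject_id)


@dataclass
class BrainMask:
    """3D boolean analysis mask with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError(f"mask must be 3D, got {self.data.ndim}D")
        if not self.data.any():
            raise ValueError("mask contains no voxels")
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class SubjectRecord:
    """One row of the cohort table.

    ``duration_use`` and ``age_first_use`` are defined for patients only and
    stay ``None`` for controls.  ``gm_index`` is filled per analysis ROI by
    the ROI statistics stage.
    """

    subject_id: str
    group: str
    motion_shift: float
    motion_rotation: float
    bis_total: int
    bis_attentional: int
    bis_motor: int
    bis_nonplan: int
    duration_use: float | None = None
    age_first_use: float | None = None
    gm_index: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(
                f"unknown group label {self.group!r}; expected one of {GROUP_LABELS}"
            )
        for name in ("bis_attentional", "bis_motor", "bis_nonplan"):
            sub = getattr(self, name)
            if self.bis_total < sub:
                raise ValueError(
                    f"BIS total ({self.bis_total}) below subscale {name} ({sub})"
                )
        if self.motion_shift < 0 or self.motion_rotation < 0:
            raise ValueError("motion maxima must be non-negative")
        if self.duration_use is not None and not self.duration_use >= 0:
            raise ValueError("duration_use must be >= 0")
        if self.age_first_use is not None and not self.age_first_use > 0:
            raise ValueError("age_first_use must be > 0")

    @property
    def is_patient(self) -> bool:
        return self.group == "patient"


@dataclass
class PipelineConfig:
    """All tunable analysis parameters for one run.

    Defaults follow the study protocol this pipeline mirrors: drop the first
    10 volumes, band-pass 0.01-0.08 Hz, 8-mm FWHM smoothing, voxel p = 0.01
    two-sided, cluster-corrected alpha = 0.05 from 1000 Monte-Carlo
    simulations, and motion screening at 1.0 mm / 1.0 degree.
    """

    n_discard: int = 10
    band: tuple[float, float] = (0.01, 0.08)
    fwhm_mm: float = 8.0
    voxel_p: float = 0.01
    alpha: float = 0.05
    n_sims: int = 1000
    connectivity: int = 18
    neighborhood: int = 27
    motion_limit_mm: float = 1.0
    motion_limit_deg: float = 1.0
    smoothness: str = "nominal"  # "nominal" | "estimated"
    tr: float | None = None  # overrides the NIfTI header when set
    seed: int = 0

    def validate(self, tr: float | None = None) -> None:
        low, high = self.band
        tr_eff = self.tr if self.tr is not None else tr
        if not (0 <= low < high):
            raise ConfigError(f"band must satisfy 0 <= low < high, got {self.band}")
        if tr_eff is not None:
            nyquist = 1.0 / (2.0 * tr_eff)
            if high > nyquist + 1e-12:
                raise ConfigError(
                    f"band upper edge {high} Hz exceeds Nyquist {nyquist} Hz"
                )
        for name in ("voxel_p", "alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if self.n_sims < 1:
            raise ConfigError("n_sims must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")
        if self.neighborhood not in (7, 19, 27):
            raise ConfigError("neighborhood must be 7, 19 or 27")
        if self.n_discard < 0:
            raise ConfigError("n_discard must be >= 0")
        if self.smoothness not in ("nominal", "estimated"):
            raise ConfigError("smoothness must be 'nominal' or 'estimated'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(float(x) for x in d["band"])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig.from_dict(raw)
    cfg.validate()
    return cfg


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# images


def read_bold(path: str | Path, tr: float | None = None,
              subject_id: str | None = None) -> BoldSeries:
    """Load a 4D NIfTI as a :class:`BoldSeries`.

    TR precedence is config override first, header ``pixdim[4]`` second; a
    zero/missing header TR with no override is a configuration error.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise GeometryError(f"{path}: expected a 4D image, got {img.ndim}D")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    tr_eff = tr if tr is not None else header_tr
    if not tr_eff or tr_eff <= 0:
        raise ConfigError(
            f"{path}: header TR is {header_tr} and no TR override was given"
        )
    sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
    log.info("%s: %s volumes of %s, TR=%.3gs", sid, img.shape[3],
             "x".join(str(d) for d in img.shape[:3]), tr_eff)
    return BoldSeries(
        data=np.asarray(img.dataobj, dtype=np.float64),
        affine=img.affine,
        tr=tr_eff,
        subject_id=sid,
    )


def read_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI map, returning ``(data, affine)``."""
    img = nib.load(str(path))
    data = np.squeeze(np.asarray(img.dataobj, dtype=np.float64))
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D image, got {data.ndim}D")
    return data, np.asarray(img.affine, dtype=np.float64)


def read_mask(path: str | Path) -> BrainMask:
    data, affine = read_map(path)
    return BrainMask(data=data > 0, affine=affine)


def write_map(path: str | Path, data: np.ndarray, affine: np.ndarray,
              tr: float | None = None) -> None:
    """Write a float32 NIfTI-1 image (3D map or 4D series)."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    if tr is not None and data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


def write_bold(path: str | Path, bold: BoldSeries) -> None:
    write_map(path, bold.data, bold.affine, tr=bold.tr)


def write_mask(path: str | Path, mask: BrainMask) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def check_geometry(shape_a, affine_a, shape_b, affine_b, what: str = "images") -> None:
    """Raise :class:`GeometryError` unless shapes match and affines agree.

    Affine agreement is entrywise to ``AFFINE_ATOL``; only the leading three
    spatial dimensions of the shapes are compared.
    """
    if tuple(shape_a[:3]) != tuple(shape_b[:3]):
        raise GeometryError(
            f"{what}: shape mismatch {tuple(shape_a[:3])} vs {tuple(shape_b[:3])}"
        )
    if not np.allclose(affine_a, affine_b, atol=AFFINE_ATOL, rtol=0):
        raise GeometryError(f"{what}: affines differ beyond {AFFINE_ATOL}")


# ---------------------------------------------------------------------------
# subject tables


def _parse_float(value, column: str, row: int) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"row {row}: non-numeric {column}={value!r}") from exc
    if math.isnan(out):
        raise ValueError(f"row {row}: missing required value for {column}")
    return out


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Parse a TSV cohort table into validated :class:`SubjectRecord` rows."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_REQUIRED_SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records: list[SubjectRecord] = []
    for i, row in df.iterrows():
        group = str(row["group"]).strip()
        if group not in GROUP_LABELS:
            raise ValueError(
                f"{path} row {i}: unknown group label {group!r}; "
                f"expected one of {GROUP_LABELS}"
            )
        kwargs: dict = {"subject_id": str(row["subject_id"]).strip(), "group": group}
        for col in ("motion_shift", "motion_rotation"):
            kwargs[col] = _parse_float(row[col], col, i)
        for col in ("bis_total", "bis_attentional", "bis_motor", "bis_nonplan"):
            kwargs[col] = int(round(_parse_float(row[col], col, i)))
        for col in _OPTIONAL_SUBJECT_COLUMNS:
            raw = row.get(col)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) \
                    or str(raw).strip() in ("", "nan", "NA", "N/A"):
                kwargs[col] = None
            else:
                kwargs[col] = _parse_float(raw, col, i)
        records.append(SubjectRecord(**kwargs))
    return records


def write_subject_table(records: list[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id,
            "group": r.group,
            "motion_shift": f"{r.motion_shift:.6f}",
            "motion_rotation": f"{r.motion_rotation:.6f}",
            "bis_total": r.bis_total,
            "bis_attentional": r.bis_attentional,
            "bis_motor": r.bis_motor,
            "bis_nonplan": r.bis_nonplan,
            "duration_use": "" if r.duration_use is None else f"{r.duration_use:.2f}",
            "age_first_use": "" if r.age_first_use is None else f"{r.age_first_use:.2f}",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
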