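"""Volume and table I/O plus the spatial data model shared by all modules.

Volumes are NIfTI-1, treated as template-space data on a common voxel grid:
all coordinates used anywhere in the package are 0-based voxel indices, and
grid compatibility means identical spatial shape. Participant tables are
comma-separated text with a header row.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BoldSeries",
    "BrainMask",
    "LabelAtlas",
    "ParticipantRecord",
    "read_bold",
    "write_bold",
    "read_mask",
    "write_mask",
    "read_atlas",
    "write_atlas",
    "read_participants",
    "participants_frame",
    "load_packaged_participants",
    "check_grid_compatible",
]

GROUP_LEVELS = ("R+", "R-")
SEX_LEVELS = ("male", "female")

#: columns a participant table must provide
REQUIRED_COLUMNS = (
    "id",
    "group",
    "sex",
    "birth_ga_weeks",
    "pma_scan_weeks",
    "postnatal_age_days",
    "birth_weight_kg",
    "head_circumference_cm",
)


@dataclass
class BoldSeries:
    """A 4D BOLD volume: ``data`` indexed (x, y, z, t).

    ``voxel_size`` is in mm per spatial axis and ``repetition_time`` in
    seconds per volume.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    repetition_time: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D BOLD data, got {self.data.ndim}D")
        if self.n_volumes < 2:
            raise ValueError("a BOLD series needs at least 2 volumes")
        if any(s < 1 for s in self.data.shape[:3]):
            raise ValueError("all spatial dimensions must be >= 1")
        if not np.isfinite(self.repetition_time) or self.repetition_time <= 0:
            raise ValueError(f"repetition_time must be positive, got {self.repetition_time}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def duration_seconds(self) -> float:
        """Total acquisition time covered by the series."""
        return self.n_volumes * self.repetition_time


@dataclass
class BrainMask:
    """Boolean 3D mask on the BOLD spatial grid."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        if not self.data.any():
            raise ValueError("mask has no in-brain voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelAtlas:
    """Integer-labelled hard parcellation (0 = background).

    ``labels`` maps each nonzero label to a region name; ``control_labels``
    flags the subset used as control regions (regions where no group or
    maturational effect is expected).
    """

    data: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)
    control_labels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D atlas, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = self.data.astype(np.int64)
            if not np.array_equal(as_int, self.data):
                raise ValueError("atlas values must be non-negative integers")
            self.data = as_int
        if (self.data < 0).any():
            raise ValueError("atlas values must be non-negative")
        present = set(np.unique(self.data)) - {0}
        if not self.labels:
            self.labels = {int(v): f"roi_{int(v):02d}" for v in sorted(present)}
        missing = present - set(self.labels)
        if missing:
            raise ValueError(f"atlas values without a label name: {sorted(missing)}")
        self.control_labels = frozenset(int(v) for v in self.control_labels)

    @property
    def roi_labels(self) -> list[int]:
        """Nonzero labels present in the volume, sorted."""
        return sorted(set(int(v) for v in np.unique(self.data)) - {0})


@dataclass
class ParticipantRecord:
    """Covariates for one scanned neonate."""

    id: str
    group: str  # "R+" (first-degree relative with ASD) or "R-"
    sex: str  # "male" / "female"
    birth_ga_weeks: float
    pma_scan_weeks: float
    postnatal_age_days: float
    birth_weight_kg: float
    head_circumference_cm: float

    def __post_init__(self) -> None:
        if self.group not in GROUP_LEVELS:
            raise ValueError(f"participant {self.id}: group must be one of {GROUP_LEVELS}")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"participant {self.id}: sex must be one of {SEX_LEVELS}")
        numeric = {
            "birth_ga_weeks": self.birth_ga_weeks,
            "pma_scan_weeks": self.pma_scan_weeks,
            "postnatal_age_days": self.postnatal_age_days,
            "birth_weight_kg": self.birth_weight_kg,
            "head_circumference_cm": self.head_circumference_cm,
        }
        for name, value in numeric.items():
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"participant {self.id}: {name} must be positive, got {value}")
        if self.pma_scan_weeks < self.birth_ga_weeks:
            raise ValueError(
                f"participant {self.id}: postmenstrual age at scan "
                f"({self.pma_scan_weeks}) precedes gestational age at birth "
                f"({self.birth_ga_weeks})"
            )


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    return aff


def read_bold(path: str | Path) -> BoldSeries:
    """Read a 4D NIfTI volume; voxel size and TR come from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BOLD file not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4D BOLD volume, got {img.ndim}D: {path}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr <= 0:
        raise ValueError(f"non-positive repetition time in header of {path}: {tr}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    return BoldSeries(
        data=data,
        voxel_size=tuple(float(z) for z in zooms[:3]),
        repetition_time=tr,
    )


def write_bold(series: BoldSeries, path: str | Path) -> Path:
    """Write a :class:`BoldSeries` as NIfTI-1, preserving voxel size and TR."""
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float64), _affine(series.voxel_size))
    img.header.set_zooms((*series.voxel_size, series.repetition_time))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> BrainMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D mask, got {img.ndim}D: {path}")
    return BrainMask(np.asarray(img.dataobj) > 0)


def write_mask(mask: BrainMask, path: str | Path, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(voxel_size))
    nib.save(img, str(path))
    return path


def read_atlas(
    path: str | Path,
    labels: dict[int, str] | None = None,
    control_labels=(),
) -> LabelAtlas:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"atlas file not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D atlas, got {img.ndim}D: {path}")
    data = np.rint(np.asarray(img.dataobj)).astype(np.int32)
    return LabelAtlas(data, labels=labels or {}, control_labels=frozenset(control_labels))


def write_atlas(atlas: LabelAtlas, path: str | Path, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(atlas.data.astype(np.int32), _affine(voxel_size))
    nib.save(img, str(path))
    return path


def write_map(data: np.ndarray, path: str | Path, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    """Write a single 3D (or stacked 4D) statistical map as NIfTI."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size))
    nib.save(img, str(path))
    return path


def _normalise_group(raw: str, row: int) -> str:
    token = str(raw).strip().replace("−", "-").replace("–", "-").upper()
    if token in {"R+", "RPLUS", "R_PLUS"}:
        return "R+"
    if token in {"R-", "RMINUS", "R_MINUS"}:
        return "R-"
    raise ValueError(f"row {row}: cannot parse group {raw!r} (expected R+ or R-)")


def _normalise_sex(raw: str, row: int) -> str:
    token = str(raw).strip().lower()
    if token in {"male", "m"}:
        return "male"
    if token in {"female", "f"}:
        return "female"
    raise ValueError(f"row {row}: cannot parse sex {raw!r}")


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    """Read a participant covariate table (CSV with header row).

    Required columns: id, group, sex, birth_ga_weeks, pma_scan_weeks,
    postnatal_age_days, birth_weight_kg, head_circumference_cm. Group and
    sex are validated case-insensitively.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"participant table not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"participant table is empty: {path}") from exc
    if df.empty:
        raise ValueError(f"participant table has no rows: {path}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"participant table missing columns: {missing}")
    records: list[ParticipantRecord] = []
    numeric_cols = REQUIRED_COLUMNS[3:]
    for i, row in enumerate(df.itertuples(index=False)):
        values = {}
        for col in numeric_cols:
            raw = getattr(row, col)
            try:
                values[col] = float(raw)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"row {i}: unparseable numeric value {raw!r} in column {col}") from exc
        records.append(
            ParticipantRecord(
                id=str(row.id),
                group=_normalise_group(row.group, i),
                sex=_normalise_sex(row.sex, i),
                **values,
            )
        )
    return records


def participants_frame(participants: list[ParticipantRecord]) -> pd.DataFrame:
    """Tabular view of a participant list (one row per record)."""
    return pd.DataFrame([vars(p) for p in participants])


def load_packaged_participants() -> list[ParticipantRecord]:
    """The packaged 36-infant cohort table (18 R+, 18 R-)."""
    with resources.as_file(resources.files("neoreho.data") / "participants.csv") as p:
        return read_participants(p)


def check_grid_compatible(*shapes_or_objects) -> tuple[int, int, int]:
    """Assert all arguments share one spatial grid; return it.

    Accepts BoldSeries/BrainMask/LabelAtlas/ndarray/shape tuples.
    """
    shapes = []
    for obj in shapes_or_objects:
        if isinstance(obj, BoldSeries):
            shapes.append(obj.spatial_shape)
        elif isinstance(obj, (BrainMask, LabelAtlas)):
            shapes.append(tuple(obj.data.shape))
        elif isinstance(obj, np.ndarray):
            shapes.append(tuple(obj.shape[:3]))
        else:
            shapes.append(tuple(obj))
    first = shapes[0]
    for s in shapes[1:]:
        if s != first:
            raise ValueError(f"incompatible spatial grids: {first} vs {s}")
    return first
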