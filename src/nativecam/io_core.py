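"""Domain types and NIfTI / tabular I/O shared by the whole pipeline.

Everything downstream speaks in two image currencies: :class:`Volume`
(scalar grid + 4x4 voxel-to-world affine) and :class:`LabelVolume`
(integer parcellation grid + affine + label table).  Voxel indices are
0-based; the affine maps the homogeneous index column ``[i, j, k, 1]`` to
world millimetre coordinates, per the NIfTI convention.  Where a file
carries both a qform and an sform, the sform wins (nibabel's default
best-affine policy, which this package adopts deliberately).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "LabelVolume",
    "ParticipantRecord",
    "RegionInfo",
    "read_volume",
    "write_volume",
    "reorient_to_ras",
    "read_phenotype",
    "write_phenotype",
    "voxel_spacing",
]

VALID_SPLITS = ("train", "validation", "test", "test2")
VALID_HEMISPHERES = ("left", "right", "bilateral", "none")


def voxel_spacing(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel size in mm: column norms of the upper-left 3x3."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) <= 0.0:
        raise ValueError("affine is singular (zero determinant of the 3x3 block)")
    if np.any(voxel_spacing(affine) <= 0):
        raise ValueError("affine implies a non-positive voxel spacing")
    return affine


@dataclass
class Volume:
    """A 3D scalar image in its native scanner frame.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (arbitrary units) or importance scores.
    affine : ndarray, shape (4, 4)
        Voxel-index-to-world-mm map; must be invertible.
    id : str
        Participant identifier; empty for anonymous volumes.
    """

    data: np.ndarray
    affine: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return voxel_spacing(self.affine)

    def with_data(self, data: np.ndarray, affine: np.ndarray | None = None) -> "Volume":
        return Volume(data=data, affine=self.affine if affine is None else affine, id=self.id)


@dataclass(frozen=True)
class RegionInfo:
    name: str
    hemisphere: str = "none"

    def __post_init__(self) -> None:
        if self.hemisphere not in VALID_HEMISPHERES:
            raise ValueError(
                f"hemisphere must be one of {VALID_HEMISPHERES}, got {self.hemisphere!r}"
            )


@dataclass
class LabelVolume:
    """Per-subject parcellation: integer labels on a grid, 0 = background."""

    labels: np.ndarray
    affine: np.ndarray
    label_table: dict[int, RegionInfo] = field(default_factory=dict)
    id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D label volume, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        self.affine = _check_affine(self.affine)
        if 0 in self.label_table:
            raise ValueError("label 0 is reserved for background and must not be in the table")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels present in grid but absent from label table: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return voxel_spacing(self.affine)


@dataclass(frozen=True)
class ParticipantRecord:
    id: str
    label: int
    site: str
    gender: str
    age: float
    split: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.gender not in ("male", "female"):
            raise ValueError(f"gender must be 'male' or 'female', got {self.gender!r}")
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")
        if self.split not in VALID_SPLITS:
            raise ValueError(f"split must be one of {VALID_SPLITS}, got {self.split!r}")


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 file as a :class:`Volume`, without any resampling."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(path)
    if len(img.shape) != 3:
        raise ValueError(f"expected 3D volume, got {len(img.shape)}D in {path}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    return Volume(data=data, affine=np.asarray(img.affine, dtype=float), id=path.name.split(".")[0])


def write_volume(v: Volume | LabelVolume, path: str | Path) -> Path:
    """Write a Volume (float) or LabelVolume (integer dtype on disk) as NIfTI-1."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(v, LabelVolume):
        data = np.asarray(v.labels, dtype=np.int32)
    else:
        data = np.asarray(v.data, dtype=np.float64)
    img = nib.Nifti1Image(data, v.affine)
    img.set_sform(v.affine, code=1)
    img.set_qform(v.affine, code=1)
    nib.save(img, path)
    return path


def reorient_to_ras(v: Volume) -> Volume:
    """Permute/flip grid axes so voxel axes point along +x/+y/+z (RAS+).

    World coordinates of every voxel are unchanged; only the storage order
    and the affine change.  For perfectly oblique axes the dominant world
    axis is ambiguous; nibabel's ``io_orientation`` breaks the tie toward
    the lowest axis index, which is the deterministic behaviour we want.
    """
    ornt = nib.orientations.io_orientation(v.affine)
    ras = nib.orientations.axcodes2ornt(("R", "A", "S"))
    transform = nib.orientations.ornt_transform(ornt, ras)
    data = nib.orientations.apply_orientation(v.data, transform)
    affine = v.affine @ nib.orientations.inv_ornt_aff(transform, v.data.shape)
    return Volume(data=data, affine=affine, id=v.id)


_PHENO_COLUMNS = ("id", "label", "site", "gender", "age", "split")


def read_phenotype(path: str | Path) -> list[ParticipantRecord]:
    """Read a phenotype table (TSV or CSV by extension) into records."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "site": str})
    missing = [c for c in _PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate participant id(s): {sorted(set(dupes))}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ParticipantRecord(
                id=str(row.id),
                label=int(row.label),
                site=str(row.site),
                gender=str(row.gender),
                age=float(row.age),
                split=str(row.split),
            )
        )
    return records


def write_phenotype(records: list[ParticipantRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([r.__dict__ for r in records], columns=list(_PHENO_COLUMNS))
    df.to_csv(path, sep="\t", index=False)
    return path
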