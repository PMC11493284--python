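"""Segmentation-provider contract: prepare scans for an external
parcellation tool and bring its label volumes onto the attention grid.

The anatomical parcellation itself (e.g. a GIF-protocol segmenter) is an
external, trained component; this module owns everything around it:
resampling scans to the 1 mm isotropic grid such tools expect, loading
and validating the label volumes they produce, and conforming those
labels onto the attention-map grid by nearest-neighbour transport so the
region-attribution step can tabulate mask voxels against regions.
Nearest-neighbour is non-negotiable for labels — linear interpolation
would blend category codes — and any attention-grid voxel whose world
position falls outside the segmented field of view becomes background 0,
which keeps the background a well-defined, scoreable region.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .attribution import AttentionMask
from .io_core import LabelVolume, RegionInfo, Volume, reorient_to_ras
from .preprocess import resample
from .region_attribution import map_voxel_coordinates

__all__ = [
    "prepare_for_segmentation",
    "load_segmentation",
    "read_label_table",
    "write_label_table",
    "conform_labels_to_attention_grid",
]


def prepare_for_segmentation(v: Volume, spacing: float = 1.0) -> Volume:
    """Standardise a scan to 1 mm isotropic RAS+ with linear interpolation."""
    return resample(reorient_to_ras(v), (spacing, spacing, spacing), "linear")


def read_label_table(path: str | Path) -> dict[int, RegionInfo]:
    """Read a TSV with columns id, name, hemisphere into a label table."""
    df = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in ("id", "name", "hemisphere") if c not in df.columns]
    if missing:
        raise ValueError(f"label table missing columns: {missing}")
    table: dict[int, RegionInfo] = {}
    for row in df.itertuples(index=False):
        rid = int(row.id)
        if rid in table:
            raise ValueError(f"duplicate label id {rid} in table")
        table[rid] = RegionInfo(name=str(row.name), hemisphere=str(row.hemisphere))
    return table


def write_label_table(table: dict[int, RegionInfo], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [{"id": rid, "name": info.name, "hemisphere": info.hemisphere}
         for rid, info in sorted(table.items())])
    df.to_csv(path, sep="\t", index=False)
    return path


def load_segmentation(path: str | Path, label_table_path: str | Path) -> LabelVolume:
    """Load an externally produced label volume plus its label table.

    Values must be integers (tolerance 1e-6 for float-stored files) and
    every nonzero label must be described in the table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such segmentation: {path}")
    img = nib.load(path)
    if len(img.shape) != 3:
        raise ValueError(f"expected 3D label volume, got {len(img.shape)}D")
    raw = np.asarray(img.dataobj, dtype=np.float64)
    rounded = np.rint(raw)
    bad = np.abs(raw - rounded) > 1e-6
    if bad.any():
        example = float(raw[bad][0])
        raise ValueError(f"non-integer label value {example} in {path}")
    labels = rounded.astype(np.int32)
    table = read_label_table(label_table_path)
    present = set(np.unique(labels).tolist()) - {0}
    unknown = sorted(present - set(table))
    if unknown:
        raise ValueError(f"label(s) {unknown} present in {path} but absent from the label table")
    return LabelVolume(labels=labels, affine=np.asarray(img.affine, dtype=float),
                       label_table=table, id=path.name.split(".")[0])


def conform_labels_to_attention_grid(s: LabelVolume, target: AttentionMask | Volume) -> LabelVolume:
    """Resample labels onto the attention grid by nearest-neighbour transport.

    The output shares the target's grid shape and affine (the matrix A of
    the coordinate-transport step); each output voxel takes the label of
    the nearest source voxel centre, and voxels outside the source field
    of view become background 0.
    """
    if isinstance(target, AttentionMask):
        t_shape, t_affine = target.mask.shape, target.affine
    else:
        t_shape, t_affine = target.shape, target.affine
    if any(n < 1 for n in t_shape):
        raise ValueError("degenerate target grid")
    t_affine = np.asarray(t_affine, dtype=float)
    if abs(np.linalg.det(t_affine[:3, :3])) <= 0:
        raise ValueError("target affine is singular")
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in t_shape], indexing="ij")
    coords = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    labels = map_voxel_coordinates(t_affine, s, coords).reshape(t_shape)
    return LabelVolume(labels=labels, affine=t_affine.copy(),
                       label_table=dict(s.label_table), id=s.id)
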