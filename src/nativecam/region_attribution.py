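"""Region-level attribution: affine coordinate transport, relative
frequencies, most-predictive region selection, and consistency tallies.

This is the pipeline's core interpretation step.  Because every scan
stays in native space, attention masks and anatomical parcellations live
on per-subject grids that are reconciled purely through affine algebra:
with A the voxel-to-world affine of one grid and B = A^-1 of the other,
a voxel index Y on the attention grid is transported to the parcellation
grid as X = B_source . A_target . Y.  Each region's score for one
participant is then the relative frequency (RF) — the fraction of the
region's voxels flagged important by the binary mask M.  Regions whose
RF strictly exceeds the 90th percentile of the RF column are "most
predictive"; tallying their presence across models, datasets and strata
(prediction outcome, gender, age bin) yields the consistency tables.
The background (label 0) is deliberately kept as a scored region so that
an attribution dominated by non-brain voxels is visible as a high
background RF rather than silently discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attribution import AttentionMask
from .io_core import LabelVolume, RegionInfo
from .model import PredictionRecord, age_bin

__all__ = [
    "RFTable",
    "RegionSet",
    "ConsistencyTable",
    "map_voxel_coordinates",
    "relative_frequencies",
    "aggregate_rf",
    "select_top_regions",
    "stratify",
    "tally_consistency",
    "background_audit",
]

_RF_COLUMNS = ["region_id", "region_name", "hemisphere",
               "n_voxels_region", "n_voxels_important", "rf"]


@dataclass
class RFTable:
    """Per-region relative frequencies for one participant or one group."""

    table: pd.DataFrame
    scope: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in _RF_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"RFTable missing columns {missing}")
        rf = self.table["rf"].to_numpy()
        if np.any((rf < 0) | (rf > 1)):
            raise ValueError("rf values must lie in [0, 1]")

    def rf_of(self, region_id: int) -> float:
        row = self.table[self.table["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"region {region_id} not in table")
        return float(row["rf"].iloc[0])


@dataclass(frozen=True)
class RegionSet:
    """The most-predictive regions for one (model, dataset, stratum) cell."""

    members: frozenset[int]
    model: str = ""
    dataset: str = ""
    stratum: str = ""
    threshold: float = float("nan")


@dataclass
class ConsistencyTable:
    """Occurrence (1/0) of most-predictive status per region across cells."""

    table: pd.DataFrame  # columns: region_id, model, dataset, stratum, present
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def map_voxel_coordinates(target_affine: np.ndarray, source_labels: LabelVolume,
                          coords: np.ndarray) -> np.ndarray:
    """Transport target-grid voxel indices to source labels via affines.

    For each target index Y the world position is ``A_target . [Y, 1]``
    and the source index is ``B . world`` with ``B`` the inverse of the
    source affine.  Indices are rounded to the nearest voxel with 0.5
    rounding toward +inf per axis (``floor(x + 0.5)``); indices outside
    the source grid return background 0.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[-1] != 3:
        raise ValueError("coords must be (..., 3) voxel indices")
    b = np.linalg.inv(source_labels.affine)
    transport = b @ target_affine  # target index -> source index (homogeneous)
    homog = np.concatenate([coords, np.ones((len(coords), 1))], axis=1)
    src = (transport @ homog.T).T[:, :3]
    idx = np.floor(src + 0.5).astype(np.int64)
    shape = np.asarray(source_labels.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros(len(coords), dtype=source_labels.labels.dtype)
    ii = idx[inside]
    out[inside] = source_labels.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def relative_frequencies(m: AttentionMask, s: LabelVolume, scope: str = "") -> RFTable:
    """RF per region: masked voxel count over total voxel count, per label.

    ``m`` and ``s`` must share grid and affine (conform the labels first).
    One row per label present in the grid, background included; the
    important-voxel counts partition the mask, so they sum to |{M=1}|.
    """
    if m.mask.shape != s.shape:
        raise ValueError(f"grid mismatch: mask {m.mask.shape} vs labels {s.shape}")
    if not np.allclose(m.affine, s.affine, atol=1e-6):
        raise ValueError("affine mismatch between mask and labels")
    labels = s.labels.ravel()
    mask = m.mask.ravel().astype(bool)
    n_labels = int(labels.max()) + 1
    total = np.bincount(labels, minlength=n_labels)
    important = np.bincount(labels[mask], minlength=n_labels)
    rows = []
    for region_id in np.nonzero(total)[0]:
        info = s.label_table.get(int(region_id), RegionInfo("background", "none"))
        rows.append({
            "region_id": int(region_id),
            "region_name": info.name,
            "hemisphere": info.hemisphere,
            "n_voxels_region": int(total[region_id]),
            "n_voxels_important": int(important[region_id]),
            "rf": important[region_id] / total[region_id],
        })
    return RFTable(pd.DataFrame(rows, columns=_RF_COLUMNS), scope=scope)


def aggregate_rf(tables: list[RFTable], scope: str = "", method: str = "mean") -> RFTable:
    """Aggregate per-participant RF tables over a group.

    Per region the group RF is the mean (or median) of per-participant
    RFs, with participants lacking the region contributing 0; the voxel
    counts are summed as audit columns.
    """
    if not tables:
        raise ValueError("cannot aggregate an empty group")
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    meta: dict[int, tuple[str, str]] = {}
    for t in tables:
        for row in t.table.itertuples(index=False):
            meta.setdefault(int(row.region_id), (row.region_name, row.hemisphere))
    region_ids = sorted(meta)
    rf_matrix = np.zeros((len(tables), len(region_ids)))
    totals = np.zeros(len(region_ids), dtype=np.int64)
    importants = np.zeros(len(region_ids), dtype=np.int64)
    col = {r: i for i, r in enumerate(region_ids)}
    for ti, t in enumerate(tables):
        for row in t.table.itertuples(index=False):
            j = col[int(row.region_id)]
            rf_matrix[ti, j] = row.rf
            totals[j] += row.n_voxels_region
            importants[j] += row.n_voxels_important
    agg = rf_matrix.mean(axis=0) if method == "mean" else np.median(rf_matrix, axis=0)
    rows = [{
        "region_id": r,
        "region_name": meta[r][0],
        "hemisphere": meta[r][1],
        "n_voxels_region": int(totals[col[r]]),
        "n_voxels_important": int(importants[col[r]]),
        "rf": float(agg[col[r]]),
    } for r in region_ids]
    return RFTable(pd.DataFrame(rows, columns=_RF_COLUMNS), scope=scope)


def select_top_regions(t: RFTable, percentile: float = 90.0,
                       include_background: bool = True,
                       model: str = "", dataset: str = "", stratum: str = "") -> RegionSet:
    """Regions whose RF strictly exceeds the table's RF percentile.

    The percentile interpolates linearly between order statistics; the
    strict ``>`` means a table of identical RFs selects nothing.  The
    background row participates by default, both in the percentile
    computation and as a candidate — a deliberate audit channel.
    """
    df = t.table if include_background else t.table[t.table["region_id"] != 0]
    if df.empty:
        raise ValueError("empty RF table")
    rf = df["rf"].to_numpy()
    threshold = float(np.percentile(rf, percentile))
    members = frozenset(int(r) for r in df.loc[df["rf"] > threshold, "region_id"])
    return RegionSet(members=members, model=model, dataset=dataset,
                     stratum=stratum, threshold=threshold)


def stratify(preds: list[PredictionRecord], scheme: str = "outcome") -> dict[str, list[PredictionRecord]]:
    """Partition predictions into strata.

    ``scheme`` is a comma-separated subset of {outcome, gender, age}:
    outcome is TP/TN/FP/FN, age uses the half-open bins [5,10), [10,15),
    [15,20), [20,inf).  Records younger than 5 go to a flagged "under-5"
    component of the age axis.  Every record lands in exactly one cell.
    """
    axes = [a.strip() for a in scheme.split(",") if a.strip()]
    valid = {"outcome", "gender", "age"}
    if not axes or not set(axes) <= valid:
        raise ValueError(f"scheme must name axes from {sorted(valid)}, got {scheme!r}")
    cells: dict[str, list[PredictionRecord]] = {}
    for p in preds:
        parts = []
        for axis in axes:
            if axis == "outcome":
                if p.outcome is None:
                    raise ValueError(f"record {p.id} lacks an outcome (no true label)")
                parts.append(p.outcome)
            elif axis == "gender":
                parts.append(p.gender)
            else:
                parts.append(age_bin(p.age))
        cells.setdefault("/".join(parts), []).append(p)
    return cells


def tally_consistency(sets: list[RegionSet],
                      label_table: dict[int, RegionInfo] | None = None) -> ConsistencyTable:
    """Tally 1/0 occurrence of most-predictive status across cells.

    Long-format rows (region, model, dataset, stratum, present) over the
    union label universe, plus a per-(region, model) summary counting the
    datasets in which the region was selected; ``in_all_models`` marks
    the regions selected in every dataset for every model.
    """
    if not sets:
        raise ValueError("no region sets to tally")
    universe = sorted(set().union(*[s.members for s in sets]))
    rows = []
    for s in sets:
        for r in universe:
            rows.append({"region_id": r, "model": s.model, "dataset": s.dataset,
                         "stratum": s.stratum, "present": int(r in s.members)})
    table = pd.DataFrame(rows)
    per_model = (table.groupby(["region_id", "model"])["present"]
                 .agg(["sum", "count"])
                 .rename(columns={"sum": "n_present", "count": "n_cells"})
                 .reset_index())
    consistent = (per_model.groupby("region_id")
                  .apply(lambda g: bool((g["n_present"] == g["n_cells"]).all()), include_groups=False)
                  .rename("in_all_models").reset_index())
    summary = per_model.merge(consistent, on="region_id")
    if label_table is not None:
        summary["region_name"] = summary["region_id"].map(
            lambda r: label_table.get(r, RegionInfo("background", "none")).name)
        summary["hemisphere"] = summary["region_id"].map(
            lambda r: label_table.get(r, RegionInfo("background", "none")).hemisphere)
    return ConsistencyTable(table=table, summary=summary)


def hemisphere_breakdown(region_ids, label_table: dict[int, RegionInfo]) -> dict[str, int]:
    """Count selected regions by hemisphere (left / right / bilateral / none)."""
    counts = {"left": 0, "right": 0, "bilateral": 0, "none": 0}
    for r in region_ids:
        info = label_table.get(int(r), RegionInfo("background", "none"))
        counts[info.hemisphere] += 1
    return counts


def background_audit(tables: dict[str, RFTable]) -> pd.DataFrame:
    """Background RF and its rank (1 = most important) per aggregated table.

    An attribution confined to brain tissue should put the background at
    or near the bottom of the ranking; a high background rank is a red
    flag for the classifier attending to non-brain context.
    """
    rows = []
    for key, t in tables.items():
        df = t.table.sort_values(["rf", "region_id"], ascending=[False, True]).reset_index(drop=True)
        bg = df.index[df["region_id"] == 0]
        if len(bg) == 0:
            raise ValueError(f"table {key!r} has no background row")
        rows.append({"table": key, "background_rf": float(df.loc[bg[0], "rf"]),
                     "rank": int(bg[0]) + 1, "n_regions": len(df)})
    return pd.DataFrame(rows)
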