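"""Minimal native-space preprocessing: no template registration, ever.

The chain standardises geometry and intensities while keeping each scan in
its own scanner frame: resample to a fixed voxel size, reorder axes to
RAS+, clip intensity outliers to an empirical percentile range, z-score,
and crop/pad to a fixed grid.  Intensity statistics (percentiles, mean,
standard deviation) are computed *before* padding, so the zero padding
never contaminates them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_core import LabelVolume, Volume, reorient_to_ras, voxel_spacing

__all__ = [
    "PreprocessConfig",
    "resample",
    "resample_labels",
    "clip_intensities",
    "zscore",
    "crop_or_pad",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    target_spacing : mm per axis after resampling (isotropic default 1.5).
    clip_percentiles : intensity clipping range in percent (0.5, 99.5).
    target_shape : voxels per axis after crop/pad (default 256).
    interpolation : 'linear' for scalar images ('nearest' for labels only).
    zscore_nonzero_only : restrict mean/sd to nonzero voxels (off by
        default: the normalisation formula is applied over all voxels).
    """

    target_spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    clip_percentiles: tuple[float, float] = (0.5, 99.5)
    target_shape: tuple[int, int, int] = (256, 256, 256)
    interpolation: str = "linear"
    zscore_nonzero_only: bool = False

    def __post_init__(self) -> None:
        low, high = self.clip_percentiles
        if not (0 <= low < high <= 100):
            raise ValueError(f"clip percentiles must satisfy 0 <= low < high <= 100, got {self.clip_percentiles}")
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")
        if any(n < 1 for n in self.target_shape):
            raise ValueError("target_shape must be >= 1 per axis")
        if self.interpolation not in ("linear", "nearest"):
            raise ValueError("interpolation must be 'linear' or 'nearest'")


_ORDER = {"linear": 1, "nearest": 0}


def _resample_geometry(affine: np.ndarray, shape: tuple[int, ...], spacing) -> tuple[np.ndarray, tuple[int, ...], np.ndarray]:
    """New affine/shape for a spacing change, plus the output->input index map.

    The output grid keeps the input's direction cosines and world origin
    (voxel (0,0,0) stays put) and covers the input field of view:
    ``out_dim = ceil(in_dim * in_spacing / out_spacing)`` per axis.
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    if np.any(spacing <= 0):
        raise ValueError("target spacing must be positive")
    in_spacing = voxel_spacing(affine)
    directions = affine[:3, :3] / in_spacing  # unit columns
    new_affine = np.eye(4)
    new_affine[:3, :3] = directions * spacing
    new_affine[:3, 3] = affine[:3, 3]
    out_shape = tuple(int(np.ceil(n * s_in / s_out)) for n, s_in, s_out in zip(shape, in_spacing, spacing))
    # affine_transform maps output index -> input index: inv(A_in) @ A_out
    index_map = np.linalg.inv(affine) @ new_affine
    return new_affine, out_shape, index_map


def resample(v: Volume, spacing, interpolation: str = "linear") -> Volume:
    """Resample a scalar volume to the requested voxel spacing.

    Linear interpolation is the default; edge samples are clamped to the
    nearest input voxel so a constant image stays exactly constant.
    """
    if interpolation not in _ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    new_affine, out_shape, index_map = _resample_geometry(v.affine, v.shape, spacing)
    data = ndimage.affine_transform(
        np.asarray(v.data, dtype=np.float64),
        index_map[:3, :3],
        offset=index_map[:3, 3],
        output_shape=out_shape,
        order=_ORDER[interpolation],
        mode="nearest",
    )
    return Volume(data=data, affine=new_affine, id=v.id)


def resample_labels(s: LabelVolume, spacing) -> LabelVolume:
    """Nearest-neighbour resampling for categorical label volumes.

    Linear interpolation on labels would average category codes into
    meaningless values, so it is rejected at the API level: this is the
    only resampling entry point for :class:`LabelVolume`.
    """
    new_affine, out_shape, index_map = _resample_geometry(s.affine, s.shape, spacing)
    labels = ndimage.affine_transform(
        s.labels,
        index_map[:3, :3],
        offset=index_map[:3, 3],
        output_shape=out_shape,
        order=0,
        mode="constant",
        cval=0,
    )
    return LabelVolume(labels=labels, affine=new_affine, label_table=dict(s.label_table), id=s.id)


def clip_intensities(v: Volume, low: float = 0.5, high: float = 99.5) -> Volume:
    """Truncate intensities to the [P_low, P_high] empirical percentile range.

    Percentiles use linear interpolation between order statistics; values
    already inside the range are untouched.
    """
    if not (0 <= low < high <= 100):
        raise ValueError(f"need 0 <= low < high <= 100, got ({low}, {high})")
    if v.data.size == 0:
        raise ValueError("cannot clip an empty volume")
    p_low, p_high = np.percentile(v.data, [low, high])
    return v.with_data(np.clip(v.data, p_low, p_high))


def zscore(v: Volume, nonzero_only: bool = False) -> Volume:
    """Normalise to zero mean and unit population standard deviation.

    v'_i = (v_i - v_m) / v_sd over all voxels (or the nonzero ones when
    ``nonzero_only``); a constant volume has v_sd = 0 and is an error.
    """
    values = v.data[v.data != 0] if nonzero_only else v.data
    if values.size == 0:
        raise ValueError("no voxels to normalise")
    mean = float(values.mean())
    sd = float(values.std())  # population (ddof=0)
    if sd == 0.0:
        raise ValueError("constant volume: standard deviation is zero, z-scoring undefined")
    return v.with_data((v.data - mean) / sd)


def crop_or_pad(v: Volume, target_shape) -> Volume:
    """Centre-crop and/or zero-pad to an exact grid shape.

    Odd size differences put the extra voxel (cropped or padded) on the
    high-index side.  The affine is translated so every retained voxel
    keeps its world coordinate.
    """
    target = tuple(int(t) for t in np.broadcast_to(np.asarray(target_shape), (3,)))
    if any(t < 1 for t in target):
        raise ValueError("target_shape must be >= 1 per axis")
    data = v.data
    # start index of the output grid expressed in input-voxel coordinates;
    # negative means padding below.
    starts = []
    for n, t in zip(data.shape, target):
        starts.append((n - t) // 2 if n >= t else -((t - n) // 2))
    out = np.zeros(target, dtype=data.dtype)
    src_slices, dst_slices = [], []
    for n, t, s in zip(data.shape, target, starts):
        src_lo = max(s, 0)
        dst_lo = max(-s, 0)
        length = min(n - src_lo, t - dst_lo)
        src_slices.append(slice(src_lo, src_lo + length))
        dst_slices.append(slice(dst_lo, dst_lo + length))
    out[tuple(dst_slices)] = data[tuple(src_slices)]
    affine = v.affine.copy()
    affine[:3, 3] = (v.affine @ np.array([*starts, 1.0]))[:3]
    return Volume(data=out, affine=affine, id=v.id)


def preprocess_pipeline(v: Volume, cfg: PreprocessConfig = PreprocessConfig()) -> Volume:
    """Full chain: resample -> RAS+ -> clip -> z-score -> crop/pad.

    Geometry first, intensities second, padding last — so the clipping
    percentiles and the z-score statistics are computed on the resampled
    brain voxels, never on padding zeros.
    """
    out = resample(v, cfg.target_spacing, cfg.interpolation)
    out = reorient_to_ras(out)
    out = clip_intensities(out, *cfg.clip_percentiles)
    out = zscore(out, nonzero_only=cfg.zscore_nonzero_only)
    out = crop_or_pad(out, cfg.target_shape)
    return out
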