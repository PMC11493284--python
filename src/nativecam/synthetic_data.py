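"""Phantom cohort generator: brain-shaped, parcellated, multi-site volumes
with a planted class effect.

The phantom emulates the statistical structure the pipeline assumes of a
multi-site structural-MRI cohort without any resemblance to real
anatomy: an ellipsoidal "brain" of base intensity 1 on a zero
background, partitioned into irregular Voronoi parcels (stand-ins for an
anatomical parcellation), with additive Gaussian noise inside the brain.
The two classes differ only by an intensity offset confined to a few
designated parcels — a localised group difference whose known location
makes end-to-end attribution recovery checkable.  Site heterogeneity is
emulated by resampling each participant's volume to their site's voxel
spacing, and the test split is drawn from a site never seen in training,
mirroring multi-site evaluation against independent collection sites.

Per-participant random streams are derived by seeding with the
(cohort seed, participant index) pair, so cohorts are reproducible and
participant order is immaterial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .io_core import (
    LabelVolume,
    ParticipantRecord,
    RegionInfo,
    Volume,
    write_phenotype,
    write_volume,
)
from .parcellation import write_label_table
from .preprocess import resample, resample_labels

__all__ = ["PhantomConfig", "Cohort", "make_atlas", "make_participant",
           "simulate_cohort", "make_cohort"]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one simulated cohort.

    Defaults define a desk-scale two-site cohort: a 48-voxel cube at
    1 mm, 30 parcels with the effect planted in three of them, an
    additive effect of 0.5 intensity units against voxel noise of
    sd 0.2, and 30 participants per class, the second site held out
    entirely for testing.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    k_parcels: int = 30
    effect_parcels: tuple[int, ...] = (1, 2, 3)
    effect_size: float = 0.5
    noise_sd: float = 0.2
    n_per_class: int = 30
    sites: tuple[tuple[str, tuple[float, float, float]], ...] = (
        ("siteA", (1.2, 1.0, 1.0)),
        ("siteB", (1.0, 1.0, 1.0)),
    )
    size_jitter: float = 0.04
    val_fraction: float = 0.3
    test_fraction: float = 0.25
    age_range: tuple[float, float] = (6.0, 26.0)
    p_male: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_parcels < 2:
            raise ValueError("need at least 2 parcels")
        if not set(self.effect_parcels) <= set(range(1, self.k_parcels + 1)):
            raise ValueError("effect_parcels must be a subset of 1..k_parcels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.size_jitter < 1):
            raise ValueError("size_jitter must lie in [0, 1)")
        if len(self.sites) < 2:
            raise ValueError("need at least 2 sites (the last is the held-out test site)")


@dataclass
class Cohort:
    """In-memory simulated cohort: atlas + per-participant volumes/records."""

    atlas: LabelVolume
    participants: list[tuple[Volume, ParticipantRecord]]
    segmentations: dict[str, LabelVolume]
    effect_parcels: tuple[int, ...]
    config: PhantomConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def split(self, name: str) -> list[tuple[Volume, ParticipantRecord]]:
        return [(v, r) for v, r in self.participants if r.split == name]


def make_atlas(shape, k_parcels: int, seed: int = 0) -> LabelVolume:
    """Ellipsoidal brain mask partitioned into Voronoi parcels.

    Semi-axes are 0.4x each grid dimension; the interior is split into
    ``k_parcels`` nonempty parcels by nearest-seed assignment from
    ``k_parcels`` distinct random interior voxels.  Hemisphere labels
    follow the sign of the seed's x offset from the grid centre
    (bilateral within one voxel of the midline).  The affine is identity
    (1 mm isotropic).
    """
    shape = tuple(int(n) for n in np.broadcast_to(np.asarray(shape), (3,)))
    rng = np.random.default_rng(seed)
    centre = (np.asarray(shape) - 1) / 2.0
    semi = 0.4 * np.asarray(shape)
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    inside = (((grid - centre) / semi) ** 2).sum(axis=-1) <= 1.0
    interior = np.argwhere(inside)
    if k_parcels > len(interior):
        raise ValueError(f"k_parcels={k_parcels} exceeds interior voxel count {len(interior)}")
    seed_idx = rng.choice(len(interior), size=k_parcels, replace=False)
    seeds = interior[seed_idx]
    _, nearest = cKDTree(seeds).query(interior)
    labels = np.zeros(shape, dtype=np.int32)
    labels[tuple(interior.T)] = nearest + 1
    table: dict[int, RegionInfo] = {}
    for pid in range(1, k_parcels + 1):
        dx = seeds[pid - 1][0] - centre[0]
        if abs(dx) < 1.0:
            hemi = "bilateral"
        else:
            hemi = "right" if dx > 0 else "left"
        table[pid] = RegionInfo(name=f"parcel-{pid:02d}", hemisphere=hemi)
    return LabelVolume(labels=labels, affine=np.eye(4), label_table=table, id="phantom-atlas")


def _participant_rng(cohort_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cohort_seed, index)))


def make_participant(atlas: LabelVolume, class_label: int, cfg: PhantomConfig,
                     participant_index: int, site: tuple[str, tuple[float, float, float]],
                     split: str, return_parcellation: bool = False):
    """One phantom scan: base 1 inside the brain, planted effect, noise.

    Class-1 participants get ``effect_size`` added inside every effect
    parcel; Gaussian noise (sd ``noise_sd``) is added inside the brain
    only.  Head-size variability is emulated by scaling the scan's world
    coordinates by a per-participant factor drawn from
    ``1 +- size_jitter`` — class-independent anatomical variability that
    keeps whole-volume intensity statistics uninformative about class,
    so the planted parcel contrast is the only reliable class signal
    even after per-volume normalisation.  The volume is then resampled
    to the participant's site spacing, so its stored grid and affine
    reflect that site's scanner.

    Returns the volume, its phenotype record, and the matching native
    parcellation (the shared atlas carried onto this participant's
    scaled frame).
    """
    if class_label not in (0, 1):
        raise ValueError("class must be 0 or 1")
    site_names = [s[0] for s in cfg.sites]
    if site[0] not in site_names:
        raise ValueError(f"unknown site {site[0]!r}; configured sites: {site_names}")
    rng = _participant_rng(cfg.seed, participant_index)
    brain = atlas.labels > 0
    data = brain.astype(np.float64)
    if class_label == 1 and cfg.effect_size != 0.0:
        data += cfg.effect_size * np.isin(atlas.labels, cfg.effect_parcels)
    if cfg.noise_sd > 0:
        data += cfg.noise_sd * rng.standard_normal(atlas.shape) * brain
    scale = float(rng.uniform(1 - cfg.size_jitter, 1 + cfg.size_jitter))
    native_affine = np.diag([scale, scale, scale, 1.0]) @ atlas.affine
    pid = f"sub-{participant_index:04d}"
    native = Volume(data=data, affine=native_affine, id=pid)
    vol = resample(native, site[1], "linear")
    gender = "male" if rng.random() < cfg.p_male else "female"
    age = float(rng.uniform(*cfg.age_range))
    record = ParticipantRecord(id=pid, label=class_label, site=site[0],
                               gender=gender, age=age, split=split)
    if not return_parcellation:
        return vol, record
    native_seg = LabelVolume(labels=atlas.labels, affine=native_affine,
                             label_table=dict(atlas.label_table), id=pid)
    seg = resample_labels(native_seg, site[1])
    return vol, record, seg


def _assign(cfg: PhantomConfig, class_label: int, i: int) -> tuple[tuple[str, tuple], str]:
    """Site and split for the i-th participant of a class.

    The last configured site is the held-out test site (site-disjoint
    evaluation); ``test_fraction`` of each class goes there.  The
    remaining participants rotate through the other sites, with the last
    ``val_fraction`` of them forming the validation set.
    """
    n = cfg.n_per_class
    n_test = int(round(cfg.test_fraction * n))
    if i >= n - n_test:
        return cfg.sites[-1], "test"
    n_main = n - n_test
    site = cfg.sites[i % (len(cfg.sites) - 1)]
    n_val = int(round(cfg.val_fraction * n_main))
    split = "validation" if i >= n_main - n_val else "train"
    return site, split


def simulate_cohort(cfg: PhantomConfig) -> Cohort:
    """Generate a full cohort in memory (atlas, volumes, per-site copies).

    Per-participant segmentations are the shared atlas carried onto each
    participant's scaled native frame and site grid by nearest-neighbour
    resampling — the phantom analogue of an external per-subject
    parcellation.
    """
    atlas = make_atlas(cfg.shape, cfg.k_parcels, cfg.seed)
    participants: list[tuple[Volume, ParticipantRecord]] = []
    segmentations: dict[str, LabelVolume] = {}
    index = 0
    for class_label in (0, 1):
        for i in range(cfg.n_per_class):
            site, split = _assign(cfg, class_label, i)
            vol, rec, seg = make_participant(atlas, class_label, cfg, index, site, split,
                                             return_parcellation=True)
            participants.append((vol, rec))
            segmentations[rec.id] = seg
            index += 1
    return Cohort(atlas=atlas, participants=participants, segmentations=segmentations,
                  effect_parcels=tuple(cfg.effect_parcels), config=cfg)


def make_cohort(cfg: PhantomConfig, out_dir: str | Path) -> Path:
    """Simulate a cohort and write it to disk.

    Layout: ``volumes/<id>.nii.gz``, ``segmentations/<id>.nii.gz``,
    ``atlas_labels.tsv``, ``phenotype.tsv`` and ``ground_truth.json``
    (naming the effect parcels).
    """
    out_dir = Path(out_dir)
    (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    (out_dir / "segmentations").mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cfg)
    for vol, rec in cohort.participants:
        write_volume(vol, out_dir / "volumes" / f"{rec.id}.nii.gz")
        write_volume(cohort.segmentations[rec.id], out_dir / "segmentations" / f"{rec.id}.nii.gz")
    write_label_table(cohort.atlas.label_table, out_dir / "atlas_labels.tsv")
    write_phenotype([rec for _, rec in cohort.participants], out_dir / "phenotype.tsv")
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump({"effect_parcels": list(cfg.effect_parcels)}, fh, indent=2)
    return out_dir
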