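"""End-to-end orchestration: simulate/load -> preprocess -> train ->
predict -> attribute -> conform labels -> region attribution -> tallies.

Two entry points:

* :func:`run_cohort_analysis` — the in-memory study on a simulated
  :class:`~nativecam.synthetic_data.Cohort`; returns every intermediate
  artifact (log, predictions, metrics, RF tables, region sets,
  consistency table, background audit) in a :class:`StudyResult`.
* :func:`run_pipeline` — the disk-based staged runner behind the CLI,
  with a manifest of per-stage config hashes so unchanged stages are
  reused instead of recomputed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .attribution import (AttentionMask, binarize_attention,
                          class_symmetric_guided_gradcam, guided_gradcam)
from .io_core import LabelVolume, Volume
from .model import (ClassifierSpec, PredictionRecord, TrainConfig,
                    TrainingLog, build_classifier, evaluate, predict, train)
from .parcellation import conform_labels_to_attention_grid
from .preprocess import PreprocessConfig, preprocess_pipeline
from .region_attribution import (ConsistencyTable, RFTable, RegionSet,
                                 aggregate_rf, background_audit,
                                 relative_frequencies, select_top_regions,
                                 stratify, tally_consistency)
from .synthetic_data import Cohort, PhantomConfig, simulate_cohort

__all__ = ["StudyResult", "run_cohort_analysis", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the name of the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class StudyResult:
    """Everything one simulated study produces."""

    log: TrainingLog
    predictions: list[PredictionRecord]
    metrics: pd.DataFrame
    rf_tables: dict[str, RFTable]              # per-participant, by id
    stratum_rf: dict[str, RFTable]             # aggregated, by stratum key
    region_sets: list[RegionSet]
    consistency: ConsistencyTable
    background: pd.DataFrame
    masks: dict[str, AttentionMask] = field(default_factory=dict)

    @property
    def validation_accuracy(self) -> float:
        """Best validation accuracy reached during training."""
        if not self.log.entries:
            raise ValueError("no evaluations recorded")
        return max(e["val_accuracy"] for e in self.log.entries)

    def mean_rf_over(self, outcome: str = "TP") -> RFTable:
        """Aggregate per-participant RF over all participants with the
        given prediction outcome (across every attributed split)."""
        by_id = {p.id: p for p in self.predictions}
        tables = [t for pid, t in self.rf_tables.items()
                  if by_id[pid].outcome == outcome]
        return aggregate_rf(tables, scope=f"all/{outcome}")


def run_cohort_analysis(
    cohort: Cohort,
    preprocess_cfg: PreprocessConfig | None = None,
    spec: ClassifierSpec | None = None,
    train_cfg: TrainConfig = TrainConfig(max_epochs=20, eval_every=2, batch_size=2, seed=0),
    target_class: str | int = "symmetric",
    percentile: float = 90.0,
    stratify_scheme: str = "outcome",
    attribution_splits: tuple[str, ...] = ("train", "validation", "test"),
) -> StudyResult:
    """Run the full interpretation study on a simulated cohort.

    Predictions and attribution use the fully-trained (final-epoch)
    model state.  The per-participant attention map is by default the
    class-symmetric guided Grad-CAM at the first conv block's rectified
    output (``target_class`` may instead be ``"predicted"`` or a fixed
    0/1 to attribute a single class score); attention maps are computed
    for every participant, the paper's protocol.  Region sets are
    selected per prediction-outcome stratum within each split, and
    consistency is tallied across the splits as the "datasets".
    """
    preprocess_cfg = preprocess_cfg or PreprocessConfig(target_shape=(24, 24, 24))
    # ---- preprocess everything once -------------------------------------
    pre: dict[str, Volume] = {}
    for vol, rec in cohort.participants:
        pre[rec.id] = preprocess_pipeline(vol, preprocess_cfg)
    input_shape = next(iter(pre.values())).shape
    spec = spec or ClassifierSpec(architecture="tiny_3d", input_shape=input_shape)
    # ---- train ----------------------------------------------------------
    train_set = [(pre[r.id], r.label) for _, r in cohort.participants if r.split == "train"]
    val_set = [(pre[r.id], r.label) for _, r in cohort.participants if r.split == "validation"]
    clf = build_classifier(spec, seed=train_cfg.seed)
    log = train(clf, train_set, val_set, train_cfg)
    clf.net.load_state_dict(log.final_checkpoint)
    # ---- predict everyone ----------------------------------------------
    preds = [predict(clf, pre[r.id], record=r) for _, r in cohort.participants]
    by_id = {p.id: p for p in preds}
    split_of = {r.id: r.split for _, r in cohort.participants}
    metrics = evaluate(preds, group_by="site")
    # ---- attribution + region attribution -------------------------------
    masks: dict[str, AttentionMask] = {}
    rf_tables: dict[str, RFTable] = {}
    conformed_cache: dict[bytes, LabelVolume] = {}
    for _, rec in cohort.participants:
        if rec.split not in attribution_splits:
            continue
        p = by_id[rec.id]
        if target_class == "symmetric":
            amap = class_symmetric_guided_gradcam(clf, pre[rec.id])
        else:
            cls = p.predicted if target_class == "predicted" else int(target_class)
            amap = guided_gradcam(clf, pre[rec.id], cls)
        mask = binarize_attention(amap)
        masks[rec.id] = mask
        seg = cohort.segmentations[rec.id]
        key = mask.affine.tobytes() + np.asarray(mask.mask.shape).tobytes() + seg.affine.tobytes()
        if key not in conformed_cache:
            conformed_cache[key] = conform_labels_to_attention_grid(seg, mask)
        rf_tables[rec.id] = relative_frequencies(mask, conformed_cache[key], scope=rec.id)
    # ---- strata, aggregation, selection, consistency --------------------
    stratum_rf: dict[str, RFTable] = {}
    region_sets: list[RegionSet] = []
    for split in attribution_splits:
        split_preds = [p for p in preds if split_of[p.id] == split and p.id in rf_tables]
        for stratum, members in stratify(split_preds, stratify_scheme).items():
            tables = [rf_tables[p.id] for p in members]
            key = f"{split}/{stratum}"
            agg = aggregate_rf(tables, scope=key)
            stratum_rf[key] = agg
            region_sets.append(select_top_regions(
                agg, percentile, model=spec.architecture, dataset=split, stratum=stratum))
    consistency = tally_consistency(region_sets, cohort.atlas.label_table)
    background = background_audit(stratum_rf)
    return StudyResult(log=log, predictions=preds, metrics=metrics,
                       rf_tables=rf_tables, stratum_rf=stratum_rf,
                       region_sets=region_sets, consistency=consistency,
                       background=background, masks=masks)


# ---------------------------------------------------------------------------
# Disk-based staged pipeline (CLI backend)
# ---------------------------------------------------------------------------

def _hash_config(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _phantom_config(sim: dict, seed: int) -> PhantomConfig:
    sites = tuple((name, tuple(sp)) for name, sp in sim.get("sites", [["siteA", [1.2, 1, 1]], ["siteB", [1, 1, 1]]]))
    return PhantomConfig(
        shape=tuple(sim.get("shape", [48, 48, 48])),
        k_parcels=int(sim.get("k_parcels", 30)),
        effect_parcels=tuple(sim.get("effect_parcels", [1, 2, 3])),
        effect_size=float(sim.get("effect_size", 0.5)),
        noise_sd=float(sim.get("noise_sd", 0.2)),
        n_per_class=int(sim.get("n_per_class", 30)),
        sites=sites,
        seed=seed,
    )


def run_pipeline(config: dict, out_dir: str | Path, use_cache: bool = True) -> StudyResult:
    """Execute the staged pipeline described by a config mapping.

    The config mirrors the CLI YAML: optional ``simulate`` block (phantom
    study), ``preprocess``, ``model``, ``regions`` blocks and a global
    ``seed``.  A manifest JSON under ``out_dir`` records per-stage config
    hashes; with ``use_cache`` a rerun whose hashes match reuses the
    simulated cohort on disk instead of regenerating it.  Final tables
    are written as TSV under ``out_dir/tables``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    seed = int(config.get("seed", 0))

    if "simulate" not in config:
        raise PipelineError("simulate", "only simulation-backed configs are supported here; "
                            "use the individual CLI stages for external data")
    sim_hash = _hash_config({"sim": config["simulate"], "seed": seed})
    cohort_dir = out_dir / "cohort"
    try:
        sim_cfg = _phantom_config(config["simulate"], seed)
        from .synthetic_data import make_cohort
        if not (use_cache and manifest.get("simulate") == sim_hash and cohort_dir.exists()):
            make_cohort(sim_cfg, cohort_dir)
            manifest["simulate"] = sim_hash
        cohort = simulate_cohort(sim_cfg)  # in-memory twin of what is on disk
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc

    pp = config.get("preprocess", {})
    preprocess_cfg = PreprocessConfig(
        target_spacing=tuple(np.broadcast_to(pp.get("target_spacing", 1.5), (3,)).astype(float)),
        clip_percentiles=tuple(pp.get("clip_percentiles", (0.5, 99.5))),
        target_shape=tuple(np.broadcast_to(pp.get("target_shape", 24), (3,)).astype(int)),
    )
    mc = config.get("model", {})
    spec = ClassifierSpec(
        architecture=mc.get("architecture", "tiny_3d"),
        input_shape=preprocess_cfg.target_shape,
        width=int(mc.get("width", 8)),
    )
    train_cfg = TrainConfig(
        max_epochs=int(mc.get("max_epochs", 20)),
        eval_every=int(mc.get("eval_every", 2)),
        learning_rate=float(mc.get("learning_rate", 0.001)),
        batch_size=int(mc.get("batch_size", 4)),
        seed=seed,
    )
    rc = config.get("regions", {})
    try:
        result = run_cohort_analysis(
            cohort, preprocess_cfg, spec, train_cfg,
            target_class=rc.get("target_class", "symmetric"),
            percentile=float(rc.get("percentile", 90)),
            stratify_scheme=rc.get("stratify", "outcome"),
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("analysis", str(exc)) from exc

    tables_dir = out_dir / "tables"
    tables_dir.mkdir(exist_ok=True)
    pd.DataFrame([p.__dict__ for p in result.predictions]).to_csv(
        tables_dir / "predictions.tsv", sep="\t", index=False)
    result.metrics.to_csv(tables_dir / "metrics_by_site.tsv", sep="\t", index=False)
    for key, t in result.stratum_rf.items():
        t.table.to_csv(tables_dir / f"rf_{key.replace('/', '_')}.tsv", sep="\t", index=False)
    result.consistency.table.to_csv(tables_dir / "consistency.tsv", sep="\t", index=False)
    result.consistency.summary.to_csv(tables_dir / "consistency_summary.tsv", sep="\t", index=False)
    result.background.to_csv(tables_dir / "background_audit.tsv", sep="\t", index=False)
    manifest["config_hash"] = _hash_config(config)
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return result
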