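"""3D CNN classifier contract, training protocol, and evaluation metrics.

Three architectures are provided, all ending in the same head — global
average pooling followed by a single fully connected layer to two class
scores — and all built exclusively from ReLU nonlinearities (a hard
requirement of the downstream guided-backpropagation attribution):

* ``tiny_3d`` — a 3-block strided conv stack for desk-scale experiments.
* ``residual_3d`` — strided stem + identity-skip residual blocks.
* ``dense_3d`` — strided stem + densely connected blocks (each conv sees
  the concatenation of all earlier features).

Training uses cross-entropy, Adam at a fixed learning rate, and periodic
validation: accuracy and ROC AUC are logged every ``eval_every`` epochs
and the best checkpoint is the one with the highest validation accuracy
(earliest epoch on ties).  Classification uses a 0.5 probability
threshold on the positive class, read strictly: a probability of exactly
0.5 is classified negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import nn
from .io_core import ParticipantRecord, Volume

__all__ = [
    "ClassifierSpec",
    "TrainConfig",
    "PredictionRecord",
    "Classifier",
    "TrainingLog",
    "build_classifier",
    "train",
    "predict",
    "evaluate",
    "save_classifier",
    "load_classifier",
]

ARCHITECTURES = ("tiny_3d", "residual_3d", "dense_3d")


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture choice and size knobs for :func:`build_classifier`."""

    architecture: str = "tiny_3d"
    input_shape: tuple[int, int, int] = (32, 32, 32)
    num_classes: int = 2
    width: int = 8          # stem / base channel count
    growth: int = 4         # dense_3d growth rate
    n_blocks: int = 2       # residual / dense block count
    norm: str = "batch"     # "batch" or "none": normalisation after each conv

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.norm not in ("batch", "none"):
            raise ValueError("norm must be 'batch' or 'none'")
        if self.num_classes != 2:
            raise ValueError("this pipeline is a binary classifier (num_classes = 2)")
        if self.width < 1 or self.growth < 1 or self.n_blocks < 1:
            raise ValueError("width, growth and n_blocks must be positive")


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 100
    eval_every: int = 2
    learning_rate: float = 0.001
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.max_epochs < 1 or self.eval_every < 1 or self.batch_size < 1:
            raise ValueError("max_epochs, eval_every and batch_size must be >= 1")


@dataclass
class PredictionRecord:
    """One participant's prediction with outcome class and demographics."""

    id: str
    probability: float
    predicted: int
    true_label: int | None = None
    outcome: str | None = None
    site: str = ""
    gender: str = ""
    age: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability must lie in [0, 1], got {self.probability}")
        if self.true_label is not None and self.outcome is None:
            self.outcome = _outcome(self.predicted, self.true_label)


def _outcome(predicted: int, true_label: int) -> str:
    return {(1, 1): "TP", (0, 0): "TN", (1, 0): "FP", (0, 1): "FN"}[(predicted, true_label)]


class _ResidualBlock(nn.Layer):
    """Two 3x3x3 convolutions with an identity skip: out = ReLU(x + F(x))."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = nn.Conv3d(channels, channels, 3, 1, 1, rng)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv3d(channels, channels, 3, 1, 1, rng)
        self.relu2 = nn.ReLU()

    def parameters(self):
        out = {}
        for tag, layer in (("conv1", self.conv1), ("conv2", self.conv2)):
            for k, v in layer.parameters().items():
                out[f"{tag}.{k}"] = v
        return out

    def gradients(self):
        out = {}
        for tag, layer in (("conv1", self.conv1), ("conv2", self.conv2)):
            for k, v in layer.gradients().items():
                out[f"{tag}.{k}"] = v
        return out

    def forward(self, x):
        h = self.relu1.forward(self.conv1.forward(x))
        return self.relu2.forward(x + self.conv2.forward(h))

    def backward(self, grad_out, mode=nn.STANDARD):
        g = self.relu2.backward(grad_out, mode)
        g_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(g, mode), mode), mode)
        return g + g_main


class _DenseBlock(nn.Layer):
    """Densely connected convs: conv_i sees the concat of all earlier maps.

    Output is the concatenation of the input with every conv's ReLU output,
    so channels grow by ``n_layers * growth``.
    """

    def __init__(self, in_channels: int, growth: int, n_layers: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.growth = growth
        self.convs = [nn.Conv3d(in_channels + i * growth, growth, 3, 1, 1, rng)
                      for i in range(n_layers)]
        self.relus = [nn.ReLU() for _ in range(n_layers)]

    @property
    def out_channels(self) -> int:
        return self.in_channels + len(self.convs) * self.growth

    def parameters(self):
        out = {}
        for i, conv in enumerate(self.convs):
            for k, v in conv.parameters().items():
                out[f"conv{i}.{k}"] = v
        return out

    def gradients(self):
        out = {}
        for i, conv in enumerate(self.convs):
            for k, v in conv.gradients().items():
                out[f"conv{i}.{k}"] = v
        return out

    def forward(self, x):
        feats = [x]
        for conv, relu in zip(self.convs, self.relus):
            inp = np.concatenate(feats, axis=1)
            feats.append(relu.forward(conv.forward(inp)))
        return np.concatenate(feats, axis=1)

    def backward(self, grad_out, mode=nn.STANDARD):
        sizes = [self.in_channels] + [self.growth] * len(self.convs)
        bounds = np.cumsum([0] + sizes)
        grad_feats = [grad_out[:, bounds[i]:bounds[i + 1]].copy() for i in range(len(sizes))]
        for i in reversed(range(len(self.convs))):
            g_h = self.relus[i].backward(grad_feats[i + 1], mode)
            g_inp = self.convs[i].backward(g_h, mode)
            inner = np.cumsum([0] + sizes[: i + 1])
            for j in range(i + 1):
                grad_feats[j] += g_inp[:, inner[j]:inner[j + 1]]
        return grad_feats[0]


def _check_depth(input_shape, n_stride2: int) -> None:
    min_dim = min(input_shape)
    if (min_dim >> n_stride2) < 1 or min_dim < 2**n_stride2:
        raise ValueError(
            f"input shape {tuple(input_shape)} too small for {n_stride2} stride-2 stages")


def _build_network(spec: ClassifierSpec, rng: np.random.Generator) -> nn.Network:
    w, layers = spec.width, []

    def bn(tag: str, channels: int):
        return [(tag, nn.BatchNorm3d(channels))] if spec.norm == "batch" else []

    if spec.architecture == "tiny_3d":
        _check_depth(spec.input_shape, 3)
        layers = [("conv1", nn.Conv3d(1, w, 3, 2, 1, rng)), *bn("bn1", w), ("relu1", nn.ReLU()),
                  ("conv2", nn.Conv3d(w, 2 * w, 3, 2, 1, rng)), *bn("bn2", 2 * w), ("relu2", nn.ReLU()),
                  ("conv3", nn.Conv3d(2 * w, 2 * w, 3, 2, 1, rng)), *bn("bn3", 2 * w), ("relu3", nn.ReLU())]
        feat = 2 * w
    elif spec.architecture == "residual_3d":
        _check_depth(spec.input_shape, 2)
        layers = [("stem", nn.Conv3d(1, w, 3, 2, 1, rng)),
                  *bn("stem_bn", w), ("stem_relu", nn.ReLU())]
        for i in range(spec.n_blocks):
            layers.append((f"resblock{i + 1}", _ResidualBlock(w, rng)))
        layers += [("down", nn.Conv3d(w, 2 * w, 3, 2, 1, rng)),
                   *bn("down_bn", 2 * w), ("down_relu", nn.ReLU()),
                   ("resblock_final", _ResidualBlock(2 * w, rng))]
        feat = 2 * w
    else:  # dense_3d
        _check_depth(spec.input_shape, 2)
        layers = [("stem", nn.Conv3d(1, w, 3, 2, 1, rng)),
                  *bn("stem_bn", w), ("stem_relu", nn.ReLU())]
        block1 = _DenseBlock(w, spec.growth, spec.n_blocks, rng)
        layers.append(("denseblock1", block1))
        layers += [("down", nn.Conv3d(block1.out_channels, w, 3, 2, 1, rng)),
                   *bn("down_bn", w), ("down_relu", nn.ReLU())]
        block2 = _DenseBlock(w, spec.growth, spec.n_blocks, rng)
        layers.append(("denseblock2", block2))
        feat = block2.out_channels
    layers += [("gap", nn.GlobalAvgPool()), ("fc", nn.Linear(feat, spec.num_classes, rng))]
    return nn.Network(layers)


class Classifier:
    """A built network plus its spec; the object the pipeline passes around.

    Satisfies the classifier contract: forward to softmax probabilities,
    and, for any named layer, access to forward activations and to the
    gradient of a chosen class score with respect to those activations
    and with respect to the input.
    """

    def __init__(self, spec: ClassifierSpec, net: nn.Network):
        self.spec = spec
        self.net = net

    def _as_batch(self, v: Volume | np.ndarray) -> np.ndarray:
        grid = v.data if isinstance(v, Volume) else np.asarray(v)
        if grid.shape != tuple(self.spec.input_shape):
            raise ValueError(
                f"volume shape {grid.shape} does not match classifier input "
                f"shape {tuple(self.spec.input_shape)}")
        return grid[None, None].astype(np.float64)

    def forward(self, v: Volume | np.ndarray) -> np.ndarray:
        """Class scores (logits), shape (2,); inference (eval) mode."""
        self.net.set_training(False)
        return self.net.forward(self._as_batch(v))[0]

    def predict_proba(self, v: Volume | np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(v))

    def class_score_gradients(self, v: Volume | np.ndarray, target_class: int,
                              guided: bool = False) -> dict[str, np.ndarray]:
        mode = nn.GUIDED if guided else nn.STANDARD
        self.net.set_training(False)
        return self.net.class_score_gradients(self._as_batch(v), target_class, mode=mode)

    def activation(self, layer: str) -> np.ndarray:
        return self.net.activation(layer)

    @property
    def first_conv_layer(self) -> str:
        return self.net.first_conv_name

    @property
    def attribution_layer(self) -> str:
        """Default Grad-CAM layer: the first conv block's rectified output.

        Grad-CAM weights activation maps, which are conventionally the
        post-nonlinearity feature maps; this is the rectifier directly
        following the first convolution (falling back to the raw conv
        output if the network has no ReLU after it).
        """
        names = self.net.layer_names
        first_conv = self.net.first_conv_name
        for name in names[names.index(first_conv) + 1:]:
            layer = self.net.layer(name)
            if isinstance(layer, nn.ReLU):
                return name
            if isinstance(layer, nn.Conv3d):
                break
        return first_conv

    def num_parameters(self) -> int:
        return self.net.num_parameters()


def build_classifier(spec: ClassifierSpec, seed: int = 0) -> Classifier:
    """Instantiate a classifier with freshly initialised weights."""
    rng = np.random.default_rng(seed)
    return Classifier(spec, _build_network(spec, rng))


@dataclass
class TrainingLog:
    """Per-evaluation history plus the best checkpoint by validation accuracy."""

    entries: list[dict] = field(default_factory=list)
    checkpoints: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    best_epoch: int | None = None

    @property
    def best_checkpoint(self) -> dict[str, np.ndarray]:
        if self.best_epoch is None:
            raise ValueError("no evaluations were recorded")
        return self.checkpoints[self.best_epoch]

    @property
    def final_checkpoint(self) -> dict[str, np.ndarray]:
        """Parameters at the last evaluated epoch (the fully-trained state)."""
        if not self.checkpoints:
            raise ValueError("no checkpoints were recorded")
        return self.checkpoints[max(self.checkpoints)]


def _dataset_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    grids, labels = [], []
    for v, y in dataset:
        grids.append(v.data if isinstance(v, Volume) else np.asarray(v))
        labels.append(int(y))
    return np.stack(grids)[:, None].astype(np.float64), np.asarray(labels)


def train(c: Classifier, train_set, val_set, cfg: TrainConfig = TrainConfig()) -> TrainingLog:
    """Train with Adam + cross-entropy, evaluating every ``eval_every`` epochs.

    ``train_set`` and ``val_set`` are sequences of ``(Volume-or-grid,
    label)`` pairs.  The log records (epoch, validation accuracy,
    validation ROC AUC) at each evaluation and keeps a parameter snapshot;
    the best epoch maximises validation accuracy with ties broken toward
    the earliest epoch.  On return the classifier carries the best
    checkpoint's weights.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    x_train, y_train = _dataset_arrays(train_set)
    x_val, y_val = _dataset_arrays(val_set)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")

    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(c.net, lr=cfg.learning_rate)
    log = TrainingLog()
    best_acc = -1.0
    n = len(y_train)
    for epoch in range(1, cfg.max_epochs + 1):
        c.net.set_training(True)
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = c.net.forward(x_train[idx])
            _, grad = nn.cross_entropy_with_grad(logits, y_train[idx])
            c.net.backward(grad)
            opt.step()
        if epoch % cfg.eval_every == 0:
            c.net.set_training(False)
            probs = np.stack([nn.softmax(c.net.forward(x_val[i:i + 1])[0]) for i in range(len(y_val))])
            pred = (probs[:, 1] > 0.5).astype(int)
            acc = float((pred == y_val).mean())
            auc = float(roc_auc_score(y_val, probs[:, 1])) if len(np.unique(y_val)) == 2 else None
            log.entries.append({"epoch": epoch, "val_accuracy": acc, "val_auc": auc})
            log.checkpoints[epoch] = c.net.state_dict()
            if acc > best_acc:  # strict: earliest epoch wins ties
                best_acc = acc
                log.best_epoch = epoch
    if log.best_epoch is not None:
        c.net.load_state_dict(log.best_checkpoint)
    return log


def predict(c: Classifier, v: Volume, threshold: float = 0.5,
            record: ParticipantRecord | None = None) -> PredictionRecord:
    """Classify one preprocessed volume.

    The decision rule is strict: predicted = 1 iff P(class 1) > threshold,
    so a probability of exactly ``threshold`` yields class 0.
    """
    prob = float(c.predict_proba(v)[1])
    predicted = int(prob > threshold)
    if record is None:
        return PredictionRecord(id=v.id, probability=prob, predicted=predicted)
    return PredictionRecord(
        id=record.id, probability=prob, predicted=predicted, true_label=record.label,
        site=record.site, gender=record.gender, age=record.age)


_AGE_BINS = ((5.0, 10.0), (10.0, 15.0), (15.0, 20.0), (20.0, float("inf")))


def age_bin(age: float) -> str:
    """Half-open age bins: [5,10), [10,15), [15,20), [20,inf); under 5 flagged."""
    if age < 5.0:
        return "under-5"
    for lo, hi in _AGE_BINS:
        if lo <= age < hi:
            return f"{lo:g}-{hi:g}" if np.isfinite(hi) else f"over-{lo:g}"
    raise AssertionError("unreachable")


def _group_key(p: PredictionRecord, group_by: str):
    if group_by == "none":
        return "all"
    if group_by == "site":
        return p.site
    if group_by == "gender":
        return p.gender
    if group_by == "age_bin":
        return age_bin(p.age)
    raise ValueError(f"unknown group_by {group_by!r}")


def evaluate(preds: list[PredictionRecord], group_by: str = "none") -> pd.DataFrame:
    """Accuracy, ROC AUC, sensitivity and specificity per group.

    AUC is the area under the ROC curve traced over probability
    thresholds; groups with a single true class have no ROC curve, so
    their AUC is reported as missing with ``auc_defined = False``.
    """
    if not preds:
        raise ValueError("no predictions to evaluate")
    if any(p.true_label is None for p in preds):
        raise ValueError("all predictions must carry a true label for evaluation")
    groups: dict[str, list[PredictionRecord]] = {}
    for p in preds:
        groups.setdefault(_group_key(p, group_by), []).append(p)
    rows = []
    for key in sorted(groups):
        ps = groups[key]
        y = np.array([p.true_label for p in ps])
        prob = np.array([p.probability for p in ps])
        pred = np.array([p.predicted for p in ps])
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        both_classes = len(np.unique(y)) == 2
        rows.append({
            "group": key,
            "n": len(ps),
            "accuracy": (tp + tn) / len(ps),
            "auc": float(roc_auc_score(y, prob)) if both_classes else np.nan,
            "auc_defined": both_classes,
            "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
            "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
            "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        })
    return pd.DataFrame(rows)


def save_classifier(c: Classifier, log: TrainingLog | None, path: str | Path) -> Path:
    """Serialise spec + best weights to an .npz checkpoint."""
    path = Path(path)
    meta = {f"spec_{k}": np.asarray(v) for k, v in c.spec.__dict__.items()}
    np.savez(path, **meta, **{f"param_{k}": v for k, v in c.net.state_dict().items()})
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_classifier(path: str | Path) -> Classifier:
    with np.load(Path(path), allow_pickle=False) as data:
        spec = ClassifierSpec(
            architecture=str(data["spec_architecture"]),
            input_shape=tuple(int(x) for x in data["spec_input_shape"]),
            num_classes=int(data["spec_num_classes"]),
            width=int(data["spec_width"]),
            growth=int(data["spec_growth"]),
            n_blocks=int(data["spec_n_blocks"]),
            norm=str(data["spec_norm"]),
        )
        c = build_classifier(spec)
        state = {k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")}
        c.net.load_state_dict(state)
    return c
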