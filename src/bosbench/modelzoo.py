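"""Desk-scale trainable border-ownership classifiers.

Three feedforward motifs mirror the architectural families compared in the
benchmark, each reduced to a size trainable on one CPU in minutes while
keeping the three parameter counts within a factor of two of each other
(so that motif comparisons are not confounded by raw capacity):

``plain_feedforward``
    five stride-1 convolution stages with interleaved max pooling — a
    shallow, strictly sequential baseline in the AlexNet mould.

``multiscale_parallel``
    an inception-style stem plus three "mixed" stages; each stage runs
    four parallel branches (1x1; 1x1->3x3; 1x1->5x5; 3x3 maxpool->1x1)
    whose same-size outputs are concatenated channelwise.

``residual_skip``
    six two-convolution residual blocks with identity bypasses, in three
    channel stages joined by 1x1 projections.

Each motif exposes named ``shallow`` / ``mid`` / ``deep`` tap points used
by the saliency module.  The binary head is a global average pool plus a
dense layer producing one logit; class 1 is ``right_owns`` and hard labels
use threshold 0.5 with ties broken toward ``right_owns``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from bosbench.errors import ConfigurationError, ValidationError
from bosbench.nn.graph import Graph, Node, INPUT
from bosbench.nn.layers import (Add, Concat, Conv2d, Dense, GlobalAvgPool,
                                MaxPool2x2, MaxPool2x2Same, MaxPool3x3Same,
                                ReLU)
from bosbench.nn.train import Adam, bce_with_logits, sigmoid

MOTIFS = ("plain_feedforward", "multiscale_parallel", "residual_skip")

POSITIVE_CLASS = "right_owns"  # encoded as y = 1


@dataclass(frozen=True)
class ArchitectureSpec:
    """Which motif to build and at what input size.

    ``width_scale`` multiplies every stage's channel count (rounded up);
    the input size must be divisible by 16 to survive the four pooling
    stages.
    """

    motif: Literal["plain_feedforward", "multiscale_parallel",
                   "residual_skip"]
    input_size: int = 64
    width_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.motif not in MOTIFS:
            raise ConfigurationError(f"unknown motif {self.motif!r}")
        if self.input_size % 16 != 0:
            raise ConfigurationError("input size must be divisible by 16")


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    patience: int = 5
    lr_decay: float = 0.3          # multiplier at 60% and 85% of the budget
    weight_decay: float = 0.0      # decoupled L2 on conv/dense weights
    seed: int = 0

    @property
    def decay_epochs(self) -> tuple[int, int]:
        return (int(self.epochs * 0.6), int(self.epochs * 0.85))

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.patience) < 1 \
                or self.learning_rate <= 0:
            raise ConfigurationError("training config values must be positive")


@dataclass
class TrainedClassifier:
    """A fitted network plus its tap points and training log."""

    spec: ArchitectureSpec
    graph: Graph
    taps: dict[str, str]
    config: TrainingConfig | None = None
    log: pd.DataFrame | None = None

    @property
    def n_parameters(self) -> int:
        return self.graph.n_parameters()

    def predict_proba(self, images: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
        """P(right_owns) per image; deterministic in evaluation mode."""
        x = _to_input(images, self.spec.input_size)
        out = np.empty(len(x), dtype=np.float64)
        for lo in range(0, len(x), batch_size):
            z = self.graph.forward(x[lo:lo + batch_size])
            out[lo:lo + batch_size] = sigmoid(z[:, 0].astype(np.float64))
        return out

    def predict(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (probabilities, hard labels) with labels in {0, 1}."""
        p = self.predict_proba(images)
        return p, (p >= 0.5).astype(np.int64)

    def save(self, path: str | Path) -> None:
        meta = dict(spec=self.spec.__dict__, taps=self.taps,
                    config=None if self.config is None else self.config.__dict__)
        np.savez_compressed(path, __meta__=json.dumps(meta, default=str),
                            **self.graph.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            state = {k: data[k] for k in data.files if k != "__meta__"}
        spec = ArchitectureSpec(**{**meta["spec"],
                                   "width_scale": float(meta["spec"]["width_scale"])})
        model = build(spec, seed=0)
        model.graph.load_state_dict(state)
        model.taps = meta["taps"]
        if meta.get("config"):
            c = meta["config"]
            model.config = TrainingConfig(
                epochs=int(c["epochs"]), batch_size=int(c["batch_size"]),
                learning_rate=float(c["learning_rate"]),
                optimizer=str(c["optimizer"]), patience=int(c["patience"]),
                lr_decay=float(c.get("lr_decay", 0.3)),
                weight_decay=float(c.get("weight_decay", 0.0)),
                seed=int(c["seed"]))
        return model


def _to_input(images: np.ndarray, size: int) -> np.ndarray:
    """uint8 (N, H, W) or float (N, 1, H, W) -> float32 NCHW in [0, 1]."""
    x = np.asarray(images)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[:, None]
    if x.shape[2] != size or x.shape[3] != size:
        raise ValidationError(
            f"image size {x.shape[2:]} does not match model input {size}")
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / 255.0
    return x.astype(np.float32)


# ---------------------------------------------------------------------------
# graph builders


def _scaled(c: int, s: float) -> int:
    return max(1, int(np.ceil(c * s)))


def _build_plain(rng: np.random.Generator, s: float) -> tuple[list[Node], str, dict]:
    chans = [_scaled(c, s) for c in (8, 16, 24, 32, 32)]
    nodes, prev, cin = [], INPUT, 1
    for i, cout in enumerate(chans, start=1):
        nodes += [Node(f"conv{i}", Conv2d(cin, cout, 3, rng), [prev]),
                  Node(f"relu{i}", ReLU(), [f"conv{i}"])]
        prev = f"relu{i}"
        if i < 5:
            nodes.append(Node(f"pool{i}", MaxPool2x2(), [prev]))
            prev = f"pool{i}"
        cin = cout
    nodes += [Node("gap", GlobalAvgPool(), [prev]),
              Node("logit", Dense(chans[-1], 1, rng), ["gap"])]
    taps = dict(shallow="pool1", mid="pool3", deep="relu5")
    return nodes, "logit", taps


def _mixed_stage(name: str, cin: int, spec: dict, rng, src: str
                 ) -> tuple[list[Node], int]:
    """Four-branch inception-style stage; returns nodes and out channels."""
    b0, (r1, c1), (r2, c2), bp = (spec["b0"], spec["b1"], spec["b2"],
                                  spec["pool"])
    n = name
    nodes = [
        Node(f"{n}_b0", Conv2d(cin, b0, 1, rng), [src]),
        Node(f"{n}_b0r", ReLU(), [f"{n}_b0"]),
        Node(f"{n}_b1a", Conv2d(cin, r1, 1, rng), [src]),
        Node(f"{n}_b1ar", ReLU(), [f"{n}_b1a"]),
        Node(f"{n}_b1b", Conv2d(r1, c1, 3, rng), [f"{n}_b1ar"]),
        Node(f"{n}_b1br", ReLU(), [f"{n}_b1b"]),
        Node(f"{n}_b2a", Conv2d(cin, r2, 1, rng), [src]),
        Node(f"{n}_b2ar", ReLU(), [f"{n}_b2a"]),
        Node(f"{n}_b2b", Conv2d(r2, c2, 5, rng), [f"{n}_b2ar"]),
        Node(f"{n}_b2br", ReLU(), [f"{n}_b2b"]),
        Node(f"{n}_bp", MaxPool3x3Same(), [src]),
        Node(f"{n}_bpc", Conv2d(cin, bp, 1, rng), [f"{n}_bp"]),
        Node(f"{n}_bpr", ReLU(), [f"{n}_bpc"]),
        Node(n, Concat(), [f"{n}_b0r", f"{n}_b1br", f"{n}_b2br",
                           f"{n}_bpr"]),
    ]
    return nodes, b0 + c1 + c2 + bp


def _build_multiscale(rng: np.random.Generator, s: float
                      ) -> tuple[list[Node], str, dict]:
    stem1, stem2 = _scaled(10, s), _scaled(20, s)
    stages = [
        dict(b0=_scaled(15, s), b1=(_scaled(10, s), _scaled(20, s)),
             b2=(_scaled(5, s), _scaled(10, s)), pool=_scaled(10, s)),
        dict(b0=_scaled(20, s), b1=(_scaled(15, s), _scaled(30, s)),
             b2=(_scaled(8, s), _scaled(15, s)), pool=_scaled(15, s)),
        dict(b0=_scaled(20, s), b1=(_scaled(20, s), _scaled(40, s)),
             b2=(_scaled(10, s), _scaled(20, s)), pool=_scaled(20, s)),
    ]
    # The stem opens with a 2x2 stride-1 max filter (grayscale dilation):
    # cross-scale pooling before any feature extraction.  On 1-px contour
    # stimuli it closes 1-px gaps exactly, which is what makes this motif
    # robust to dash fragmentation up to gap ratio n = 1 despite training
    # only on intact contours.  Two conv+pool stages then bring the mixed
    # stages to quarter resolution.
    nodes = [Node("dilate", MaxPool2x2Same(), [INPUT]),
             Node("stem", Conv2d(1, stem1, 3, rng), ["dilate"]),
             Node("stem_r", ReLU(), ["stem"]),
             Node("stem_p", MaxPool2x2(), ["stem_r"]),
             Node("stem2", Conv2d(stem1, stem2, 3, rng), ["stem_p"]),
             Node("stem2_r", ReLU(), ["stem2"]),
             Node("stem2_p", MaxPool2x2(), ["stem2_r"])]
    prev, cin = "stem2_p", stem2
    for i, st in enumerate(stages, start=1):
        stage_nodes, cout = _mixed_stage(f"mixed{i}", cin, st, rng, prev)
        nodes += stage_nodes
        prev, cin = f"mixed{i}", cout
        if i == 1:
            nodes.append(Node(f"pool{i}", MaxPool2x2(), [prev]))
            prev = f"pool{i}"
    nodes += [Node("gap", GlobalAvgPool(), [prev]),
              Node("logit", Dense(cin, 1, rng), ["gap"])]
    taps = dict(shallow="mixed1", mid="mixed2", deep="mixed3")
    return nodes, "logit", taps


def _build_residual(rng: np.random.Generator, s: float
                    ) -> tuple[list[Node], str, dict]:
    c1, c2, c3 = _scaled(8, s), _scaled(16, s), _scaled(24, s)
    nodes = [Node("stem", Conv2d(1, c1, 3, rng), [INPUT]),
             Node("stem_r", ReLU(), ["stem"]),
             Node("stem_p", MaxPool2x2(), ["stem_r"])]
    prev = "stem_p"

    def block(i: int, c: int, src: str) -> str:
        nodes.extend([
            Node(f"b{i}_c1", Conv2d(c, c, 3, rng), [src]),
            Node(f"b{i}_r1", ReLU(), [f"b{i}_c1"]),
            Node(f"b{i}_c2", Conv2d(c, c, 3, rng), [f"b{i}_r1"]),
            Node(f"add{i}", Add(), [f"b{i}_c2", src]),
            Node(f"add{i}_r", ReLU(), [f"add{i}"]),
        ])
        return f"add{i}_r"

    prev = block(1, c1, prev)
    prev = block(2, c1, prev)
    nodes += [Node("pool1", MaxPool2x2(), [prev]),
              Node("proj1", Conv2d(c1, c2, 1, rng), ["pool1"]),
              Node("proj1_r", ReLU(), ["proj1"])]
    prev = block(3, c2, "proj1_r")
    prev = block(4, c2, prev)
    nodes += [Node("pool2", MaxPool2x2(), [prev]),
              Node("proj2", Conv2d(c2, c3, 1, rng), ["pool2"]),
              Node("proj2_r", ReLU(), ["proj2"])]
    prev = block(5, c3, "proj2_r")
    prev = block(6, c3, prev)
    nodes += [Node("gap", GlobalAvgPool(), [prev]),
              Node("logit", Dense(c3, 1, rng), ["gap"])]
    taps = dict(shallow="add1", mid="add4", deep="add6")
    return nodes, "logit", taps


_BUILDERS = {"plain_feedforward": _build_plain,
             "multiscale_parallel": _build_multiscale,
             "residual_skip": _build_residual}


def build(arch: ArchitectureSpec, seed: int = 0) -> TrainedClassifier:
    """Construct an untrained classifier with seeded weight init."""
    rng = np.random.default_rng(seed)
    nodes, output, taps = _BUILDERS[arch.motif](rng, arch.width_scale)
    graph = Graph(nodes=nodes, output=output)
    return TrainedClassifier(spec=arch, graph=graph, taps=taps)


# ---------------------------------------------------------------------------
# training


def labels_to_y(labels) -> np.ndarray:
    """Ownership labels -> {0, 1} with 1 = right_owns."""
    return np.asarray([1 if l == POSITIVE_CLASS else 0 for l in labels],
                      dtype=np.float64)


def train(model: TrainedClassifier, manifest: pd.DataFrame,
          images: np.ndarray, cfg: TrainingConfig,
          verbose: bool = False) -> TrainedClassifier:
    """Supervised training with early stopping on validation accuracy.

    The parameters achieving the best validation accuracy are retained.
    The manifest must carry ``label`` and ``split`` columns aligned with
    ``images`` (row i describes image i).
    """
    rng = np.random.default_rng(cfg.seed)
    y = labels_to_y(manifest["label"].to_numpy())
    split = manifest["split"].to_numpy()
    tr, va = np.flatnonzero(split == "train"), np.flatnonzero(split == "val")
    if len(tr) == 0 or len(va) == 0:
        raise ValidationError("manifest needs nonempty train and val splits")
    if len(np.unique(y[tr])) < 2:
        raise ValidationError("training split contains a single class")
    x = _to_input(images, model.spec.input_size)
    graph = model.graph
    opt = Adam(graph.params(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    best_acc, best_state, best_epoch = -1.0, None, -1
    rows = []
    for epoch in range(cfg.epochs):
        if epoch in cfg.decay_epochs:
            opt.lr *= cfg.lr_decay
        order = rng.permutation(tr)
        losses, correct = [], 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            z = graph.forward(x[idx])[:, 0]
            loss, gz = bce_with_logits(z, y[idx])
            graph.backward(gz[:, None])
            opt.step()
            losses.append(loss)
            correct += int(((z >= 0) == (y[idx] == 1)).sum())
        val_p = model.predict_proba(x[va])
        val_acc = float(((val_p >= 0.5) == (y[va] == 1)).mean())
        rows.append(dict(epoch=epoch, train_loss=float(np.mean(losses)),
                         train_acc=correct / len(order), val_acc=val_acc))
        if verbose:
            print(f"[{model.spec.motif}] epoch {epoch}: "
                  f"loss {rows[-1]['train_loss']:.4f} "
                  f"train {rows[-1]['train_acc']:.3f} val {val_acc:.3f}",
                  flush=True)
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = {k: v.copy() for k, v in graph.state_dict().items()}
        elif epoch - best_epoch >= cfg.patience:
            break
        if best_acc == 1.0 and epoch - best_epoch >= 1:
            break  # nothing left to improve
    graph.load_state_dict(best_state)
    model.config = cfg
    model.log = pd.DataFrame(rows)
    return model


def accuracy(model: TrainedClassifier, images: np.ndarray,
             labels) -> float:
    """Fraction of correct hard-label predictions."""
    _, yhat = model.predict(images)
    return float((yhat == labels_to_y(labels)).mean())
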