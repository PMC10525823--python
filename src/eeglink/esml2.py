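"""EEG-task linking: a five-block 1-D CNN over single-channel sequences.

Task classification consumes whole single-channel sequences (vertical
segmentation), because the task signature lives in the long-range band-power
structure that time-slicing would destroy.  The architecture:

    block 1: BN-conv(16,k3,s1,same)-ReLU, BN-conv(16)-ReLU, maxpool(2,2)
    block 2: BN-conv(32)-ReLU,  maxpool(2,2)
    block 3: BN-conv(64)-ReLU,  maxpool(2,2)
    block 4: BN-conv(128)-ReLU, maxpool(2,2), dropout
    block 5: BN-conv(128)-ReLU, maxpool(2,2), dropout
    flatten -> linear softmax head

Batch normalization sits before every convolution's input; dropout (default
rate 0.5) is active only in the last two blocks and only during training.
For a 9600-sample input the block outputs are 4800x16, 2400x32, 1200x64,
600x128 and 300x128.  Training shares the Adam setup of the LSTM model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import (
    Adam,
    BatchNorm1d,
    Conv1d,
    Dense,
    Dropout,
    MaxPool1d,
    ReLU,
    clip_gradients,
    cross_entropy,
    softmax,
)
from .eeg_io import ClassScheme, EEGRecording
from .esml1 import TrainConfig, _encode_labels
from .segment import SegmentBatch, vertical_split

__all__ = [
    "ConvBlockSpec",
    "CNNArchitecture",
    "ConvNet1D",
    "output_shape",
    "train",
    "predict_task",
]

DEFAULT_FILTERS = ((16, 16), (32,), (64,), (128,), (128,))


@dataclass(frozen=True)
class ConvBlockSpec:
    """One conv block: n-filter convolutions, then a time-axis max-pool."""

    filters: tuple[int, ...]
    kernel: int = 3
    stride: int = 1
    padding: str = "same"
    pool: int = 2
    pool_stride: int = 2
    dropout: bool = False

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.stride < 1 or self.pool < 1:
            raise ValueError("kernel, stride and pool must be >= 1")
        if self.padding != "same" or self.stride != 1:
            raise ValueError("only stride-1 same-padding convolutions are supported")


@dataclass(frozen=True)
class CNNArchitecture:
    """Ordered block specs plus input length and class count."""

    input_length: int
    n_classes: int
    blocks: tuple[ConvBlockSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.blocks:
            blocks = tuple(
                ConvBlockSpec(filters=f, dropout=(i >= len(DEFAULT_FILTERS) - 2))
                for i, f in enumerate(DEFAULT_FILTERS)
            )
            object.__setattr__(self, "blocks", blocks)
        if self.input_length < 2 ** len(self.blocks):
            raise ValueError(
                f"input length {self.input_length} too short to pool "
                f"{len(self.blocks)} times"
            )


def output_shape(arch: CNNArchitecture, input_length: int | None = None) -> list[tuple[int, int]]:
    """Per-block (length, channels) after pooling.

    Stride-1 same-padding convolutions keep the length; each pool divides it
    by its stride (floor).
    """
    L = arch.input_length if input_length is None else input_length
    if L < 2 ** len(arch.blocks):
        raise ValueError(f"input length {L} too short to pool {len(arch.blocks)} times")
    shapes = []
    for blk in arch.blocks:
        L = L // blk.pool_stride
        shapes.append((L, blk.filters[-1]))
    return shapes


class ConvNet1D:
    """The five-block CNN with explicit forward/backward."""

    def __init__(self, arch: CNNArchitecture, seed: int = 0,
                 dropout_rate: float = 0.5, class_ids: list[int] | None = None) -> None:
        rng = np.random.default_rng(seed)
        self.arch = arch
        self.params: dict[str, np.ndarray] = {}
        self.stages: list[tuple[str, object]] = []
        self.bns: list[BatchNorm1d] = []
        c_in = 1
        for bi, blk in enumerate(arch.blocks):
            for ci, c_out in enumerate(blk.filters):
                bn = BatchNorm1d(c_in, prefix=f"b{bi}.bn{ci}")
                conv = Conv1d(c_in, c_out, blk.kernel, rng, prefix=f"b{bi}.conv{ci}")
                self.stages += [("bn", bn), ("conv", conv), ("relu", ReLU())]
                self.bns.append(bn)
                self.params.update(bn.params)
                self.params.update(conv.params)
                c_in = c_out
            self.stages.append(("pool", MaxPool1d(blk.pool)))
            if blk.dropout:
                self.stages.append(("dropout", Dropout(dropout_rate)))
        final_len, final_ch = output_shape(arch)[-1]
        self.head = Dense(final_len * final_ch, arch.n_classes, rng, prefix="head")
        self.params.update(self.head.params)
        self.class_ids = class_ids or list(range(1, arch.n_classes + 1))
        self._flat_shape: tuple[int, ...] | None = None
        self._drop_rng = np.random.default_rng(seed + 7)

    def forward_batch(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (B, 1, L) -> (B, n_classes) probabilities."""
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.arch.input_length:
            raise ValueError(
                f"input length {x.shape[2]} != architecture length {self.arch.input_length}"
            )
        for kind, stage in self.stages:
            if kind == "bn":
                x = stage.forward(x, training)
            elif kind == "dropout":
                x = stage.forward(x, training, self._drop_rng)
            else:
                x = stage.forward(x)
        self._flat_shape = x.shape
        logits = self.head.forward(x.reshape(x.shape[0], -1))
        return softmax(logits)

    def backward_batch(self, probs: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
        B = y.size
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads: dict[str, np.ndarray] = {}
        dx = self.head.backward(dlogits, grads).reshape(self._flat_shape)
        for kind, stage in reversed(self.stages):
            if kind in ("bn", "conv"):
                dx = stage.backward(dx, grads)
            else:
                dx = stage.backward(dx)
        return grads

    def forward(self, segment: np.ndarray, training: bool = False) -> np.ndarray:
        """Single 1 x L segment -> probability vector over classes."""
        seg = np.asarray(segment, float).reshape(1, 1, -1)
        return self.forward_batch(seg, training=training)[0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = dict(self.params)
        for i, bn in enumerate(self.bns):
            arrays[f"running_mean{i}"] = bn.running_mean
            arrays[f"running_var{i}"] = bn.running_var
        np.savez(path.with_suffix(".npz"), **arrays)
        cfg = {
            "input_length": self.arch.input_length,
            "n_classes": self.arch.n_classes,
            "class_ids": self.class_ids,
        }
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ConvNet1D":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        arch = CNNArchitecture(cfg["input_length"], cfg["n_classes"])
        model = cls(arch, class_ids=cfg["class_ids"])
        with np.load(path.with_suffix(".npz")) as arc:
            for k in model.params:
                model.params[k][...] = arc[k]
            for i, bn in enumerate(model.bns):
                bn.running_mean[...] = arc[f"running_mean{i}"]
                bn.running_var[...] = arc[f"running_var{i}"]
        return model


@dataclass
class TrainResult:
    model: ConvNet1D
    loss_trace: list[float] = field(default_factory=list)
    acc_trace: list[float] = field(default_factory=list)


def train(
    dataset: SegmentBatch,
    scheme: ClassScheme | None = None,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Train the task CNN on a vertical SegmentBatch.

    Labels come from the batch's class_ids, or from mapping task_ids through
    ``scheme`` when given.  Cross-entropy minimized with Adam; dropout only in
    the last two blocks and only while training.
    """
    config = config or TrainConfig(epochs=30)
    X = dataset.as_array()  # (B, 1, L)
    if scheme is not None:
        y_raw = np.array([scheme(t) for t in dataset.task_ids])
    else:
        y_raw = dataset.class_ids
    y, class_ids = _encode_labels(y_raw)
    if len(class_ids) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    arch = CNNArchitecture(input_length=X.shape[2], n_classes=len(class_ids))
    model = ConvNet1D(arch, seed=config.seed, dropout_rate=config.dropout,
                      class_ids=class_ids)
    opt = Adam(model.params, lr=config.lr, beta1=config.beta1,
               beta2=config.beta2, eps=config.eps)
    rng = np.random.default_rng(config.seed + 1)
    n = X.shape[0]
    losses, accs = [], []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss, ep_hits = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            probs = model.forward_batch(X[idx], training=True)
            ep_loss += cross_entropy(probs, y[idx]) * idx.size
            ep_hits += int((probs.argmax(axis=1) == y[idx]).sum())
            grads = model.backward_batch(probs, y[idx])
            clip_gradients(grads, config.clip_norm)
            opt.step(grads)
        losses.append(ep_loss / n)
        accs.append(ep_hits / n)
        if (config.early_stop_train_acc is not None
                and accs[-1] >= config.early_stop_train_acc):
            break
    return TrainResult(model=model, loss_trace=losses, acc_trace=accs)


def predict_segments(model: ConvNet1D, batch: SegmentBatch) -> np.ndarray:
    """Per-channel-segment predicted class ids (eval mode)."""
    probs = model.forward_batch(batch.as_array(), training=False)
    return np.array([model.class_ids[j] for j in probs.argmax(axis=1)])


def predict_task(model: ConvNet1D, rec: EEGRecording,
                 scheme: ClassScheme | None = None) -> int:
    """Recording-level decision: per-channel argmax, then majority vote.

    Ties break by summed probability over the tied classes.  ``scheme`` is
    accepted for interface symmetry; predictions are already class ids.
    """
    batch = vertical_split(rec)
    probs = model.forward_batch(batch.as_array(), training=False)
    votes = probs.argmax(axis=1)
    counts = np.bincount(votes, minlength=probs.shape[1])
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if tied.size == 1:
        return model.class_ids[tied[0]]
    sums = probs.sum(axis=0)[tied]
    return model.class_ids[tied[int(sums.argmax())]]
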