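"""EEG-user linking: a stacked peephole-LSTM classifier over raw segments.

A recording is cut into short multichannel windows (channels are the input
features, samples the time steps).  Five identical peephole-LSTM layers are
stacked; the final hidden state of the top layer feeds a linear softmax head
with one output per subject.  The peephole variant lets the input and forget
gates observe the previous cell state and the output gate observe the freshly
updated cell state:

    I_t = sigmoid(W_I x_t + U_I h_{t-1} + v_I * c_{t-1} + b_I)
    F_t = sigmoid(W_F x_t + U_F h_{t-1} + v_F * c_{t-1} + b_F)
    c_t = F_t * c_{t-1} + I_t * tanh(W_C x_t + U_C h_{t-1} + b_C)
    O_t = sigmoid(W_O x_t + U_O h_{t-1} + v_O * c_t + b_O)
    h_t = O_t * tanh(c_t)

Peephole weights are elementwise (diagonal).  The forget-gate bias is
initialized to 1.0 so early training retains memory.  Training minimizes
cross-entropy with Adam (stepsize 1e-3, decay rates 0.9/0.999, eps 1e-8);
everything is numpy with explicit backpropagation through time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Adam, Dense, clip_gradients, cross_entropy, softmax, glorot
from .segment import SegmentBatch

__all__ = [
    "TrainConfig",
    "LSTMLayerParams",
    "LSTMState",
    "PeepholeLSTMLayer",
    "StackedLSTMClassifier",
    "lstm_cell_step",
    "train",
    "predict_subject",
]

_GATES = ("I", "F", "C", "O")  # slice order inside the fused weight matrices


@dataclass
class TrainConfig:
    """Optimizer and schedule settings shared by both deep models."""

    lr: float = 1e-3          # Adam stepsize alpha
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    hidden: int = 64
    n_layers: int = 5
    forget_bias: float = 1.0  # "forgetting rate": forget-gate bias init
    clip_norm: float = 5.0
    dropout: float = 0.5      # CNN only
    early_stop_train_acc: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("decay rates must lie in (0, 1)")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class LSTMState:
    """Hidden and cell vectors of one layer."""

    h: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, float)
        self.c = np.asarray(self.c, float)
        if self.h.shape != self.c.shape:
            raise ValueError("h and c must share a shape")


class LSTMLayerParams:
    """Fused gate parameters of one peephole-LSTM layer.

    W: (n_in, 4H), U: (H, 4H), b: (4H,) with gate order I, F, C, O;
    v_I, v_F, v_O: (H,) elementwise peephole weights.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 prefix: str, forget_bias: float = 1.0) -> None:
        self.n_in, self.hidden, self.prefix = n_in, hidden, prefix
        H = hidden
        b = np.zeros(4 * H)
        b[H:2 * H] = forget_bias
        self.params = {
            f"{prefix}.W": glorot(rng, (n_in, 4 * H), n_in),
            f"{prefix}.U": glorot(rng, (H, 4 * H), H),
            f"{prefix}.b": b,
            f"{prefix}.vI": glorot(rng, (H,), H),
            f"{prefix}.vF": glorot(rng, (H,), H),
            f"{prefix}.vO": glorot(rng, (H,), H),
        }

    def gate_slices(self) -> dict[str, slice]:
        H = self.hidden
        return {g: slice(i * H, (i + 1) * H) for i, g in enumerate(_GATES)}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def lstm_cell_step(layer: LSTMLayerParams, x: np.ndarray, state: LSTMState) -> LSTMState:
    """One vectorized peephole-LSTM step; x is (..., n_in)."""
    p, H = layer.params, layer.hidden
    pre = x @ p[f"{layer.prefix}.W"] + state.h @ p[f"{layer.prefix}.U"] + p[f"{layer.prefix}.b"]
    sl = layer.gate_slices()
    i = _sigmoid(pre[..., sl["I"]] + p[f"{layer.prefix}.vI"] * state.c)
    f = _sigmoid(pre[..., sl["F"]] + p[f"{layer.prefix}.vF"] * state.c)
    g = np.tanh(pre[..., sl["C"]])
    c = f * state.c + i * g
    o = _sigmoid(pre[..., sl["O"]] + p[f"{layer.prefix}.vO"] * c)
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c)


class PeepholeLSTMLayer:
    """One layer unrolled over a sequence, with caches for BPTT."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 prefix: str, forget_bias: float = 1.0) -> None:
        self.layer = LSTMLayerParams(n_in, hidden, rng, prefix, forget_bias)
        self.params = self.layer.params

    def forward(self, xs: np.ndarray) -> np.ndarray:
        """xs: (T, B, n_in) -> hidden sequence (T, B, H).

        The input projection xs @ W is hoisted out of the time loop; only the
        recurrent matmul and the gate nonlinearities stay inside it.
        """
        T, B, _ = xs.shape
        H = self.layer.hidden
        p, pre_slices = self.layer.params, self.layer.gate_slices()
        pfx = self.layer.prefix
        W, U, b = p[f"{pfx}.W"], p[f"{pfx}.U"], p[f"{pfx}.b"]
        vI, vF, vO = p[f"{pfx}.vI"], p[f"{pfx}.vF"], p[f"{pfx}.vO"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((T, B, H))
        self._xs = xs
        self._gates = np.empty((T, B, 4 * H))  # i, f, g, o after nonlinearity
        self._cells = np.empty((T, B, H))
        self._cells_prev = np.empty((T, B, H))
        self._tc = np.empty((T, B, H))
        xW = xs @ W
        sI, sF, sC, sO = (pre_slices[g] for g in _GATES)
        for t in range(T):
            pre = xW[t] + h @ U + b
            i = _sigmoid(pre[:, sI] + vI * c)
            f = _sigmoid(pre[:, sF] + vF * c)
            g = np.tanh(pre[:, sC])
            self._cells_prev[t] = c
            c = f * c + i * g
            o = _sigmoid(pre[:, sO] + vO * c)
            tc = np.tanh(c)
            h = o * tc
            gt = self._gates[t]
            gt[:, sI], gt[:, sF], gt[:, sC], gt[:, sO] = i, f, g, o
            self._cells[t] = c
            self._tc[t] = tc
            hs[t] = h
        self._hs = hs
        return hs

    def backward(self, dhs: np.ndarray, grads: dict[str, np.ndarray]) -> np.ndarray:
        """dhs: (T, B, H) upstream gradient on each hidden output -> dxs.

        Per-step work is elementwise plus one recurrent matmul; the weight
        gradients and the input gradient are single stacked matmuls after
        the loop.
        """
        p = self.layer.params
        pfx = self.layer.prefix
        W, U = p[f"{pfx}.W"], p[f"{pfx}.U"]
        vI, vF, vO = p[f"{pfx}.vI"], p[f"{pfx}.vF"], p[f"{pfx}.vO"]
        T, B, H = dhs.shape
        sl = self.layer.gate_slices()
        sI, sF, sC, sO = (sl[g] for g in _GATES)
        dpre_all = np.empty((T, B, 4 * H))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            gt = self._gates[t]
            i, f, g, o = gt[:, sI], gt[:, sF], gt[:, sC], gt[:, sO]
            c_prev, c, tc = self._cells_prev[t], self._cells[t], self._tc[t]
            dh = dhs[t] + dh_next
            do_pre = dh * tc * o * (1 - o)
            dc = dc_next + dh * o * (1 - tc**2) + do_pre * vO
            d = dpre_all[t]
            d[:, sI] = dc * g * i * (1 - i)
            d[:, sF] = dc * c_prev * f * (1 - f)
            d[:, sC] = dc * i * (1 - g**2)
            d[:, sO] = do_pre
            dh_next = d @ U.T
            dc_next = dc * f + d[:, sI] * vI + d[:, sF] * vF
        flat = dpre_all.reshape(T * B, 4 * H)
        grads[f"{pfx}.W"] = self._xs.reshape(T * B, -1).T @ flat
        h_prev = np.concatenate([np.zeros((1, B, H)), self._hs[:-1]])
        grads[f"{pfx}.U"] = h_prev.reshape(T * B, H).T @ flat
        grads[f"{pfx}.b"] = flat.sum(axis=0)
        grads[f"{pfx}.vI"] = (dpre_all[:, :, sI] * self._cells_prev).sum(axis=(0, 1))
        grads[f"{pfx}.vF"] = (dpre_all[:, :, sF] * self._cells_prev).sum(axis=(0, 1))
        grads[f"{pfx}.vO"] = (dpre_all[:, :, sO] * self._cells).sum(axis=(0, 1))
        return dpre_all @ W.T


class StackedLSTMClassifier:
    """Five stacked peephole-LSTM layers plus a linear softmax head."""

    def __init__(
        self,
        n_inputs: int,
        n_subjects: int,
        hidden: int = 64,
        n_layers: int = 5,
        forget_bias: float = 1.0,
        seed: int = 0,
        subject_ids: list[int] | None = None,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.n_inputs, self.n_subjects = n_inputs, n_subjects
        self.hidden, self.n_layers = hidden, n_layers
        self.layers = [
            PeepholeLSTMLayer(
                n_inputs if j == 0 else hidden, hidden, rng,
                prefix=f"lstm{j}", forget_bias=forget_bias,
            )
            for j in range(n_layers)
        ]
        self.head = Dense(hidden, n_subjects, rng, prefix="head")
        self.params: dict[str, np.ndarray] = {}
        for lyr in self.layers:
            self.params.update(lyr.params)
        self.params.update(self.head.params)
        self.subject_ids = subject_ids or list(range(1, n_subjects + 1))

    def forward_batch(self, segs: np.ndarray) -> np.ndarray:
        """segs: (B, K, l) raw segments -> (B, n_subjects) probabilities."""
        xs = segs.transpose(2, 0, 1)  # time-major (T, B, K)
        for lyr in self.layers:
            xs = lyr.forward(xs)
        logits = self.head.forward(xs[-1])
        return softmax(logits)

    def backward_batch(self, probs: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
        """Gradient of mean cross-entropy wrt all parameters."""
        B = y.size
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads: dict[str, np.ndarray] = {}
        dh_last = self.head.backward(dlogits, grads)
        T = self.layers[-1]._hs.shape[0]
        dhs = np.zeros((T,) + dh_last.shape)
        dhs[-1] = dh_last
        for lyr in reversed(self.layers):
            dhs = lyr.backward(dhs, grads)
        return grads

    def forward(self, segment: np.ndarray) -> np.ndarray:
        """Single k x l segment -> probability vector over subjects."""
        return self.forward_batch(segment[None])[0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        cfg = {
            "n_inputs": self.n_inputs, "n_subjects": self.n_subjects,
            "hidden": self.hidden, "n_layers": self.n_layers,
            "subject_ids": self.subject_ids,
        }
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "StackedLSTMClassifier":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        ids = cfg.pop("subject_ids")
        model = cls(**cfg, subject_ids=ids)
        with np.load(path.with_suffix(".npz")) as arc:
            for k in model.params:
                model.params[k][...] = arc[k]
        return model


@dataclass
class TrainResult:
    model: StackedLSTMClassifier
    loss_trace: list[float] = field(default_factory=list)
    acc_trace: list[float] = field(default_factory=list)

    @property
    def config_echo(self) -> dict:
        return {"loss_final": self.loss_trace[-1] if self.loss_trace else None}


def _encode_labels(ids: np.ndarray) -> tuple[np.ndarray, list[int]]:
    uniq = sorted(set(int(v) for v in ids))
    lut = {v: j for j, v in enumerate(uniq)}
    return np.array([lut[int(v)] for v in ids]), uniq


def train(dataset: SegmentBatch, config: TrainConfig | None = None) -> TrainResult:
    """Train the subject classifier on a horizontal SegmentBatch.

    Minimizes cross-entropy over subjects with Adam; the loss trace holds one
    mean-loss entry per epoch.  Deterministic given config.seed.
    """
    config = config or TrainConfig()
    X = dataset.as_array()  # (B, K, l)
    y_raw = dataset.subject_ids
    y, subject_ids = _encode_labels(y_raw)
    if len(subject_ids) < 2:
        raise ValueError("need at least 2 subjects to train a classifier")
    counts = np.bincount(y)
    if counts.min() < 1:
        raise ValueError("every subject needs at least one training segment")
    model = StackedLSTMClassifier(
        n_inputs=X.shape[1],
        n_subjects=len(subject_ids),
        hidden=config.hidden,
        n_layers=config.n_layers,
        forget_bias=config.forget_bias,
        seed=config.seed,
        subject_ids=subject_ids,
    )
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
            probs = model.forward_batch(X[idx])
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


def predict_segments(model: StackedLSTMClassifier, batch: SegmentBatch) -> np.ndarray:
    """Per-segment predicted subject ids."""
    probs = model.forward_batch(batch.as_array())
    return np.array([model.subject_ids[j] for j in probs.argmax(axis=1)])


def predict_subject(model: StackedLSTMClassifier, segments: SegmentBatch | np.ndarray) -> int:
    """Recording-level decision: per-segment argmax, then majority vote.

    Ties are broken by the summed probability over the tied subjects.
    """
    X = segments.as_array() if isinstance(segments, SegmentBatch) else np.asarray(segments)
    if X.ndim == 2:
        X = X[None]
    if X.shape[0] < 1:
        raise ValueError("need at least one segment")
    probs = model.forward_batch(X)
    votes = probs.argmax(axis=1)
    counts = np.bincount(votes, minlength=probs.shape[1])
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if tied.size == 1:
        return model.subject_ids[tied[0]]
    sums = probs.sum(axis=0)[tied]
    return model.subject_ids[tied[int(sums.argmax())]]
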