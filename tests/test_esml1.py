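"""Peephole-LSTM subject classifier: cell math, stack, training."""

import numpy as np
import pytest

from eeglink import esml1
from eeglink.esml1 import (
    LSTMLayerParams,
    LSTMState,
    PeepholeLSTMLayer,
    StackedLSTMClassifier,
    TrainConfig,
    lstm_cell_step,
    predict_subject,
    train,
)
from eeglink.segment import SegmentBatch


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def scalar_peephole_step(W, U, b, vI, vF, vO, x, h_prev, c_prev):
    """Independent explicit-loop reference for one peephole-LSTM step.

    Works element by element with plain Python loops; gate order in the fused
    matrices is I, F, C, O.
    """
    H = len(h_prev)
    n_in = len(x)

    def affine(gate, j):
        off = gate * H + j
        s = b[off]
        for i in range(n_in):
            s += W[i, off] * x[i]
        for i in range(H):
            s += U[i, off] * h_prev[i]
        return s

    h, c = np.zeros(H), np.zeros(H)
    for j in range(H):
        i_j = _sigmoid(affine(0, j) + vI[j] * c_prev[j])
        f_j = _sigmoid(affine(1, j) + vF[j] * c_prev[j])
        g_j = np.tanh(affine(2, j))
        c[j] = f_j * c_prev[j] + i_j * g_j
        o_j = _sigmoid(affine(3, j) + vO[j] * c[j])
        h[j] = o_j * np.tanh(c[j])
    return h, c


def _zero_layer(n_in, hidden):
    layer = LSTMLayerParams(n_in, hidden, np.random.default_rng(0), "z", forget_bias=0.0)
    for k in layer.params:
        layer.params[k][...] = 0.0
    return layer


class TestCell:
    def test_zero_weights_zero_state(self):
        """sigmoid(0)=0.5 and tanh(0)=0 make all outputs vanish."""
        layer = _zero_layer(2, 3)
        state = lstm_cell_step(layer, np.array([1.0, -2.0]), LSTMState(np.zeros(3), np.zeros(3)))
        assert np.allclose(state.c, 0.0)
        assert np.allclose(state.h, 0.0)

    def test_zero_weights_unit_cell(self):
        """Scalar evaluation: c=0.5*1+0.5*0=0.5, h=0.5*tanh(0.5)~0.23106."""
        layer = _zero_layer(1, 1)
        state = lstm_cell_step(layer, np.array([3.0]), LSTMState(np.zeros(1), np.ones(1)))
        assert state.c[0] == pytest.approx(0.5)
        assert state.h[0] == pytest.approx(0.5 * np.tanh(0.5), abs=1e-6)
        assert state.h[0] == pytest.approx(0.23106, abs=1e-5)

    def test_matches_scalar_loop_oracle(self):
        """Vectorized cell equals the explicit-loop implementation on 100
        random instances within 1e-10."""
        rng = np.random.default_rng(123)
        for trial in range(100):
            n_in = int(rng.integers(1, 5))
            H = int(rng.integers(1, 6))
            layer = LSTMLayerParams(n_in, H, rng, f"t{trial}")
            x = rng.normal(size=n_in)
            h_prev = rng.normal(size=H)
            c_prev = rng.normal(size=H)
            out = lstm_cell_step(layer, x, LSTMState(h_prev, c_prev))
            p = layer.params
            h_ref, c_ref = scalar_peephole_step(
                p[f"t{trial}.W"], p[f"t{trial}.U"], p[f"t{trial}.b"],
                p[f"t{trial}.vI"], p[f"t{trial}.vF"], p[f"t{trial}.vO"],
                x, h_prev, c_prev,
            )
            assert np.allclose(out.h, h_ref, atol=1e-10)
            assert np.allclose(out.c, c_ref, atol=1e-10)

    def test_gate_boundedness(self):
        """Hidden state stays in (-1, 1) and cell magnitude grows at most
        linearly in t over random rollouts."""
        rng = np.random.default_rng(5)
        lyr = PeepholeLSTMLayer(3, 4, rng, "g")
        T = 50
        xs = rng.normal(size=(T, 2, 3))
        hs = lyr.forward(xs)
        assert np.all(np.abs(hs) < 1.0)
        # |c_t| <= t when c_0 = 0: each step adds at most 1 in magnitude
        bound = np.arange(1, T + 1)[:, None, None]
        assert np.all(np.abs(lyr._cells) <= bound + 1e-9)


class TestForward:
    def test_probabilities_sum_to_one(self):
        m = StackedLSTMClassifier(n_inputs=3, n_subjects=5, hidden=8, seed=0)
        rng = np.random.default_rng(0)
        probs = m.forward_batch(rng.normal(size=(4, 3, 20)))
        assert probs.shape == (4, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-8)
        assert np.all((probs > 0) & (probs < 1))

    def test_zero_head_gives_uniform(self):
        m = StackedLSTMClassifier(n_inputs=2, n_subjects=4, hidden=6, seed=1)
        m.params["head.W"][...] = 0.0
        m.params["head.b"][...] = 0.0
        probs = m.forward(np.random.default_rng(1).normal(size=(2, 15)))
        assert np.allclose(probs, 0.25, atol=1e-12)

    def test_softmax_closed_form(self):
        from eeglink._nn import softmax

        probs = softmax(np.array([0.0, np.log(2.0)]))
        assert probs == pytest.approx([1 / 3, 2 / 3])

    def test_five_layer_default(self):
        m = StackedLSTMClassifier(n_inputs=2, n_subjects=2)
        assert len(m.layers) == 5
        assert m.hidden == 64


def _toy_batch(n_per=20, l=30, seed=0):
    """Two subjects with cleanly separated signal mean; trivially learnable."""
    rng = np.random.default_rng(seed)
    segs, labels = [], []
    for subj, mu in ((1, -1.0), (2, 1.0)):
        for _ in range(n_per):
            segs.append(rng.normal(mu, 0.3, size=(2, l)))
            labels.append((subj, 1, 0))
    return SegmentBatch(segments=segs, labels=labels)


class TestTrain:
    def test_separable_toy_converges(self):
        batch = _toy_batch()
        cfg = TrainConfig(hidden=8, n_layers=2, epochs=50, batch_size=8, seed=0,
                          early_stop_train_acc=1.0)
        res = train(batch, cfg)
        assert res.acc_trace[-1] == 1.0
        assert len(res.loss_trace) <= 50

    def test_initial_loss_near_ln_n(self):
        batch = _toy_batch(n_per=10)
        cfg = TrainConfig(hidden=8, n_layers=2, epochs=1, batch_size=1000, seed=0)
        res = train(batch, cfg)
        # one full-batch epoch: loss recorded before the single update
        assert res.loss_trace[0] == pytest.approx(np.log(2), abs=0.05)

    def test_same_seed_same_trace(self):
        cfg = TrainConfig(hidden=6, n_layers=2, epochs=3, seed=4)
        r1 = train(_toy_batch(n_per=5), cfg)
        r2 = train(_toy_batch(n_per=5), cfg)
        assert r1.loss_trace == r2.loss_trace

    def test_single_subject_rejected(self):
        rng = np.random.default_rng(0)
        batch = SegmentBatch([rng.normal(size=(2, 10))] * 4, [(1, 1, 0)] * 4)
        with pytest.raises(ValueError, match="2 subjects"):
            train(batch, TrainConfig(epochs=1))

    def test_untrained_accuracy_at_chance(self):
        """Random weights score within 3 SE of 1/N on balanced classes."""
        rng = np.random.default_rng(8)
        N, per = 4, 50
        segs = [rng.normal(size=(3, 20)) for _ in range(N * per)]
        labels = [(1 + i // per, 1, 0) for i in range(N * per)]
        batch = SegmentBatch(segments=segs, labels=labels)
        m = StackedLSTMClassifier(n_inputs=3, n_subjects=N, hidden=8, seed=3)
        preds = esml1.predict_segments(m, batch)
        acc = (preds == batch.subject_ids).mean()
        n = N * per
        se = np.sqrt(0.25 / n / N) * np.sqrt(N)  # binomial SE at p=1/N
        assert abs(acc - 1.0 / N) <= 3 * np.sqrt((1 / N) * (1 - 1 / N) / n)


class TestPredictSubject:
    def _const_model(self, probs_matrix):
        """Model stub whose forward_batch returns fixed probabilities."""

        class Stub:
            subject_ids = list(range(1, probs_matrix.shape[1] + 1))

            def forward_batch(self, X):
                return probs_matrix[: X.shape[0]]

        return Stub()

    def test_unanimous(self):
        probs = np.array([[0.1, 0.1, 0.8]] * 3)
        m = self._const_model(probs)
        assert predict_subject(m, np.zeros((3, 2, 4))) == 3

    def test_tie_broken_by_summed_probability(self):
        probs = np.array([
            [0.6, 0.4],
            [0.55, 0.45],
            [0.1, 0.9],
            [0.2, 0.8],
        ])
        m = self._const_model(probs)
        # votes 2:2; summed probs favour subject 2 (1.45+1.1 vs ...)
        assert predict_subject(m, np.zeros((4, 2, 4))) == 2

    def test_single_segment(self):
        probs = np.array([[0.7, 0.3]])
        m = self._const_model(probs)
        assert predict_subject(m, np.zeros((1, 2, 4))) == 1


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        m = StackedLSTMClassifier(n_inputs=2, n_subjects=3, hidden=4, n_layers=2, seed=0)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 2, 10))
        before = m.forward_batch(X)
        m.save(tmp_path / "model")
        m2 = StackedLSTMClassifier.load(tmp_path / "model")
        assert np.allclose(m2.forward_batch(X), before, atol=1e-12)
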