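"""Tests for the LSTM cell, stacked classifiers, training and evaluation."""

import copy
import math

import numpy as np
import pytest

from ttcoach import lstm_core as lc
from ttcoach.dataio import LabelSpec, StrokeDataset, StrokeSequence


def _cell(H, I, fill=0.0):
    return lc.LSTMCellParams(
        Wx=np.full((4 * H, I), fill),
        Wh=np.full((4 * H, H), fill),
        b=np.zeros(4 * H),
    )


class TestCellStep:
    def test_zero_parameter_fixed_point(self):
        """All-zero weights: every gate sits at 0.5, g=0, so c and h stay 0."""
        cell = _cell(H=3, I=2)
        state = lc.cell_step(
            cell, np.ones(2), lc.LSTMCellState(c=np.zeros(3), h=np.zeros(3))
        )
        assert np.allclose(state.c, 0.0)
        assert np.allclose(state.h, 0.0)

    def test_forget_gate_saturation_keeps_memory(self, rng):
        """A large forget bias pins f ~ 1: the internal state is carried over
        (plus the g*i leak, zero here because Wxg = 0)."""
        H = 4
        cell = _cell(H=H, I=2)
        cell.b[:H] = 20.0  # forget-gate block
        v = rng.normal(size=H)
        state = lc.cell_step(
            cell, np.zeros(2), lc.LSTMCellState(c=v.copy(), h=np.zeros(H))
        )
        sig20 = 1.0 / (1.0 + math.exp(-20.0))
        assert np.max(np.abs(state.c - sig20 * v)) < 1e-8 * np.linalg.norm(v)

    def test_scalar_hand_computed_step(self):
        """Scalar cell with unit input weights: values match the gate
        equations evaluated by hand."""
        cell = lc.LSTMCellParams(
            Wx=np.ones((4, 1)), Wh=np.zeros((4, 1)), b=np.zeros(4)
        )
        state = lc.cell_step(
            cell, np.array([1.0]), lc.LSTMCellState(c=np.zeros(1), h=np.zeros(1))
        )
        sig1 = 1.0 / (1.0 + math.exp(-1.0))  # ~0.73106
        g = math.tanh(1.0)  # ~0.76159
        c = sig1 * g  # ~0.55677
        h = sig1 * math.tanh(c)  # ~0.36960
        assert abs(state.c[0] - c) < 1e-8
        assert abs(state.h[0] - h) < 1e-8
        assert abs(c - 0.55677) < 1e-5 and abs(h - 0.36960) < 1e-5

    def test_shape_mismatch_raises(self):
        cell = _cell(H=3, I=2)
        with pytest.raises(ValueError, match="input size"):
            lc.cell_step(
                cell, np.ones(5), lc.LSTMCellState(c=np.zeros(3), h=np.zeros(3))
            )

    def test_gate_and_hidden_ranges(self, rng):
        """Gates are logistic (0,1); h = o * tanh(c) lies in (-1, 1)."""
        H, I = 6, 4
        for _ in range(50):
            cell = lc.LSTMCellParams(
                Wx=rng.normal(size=(4 * H, I)),
                Wh=rng.normal(size=(4 * H, H)),
                b=rng.normal(size=4 * H),
            )
            state = lc.cell_step(
                cell,
                rng.normal(size=I),
                lc.LSTMCellState(c=rng.normal(size=H), h=np.tanh(rng.normal(size=H))),
            )
            assert np.all(np.abs(state.h) < 1.0)


class TestRunStack:
    def test_softmax_scores_sum_to_one(self, rng):
        params = lc.init_params("bi", hidden=5, input_size=4, n_classes=7, seed=0)
        out = lc.run_stack(params, rng.normal(size=(9, 4)))
        assert abs(out["scores"].sum() - 1.0) < 1e-12
        assert out["h2"].shape == (9, 10)

    def test_bidirectional_with_zeroed_backward_path_equals_unidirectional(self, rng):
        H, I, K = 5, 4, 7
        uni = lc.init_params("uni", hidden=H, input_size=I, n_classes=K, seed=1)
        bi = lc.init_params("bi", hidden=H, input_size=I, n_classes=K, seed=2)
        # copy forward cells; level 2's forward cell must ignore the backward
        # half of its concatenated input
        bi.cells[(1, "f")] = copy.deepcopy(uni.cells[(1, "f")])
        l2 = copy.deepcopy(uni.cells[(2, "f")])
        Wx2 = np.zeros((4 * H, 2 * H))
        Wx2[:, :H] = l2.Wx
        bi.cells[(2, "f")] = lc.LSTMCellParams(Wx=Wx2, Wh=l2.Wh, b=l2.b)
        for lvl in (1, 2):
            c = bi.cells[(lvl, "b")]
            c.Wx[:], c.Wh[:], c.b[:] = 0.0, 0.0, 0.0
        bi.W_out[:, :H] = uni.W_out
        bi.W_out[:, H:] = 0.0
        bi.b_out[:] = uni.b_out
        x = rng.normal(size=(9, I))
        # zeroed backward cells still produce nonzero h via gate offsets only
        # when biases are zero and inputs are zero-weighted: f=i=o=0.5, g=0
        # so h stays exactly 0 at every step.
        assert np.allclose(
            lc.run_stack(bi, x)["scores"], lc.run_stack(uni, x)["scores"], atol=1e-12
        )

    def test_time_reversal_symmetry(self, rng):
        """Swapping forward/backward parameters and reversing the input
        reproduces the original scores."""
        params = lc.init_params("bi", hidden=4, input_size=3, n_classes=5, seed=3)
        swapped = copy.deepcopy(params)
        for lvl in (1, 2):
            swapped.cells[(lvl, "f")], swapped.cells[(lvl, "b")] = (
                swapped.cells[(lvl, "b")],
                swapped.cells[(lvl, "f")],
            )
        H = params.hidden
        swapped.W_out = np.concatenate(
            [params.W_out[:, H:], params.W_out[:, :H]], axis=1
        )
        # level-2 inputs are [fwd, bwd] concatenations; swap those halves too
        for lvl in (2,):
            for d in ("f", "b"):
                c = swapped.cells[(lvl, d)]
                c.Wx = np.concatenate([c.Wx[:, H:], c.Wx[:, :H]], axis=1)
        x = rng.normal(size=(8, 3))
        a = lc.run_stack(params, x)["scores"]
        b = lc.run_stack(swapped, x[::-1])["scores"]
        assert np.allclose(a, b, atol=1e-12)

    def test_nonfinite_activation_names_time_step(self):
        params = lc.init_params("uni", hidden=3, input_size=2, n_classes=4, seed=0)
        x = np.zeros((6, 2))
        x[4, 0] = np.nan
        with pytest.raises(FloatingPointError, match="time step 4"):
            lc.run_stack(params, x)


class TestParamCount:
    @pytest.mark.parametrize("direction", ["uni", "bi"])
    def test_formula_matches_brute_force(self, direction):
        params = lc.init_params(direction, hidden=38, input_size=18, n_classes=10)
        counts = lc.count_params(params)
        assert counts["formula"] == counts["brute_force"]

    def test_single_cell_formula(self):
        # one cell: 4 * (H*(I+H) + H)
        params = lc.init_params("uni", hidden=3, input_size=2, n_classes=2, levels=1)
        cell = 4 * (3 * (2 + 3) + 3)
        readout = 2 * 3 + 2
        assert lc.count_params(params)["brute_force"] == cell + readout


def _toy_two_class(n=20, T=6, C=3, seed=0):
    """Linearly separable two-class toy wrapped as a StrokeDataset."""
    rng = np.random.default_rng(seed)
    labels = LabelSpec(subjects=("coach", "beginner"), skills=("forehand_stroke",))
    strokes = []
    for i in range(n):
        cls = i % 2
        base = np.full((T, C), 0.8 if cls else 0.2)
        strokes.append(
            StrokeSequence(
                "beginner" if cls else "coach",
                "forehand_stroke",
                i,
                "train",
                base + 0.05 * rng.normal(size=(T, C)),
            )
        )
    return StrokeDataset(strokes, labels)


class TestTraining:
    def test_gradients_match_finite_differences(self, rng):
        """Full BPTT gradient of the regularized cross-entropy loss checked
        against central finite differences on a small bidirectional net."""
        params = lc.init_params("bi", hidden=3, input_size=2, n_classes=4, seed=0)
        X = rng.normal(size=(3, 5, 2))
        Y = np.eye(4)[[0, 2, 3]]
        _, _, grads, _ = lc._loss_and_grads(params, X, Y, l2=1e-3)
        pairs = lc._flat_grad_arrays(params, grads)
        eps = 1e-6
        for arr, g in pairs:
            flat = arr.ravel()
            idx = rng.choice(flat.size, size=min(10, flat.size), replace=False)
            for j in idx:
                old = flat[j]
                flat[j] = old + eps
                lp, *_ = lc._loss_and_grads(params, X, Y, l2=1e-3)
                flat[j] = old - eps
                lm, *_ = lc._loss_and_grads(params, X, Y, l2=1e-3)
                flat[j] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - g.ravel()[j]) < 1e-6 * max(1.0, abs(num))

    def test_cost_decreases_on_separable_toy(self):
        ds = _toy_two_class()
        cfg = lc.TrainConfig(epochs=40, seed=0, batch_size=5)
        _, curves = lc.train_classifier(ds, cfg, direction="uni", hidden=4)
        cost = np.array(curves["train_cost"])
        assert cost[-1] < cost[0]
        upticks = np.sum(np.diff(cost) > 1e-9)
        assert upticks <= 0.05 * len(cost) + 1

    def test_training_deterministic_given_seed(self, small_scaled):
        train, _, _ = small_scaled
        cfg = lc.TrainConfig(epochs=5, seed=7)
        p1, _ = lc.train_classifier(train, cfg, direction="uni", hidden=6)
        p2, _ = lc.train_classifier(train, cfg, direction="uni", hidden=6)
        for (n1, a1), (n2, a2) in zip(p1.named_arrays(), p2.named_arrays()):
            assert n1 == n2
            assert np.array_equal(a1, a2)

    def test_divergence_raises_helpful_error(self, small_scaled):
        """A non-finite cost aborts training with actionable advice."""
        train, _, _ = small_scaled
        bad = lc.init_params("uni", hidden=6, input_size=18, n_classes=10, seed=0)
        bad.W_out[0, 0] = np.inf  # drives the cost non-finite on step one
        cfg = lc.TrainConfig(epochs=2, seed=0)
        with np.errstate(invalid="ignore"), pytest.raises(
            FloatingPointError, match="learning rate"
        ):
            lc.train_classifier(train, cfg, arch=bad)


class TestEvaluate:
    def _dataset_with_labels(self, y, T=4, C=2):
        spec = LabelSpec()
        strokes = []
        for i, lab in enumerate(y):
            subj, skill = spec.split_index(lab)
            strokes.append(
                StrokeSequence(subj, skill, i, "test", np.zeros((T, C)) + lab)
            )
        return StrokeDataset(strokes, spec)

    def test_perfect_predictions(self, monkeypatch):
        y = list(range(10)) * 3
        ds = self._dataset_with_labels(y)
        monkeypatch.setattr(lc, "predict", lambda p, d: np.array(y))
        rep = lc.evaluate(None, ds)
        assert rep.as_percentages()["overall_accuracy"] == 100.0
        assert rep.f1 == 1.0

    def test_28_of_30_is_93_3_percent(self, monkeypatch):
        y = list(range(10)) * 3
        yhat = list(y)
        yhat[0] = (y[0] + 1) % 10
        yhat[11] = (y[11] + 1) % 10
        ds = self._dataset_with_labels(y)
        monkeypatch.setattr(lc, "predict", lambda p, d: np.array(yhat))
        rep = lc.evaluate(None, ds)
        assert rep.as_percentages()["overall_accuracy"] == 93.3

    def test_single_class_collapse_on_balanced_set(self, monkeypatch):
        y = list(range(10)) * 3
        ds = self._dataset_with_labels(y)
        monkeypatch.setattr(lc, "predict", lambda p, d: np.zeros(30, dtype=int))
        rep = lc.evaluate(None, ds)
        assert rep.as_percentages()["overall_accuracy"] == 10.0
        assert abs(rep.recall - 0.1) < 1e-12

    def test_absent_class_warns(self, monkeypatch):
        y = [0, 1] * 3
        ds = self._dataset_with_labels(y)
        monkeypatch.setattr(lc, "predict", lambda p, d: np.array(y))
        with pytest.warns(UserWarning, match="absent"):
            rep = lc.evaluate(None, ds)
        assert rep.accuracy == 1.0

    def test_empty_test_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            lc.evaluate(None, StrokeDataset([]))
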