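"""Two-stacked uni/bi-directional LSTM classifiers for IMU stroke sequences.

The LSTM cell follows the standard gating scheme: forget, input and output
gates use the logistic function, the input-modulation gate and the output
nonlinearity use tanh,

    f_t = sigma(Wxf x_t + Whf h_{t-1} + bf)        (likewise i_t, o_t)
    g_t = tanh (Wxg x_t + Whg h_{t-1} + bg)
    c_t = f_t * c_{t-1} + g_t * i_t
    h_t = o_t * tanh(c_t)

Two cells are stacked (level 2 consumes level 1's hidden states); the
bidirectional variant runs a time-reversed copy of each level and
concatenates forward and backward states. Classification reads out the
final level-2 state(s) through an affine softmax layer over the 10 joint
(subject x skill) classes.

Training (mean cross-entropy + L2, Adam, no dropout) is implemented with
hand-derived backpropagation through time on NumPy arrays; gradients are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .dataio import StrokeDataset

_GATES = ("f", "i", "o", "g")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class LSTMCellParams:
    """One cell's parameters; gates stacked in f, i, o, g order.

    ``Wx`` is (4H, input), ``Wh`` is (4H, H), ``b`` is (4H,). Per-gate
    blocks are exposed through :meth:`gate`.
    """

    Wx: np.ndarray
    Wh: np.ndarray
    b: np.ndarray

    @property
    def hidden(self) -> int:
        return self.Wh.shape[1]

    @property
    def input_size(self) -> int:
        return self.Wx.shape[1]

    def gate(self, k: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(W_xk, W_hk, b_k) for gate k in {f, i, o, g}."""
        j = _GATES.index(k)
        H = self.hidden
        sl = slice(j * H, (j + 1) * H)
        return self.Wx[sl], self.Wh[sl], self.b[sl]


@dataclass
class LSTMCellState:
    """Internal state c_t (memory recurrence) and hidden state h_t (output)."""

    c: np.ndarray
    h: np.ndarray


@dataclass
class ClassifierParams:
    """Full two-stacked classifier: cells keyed by (level, direction)."""

    direction: str  # "uni" | "bi"
    hidden: int
    input_size: int
    n_classes: int
    cells: dict  # {(level:int, dir:str): LSTMCellParams}; dir in {"f","b"}
    W_out: np.ndarray  # (n_classes, feature)
    b_out: np.ndarray  # (n_classes,)
    levels: int = 2

    @property
    def feature_size(self) -> int:
        return self.hidden * (2 if self.direction == "bi" else 1)

    def directions(self) -> tuple[str, ...]:
        return ("f", "b") if self.direction == "bi" else ("f",)

    def named_weights(self) -> list[tuple[str, np.ndarray]]:
        """Maskable weight matrices in deterministic order (biases excluded)."""
        out = []
        for lvl in range(1, self.levels + 1):
            for d in self.directions():
                cell = self.cells[(lvl, d)]
                out.append((f"l{lvl}{d}.Wx", cell.Wx))
                out.append((f"l{lvl}{d}.Wh", cell.Wh))
        out.append(("readout.W", self.W_out))
        return out

    def named_arrays(self) -> list[tuple[str, np.ndarray]]:
        """All parameter arrays (weights and biases) in deterministic order."""
        out = []
        for lvl in range(1, self.levels + 1):
            for d in self.directions():
                cell = self.cells[(lvl, d)]
                out += [
                    (f"l{lvl}{d}.Wx", cell.Wx),
                    (f"l{lvl}{d}.Wh", cell.Wh),
                    (f"l{lvl}{d}.b", cell.b),
                ]
        out += [("readout.W", self.W_out), ("readout.b", self.b_out)]
        return out


@dataclass
class TrainConfig:
    """Supervised training protocol: Adam on mean cross-entropy + L2."""

    learning_rate: float = 2e-3
    epochs: int = 300
    batch_size: int = 10
    l2: float = 1e-4
    seed: int = 0
    clip_norm: float = 5.0  # global gradient-norm clip; 0 disables
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if min(self.learning_rate, self.epochs, self.batch_size) <= 0:
            raise ValueError("learning rate, epochs and batch size must be positive")
        if self.l2 < 0:
            raise ValueError("l2 coefficient must be >= 0")


@dataclass
class EvalReport:
    """Confusion matrix (rows = true) and overall / macro-averaged metrics."""

    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_percentages(self) -> dict:
        """Metrics on the 0-100 scale rounded to one decimal."""
        return {
            "overall_accuracy": round(100 * self.accuracy, 1),
            "average_precision": round(100 * self.precision, 1),
            "average_recall": round(100 * self.recall, 1),
            "f1_score": round(100 * self.f1, 1),
        }


# -- initialization --------------------------------------------------------


def init_params(
    direction: str,
    hidden: int = 38,
    input_size: int = 18,
    n_classes: int = 10,
    seed: int = 0,
    levels: int = 2,
) -> ClassifierParams:
    """Random initialization: uniform scaled by fan-in; biases zero except
    the forget gate's, set to 1 so memory is initially retained (the
    standard LSTM trainability device)."""
    if direction not in ("uni", "bi"):
        raise ValueError("direction must be 'uni' or 'bi'")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    dirs = ("f", "b") if direction == "bi" else ("f",)
    width = len(dirs)
    cells = {}
    for lvl in range(1, levels + 1):
        in_size = input_size if lvl == 1 else hidden * width
        for d in dirs:
            sx = 1.0 / np.sqrt(in_size)
            sh = 1.0 / np.sqrt(hidden)
            b = np.zeros(4 * hidden)
            b[:hidden] = 1.0  # forget-gate bias
            cells[(lvl, d)] = LSTMCellParams(
                Wx=rng.uniform(-sx, sx, size=(4 * hidden, in_size)),
                Wh=rng.uniform(-sh, sh, size=(4 * hidden, hidden)),
                b=b,
            )
    feat = hidden * width
    sf = 1.0 / np.sqrt(feat)
    return ClassifierParams(
        direction=direction,
        hidden=hidden,
        input_size=input_size,
        n_classes=n_classes,
        cells=cells,
        W_out=rng.uniform(-sf, sf, size=(n_classes, feat)),
        b_out=np.zeros(n_classes),
        levels=levels,
    )


def count_params(params: ClassifierParams) -> dict:
    """Closed-form parameter count plus a brute-force array enumeration."""
    H = params.hidden
    width = 2 if params.direction == "bi" else 1
    formula = 0
    for lvl in range(1, params.levels + 1):
        in_size = params.input_size if lvl == 1 else H * width
        formula += width * 4 * (H * (in_size + H) + H)
    feat = H * width
    formula += params.n_classes * feat + params.n_classes
    brute = sum(a.size for _, a in params.named_arrays())
    return {"formula": formula, "brute_force": brute}


# -- forward ---------------------------------------------------------------


def cell_step(
    params: LSTMCellParams, x_t: np.ndarray, prev: LSTMCellState
) -> LSTMCellState:
    """One LSTM cell update; ``x_t`` may be (input,) or (B, input)."""
    x = np.atleast_2d(np.asarray(x_t, dtype=np.float64))
    if x.shape[-1] != params.input_size:
        raise ValueError(
            f"input size mismatch: got {x.shape[-1]}, cell expects {params.input_size}"
        )
    h_prev = np.atleast_2d(prev.h)
    c_prev = np.atleast_2d(prev.c)
    h, c, _ = _cell_forward(params, x, h_prev, c_prev)
    if np.asarray(x_t).ndim == 1:
        return LSTMCellState(c=c[0], h=h[0])
    return LSTMCellState(c=c, h=h)


def _cell_forward(cell: LSTMCellParams, x, h_prev, c_prev):
    H = cell.hidden
    a = x @ cell.Wx.T + h_prev @ cell.Wh.T + cell.b
    f = _sigmoid(a[:, :H])
    i = _sigmoid(a[:, H : 2 * H])
    o = _sigmoid(a[:, 2 * H : 3 * H])
    g = np.tanh(a[:, 3 * H :])
    c = f * c_prev + g * i
    tc = np.tanh(c)
    h = o * tc
    return h, c, (x, h_prev, c_prev, f, i, o, g, c, tc)


def _layer_forward(cell: LSTMCellParams, X: np.ndarray):
    """Run one cell over a (B, T, I) batch; returns (B, T, H) and caches."""
    B, T, _ = X.shape
    H = cell.hidden
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.empty((B, T, H))
    caches = []
    for t in range(T):
        h, c, cache = _cell_forward(cell, X[:, t], h, c)
        if not np.all(np.isfinite(h)):
            raise FloatingPointError(f"non-finite activation at time step {t}")
        Hs[:, t] = h
        caches.append(cache)
    return Hs, caches


def _layer_backward(cell: LSTMCellParams, caches, dHs: np.ndarray):
    """BPTT through one cell run. ``dHs`` is dLoss/dh_t per step (B, T, H)."""
    B, T, H = dHs.shape
    dWx = np.zeros_like(cell.Wx)
    dWh = np.zeros_like(cell.Wh)
    db = np.zeros_like(cell.b)
    dX = np.empty((B, T, cell.input_size))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        x, h_prev, c_prev, f, i, o, g, c, tc = caches[t]
        dh = dHs[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc**2)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dc_next = dc * f
        da = np.concatenate(
            [
                df * f * (1.0 - f),
                di * i * (1.0 - i),
                do * o * (1.0 - o),
                dg * (1.0 - g**2),
            ],
            axis=1,
        )
        dWx += da.T @ x
        dWh += da.T @ h_prev
        db += da.sum(axis=0)
        dX[:, t] = da @ cell.Wx
        dh_next = da @ cell.Wh
    return dX, {"Wx": dWx, "Wh": dWh, "b": db}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _stack_forward(params: ClassifierParams, X: np.ndarray, want_caches=False):
    """Forward through both levels; X is (B, T, C)."""
    caches = {}
    inp = X
    for lvl in range(1, params.levels + 1):
        outs = []
        for d in params.directions():
            Xd = inp[:, ::-1] if d == "b" else inp
            Hs, cc = _layer_forward(params.cells[(lvl, d)], Xd)
            if d == "b":
                Hs = Hs[:, ::-1]  # align to original time
            outs.append(Hs)
            if want_caches:
                caches[(lvl, d)] = cc
        inp = np.concatenate(outs, axis=2) if len(outs) > 1 else outs[0]
        caches[f"h{lvl}"] = inp
    H = params.hidden
    if params.direction == "bi":
        feature = np.concatenate([inp[:, -1, :H], inp[:, 0, H:]], axis=1)
    else:
        feature = inp[:, -1]
    logits = feature @ params.W_out.T + params.b_out
    caches["feature"] = feature
    caches["logits"] = logits
    return caches


def run_stack(params: ClassifierParams, seq: np.ndarray) -> dict:
    """Run the stacked classifier on one stroke (T, C) or a batch (B, T, C).

    Returns per-time level-1/level-2 hidden features, the readout feature,
    logits, and softmax class scores.
    """
    seq = np.asarray(seq, dtype=np.float64)
    single = seq.ndim == 2
    X = seq[None] if single else seq
    if X.shape[-1] != params.input_size:
        raise ValueError(
            f"channel mismatch: got {X.shape[-1]}, model expects {params.input_size}"
        )
    cc = _stack_forward(params, X)
    out = {
        "h1": cc["h1"],
        "h2": cc["h2"],
        "feature": cc["feature"],
        "logits": cc["logits"],
        "scores": _softmax(cc["logits"]),
    }
    if single:
        out = {k: v[0] for k, v in out.items()}
    return out


# -- training --------------------------------------------------------------


def _loss_and_grads(params: ClassifierParams, X, y_onehot, l2: float):
    """Mean cross-entropy + L2 on weights; returns loss, grads, probs."""
    cc = _stack_forward(params, X, want_caches=True)
    B = X.shape[0]
    probs = _softmax(cc["logits"])
    ce = -np.mean(np.sum(y_onehot * np.log(probs + 1e-300), axis=1))
    loss = ce
    dlogits = (probs - y_onehot) / B
    dW_out = dlogits.T @ cc["feature"]
    db_out = dlogits.sum(axis=0)
    dfeature = dlogits @ params.W_out

    H = params.hidden
    T = X.shape[1]
    # seed gradient w.r.t. level-2 output sequence
    dh2 = np.zeros_like(cc["h2"])
    if params.direction == "bi":
        dh2[:, -1, :H] += dfeature[:, :H]
        dh2[:, 0, H:] += dfeature[:, H:]
    else:
        dh2[:, -1] += dfeature
    grads = {}
    dinp = dh2
    for lvl in range(params.levels, 0, -1):
        dirs = params.directions()
        dX_lower = None
        for j, d in enumerate(dirs):
            dHs = dinp[:, :, j * H : (j + 1) * H]
            if d == "b":
                dHs = dHs[:, ::-1]
            dXd, g = _layer_backward(
                params.cells[(lvl, d)], cc[(lvl, d)], np.ascontiguousarray(dHs)
            )
            if d == "b":
                dXd = dXd[:, ::-1]
            dX_lower = dXd if dX_lower is None else dX_lower + dXd
            grads[(lvl, d)] = g
        dinp = dX_lower
    grads["W_out"] = dW_out
    grads["b_out"] = db_out
    if l2:
        for name, W in params.named_weights():
            loss = loss + l2 * float(np.sum(W**2))
        for lvl in range(1, params.levels + 1):
            for d in params.directions():
                cell = params.cells[(lvl, d)]
                grads[(lvl, d)]["Wx"] += 2 * l2 * cell.Wx
                grads[(lvl, d)]["Wh"] += 2 * l2 * cell.Wh
        grads["W_out"] += 2 * l2 * params.W_out
    return loss, ce, grads, probs


def _flat_grad_arrays(params: ClassifierParams, grads) -> list:
    """(array, grad) pairs in the order of named_arrays()."""
    pairs = []
    for lvl in range(1, params.levels + 1):
        for d in params.directions():
            cell = params.cells[(lvl, d)]
            g = grads[(lvl, d)]
            pairs += [(cell.Wx, g["Wx"]), (cell.Wh, g["Wh"]), (cell.b, g["b"])]
    pairs += [(params.W_out, grads["W_out"]), (params.b_out, grads["b_out"])]
    return pairs


def train_classifier(
    train: StrokeDataset,
    cfg: TrainConfig,
    arch: ClassifierParams | None = None,
    direction: str = "bi",
    hidden: int = 38,
    test: StrokeDataset | None = None,
    mask=None,
) -> tuple[ClassifierParams, dict]:
    """Train by Adam on mean cross-entropy + L2; deterministic given seed.

    ``arch`` may supply pre-initialized (e.g. pruned) parameters; otherwise
    a fresh model of the given direction/hidden size is initialized from
    ``cfg.seed``. ``mask`` is an optional PruneMask-style object with an
    ``apply(params)`` method enforced after every optimizer step.

    Returns the trained parameters and learning curves: per-epoch train
    cost/accuracy and, when a test set is given, test cost/accuracy.
    """
    X, y = train.to_arrays()
    n_classes = train.labels.n_classes
    Y = np.eye(n_classes)[y]
    params = arch if arch is not None else init_params(
        direction, hidden=hidden, input_size=X.shape[2],
        n_classes=n_classes, seed=cfg.seed,
    )
    if mask is not None:
        mask.apply(params)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 3)))
    # Adam state per parameter array
    arrays = [a for _, a in params.named_arrays()]
    m = [np.zeros_like(a) for a in arrays]
    v = [np.zeros_like(a) for a in arrays]
    step = 0
    curves = {"train_cost": [], "train_accuracy": [], "test_cost": [], "test_accuracy": []}
    Xte = Yte = None
    if test is not None and len(test):
        Xte, yte = test.to_arrays()
        Yte = np.eye(n_classes)[yte]
    N = X.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(N)
        ep_cost = 0.0
        ep_hits = 0
        for start in range(0, N, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, ce, grads, probs = _loss_and_grads(params, X[idx], Y[idx], cfg.l2)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "training diverged (cost is not finite); try a smaller "
                    "learning rate"
                )
            ep_cost += ce * len(idx)
            ep_hits += int(np.sum(np.argmax(probs, 1) == y[idx]))
            step += 1
            pairs = _flat_grad_arrays(params, grads)
            if cfg.clip_norm:
                gnorm = np.sqrt(sum(float(np.sum(g**2)) for _, g in pairs))
                if gnorm > cfg.clip_norm:
                    scale = cfg.clip_norm / gnorm
                    for _, g in pairs:
                        g *= scale
            b1, b2 = cfg.adam_beta1, cfg.adam_beta2
            lr_t = cfg.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
            for k, (a, g) in enumerate(pairs):
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g**2
                a -= lr_t * m[k] / (np.sqrt(v[k]) + cfg.adam_eps)
            if mask is not None:
                mask.apply(params)
        curves["train_cost"].append(ep_cost / N)
        curves["train_accuracy"].append(ep_hits / N)
        if Xte is not None:
            cc = _stack_forward(params, Xte)
            pte = _softmax(cc["logits"])
            curves["test_cost"].append(
                float(-np.mean(np.sum(Yte * np.log(pte + 1e-300), axis=1)))
            )
            curves["test_accuracy"].append(
                float(np.mean(np.argmax(pte, 1) == np.argmax(Yte, 1)))
            )
    return params, curves


def predict(params: ClassifierParams, dataset: StrokeDataset) -> np.ndarray:
    X, _ = dataset.to_arrays()
    cc = _stack_forward(params, X)
    return np.argmax(cc["logits"], axis=1)


def evaluate(params: ClassifierParams, test: StrokeDataset) -> EvalReport:
    """Confusion matrix plus overall accuracy and macro P/R/F1 on a test set."""
    if not len(test):
        raise ValueError("test dataset is empty")
    X, y = test.to_arrays()
    yhat = predict(params, test)
    n = test.labels.n_classes
    cm = confusion_matrix(y, yhat, labels=np.arange(n))
    present = np.unique(y)
    if len(present) < n:
        warnings.warn(
            f"{n - len(present)} class(es) absent from test set; macro averages "
            "computed over present classes only",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division inside sklearn
        prec, rec, f1, _ = precision_recall_fscore_support(
            y, yhat, labels=present, average="macro", zero_division=0
        )
    return EvalReport(
        confusion=cm,
        accuracy=float(np.trace(cm) / cm.sum()),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
    )
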