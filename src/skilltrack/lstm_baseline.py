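"""Recurrent sequence-regression baseline over (n-level, accuracy) windows.

A single LSTM layer (default 32 units) followed by a dense affine head maps a
sliding window of ``(z_t, y_t)`` pairs to the next block's ``(z, y)`` pair.
Windows are causal and never span participant boundaries, so the prediction
for block t uses only blocks before t.  Presented n-levels are standardised
by the training-set mean and standard deviation; accuracies stay on [0, 1].

The network is implemented directly in numpy (forward pass, backpropagation
through time, Adam), which keeps training fully deterministic under a seed
and carries no framework dependency; the analytic gradients are checked
against numerical differentiation in the test-suite.  Parameter counts follow
the closed forms 4u(u + d + 1) for the recurrent layer and u*o + o for the
dense head (4,480 and 66 at u=32, d=2, o=2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .emission import ParticipantSequence

__all__ = [
    "LSTMConfig",
    "WindowedDataset",
    "LSTMRegressor",
    "lstm_param_count",
    "dense_param_count",
    "make_windows",
    "build_model",
    "train_and_predict",
    "LSTMPredictor",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LSTMConfig:
    units: int = 32
    window: int = 20
    input_dim: int = 2
    output_dim: int = 2
    epochs: int = 80
    batch_size: int = 32
    learning_rate: float = 3e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.units < 1:
            raise ValueError("need at least one recurrent unit")
        if self.window < 2:
            raise ValueError("window must be at least 2")


def lstm_param_count(units: int, input_dim: int) -> int:
    """Parameters of one LSTM layer: 4 gates of (input + recurrent + bias)."""
    return 4 * units * (units + input_dim + 1)


def dense_param_count(units: int, output_dim: int) -> int:
    return units * output_dim + output_dim


@dataclass
class WindowedDataset:
    """Sliding windows of (z, y) pairs with next-step targets.

    ``index`` holds, per window, the participant id and the (0-based) block
    position of the target, so predictions can be re-aligned to sequences.
    z values in inputs and targets are standardised by ``z_mean``/``z_std``.
    """

    inputs: np.ndarray  # (n_windows, window, 2)
    targets: np.ndarray  # (n_windows, 2)
    index: list[tuple[str, int]]
    z_mean: float
    z_std: float

    def __len__(self) -> int:
        return len(self.targets)


def _zy_matrix(seq: ParticipantSequence) -> np.ndarray:
    """(T, 2) matrix of presented level and accuracy; undefined accuracy -> 0.5."""
    out = np.empty((len(seq.blocks), 2))
    for t, blk in enumerate(seq.blocks):
        out[t, 0] = blk.z
        out[t, 1] = 0.5 if blk.y_frac is None else blk.y_frac
    return out


def make_windows(
    cohort: Sequence[ParticipantSequence],
    config: LSTMConfig,
    stats: Optional[tuple[float, float]] = None,
) -> WindowedDataset:
    """Causal sliding windows; pass training ``stats`` to normalise new data."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    w = config.window
    mats = [_zy_matrix(seq) for seq in cohort]
    if stats is None:
        all_z = np.concatenate([m[:, 0] for m in mats])
        z_mean = float(all_z.mean())
        z_std = float(all_z.std()) or 1.0
    else:
        z_mean, z_std = stats
    inputs, targets, index = [], [], []
    for seq, mat in zip(cohort, mats):
        norm = mat.copy()
        norm[:, 0] = (norm[:, 0] - z_mean) / z_std
        T = len(seq.blocks)
        if T < w + 1:
            logger.info(
                "participant %s shorter than window+1 (%d blocks): no windows",
                seq.participant_id, T,
            )
            continue
        for start in range(T - w):
            inputs.append(norm[start : start + w])
            targets.append(norm[start + w])
            index.append((seq.participant_id, start + w))
    return WindowedDataset(
        inputs=np.array(inputs),
        targets=np.array(targets),
        index=index,
        z_mean=z_mean,
        z_std=z_std,
    )


class LSTMRegressor:
    """Single-layer LSTM + dense head, trained with Adam on MSE.

    Weights are stored as ``Wx (D, 4H)``, ``Wh (H, 4H)``, ``b (4H,)`` with
    gate order (input, forget, cell, output), plus the dense ``Wd (H, O)``,
    ``bd (O,)``.
    """

    def __init__(self, config: LSTMConfig):
        self.config = config
        H, D, O = config.units, config.input_dim, config.output_dim
        rng = np.random.default_rng(config.seed)
        s_in = 1.0 / np.sqrt(D + H)
        self.Wx = rng.normal(0.0, s_in, size=(D, 4 * H))
        self.Wh = rng.normal(0.0, s_in, size=(H, 4 * H))
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias: remember by default
        self.Wd = rng.normal(0.0, 1.0 / np.sqrt(H), size=(H, O))
        self.bd = np.zeros(O)
        self._adam_state = None

    # -- bookkeeping

    @property
    def param_counts(self) -> dict[str, int]:
        lstm = self.Wx.size + self.Wh.size + self.b.size
        dense = self.Wd.size + self.bd.size
        return {"lstm": lstm, "dense": dense, "total": lstm + dense}

    def _params(self):
        return [self.Wx, self.Wh, self.b, self.Wd, self.bd]

    # -- forward / backward

    @staticmethod
    def _sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    def _forward(self, X: np.ndarray):
        """X: (B, T, D) -> predictions (B, O) plus the BPTT cache."""
        B, T, _ = X.shape
        H = self.config.units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            zbar = X[:, t] @ self.Wx + h @ self.Wh + self.b
            i = self._sigmoid(zbar[:, :H])
            f = self._sigmoid(zbar[:, H : 2 * H])
            g = np.tanh(zbar[:, 2 * H : 3 * H])
            o = self._sigmoid(zbar[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((X[:, t], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        out = h @ self.Wd + self.bd
        return out, (cache, h)

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self._forward(np.asarray(X, dtype=float))
        return out

    def _backward(self, X, Y, out, ctx):
        """Gradients of the mean-squared-error loss; mirrors `_forward`."""
        cache, h_last = ctx
        B, T, _ = X.shape
        H = self.config.units
        dout = 2.0 * (out - Y) / Y.size
        gWd = h_last.T @ dout
        gbd = dout.sum(axis=0)
        dh = dout @ self.Wd.T
        dc = np.zeros_like(dh)
        gWx = np.zeros_like(self.Wx)
        gWh = np.zeros_like(self.Wh)
        gb = np.zeros_like(self.b)
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = cache[t]
            dc = dc + dh * o * (1.0 - tanh_c**2)
            do = dh * tanh_c
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            gWx += x_t.T @ dz
            gWh += h_prev.T @ dz
            gb += dz.sum(axis=0)
            dh = dz @ self.Wh.T
            dc = dc * f
        return [gWx, gWh, gb, gWd, gbd]

    def loss_and_grads(self, X: np.ndarray, Y: np.ndarray):
        out, ctx = self._forward(X)
        loss = float(np.mean((out - Y) ** 2))
        return loss, self._backward(X, Y, out, ctx)

    # -- training

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        epochs: Optional[int] = None,
        verbose: bool = False,
    ) -> list[float]:
        """Adam/MSE training; returns the per-epoch mean training loss."""
        cfg = self.config
        epochs = epochs if epochs is not None else cfg.epochs
        rng = np.random.default_rng(cfg.seed + 1)
        params = self._params()
        mom = [np.zeros_like(p) for p in params]
        vel = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        history: list[float] = []
        n = len(Y)
        bs = min(cfg.batch_size, n)
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, bs):
                idx = order[lo : lo + bs]
                loss, grads = self.loss_and_grads(X[idx], Y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError("training loss diverged (non-finite)")
                losses.append(loss)
                step += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
                for p, m, v, g in zip(params, mom, vel, grads):
                    m *= b1
                    m += (1 - b1) * g
                    v *= b2
                    v += (1 - b2) * g**2
                    p -= lr_t * m / (np.sqrt(v) + eps)
            history.append(float(np.mean(losses)))
            if verbose:
                logger.info("epoch %d: loss %.5f", epoch, history[-1])
        return history


def build_model(config: Optional[LSTMConfig] = None) -> LSTMRegressor:
    """Construct the regressor; parameter counts follow the closed forms."""
    config = config or LSTMConfig()
    model = LSTMRegressor(config)
    counts = model.param_counts
    assert counts["lstm"] == lstm_param_count(config.units, config.input_dim)
    assert counts["dense"] == dense_param_count(config.units, config.output_dim)
    return model


@dataclass
class LSTMTrainResult:
    model: LSTMRegressor
    loss_history: list[float]
    predictions: dict[str, dict[int, tuple[float, float]]]
    stats: tuple[float, float]


def train_and_predict(
    dataset: WindowedDataset, config: Optional[LSTMConfig] = None
) -> LSTMTrainResult:
    """Train on the windowed dataset and emit per-block causal predictions.

    Predictions are de-standardised back to raw n-level units and keyed by
    (participant, block position); the first ``window`` blocks of each
    participant have no prediction (insufficient history).
    """
    config = config or LSTMConfig()
    if len(dataset) == 0:
        raise ValueError("windowed dataset is empty")
    model = build_model(config)
    history = model.fit(dataset.inputs, dataset.targets)
    raw = model.predict(dataset.inputs)
    preds: dict[str, dict[int, tuple[float, float]]] = {}
    for (pid, pos), row in zip(dataset.index, raw):
        z_pred = row[0] * dataset.z_std + dataset.z_mean
        preds.setdefault(pid, {})[pos] = (float(z_pred), float(row[1]))
    return LSTMTrainResult(
        model=model,
        loss_history=history,
        predictions=preds,
        stats=(dataset.z_mean, dataset.z_std),
    )


class LSTMPredictor:
    """One-step-ahead accuracy predictions from a trained window regressor.

    Blocks with fewer than ``window`` preceding blocks get NaN (no
    prediction); the evaluation harness excludes and counts them.
    """

    def __init__(self, model: LSTMRegressor, stats: tuple[float, float]):
        self.model = model
        self.stats = stats

    def predict_sequence(self, seq: ParticipantSequence) -> np.ndarray:
        w = self.model.config.window
        z_mean, z_std = self.stats
        mat = _zy_matrix(seq)
        mat[:, 0] = (mat[:, 0] - z_mean) / z_std
        T = len(seq.blocks)
        preds = np.full(T, np.nan)
        if T < w + 1:
            return preds
        windows = np.stack([mat[s : s + w] for s in range(T - w)])
        out = self.model.predict(windows)
        preds[w:] = out[:, 1]
        return preds

    def describe(self) -> str:
        return "lstm"
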