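"""A compact Temporal Fusion Transformer for daily index forecasting.

The model follows the classic TFT recipe at small scale:

1. **Variable selection** — each input variable (past target + dynamic
   covariates) is embedded to the hidden width; a gated residual network
   (GRN) over the window-averaged inputs produces softmax weights over
   variables, giving interpretable, nonnegative selection weights that
   sum to one.
2. **LSTM encoder-decoder** — the encoder consumes the weighted embedding
   sequence; the decoder unrolls over the forecast horizon. Future
   covariates are unknown for pure forecasting, so the decoder receives
   zero input placeholders and relies on its recurrent state.
3. **Temporal attention** — scaled dot-product attention
   ``softmax(Q Kᵀ / sqrt(d_k))`` from decoder states (queries) over encoder
   states (keys/values) produces per-step context vectors and attention
   weights over past positions.
4. **Output layer** — ``ŷ_{t+τ} = W_o [h̃_{t+τ}; c_{t+τ}] + b_o``.

Training minimizes the mean squared horizon loss
``L = (1/N) Σ_n (1/τ_max) Σ_τ (y − ŷ)²`` with Adam. Gradients come from the
in-package autodiff tape (:mod:`hairsentinel.forecasting.autograd`).
A single attention head implements the printed equations; ``heads > 1``
averages per-head contexts behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..errors import ContractError, DomainError, TrainingError
from .autograd import Adam, Tensor, concatenate, elu, sigmoid, softmax, stack, tanh

__all__ = [
    "SeriesWindow",
    "ForecastResult",
    "GRNParams",
    "glu",
    "grn",
    "temporal_attention",
    "make_windows",
    "persistence_baseline",
    "TFTForecaster",
]


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def glu(a, b):
    """Gated linear unit ``a ⊗ σ(b)`` (elementwise)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ContractError(f"GLU shapes differ: {a.shape} vs {b.shape}")
    return a / (1.0 + np.exp(-b))


@dataclass
class GRNParams:
    """Weights of one gated residual network (hidden width h, io width d)."""

    W1: np.ndarray  # (d, h)
    b1: np.ndarray  # (h,)
    W2: np.ndarray  # (h, d)
    b2: np.ndarray  # (d,)
    Wg: np.ndarray  # (h, d) gate projection
    bg: np.ndarray  # (d,)

    @classmethod
    def init(cls, d: int, h: int, rng: np.random.Generator) -> "GRNParams":
        s1 = 1.0 / np.sqrt(d)
        s2 = 1.0 / np.sqrt(h)
        return cls(W1=rng.normal(0, s1, (d, h)), b1=np.zeros(h),
                   W2=rng.normal(0, s2, (h, d)), b2=np.zeros(d),
                   Wg=rng.normal(0, s2, (h, d)), bg=np.zeros(d))

    @classmethod
    def zeros(cls, d: int, h: int) -> "GRNParams":
        return cls(W1=np.zeros((d, h)), b1=np.zeros(h), W2=np.zeros((h, d)),
                   b2=np.zeros(d), Wg=np.zeros((h, d)), bg=np.zeros(d))


def _layer_norm_t(x: Tensor, eps: float = 1e-10) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * ((var + eps) ** -0.5)


def _grn_t(x: Tensor, p: Sequence[Tensor]) -> Tensor:
    """Tensor-space GRN: LayerNorm(x + GLU(W2·ELU(W1x+b1)+b2, gate))."""
    W1, b1, W2, b2, Wg, bg = p
    hidden = elu(x @ W1 + b1)
    a = hidden @ W2 + b2
    g = hidden @ Wg + bg
    return _layer_norm_t(x + a * sigmoid(g))


def grn(x, params: GRNParams):
    """Gated residual network on a plain array (vector or batch of vectors).

    With all-zero weights the gated branch vanishes and the output is
    exactly ``LayerNorm(x)``.
    """
    xt = Tensor(np.atleast_2d(np.asarray(x, dtype=float)))
    if xt.shape[1] != params.W1.shape[0]:
        raise ContractError(
            f"input width {xt.shape[1]} does not match GRN width {params.W1.shape[0]}")
    out = _grn_t(xt, [Tensor(params.W1), Tensor(params.b1), Tensor(params.W2),
                      Tensor(params.b2), Tensor(params.Wg), Tensor(params.bg)])
    return out.data[0] if np.asarray(x).ndim == 1 else out.data


def temporal_attention(queries, keys, values, d_k: int | None = None):
    """Scaled dot-product attention: rows of softmax(QKᵀ/√d_k), context = W·V."""
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    K = np.atleast_2d(np.asarray(keys, dtype=float))
    V = np.atleast_2d(np.asarray(values, dtype=float))
    if K.shape[0] == 0:
        raise ContractError("keys must be non-empty")
    if K.shape[0] != V.shape[0]:
        raise ContractError("key and value counts differ")
    if d_k is None:
        d_k = K.shape[1]
    logits = Q @ K.T / np.sqrt(d_k)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    weights = e / e.sum(axis=1, keepdims=True)
    return weights @ V, weights


# --------------------------------------------------------------------------
# windows
# --------------------------------------------------------------------------

@dataclass
class SeriesWindow:
    """One encoder/decoder training example."""

    past_covariates: np.ndarray  # (p, d)
    static: np.ndarray           # (s,)
    past_targets: np.ndarray     # (p,)
    horizon: int
    future_targets: np.ndarray | None = None  # (horizon,) when known

    def __post_init__(self) -> None:
        self.past_covariates = np.asarray(self.past_covariates, dtype=float)
        self.static = np.asarray(self.static, dtype=float)
        self.past_targets = np.asarray(self.past_targets, dtype=float)
        p = len(self.past_targets)
        if p < 1 or self.horizon < 1:
            raise DomainError("window length and horizon must be >= 1")
        if self.past_covariates.shape[0] != p:
            raise ContractError("covariates and targets must cover the same window")
        arrays = [self.past_covariates, self.static, self.past_targets]
        if self.future_targets is not None:
            self.future_targets = np.asarray(self.future_targets, dtype=float)
            if len(self.future_targets) != self.horizon:
                raise ContractError("future_targets length must equal horizon")
            arrays.append(self.future_targets)
        if any(np.isnan(a).any() for a in arrays):
            raise ContractError("window contains missing values")

    @property
    def window(self) -> int:
        return len(self.past_targets)


@dataclass
class ForecastResult:
    predictions: np.ndarray                 # (horizon,)
    attention_weights: np.ndarray           # (horizon, p), rows sum to 1
    variable_selection_weights: np.ndarray  # (d+1,), >= 0, sums to 1
    train_loss_curve: list = field(default_factory=list)


def make_windows(target: np.ndarray, covariates: np.ndarray,
                 static: np.ndarray | None = None, window: int = 30,
                 horizon: int = 14, train_fraction: float = 0.75
                 ) -> tuple[list, list]:
    """Sliding windows split by time: a window is a training example only if
    its whole forecast span ends before the split point, so no test target
    ever appears in training."""
    y = np.asarray(target, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != len(X):
        raise ContractError("target and covariates lengths differ")
    if len(y) < window + horizon:
        raise ContractError("series too short for one window")
    z = np.zeros(1) if static is None else np.asarray(static, dtype=float)
    split = int(len(y) * train_fraction)
    train, test = [], []
    for i in range(len(y) - window - horizon + 1):
        w = SeriesWindow(past_covariates=X[i:i + window], static=z,
                         past_targets=y[i:i + window], horizon=horizon,
                         future_targets=y[i + window:i + window + horizon])
        (train if i + window + horizon <= split else test).append(w)
    return train, test


def persistence_baseline(window: SeriesWindow) -> np.ndarray:
    """Naive forecaster: every horizon step repeats the last observed target."""
    if len(window.past_targets) == 0:
        raise ContractError("past_targets is empty")
    return np.full(window.horizon, window.past_targets[-1])


# --------------------------------------------------------------------------
# the forecaster
# --------------------------------------------------------------------------

class TFTForecaster:
    """Small TFT trained by Adam on the mean squared horizon loss.

    Parameters follow the published tuning: hidden size 128 and learning
    rate 3e-4 by default; heads, dropout and batch size are exposed knobs.
    Training is seed-deterministic for a fixed window ordering.
    """

    def __init__(self, hidden_size: int = 128, learning_rate: float = 3e-4,
                 epochs: int = 200, heads: int = 1, dropout: float = 0.1,
                 batch_size: int = 64, seed: int = 0):
        self.hidden_size = hidden_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.heads = heads
        self.dropout = dropout
        self.batch_size = batch_size
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"hidden_size": self.hidden_size, "learning_rate": self.learning_rate,
                "epochs": self.epochs, "heads": self.heads, "dropout": self.dropout,
                "batch_size": self.batch_size, "seed": self.seed}

    def set_params(self, **params) -> "TFTForecaster":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ContractError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ---- parameter setup ---------------------------------------------------
    def _init_params(self, d_in: int, d_static: int, rng: np.random.Generator) -> None:
        H = self.hidden_size

        def mat(shape, scale):
            return Tensor(rng.normal(0, scale, shape), requires_grad=True)

        def zeros(shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        s_in, s_h = 1.0, 1.0 / np.sqrt(H)
        p = {}
        p["var_emb_w"] = mat((d_in, H), s_in)
        p["var_emb_b"] = zeros((d_in, H))
        p["sel_grn"] = [mat((d_in, H), 1.0 / np.sqrt(d_in)), zeros(H),
                        mat((H, d_in), s_h), zeros(d_in),
                        mat((H, d_in), s_h), zeros(d_in)]
        p["static_w"] = mat((d_static, H), 1.0 / np.sqrt(max(d_static, 1)))
        p["static_b"] = zeros(H)
        for side in ("enc", "dec"):
            p[f"{side}_wx"] = mat((H, 4 * H), s_h)
            p[f"{side}_wh"] = mat((H, 4 * H), s_h)
            p[f"{side}_b"] = zeros(4 * H)
        p["attn"] = [(mat((H, H), s_h), mat((H, H), s_h), mat((H, H), s_h))
                     for _ in range(self.heads)]
        p["out_w"] = mat((2 * H, 1), 1.0 / np.sqrt(2 * H))
        p["out_b"] = zeros(1)
        self.params_ = p

    def _param_list(self) -> list:
        p = self.params_
        flat = [p["var_emb_w"], p["var_emb_b"], *p["sel_grn"], p["static_w"], p["static_b"],
                p["enc_wx"], p["enc_wh"], p["enc_b"], p["dec_wx"], p["dec_wh"], p["dec_b"],
                p["out_w"], p["out_b"]]
        for wq, wk, wv in p["attn"]:
            flat += [wq, wk, wv]
        return flat

    # ---- forward ------------------------------------------------------------
    def _lstm_step(self, x: Tensor, h: Tensor, c: Tensor, side: str):
        H = self.hidden_size
        p = self.params_
        gates = x @ p[f"{side}_wx"] + h @ p[f"{side}_wh"] + p[f"{side}_b"]
        i = sigmoid(gates[:, 0 * H:1 * H])
        f = sigmoid(gates[:, 1 * H:2 * H])
        o = sigmoid(gates[:, 2 * H:3 * H])
        g = tanh(gates[:, 3 * H:4 * H])
        c_new = f * c + i * g
        return o * tanh(c_new), c_new

    def _forward(self, U: np.ndarray, Z: np.ndarray, horizon: int,
                 drop_rng: np.random.Generator | None = None):
        """U: (B, P, D) standardized inputs; Z: (B, S) statics."""
        B, P, D = U.shape
        H = self.hidden_size
        p = self.params_
        Ut = Tensor(U)

        # per-variable embeddings: (B, P, D, H)
        E = Ut.reshape(B, P, D, 1) * p["var_emb_w"].reshape(1, 1, D, H) \
            + p["var_emb_b"].reshape(1, 1, D, H)
        # selection weights from the window-averaged inputs
        logits = _grn_t(Tensor(U.mean(axis=1)), p["sel_grn"])
        sel = softmax(logits, axis=-1)                      # (B, D)
        m = (E * sel.reshape(B, 1, D, 1)).sum(axis=2)       # (B, P, H)
        if drop_rng is not None and self.dropout > 0:
            mask = (drop_rng.random((B, P, H)) >= self.dropout) / (1 - self.dropout)
            m = m * Tensor(mask)

        h = tanh(Tensor(Z) @ p["static_w"] + p["static_b"])
        c = Tensor(np.zeros((B, H)))
        enc_states = []
        for t in range(P):
            h, c = self._lstm_step(m[:, t, :], h, c, "enc")
            enc_states.append(h)

        zero_in = Tensor(np.zeros((B, H)))
        dec_states = []
        for _ in range(horizon):
            h, c = self._lstm_step(zero_in, h, c, "dec")
            dec_states.append(h)
        Hd = stack(dec_states, axis=1)                      # (B, T, H)

        contexts, attn_list = [], []
        for wq, wk, wv in p["attn"]:
            Qs = stack([hd @ wq for hd in dec_states], axis=1)      # (B, T, H)
            K_T = stack([he @ wk for he in enc_states], axis=2)     # (B, H, P)
            V = stack([he @ wv for he in enc_states], axis=1)       # (B, P, H)
            scores = (Qs @ K_T) * (1.0 / np.sqrt(H))                # (B, T, P)
            alpha = softmax(scores, axis=-1)
            contexts.append(alpha @ V)                              # (B, T, H)
            attn_list.append(alpha)
        ctx = contexts[0]
        for extra in contexts[1:]:
            ctx = ctx + extra
        ctx = ctx * (1.0 / len(contexts))

        combined = concatenate([Hd, ctx], axis=-1)                  # (B, T, 2H)
        pred = (combined @ p["out_w"] + p["out_b"]).reshape(B, horizon)
        attn_mean = np.mean(np.stack([a.data for a in attn_list]), axis=0)
        return pred, attn_mean, sel

    # ---- fitting --------------------------------------------------------------
    def _standardize(self, w: SeriesWindow) -> tuple[np.ndarray, float]:
        """Window-relative target normalization (anchored at the last observed
        value) so trends extrapolate; covariates are standardized globally."""
        anchor = float(w.past_targets[-1])
        U = np.column_stack([
            (w.past_targets - anchor) / self.y_sd_,
            (w.past_covariates - self.x_mean_) / self.x_sd_,
        ])
        return U, anchor

    def fit(self, windows: Sequence[SeriesWindow]) -> "TFTForecaster":
        windows = list(windows)
        if not windows:
            raise ContractError("need at least one training window")
        if any(w.future_targets is None for w in windows):
            raise ContractError("training windows need future_targets")
        if self.epochs < 1:
            raise DomainError("epochs must be >= 1")

        y_all = np.concatenate([w.past_targets for w in windows])
        x_all = np.vstack([w.past_covariates for w in windows])
        self.y_sd_ = float(y_all.std()) or 1.0
        self.x_mean_ = x_all.mean(axis=0)
        self.x_sd_ = np.where(x_all.std(axis=0) == 0, 1.0, x_all.std(axis=0))

        d_in = windows[0].past_covariates.shape[1] + 1
        d_static = len(windows[0].static)
        horizon = windows[0].horizon
        rng = np.random.default_rng(self.seed)
        self._init_params(d_in, d_static, rng)
        opt = Adam(self._param_list(), lr=self.learning_rate)

        std = [self._standardize(w) for w in windows]
        U = np.stack([u for u, _ in std])
        Z = np.stack([w.static for w in windows])
        Y = np.stack([(w.future_targets - anchor) / self.y_sd_
                      for w, (_, anchor) in zip(windows, std)])

        n = len(windows)
        batch = min(self.batch_size, n)
        self.loss_curve_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, batch):
                idx = order[lo:lo + batch]
                pred, _, _ = self._forward(U[idx], Z[idx], horizon, drop_rng=rng)
                err = pred - Tensor(Y[idx])
                loss = (err * err).mean()
                if not np.isfinite(loss.data):
                    raise TrainingError(f"non-finite loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            self.loss_curve_ = self.loss_curve_ + [epoch_loss / n]
        self.horizon_ = horizon
        return self

    def predict(self, window: SeriesWindow) -> ForecastResult:
        if not hasattr(self, "params_"):
            raise ContractError("model is not fitted")
        U, anchor = self._standardize(window)
        pred, attn, sel = self._forward(U[None], window.static[None], self.horizon_,
                                        drop_rng=None)
        return ForecastResult(
            predictions=pred.data[0] * self.y_sd_ + anchor,
            attention_weights=attn[0],
            variable_selection_weights=sel.data[0],
            train_loss_curve=list(self.loss_curve_),
        )

    def score_mse(self, windows: Sequence[SeriesWindow]) -> float:
        """Mean squared horizon error over windows with known futures."""
        errs = []
        for w in windows:
            if w.future_targets is None:
                raise ContractError("window lacks future_targets")
            res = self.predict(w)
            errs.append(np.mean((res.predictions - w.future_targets) ** 2))
        return float(np.mean(errs))
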