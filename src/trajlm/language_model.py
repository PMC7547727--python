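"""Character-level LSTM language model of a discretized trajectory.

The model is a three-stage map applied at each time step t:

1. embedding:  ``x(t) = Lambda s(t)`` — a linear look-up of the one-hot
   character ``s(t)`` into a dense M-vector;
2. LSTM cell:  forget/input/output gates and candidate cell value
   ``f, i, o = sigmoid(W x + U h + b)``, ``c~ = tanh(W_c x + U_c h + b_c)``,
   ``c(t) = f * c(t-1) + i * c~``, ``h(t) = o * tanh(c(t))``;
3. output head: ``y^(t) = softmax(D_d h(t) + b_d)``, the predicted
   distribution of the next character.

Training minimizes the summed cross-entropy ``J = -sum_t ln y^(t)[s(t+1)]``
(teacher forcing).  Because the per-symbol cross-entropy of a stationary
ergodic source is bounded below by its entropy rate, the per-symbol loss
converging onto that rate is the operational signature that the model has
learned the path distribution.

Everything — forward pass, backprop through time, Adam and plain SGD — is
implemented here in NumPy.  The public surface is both functional
(``lstm_step``, ``sequence_loss``, ``train`` ...) and object-based
(``TrajectoryLM`` / ``TrajectoryLMResults`` in ``model.py``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .encoding import LabelSeries

__all__ = [
    "ModelDims", "TrainConfig", "TrajLMParams", "LSTMState",
    "embed", "lstm_step", "output_probs", "sequence_loss",
    "train", "conditional_probs", "save_params", "load_params",
]

# gate block order inside the stacked weight matrices
_GATES = ("f", "i", "o", "c")


@dataclass(frozen=True)
class ModelDims:
    """Architecture sizes: N characters, M-dim embedding, L LSTM units."""

    n_labels: int
    embed_dim: int = 8
    hidden_dim: int = 64

    def __post_init__(self) -> None:
        if min(self.n_labels, self.embed_dim, self.hidden_dim) < 1:
            raise ValueError("all dimensions must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Teacher-forced training settings.

    Windows of ``seq_len`` symbols (+1 for targets) are cut from the series
    without overlap, shuffled each epoch, and batched.  The final
    ``validation_fraction`` of the series (contiguous, never shuffled) is
    held out.  ``optimizer`` is "adaptive" (Adam) or "sgd".
    """

    seq_len: int = 100
    batch_size: int = 64
    epochs: int = 20
    learning_rate: float = 2e-3
    optimizer: str = "adaptive"
    seed: int = 0
    validation_fraction: float = 0.1
    clip_norm: float = 5.0

    def __post_init__(self) -> None:
        if self.seq_len < 2:
            raise ValueError("seq_len must be >= 2")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.optimizer not in ("adaptive", "sgd"):
            raise ValueError("optimizer must be 'adaptive' or 'sgd'")


class LSTMState(NamedTuple):
    """Hidden and cell state h(t), c(t); either (L,) or batched (B, L)."""

    hidden: np.ndarray
    cell: np.ndarray

    @classmethod
    def zeros(cls, hidden_dim: int, batch: int | None = None) -> "LSTMState":
        shape = (hidden_dim,) if batch is None else (batch, hidden_dim)
        return cls(np.zeros(shape), np.zeros(shape))


class TrajLMParams:
    """All trainable parameters.

    The four gate blocks are stored stacked — ``w_x`` is (4L, M), ``u_h`` is
    (4L, L), ``b`` is (4L,), in gate order f, i, o, c — which keeps the
    forward pass to two matrix products per step.  Per-gate views (``W_f``,
    ``U_c``, ...) are exposed as properties.
    """

    def __init__(self, dims: ModelDims, embedding, w_x, u_h, b, d_d, b_d):
        L, M, N = dims.hidden_dim, dims.embed_dim, dims.n_labels
        self.dims = dims
        self.embedding = np.asarray(embedding, dtype=float)   # (M, N)
        self.w_x = np.asarray(w_x, dtype=float)               # (4L, M)
        self.u_h = np.asarray(u_h, dtype=float)               # (4L, L)
        self.b = np.asarray(b, dtype=float)                   # (4L,)
        self.d_d = np.asarray(d_d, dtype=float)               # (N, L)
        self.b_d = np.asarray(b_d, dtype=float)               # (N,)
        expected = {
            "embedding": (M, N), "w_x": (4 * L, M), "u_h": (4 * L, L),
            "b": (4 * L,), "d_d": (N, L), "b_d": (N,),
        }
        for name, shape in expected.items():
            got = getattr(self, name).shape
            if got != shape:
                raise ValueError(f"{name}: expected shape {shape}, got {got}")

    _FIELDS = ("embedding", "w_x", "u_h", "b", "d_d", "b_d")

    def _gate(self, array_name: str, gate: str) -> np.ndarray:
        L = self.dims.hidden_dim
        k = _GATES.index(gate)
        return getattr(self, array_name)[k * L:(k + 1) * L]

    # per-gate views matching the update equations
    @property
    def W_f(self): return self._gate("w_x", "f")
    @property
    def W_i(self): return self._gate("w_x", "i")
    @property
    def W_o(self): return self._gate("w_x", "o")
    @property
    def W_c(self): return self._gate("w_x", "c")
    @property
    def U_f(self): return self._gate("u_h", "f")
    @property
    def U_i(self): return self._gate("u_h", "i")
    @property
    def U_o(self): return self._gate("u_h", "o")
    @property
    def U_c(self): return self._gate("u_h", "c")
    @property
    def b_f(self): return self._gate("b", "f")
    @property
    def b_i(self): return self._gate("b", "i")
    @property
    def b_o(self): return self._gate("b", "o")
    @property
    def b_c(self): return self._gate("b", "c")

    @classmethod
    def zeros(cls, dims: ModelDims) -> "TrajLMParams":
        L, M, N = dims.hidden_dim, dims.embed_dim, dims.n_labels
        return cls(dims, np.zeros((M, N)), np.zeros((4 * L, M)),
                   np.zeros((4 * L, L)), np.zeros(4 * L),
                   np.zeros((N, L)), np.zeros(N))

    @classmethod
    def init(cls, dims: ModelDims, rng: np.random.Generator) -> "TrajLMParams":
        """Glorot-uniform input weights, orthogonal recurrent weights,
        forget-gate bias 1 (standard LSTM initialization), small uniform
        embedding."""
        L, M, N = dims.hidden_dim, dims.embed_dim, dims.n_labels

        def glorot(shape):
            bound = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-bound, bound, size=shape)

        def orthogonal(n):
            q, r = np.linalg.qr(rng.standard_normal((n, n)))
            return q * np.sign(np.diag(r))

        u_h = np.vstack([orthogonal(L) for _ in _GATES])
        b = np.zeros(4 * L)
        b[:L] = 1.0  # forget gate open at start
        return cls(dims, rng.uniform(-0.05, 0.05, size=(M, N)),
                   glorot((4 * L, M)), u_h, b, glorot((N, L)), np.zeros(N))

    def copy(self) -> "TrajLMParams":
        return TrajLMParams(self.dims, *(getattr(self, f).copy() for f in self._FIELDS))

    def as_dict(self) -> dict[str, np.ndarray]:
        return {f: getattr(self, f) for f in self._FIELDS}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    shifted = logits - m
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


# -- elementary operations --------------------------------------------------

def embed(params: TrajLMParams, s: np.ndarray) -> np.ndarray:
    """x = Lambda s for a one-hot character s."""
    s = np.asarray(s)
    N = params.dims.n_labels
    if s.shape != (N,) or not np.all((s == 0) | (s == 1)) or s.sum() != 1:
        raise ValueError("input must be a one-hot vector of length n_labels")
    return params.embedding[:, int(np.argmax(s))].copy()


def lstm_step(params: TrajLMParams, x: np.ndarray,
              state: LSTMState) -> tuple[LSTMState, np.ndarray]:
    """One LSTM update; accepts a single (M,) input or a batch (B, M)."""
    x = np.asarray(x, dtype=float)
    h_prev, c_prev = state
    L = params.dims.hidden_dim
    if x.shape[-1] != params.dims.embed_dim or h_prev.shape[-1] != L:
        raise ValueError("input/state shape mismatch with model dimensions")
    z = x @ params.w_x.T + h_prev @ params.u_h.T + params.b
    f = _sigmoid(z[..., 0 * L:1 * L])
    i = _sigmoid(z[..., 1 * L:2 * L])
    o = _sigmoid(z[..., 2 * L:3 * L])
    c_tilde = np.tanh(z[..., 3 * L:4 * L])
    c = f * c_prev + i * c_tilde
    h = o * np.tanh(c)
    return LSTMState(h, c), h


def output_probs(params: TrajLMParams, h: np.ndarray) -> np.ndarray:
    """softmax(D_d h + b_d): predicted next-character distribution."""
    logits = np.asarray(h) @ params.d_d.T + params.b_d
    return np.exp(_log_softmax(logits))


class SequenceLoss(NamedTuple):
    total: float        # J, summed cross-entropy in nats
    per_symbol: float   # J / T, comparable to an entropy rate
    n_transitions: int  # T


def sequence_loss(params: TrajLMParams, labels,
                  initial_state: LSTMState | None = None) -> SequenceLoss:
    """Teacher-forced cross-entropy of a label sequence.

    Each symbol is fed in turn and the model's prediction is scored against
    the next symbol; the total is ``J = -sum_t ln y^(t)[s(t+1)]`` over the
    T = len - 1 transitions.
    """
    labels = np.asarray(labels.labels if isinstance(labels, LabelSeries) else labels,
                        dtype=np.int64)
    if labels.size < 2:
        raise ValueError("sequence must contain at least 2 symbols")
    inputs = labels[None, :-1]
    targets = labels[None, 1:]
    h0 = None
    if initial_state is not None:
        h0 = LSTMState(np.atleast_2d(initial_state.hidden),
                       np.atleast_2d(initial_state.cell))
    mean_loss, _ = _forward_loss(params, inputs, targets, initial_state=h0)
    T = labels.size - 1
    return SequenceLoss(total=float(mean_loss * T), per_symbol=float(mean_loss),
                        n_transitions=T)


def conditional_probs(params: TrajLMParams, context) -> np.ndarray:
    """Next-character distribution after running ``context`` from zero state."""
    context = np.asarray(
        context.labels if isinstance(context, LabelSeries) else context,
        dtype=np.int64)
    if context.size == 0:
        raise ValueError("context must contain at least one symbol")
    if context.min() < 0 or context.max() >= params.dims.n_labels:
        raise ValueError("context labels out of range for the model")
    state = LSTMState.zeros(params.dims.hidden_dim)
    x_all = params.embedding.T[context]  # (T, M)
    for x in x_all:
        state, h = lstm_step(params, x, state)
    return output_probs(params, h)


# -- batched forward / backward ---------------------------------------------

def _forward_loss(params, inputs, targets, initial_state=None, cache=None):
    """Mean per-symbol cross-entropy over a batch of windows.

    inputs, targets: (B, T) int arrays.  If ``cache`` is a dict, the
    intermediates needed for backprop are stored in it.
    """
    B, T = inputs.shape
    L = params.dims.hidden_dim
    x = params.embedding.T[inputs]  # (B, T, M)
    if initial_state is None:
        h = np.zeros((B, L))
        c = np.zeros((B, L))
    else:
        h, c = initial_state
    keep = cache is not None
    if keep:
        gates = np.empty((T, 4, B, L))  # f, i, o, c_tilde
        cells = np.empty((T, B, L))
        tanh_c = np.empty((T, B, L))
        hs = np.empty((T, B, L))
        c_prevs = np.empty((T, B, L))
    # precompute input contribution for all steps at once
    zx = x @ params.w_x.T  # (B, T, 4L)
    logps = np.empty((T, B, params.dims.n_labels)) if keep else None
    total = 0.0
    for t in range(T):
        z = zx[:, t, :] + h @ params.u_h.T + params.b
        f = _sigmoid(z[:, 0 * L:1 * L])
        i = _sigmoid(z[:, 1 * L:2 * L])
        o = _sigmoid(z[:, 2 * L:3 * L])
        c_tilde = np.tanh(z[:, 3 * L:4 * L])
        if keep:
            c_prevs[t] = c
        c = f * c + i * c_tilde
        tc = np.tanh(c)
        h = o * tc
        logits = h @ params.d_d.T + params.b_d
        logp = _log_softmax(logits)
        total += -logp[np.arange(B), targets[:, t]].sum()
        if keep:
            gates[t, 0], gates[t, 1], gates[t, 2], gates[t, 3] = f, i, o, c_tilde
            cells[t] = c
            tanh_c[t] = tc
            hs[t] = h
            logps[t] = logp
    mean_loss = total / (B * T)
    if keep:
        cache.update(x=x, gates=gates, cells=cells, tanh_c=tanh_c, hs=hs,
                     c_prevs=c_prevs, logps=logps, inputs=inputs, targets=targets)
    return mean_loss, (h, c)


def _backward(params, cache):
    """Gradients of the mean per-symbol cross-entropy; returns a dict
    matching ``params.as_dict()``."""
    x, gates, cells = cache["x"], cache["gates"], cache["cells"]
    tanh_c, hs, c_prevs = cache["tanh_c"], cache["hs"], cache["c_prevs"]
    logps, inputs, targets = cache["logps"], cache["inputs"], cache["targets"]
    B, T, M = x.shape
    L = params.dims.hidden_dim
    N = params.dims.n_labels
    scale = 1.0 / (B * T)

    grads = {f: np.zeros_like(getattr(params, f)) for f in TrajLMParams._FIELDS}
    d_h_next = np.zeros((B, L))
    d_c_next = np.zeros((B, L))
    rows = np.arange(B)
    d_x = np.empty((B, T, M))
    for t in range(T - 1, -1, -1):
        # output head
        d_logits = np.exp(logps[t])
        d_logits[rows, targets[:, t]] -= 1.0
        d_logits *= scale
        grads["d_d"] += d_logits.T @ hs[t]
        grads["b_d"] += d_logits.sum(axis=0)
        d_h = d_logits @ params.d_d + d_h_next
        # cell/gate backprop
        f, i, o, c_tilde = gates[t]
        d_o = d_h * tanh_c[t]
        d_c = d_h * o * (1.0 - tanh_c[t] ** 2) + d_c_next
        d_f = d_c * c_prevs[t]
        d_i = d_c * c_tilde
        d_ct = d_c * i
        d_z = np.concatenate([
            d_f * f * (1.0 - f),
            d_i * i * (1.0 - i),
            d_o * o * (1.0 - o),
            d_ct * (1.0 - c_tilde ** 2),
        ], axis=1)  # (B, 4L)
        h_prev = hs[t - 1] if t > 0 else np.zeros((B, L))
        grads["w_x"] += d_z.T @ x[:, t, :]
        grads["u_h"] += d_z.T @ h_prev
        grads["b"] += d_z.sum(axis=0)
        d_x[:, t, :] = d_z @ params.w_x
        d_h_next = d_z @ params.u_h
        d_c_next = d_c * f
    # scatter-add embedding gradient by input label
    np.add.at(grads["embedding"].T, inputs.ravel(),
              d_x.reshape(B * T, M))
    return grads


def _clip_global_norm(grads: dict, max_norm: float) -> None:
    total = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if total > max_norm:
        factor = max_norm / total
        for g in grads.values():
            g *= factor


class _Adam:
    def __init__(self, params: TrajLMParams, lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {f: np.zeros_like(getattr(params, f)) for f in TrajLMParams._FIELDS}
        self.v = {f: np.zeros_like(getattr(params, f)) for f in TrajLMParams._FIELDS}
        self.t = 0

    def step(self, params: TrajLMParams, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for f in TrajLMParams._FIELDS:
            g = grads[f]
            self.m[f] = b1 * self.m[f] + (1 - b1) * g
            self.v[f] = b2 * self.v[f] + (1 - b2) * g * g
            m_hat = self.m[f] / corr1
            v_hat = self.v[f] / corr2
            getattr(params, f)[...] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class _SGD:
    def __init__(self, params: TrajLMParams, lr: float):
        self.lr = lr

    def step(self, params: TrajLMParams, grads: dict) -> None:
        for f in TrajLMParams._FIELDS:
            getattr(params, f)[...] -= self.lr * grads[f]


def _windows(labels: np.ndarray, seq_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Cut non-overlapping (input, target) windows of length seq_len."""
    n_win = (labels.size - 1) // seq_len
    if n_win == 0:
        raise ValueError(
            f"series of length {labels.size} too short for seq_len {seq_len}")
    base = np.arange(n_win)[:, None] * seq_len + np.arange(seq_len)[None, :]
    return labels[base], labels[base + 1]


class TrainingDivergedError(RuntimeError):
    pass


def train(labels, dims: ModelDims, cfg: TrainConfig,
          params: TrajLMParams | None = None):
    """Fit the model by teacher-forced gradient descent.

    Returns ``(params, history)`` where history is a pandas DataFrame with
    per-epoch ``train_loss`` and ``val_loss`` (nats per symbol).
    """
    import pandas as pd

    labels = np.asarray(labels.labels if isinstance(labels, LabelSeries) else labels,
                        dtype=np.int64)
    if labels.size < cfg.seq_len + 1:
        raise ValueError("label series shorter than seq_len + 1")
    rng = np.random.default_rng(cfg.seed)
    if params is None:
        params = TrajLMParams.init(dims, rng)

    n_val = int(np.floor(cfg.validation_fraction * labels.size))
    train_labels = labels[:labels.size - n_val]
    val_labels = labels[labels.size - n_val:]
    tr_in, tr_tg = _windows(train_labels, cfg.seq_len)
    has_val = val_labels.size >= cfg.seq_len + 1
    if has_val:
        va_in, va_tg = _windows(val_labels, cfg.seq_len)

    opt = (_Adam if cfg.optimizer == "adaptive" else _SGD)(params, cfg.learning_rate)
    rows = []
    n_win = tr_in.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_win)
        epoch_loss = 0.0
        n_sym = 0
        for start in range(0, n_win, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            cache: dict = {}
            loss, _ = _forward_loss(params, tr_in[sel], tr_tg[sel], cache=cache)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}")
            grads = _backward(params, cache)
            if cfg.clip_norm:
                _clip_global_norm(grads, cfg.clip_norm)
            opt.step(params, grads)
            epoch_loss += loss * sel.size * cfg.seq_len
            n_sym += sel.size * cfg.seq_len
        val_loss = np.nan
        if has_val:
            val_loss, _ = _forward_loss(params, va_in, va_tg)
        rows.append({"epoch": epoch, "train_loss": epoch_loss / n_sym,
                     "val_loss": float(val_loss)})
    history = pd.DataFrame(rows)
    return params, history


# -- checkpointing ----------------------------------------------------------

def save_params(params: TrajLMParams, directory: str | Path,
                manifest_extra: dict | None = None) -> None:
    """Write a checkpoint directory: ``params.npz`` + ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "params.npz", **params.as_dict())
    manifest = {
        "n_labels": params.dims.n_labels,
        "embed_dim": params.dims.embed_dim,
        "hidden_dim": params.dims.hidden_dim,
        "format": "trajlm-checkpoint-v1",
        "numpy_version": np.__version__,
    }
    manifest.update(manifest_extra or {})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_params(directory: str | Path) -> tuple[TrajLMParams, dict]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    dims = ModelDims(n_labels=int(manifest["n_labels"]),
                     embed_dim=int(manifest["embed_dim"]),
                     hidden_dim=int(manifest["hidden_dim"]))
    with np.load(directory / "params.npz") as blob:
        params = TrajLMParams(dims, **{f: blob[f] for f in TrajLMParams._FIELDS})
    return params, manifest
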