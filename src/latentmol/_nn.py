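"""Minimal NumPy neural-network kernels for the recurrent translator.

Implements exactly what the seq2seq model needs — embeddings, stacked GRU
layers with sequence masking, dense layers, masked softmax cross-entropy
and Adam — with hand-derived backward passes.  All computation is float32
and vectorized over the batch; the only Python-level loop is over time
steps.

GRU convention used throughout (r = reset gate, u = update gate):

    r_t = sigmoid([x_t, h_{t-1}] @ Wg[:, :H] + bg[:H])
    u_t = sigmoid([x_t, h_{t-1}] @ Wg[:, H:] + bg[H:])
    c_t = tanh([x_t, r_t * h_{t-1}] @ Wc + bc)
    h_t = u_t * h_{t-1} + (1 - u_t) * c_t

Masked positions (padding) hold the previous hidden state.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    np.negative(x, out=out)
    with np.errstate(over="ignore"):  # saturates cleanly to 0
        np.exp(out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


# ---------------------------------------------------------------------------
# Parameter initialization
# ---------------------------------------------------------------------------

def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out)).astype(F32)


def init_gru(rng: np.random.Generator, in_dim: int, hidden: int) -> dict:
    return {
        "Wg": glorot(rng, in_dim + hidden, 2 * hidden),
        "bg": np.zeros(2 * hidden, dtype=F32),
        "Wc": glorot(rng, in_dim + hidden, hidden),
        "bc": np.zeros(hidden, dtype=F32),
    }


def init_dense(rng: np.random.Generator, in_dim: int, out_dim: int) -> dict:
    return {"W": glorot(rng, in_dim, out_dim), "b": np.zeros(out_dim, dtype=F32)}


# ---------------------------------------------------------------------------
# GRU: single cell step (used by beam search) and full-sequence fwd/bwd
# ---------------------------------------------------------------------------

def gru_cell(p: dict, xt: np.ndarray, h: np.ndarray) -> np.ndarray:
    """One GRU step for a batch: xt (B, I), h (B, H) -> new h (B, H)."""
    H = h.shape[1]
    xh = np.concatenate([xt, h], axis=1)
    g = sigmoid(xh @ p["Wg"] + p["bg"])
    r, u = g[:, :H], g[:, H:]
    xrh = np.concatenate([xt, r * h], axis=1)
    c = np.tanh(xrh @ p["Wc"] + p["bc"])
    return u * h + (1.0 - u) * c


def gru_forward(
    p: dict, x: np.ndarray, h0: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list]:
    """Run a GRU over a full sequence.

    x: (T, B, I), h0: (B, H), mask: (T, B) in {0, 1}.
    Returns (hidden sequence (T, B, H), final hidden (B, H), caches).
    """
    T, B, _ = x.shape
    H = h0.shape[1]
    hs = np.empty((T, B, H), dtype=F32)
    h = h0
    caches = []
    for t in range(T):
        xt = x[t]
        h_prev = h
        xh = np.concatenate([xt, h_prev], axis=1)
        g = sigmoid(xh @ p["Wg"] + p["bg"])
        r, u = g[:, :H], g[:, H:]
        rh = r * h_prev
        xrh = np.concatenate([xt, rh], axis=1)
        c = np.tanh(xrh @ p["Wc"] + p["bc"])
        h_new = u * h_prev + (1.0 - u) * c
        m = mask[t][:, None]
        h = m * h_new + (1.0 - m) * h_prev
        hs[t] = h
        caches.append((xt, h_prev, r, u, c, m))
    return hs, h, caches


def gru_backward(
    p: dict,
    caches: list,
    d_hs: np.ndarray | None,
    d_h_last: np.ndarray,
    grads: dict,
) -> tuple[np.ndarray, np.ndarray]:
    """Backward pass matching :func:`gru_forward`.

    d_hs: (T, B, H) gradient w.r.t. each output hidden state (or None),
    d_h_last: (B, H) gradient w.r.t. the final hidden state.
    Accumulates parameter gradients into ``grads`` and returns
    (d_x (T, B, I), d_h0 (B, H)).
    """
    T = len(caches)
    B, H = d_h_last.shape
    I = caches[0][0].shape[1]
    dWg = grads["Wg"]
    dbg = grads["bg"]
    dWc = grads["Wc"]
    dbc = grads["bc"]
    WgT = p["Wg"].T
    WcT = p["Wc"].T
    dx = np.empty((T, B, I), dtype=F32)
    dh = d_h_last.copy()
    for t in range(T - 1, -1, -1):
        xt, h_prev, r, u, c, m = caches[t]
        if d_hs is not None:
            dh += d_hs[t]
        d_new = dh * m
        dh = dh * (1.0 - m)
        du = d_new * (h_prev - c)
        dc = d_new * (1.0 - u)
        dh += d_new * u
        dac = dc * (1.0 - c * c)
        xrh = np.concatenate([xt, r * h_prev], axis=1)
        dWc += xrh.T @ dac
        dbc += dac.sum(axis=0)
        dxrh = dac @ WcT
        dxt = dxrh[:, :I].copy()
        drh = dxrh[:, I:]
        dr = drh * h_prev
        dh += drh * r
        dag = np.concatenate([dr * r * (1.0 - r), du * u * (1.0 - u)], axis=1)
        xh = np.concatenate([xt, h_prev], axis=1)
        dWg += xh.T @ dag
        dbg += dag.sum(axis=0)
        dxh = dag @ WgT
        dxt += dxh[:, :I]
        dh += dxh[:, I:]
        dx[t] = dxt
    return dx, dh


# ---------------------------------------------------------------------------
# Softmax cross-entropy over a masked token grid
# ---------------------------------------------------------------------------

def softmax_xent(
    logits: np.ndarray, targets: np.ndarray, mask: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Masked mean cross-entropy and token accuracy.

    logits: (N, V), targets: (N,), mask: (N,) in {0, 1}.
    Returns (loss, accuracy, d_logits) where both are means over unmasked
    positions and d_logits is the gradient of the mean loss.
    """
    n_valid = float(mask.sum())
    if n_valid == 0:
        return 0.0, 0.0, np.zeros_like(logits)
    shifted = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    probs = exp / exp.sum(axis=1, keepdims=True)
    idx = np.arange(len(targets))
    logp = shifted[idx, targets] - np.log(exp.sum(axis=1))
    loss = float(-(logp * mask).sum() / n_valid)
    pred = logits.argmax(axis=1)
    acc = float(((pred == targets) * mask).sum() / n_valid)
    d = probs
    d[idx, targets] -= 1.0
    d *= (mask / n_valid)[:, None]
    return loss, acc, d.astype(F32)


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    """Adam over a flat dict of parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, lr: float | None = None,
             weight_decay: float = 0.0) -> None:
        """One update; ``weight_decay`` is decoupled (AdamW-style) and
        applied to matrices only, not biases or embeddings."""
        self.t += 1
        lr = self.lr if lr is None else lr
        b1, b2 = self.beta1, self.beta2
        corr = lr * np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * (g * g)
            params[k] -= corr * m / (np.sqrt(v) + self.eps)
            if weight_decay > 0.0 and params[k].ndim == 2 and not k.startswith("emb"):
                params[k] *= F32(1.0 - lr * weight_decay)


def clip_grads(grads: dict, max_norm: float) -> float:
    """Global-norm gradient clipping; returns the pre-clip norm."""
    total = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if total > max_norm and total > 0:
        scale = F32(max_norm / total)
        for g in grads.values():
            g *= scale
    return total
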