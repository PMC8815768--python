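"""Minimal NumPy neural-network engine.

Implements exactly the pieces the model needs — embeddings, a single masked
LSTM layer, two-layer ReLU perceptrons, softmax cross-entropy and Adam — as
pure functions over parameter dictionaries, with hand-written backward passes.
Gradients are validated against finite differences in the test suite. Running
single-threaded NumPy keeps every forward/backward bit-deterministic for a
fixed seed.

Conventions: parameters live in ``dict[str, np.ndarray]``; each ``*_backward``
returns gradients keyed identically, plus gradients w.r.t. inputs where the
caller needs them. LSTM gate order is [i, f, g, o].
"""

from __future__ import annotations

import numpy as np

Params = dict[str, np.ndarray]


# ---------------------------------------------------------------- primitives
def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-s, s, size=(n_in, n_out))


# --------------------------------------------------------------------- Adam
class Adam:
    """Adam over a parameter dict; state keyed by parameter name."""

    def __init__(self, params: Params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Params) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------- embedding
def embedding_forward(W: np.ndarray, ids: np.ndarray) -> np.ndarray:
    return W[ids]


def embedding_backward(W: np.ndarray, ids: np.ndarray, dout: np.ndarray) -> np.ndarray:
    dW = np.zeros_like(W)
    np.add.at(dW, ids.ravel(), dout.reshape(-1, dout.shape[-1]))
    return dW


# --------------------------------------------------------------------- LSTM
def lstm_init(rng: np.random.Generator, d_in: int, d_hidden: int) -> Params:
    p = {
        "Wx": glorot(rng, d_in, 4 * d_hidden),
        "Wh": glorot(rng, d_hidden, 4 * d_hidden),
        "b": np.zeros(4 * d_hidden),
    }
    # forget-gate bias 1: standard stabilization for recurrent training
    p["b"][d_hidden:2 * d_hidden] = 1.0
    return p


def lstm_forward(p: Params, x: np.ndarray, mask: np.ndarray,
                 h0: np.ndarray | None = None, c0: np.ndarray | None = None):
    """Masked LSTM over a padded batch.

    x: (B, T, d_in); mask: (B, T) with 1 on real positions. Masked positions
    carry h/c through unchanged, so the final state equals the state at each
    sequence's last real token.

    Returns (hs, h_T, c_T, cache) with hs: (B, T, H).
    """
    B, T, _ = x.shape
    H = p["Wh"].shape[0]
    h = np.zeros((B, H)) if h0 is None else h0.copy()
    c = np.zeros((B, H)) if c0 is None else c0.copy()
    hs = np.empty((B, T, H))
    cache = {"x": x, "mask": mask, "steps": [], "h0": h.copy(), "c0": c.copy()}
    for t in range(T):
        m = mask[:, t][:, None]
        a = x[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
        i, f = sigmoid(a[:, :H]), sigmoid(a[:, H:2 * H])
        g, o = np.tanh(a[:, 2 * H:3 * H]), sigmoid(a[:, 3 * H:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache["steps"].append((h.copy(), c.copy(), i, f, g, o, c_new, tc, m))
        h = m * h_new + (1 - m) * h
        c = m * c_new + (1 - m) * c
        hs[:, t] = h
    return hs, h, c, cache


def lstm_backward(p: Params, cache, dhs: np.ndarray | None,
                  dh_T: np.ndarray | None = None, dc_T: np.ndarray | None = None):
    """Backprop through ``lstm_forward``.

    dhs: (B, T, H) upstream gradient on each emitted h (or None); dh_T / dc_T:
    gradient on the final state. Returns (grads, dx, dh0, dc0).
    """
    x, mask = cache["x"], cache["mask"]
    B, T, _ = x.shape
    H = p["Wh"].shape[0]
    grads = {"Wx": np.zeros_like(p["Wx"]), "Wh": np.zeros_like(p["Wh"]),
             "b": np.zeros_like(p["b"])}
    dx = np.zeros_like(x)
    dh = np.zeros((B, H)) if dh_T is None else dh_T.copy()
    dc = np.zeros((B, H)) if dc_T is None else dc_T.copy()
    for t in range(T - 1, -1, -1):
        h_prev, c_prev, i, f, g, o, c_new, tc, m = cache["steps"][t]
        if dhs is not None:
            dh = dh + dhs[:, t]
        # h_t = m*h_new + (1-m)*h_prev ; c_t likewise
        dh_new = m * dh
        dh_prev_carry = (1 - m) * dh
        dc_new = m * dc
        dc_prev_carry = (1 - m) * dc

        do = dh_new * tc
        dc_new = dc_new + dh_new * o * (1 - tc * tc)
        di = dc_new * g
        df = dc_new * c_prev
        dg = dc_new * i
        dc_prev = dc_new * f + dc_prev_carry

        da = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        grads["Wx"] += x[:, t].T @ da
        grads["Wh"] += h_prev.T @ da
        grads["b"] += da.sum(axis=0)
        dx[:, t] = da @ p["Wx"].T
        dh = da @ p["Wh"].T + dh_prev_carry
        dc = dc_prev
    return grads, dx, dh, dc


# ---------------------------------------------------------------- MLP (2-layer)
def mlp_init(rng: np.random.Generator, d_in: int, d_hidden: int, d_out: int) -> Params:
    return {
        "W1": glorot(rng, d_in, d_hidden),
        "b1": np.zeros(d_hidden),
        "W2": glorot(rng, d_hidden, d_out),
        "b2": np.zeros(d_out),
    }


def mlp_forward(p: Params, x: np.ndarray):
    """Two-layer ReLU perceptron. x: (B, d_in) -> (B, d_out), plus cache."""
    pre = x @ p["W1"] + p["b1"]
    hid = np.maximum(pre, 0.0)
    out = hid @ p["W2"] + p["b2"]
    return out, (x, pre, hid)


def mlp_backward(p: Params, cache, dout: np.ndarray):
    """Returns (grads, dx)."""
    x, pre, hid = cache
    grads = {
        "W2": hid.T @ dout,
        "b2": dout.sum(axis=0),
    }
    dhid = dout @ p["W2"].T
    dpre = dhid * (pre > 0)
    grads["W1"] = x.T @ dpre
    grads["b1"] = dpre.sum(axis=0)
    dx = dpre @ p["W1"].T
    return grads, dx


# -------------------------------------------------------- softmax cross-entropy
def cross_entropy(logits: np.ndarray, labels: np.ndarray,
                  weights: np.ndarray | None = None):
    """Mean softmax cross-entropy and gradient w.r.t. logits.

    logits: (N, K); labels: (N,) ints; weights: optional (N,) 0/1 mask.
    The mean is over rows with nonzero weight.
    """
    N = logits.shape[0]
    if weights is None:
        weights = np.ones(N)
    total = weights.sum()
    if total == 0:
        raise ValueError("cross_entropy: no unmasked positions")
    z = logits - logits.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(z).sum(axis=1))
    ll = z[np.arange(N), labels] - logZ
    loss = -(weights * ll).sum() / total
    p = softmax(logits)
    dlogits = p.copy()
    dlogits[np.arange(N), labels] -= 1.0
    dlogits *= (weights / total)[:, None]
    return float(loss), dlogits
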