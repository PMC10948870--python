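"""Minimal NumPy neural-network engine used by the generator and classifier.

Parameters live in a flat ``dict[str, ndarray]`` keyed ``"<layer>/<name>"``;
gradients mirror that layout.  Layers provide paired forward/backward
functions with explicit caches, and :class:`Adam` updates only the layer
prefixes it is told are trainable, which is what makes the layer-freezing
contract of transfer learning exact (frozen tensors are never touched).

Gradient correctness is pinned down by finite-difference tests rather than
autodiff.
"""

from __future__ import annotations

import numpy as np

Params = dict[str, np.ndarray]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# Embedding

def embedding_init(rng: np.random.Generator, vocab_size: int, dim: int) -> Params:
    return {"E": rng.normal(0.0, 0.1, size=(vocab_size, dim))}


def embedding_forward(params: Params, prefix: str, ids: np.ndarray) -> np.ndarray:
    return params[f"{prefix}/E"][ids]


def embedding_backward(grads: Params, prefix: str, ids: np.ndarray, dX: np.ndarray) -> None:
    np.add.at(grads[f"{prefix}/E"], ids, dX)


# ---------------------------------------------------------------------------
# GRU (reset gate applied to the previous state before its matmul)
#
#   z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)        update (keep-previous) gate
#   r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)        reset gate
#   n_t = tanh(x_t Wn + (r_t * h_{t-1}) Un + bn)   candidate state
#   h_t = z_t * h_{t-1} + (1 - z_t) * n_t

def gru_init(rng: np.random.Generator, in_dim: int, units: int) -> Params:
    return {
        "Wx": glorot(rng, (in_dim, 3 * units)),
        "Wh": glorot(rng, (units, 3 * units)),
        "b": np.zeros(3 * units),
    }


def gru_forward(params: Params, prefix: str, X: np.ndarray, h0: np.ndarray | None = None):
    """Run a GRU over (B, T, D) inputs; returns (B, T, U) states and a cache."""
    Wx, Wh, b = params[f"{prefix}/Wx"], params[f"{prefix}/Wh"], params[f"{prefix}/b"]
    B, T, _ = X.shape
    U = Wh.shape[0]
    h = np.zeros((B, U)) if h0 is None else h0
    H = np.empty((B, T, U))
    cache = []
    A_x = X @ Wx + b  # precompute input contributions for all t
    for t in range(T):
        az = A_x[:, t, :U] + h @ Wh[:, :U]
        ar = A_x[:, t, U:2 * U] + h @ Wh[:, U:2 * U]
        z = sigmoid(az)
        r = sigmoid(ar)
        rh = r * h
        n = np.tanh(A_x[:, t, 2 * U:] + rh @ Wh[:, 2 * U:])
        h_new = z * h + (1.0 - z) * n
        cache.append((h, z, r, rh, n))
        h = h_new
        H[:, t] = h
    return H, cache


def gru_step(params: Params, prefix: str, x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Single decoding step: (B, D) input and (B, U) state -> new state."""
    Wx, Wh, b = params[f"{prefix}/Wx"], params[f"{prefix}/Wh"], params[f"{prefix}/b"]
    U = Wh.shape[0]
    a = x @ Wx + b
    z = sigmoid(a[:, :U] + h @ Wh[:, :U])
    r = sigmoid(a[:, U:2 * U] + h @ Wh[:, U:2 * U])
    n = np.tanh(a[:, 2 * U:] + (r * h) @ Wh[:, 2 * U:])
    return z * h + (1.0 - z) * n


def gru_backward(params: Params, grads: Params, prefix: str, X: np.ndarray, cache, dH: np.ndarray) -> np.ndarray:
    """Backprop through time; accumulates into grads and returns dX."""
    Wx, Wh = params[f"{prefix}/Wx"], params[f"{prefix}/Wh"]
    U = Wh.shape[0]
    B, T, _ = X.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(3 * U)
    dX = np.empty_like(X)
    dh_next = np.zeros((B, U))
    for t in range(T - 1, -1, -1):
        h_prev, z, r, rh, n = cache[t]
        dh = dH[:, t] + dh_next
        dz = dh * (h_prev - n)
        dn = dh * (1.0 - z)
        dh_prev = dh * z
        dan = dn * (1.0 - n * n)
        drh = dan @ Wh[:, 2 * U:].T
        dWh[:, 2 * U:] += rh.T @ dan
        dr = drh * h_prev
        dh_prev += drh * r
        daz = dz * z * (1.0 - z)
        dar = dr * r * (1.0 - r)
        dWh[:, :U] += h_prev.T @ daz
        dWh[:, U:2 * U] += h_prev.T @ dar
        dh_prev += daz @ Wh[:, :U].T + dar @ Wh[:, U:2 * U].T
        dA = np.concatenate([daz, dar, dan], axis=1)
        dWx += X[:, t].T @ dA
        db += dA.sum(axis=0)
        dX[:, t] = dA @ Wx.T
        dh_next = dh_prev
    grads[f"{prefix}/Wx"] += dWx
    grads[f"{prefix}/Wh"] += dWh
    grads[f"{prefix}/b"] += db
    return dX


# ---------------------------------------------------------------------------
# Dense + softmax cross-entropy

def dense_init(rng: np.random.Generator, in_dim: int, out_dim: int) -> Params:
    return {"W": glorot(rng, (in_dim, out_dim)), "b": np.zeros(out_dim)}


def dense_forward(params: Params, prefix: str, X: np.ndarray) -> np.ndarray:
    return X @ params[f"{prefix}/W"] + params[f"{prefix}/b"]


def dense_backward(params: Params, grads: Params, prefix: str, X: np.ndarray, dY: np.ndarray) -> np.ndarray:
    flatX = X.reshape(-1, X.shape[-1])
    flatdY = dY.reshape(-1, dY.shape[-1])
    grads[f"{prefix}/W"] += flatX.T @ flatdY
    grads[f"{prefix}/b"] += flatdY.sum(axis=0)
    return dY @ params[f"{prefix}/W"].T


def log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    s = logits - m
    return s - np.log(np.exp(s).sum(axis=-1, keepdims=True))


def softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(logits))


def masked_softmax_xent(logits: np.ndarray, targets: np.ndarray, mask: np.ndarray):
    """Mean cross-entropy over masked positions; returns (loss, dlogits).

    logits (B, T, V), integer targets (B, T), boolean mask (B, T); padding
    positions (mask False) contribute nothing to loss or gradient.
    """
    denom = max(int(mask.sum()), 1)
    lp = log_softmax(logits)
    picked = np.take_along_axis(lp, targets[..., None], axis=-1)[..., 0]
    loss = -(picked * mask).sum() / denom
    dlogits = np.exp(lp)
    B, T, V = logits.shape
    onehot_idx = (np.arange(B)[:, None], np.arange(T)[None, :], targets)
    dlogits[onehot_idx] -= 1.0
    dlogits *= mask[..., None] / denom
    return loss, dlogits


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12):
    """Binary cross-entropy on sigmoid outputs; returns (loss, dlogit)."""
    p = np.clip(p, eps, 1.0 - eps)
    loss = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean()
    dlogit = (p - y) / len(y)  # gradient wrt pre-sigmoid logit
    return loss, dlogit


# ---------------------------------------------------------------------------
# 1-D convolution over the time axis (valid padding) and layer norm

def conv1d_init(rng: np.random.Generator, kernel: int, in_dim: int, filters: int) -> Params:
    limit = np.sqrt(6.0 / (kernel * in_dim + filters))
    return {"W": rng.uniform(-limit, limit, size=(kernel, in_dim, filters)),
            "b": np.zeros(filters)}


def conv1d_forward(params: Params, prefix: str, X: np.ndarray):
    W, b = params[f"{prefix}/W"], params[f"{prefix}/b"]
    k = W.shape[0]
    T_out = X.shape[1] - k + 1
    C = np.zeros((X.shape[0], T_out, W.shape[2]))
    for j in range(k):
        C += X[:, j:j + T_out] @ W[j]
    return C + b


def conv1d_backward(params: Params, grads: Params, prefix: str, X: np.ndarray, dC: np.ndarray) -> np.ndarray:
    W = params[f"{prefix}/W"]
    k = W.shape[0]
    T_out = dC.shape[1]
    dX = np.zeros_like(X)
    for j in range(k):
        grads[f"{prefix}/W"][j] += np.einsum("btd,btf->df", X[:, j:j + T_out], dC)
        dX[:, j:j + T_out] += dC @ W[j].T
    grads[f"{prefix}/b"] += dC.sum(axis=(0, 1))
    return dX


def layernorm_init(dim: int) -> Params:
    return {"gamma": np.ones(dim), "beta": np.zeros(dim)}


def layernorm_forward(params: Params, prefix: str, X: np.ndarray, eps: float = 1e-5):
    mu = X.mean(axis=-1, keepdims=True)
    var = X.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (X - mu) * inv
    Y = params[f"{prefix}/gamma"] * xhat + params[f"{prefix}/beta"]
    return Y, (xhat, inv)


def layernorm_backward(params: Params, grads: Params, prefix: str, cache, dY: np.ndarray) -> np.ndarray:
    xhat, inv = cache
    gamma = params[f"{prefix}/gamma"]
    grads[f"{prefix}/gamma"] += (dY * xhat).sum(axis=0)
    grads[f"{prefix}/beta"] += dY.sum(axis=0)
    d = dY.shape[-1]
    dxhat = dY * gamma
    return inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                  - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))


# ---------------------------------------------------------------------------
# Optimizer

class Adam:
    """Adam with per-layer trainability: frozen prefixes are never written."""

    def __init__(self, params: Params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Params, grads: Params, trainable_prefixes: set[str]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for key, g in grads.items():
            if key.split("/", 1)[0] not in trainable_prefixes:
                continue
            self.m[key] = self.beta1 * self.m[key] + (1.0 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1.0 - self.beta2) * g * g
            params[key] -= self.lr * (self.m[key] / b1c) / (np.sqrt(self.v[key] / b2c) + self.eps)


def zero_grads(params: Params) -> Params:
    return {k: np.zeros_like(v) for k, v in params.items()}


def clone_params(params: Params) -> Params:
    return {k: v.copy() for k, v in params.items()}
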