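"""Dilated GRU feature extractor with prototype / softmax heads.

This is a self-contained numpy implementation with hand-derived
backpropagation (verified against central finite differences in the test
suite).  The architecture:

* a stack of GRU layers in which layer ``l`` updates its hidden state from
  the state ``d_l`` steps back (dilated skip recurrence).  Dilation changes
  only the connectivity, not the parameter count, and enlarges the temporal
  receptive field exponentially with depth;
* a linear readout of the top layer's final states (one per interleaved
  chain) into a feature vector;
* either a *prototype* head — class ``k`` scores ``-gamma * ||f - m_k||^2``
  with one learned prototype ``m_k`` per class, trained with distance-based
  cross-entropy plus a pull term ``lambda * ||f - m_y||^2`` — or a plain
  *softmax* linear classification head.

GRU update (gates ``z`` update, ``r`` reset, candidate ``n``)::

    z = sigmoid(x Wxz + h Whz + bz)
    r = sigmoid(x Wxr + h Whr + br)
    n = tanh(x Wxn + (r * h) Whn + bn)
    h' = (1 - z) * h + z * n

A dilated layer is evaluated by folding the time axis: the sequence is
left-padded to a multiple of ``d`` and reshaped so the ``d`` interleaved
subsequences become extra batch rows, after which a plain GRU pass realises
exactly the skip recurrence ``h_t <- h_{t-d}``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid


class ShapeMismatchError(ValueError):
    """Inconsistent array shapes passed to the network."""


# ---------------------------------------------------------------------------
# parameter containers (plain dicts of float64 arrays keyed by name)

def init_params(input_size: int, hidden_size: int, n_layers: int,
                feature_dim: int, n_classes: int, head: str,
                rng: np.random.Generator) -> dict:
    """Uniform(-k, k) initialisation with k = 1/sqrt(hidden_size)."""
    k = 1.0 / np.sqrt(hidden_size)
    p: dict = {}
    for l in range(n_layers):
        i_sz = input_size if l == 0 else hidden_size
        p[f"l{l}_Wx"] = rng.uniform(-k, k, size=(i_sz, 3 * hidden_size))
        p[f"l{l}_Wh"] = rng.uniform(-k, k, size=(hidden_size, 3 * hidden_size))
        p[f"l{l}_b"] = np.zeros(3 * hidden_size)
    p["Wf"] = rng.uniform(-k, k, size=(hidden_size, feature_dim))
    p["bf"] = np.zeros(feature_dim)
    if head == "prototype":
        p["M"] = rng.normal(0.0, 0.1, size=(n_classes, feature_dim))
    elif head == "softmax":
        kf = 1.0 / np.sqrt(feature_dim)
        p["Wc"] = rng.uniform(-kf, kf, size=(feature_dim, n_classes))
        p["bc"] = np.zeros(n_classes)
    else:
        raise ValueError("head must be 'prototype' or 'softmax'")
    return p


def n_parameters(params: dict) -> int:
    return int(sum(v.size for v in params.values()))


# ---------------------------------------------------------------------------
# GRU cell and layer

def gru_step(x: np.ndarray, h_prev: np.ndarray, Wx: np.ndarray,
             Wh: np.ndarray, b: np.ndarray) -> np.ndarray:
    """One GRU update for a batch: x (B, I), h_prev (B, H) -> h (B, H)."""
    H = h_prev.shape[-1]
    if Wx.shape[1] != 3 * H or Wh.shape != (H, 3 * H) or x.shape[-1] != Wx.shape[0]:
        raise ShapeMismatchError("inconsistent GRU parameter shapes")
    a = x @ Wx + b
    hz = h_prev @ Wh[:, : 2 * H]
    z = sigmoid(a[..., :H] + hz[..., :H])
    r = sigmoid(a[..., H:2 * H] + hz[..., H:])
    n = np.tanh(a[..., 2 * H:] + (r * h_prev) @ Wh[:, 2 * H:])
    return (1.0 - z) * h_prev + z * n


def gru_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Run a GRU over X (B, T, I); returns outputs (B, T, H) and a cache."""
    B, T, _ = X.shape
    H = Wh.shape[0]
    dt = X.dtype
    A = X @ Wx + b                       # input contributions, all steps
    Hs = np.empty((B, T, H), dtype=dt)
    Zs = np.empty((B, T, H), dtype=dt)
    Rs = np.empty((B, T, H), dtype=dt)
    Ns = np.empty((B, T, H), dtype=dt)
    Hp = np.empty((B, T, H), dtype=dt)
    h = np.zeros((B, H), dtype=dt)
    Wh_zr, Wh_n = Wh[:, : 2 * H], Wh[:, 2 * H:]
    for t in range(T):
        hz = h @ Wh_zr
        z = sigmoid(A[:, t, :H] + hz[:, :H])
        r = sigmoid(A[:, t, H:2 * H] + hz[:, H:])
        n = np.tanh(A[:, t, 2 * H:] + (r * h) @ Wh_n)
        Hp[:, t] = h
        h = (1.0 - z) * h + z * n
        Hs[:, t], Zs[:, t], Rs[:, t], Ns[:, t] = h, z, r, n
    return Hs, (X, Zs, Rs, Ns, Hp)


def gru_backward(dY: np.ndarray, cache, Wx: np.ndarray, Wh: np.ndarray):
    """Backprop through :func:`gru_forward`.

    ``dY`` (B, T, H) is the gradient w.r.t. the output sequence.  Returns
    ``(dX, dWx, dWh, db)``.
    """
    X, Zs, Rs, Ns, Hp = cache
    B, T, H = dY.shape
    Wh_zr, Wh_n = Wh[:, : 2 * H], Wh[:, 2 * H:]
    dA = np.empty((B, T, 3 * H), dtype=dY.dtype)
    dh = np.zeros((B, H), dtype=dY.dtype)
    for t in range(T - 1, -1, -1):
        dht = dh + dY[:, t]
        z, r, n, hp = Zs[:, t], Rs[:, t], Ns[:, t], Hp[:, t]
        dz = dht * (n - hp)
        dn = dht * z
        dhp = dht * (1.0 - z)
        dnpre = dn * (1.0 - n * n)
        drh = dnpre @ Wh_n.T
        dr = drh * hp
        dhp += drh * r
        dzpre = dz * z * (1.0 - z)
        drpre = dr * r * (1.0 - r)
        dzr = np.concatenate([dzpre, drpre], axis=1)
        dhp += dzr @ Wh_zr.T
        dA[:, t, : 2 * H] = dzr
        dA[:, t, 2 * H:] = dnpre
        dh = dhp
    flat = lambda a: a.reshape(B * T, -1)
    dWx = flat(X).T @ flat(dA)
    db = dA.sum(axis=(0, 1))
    dWh = np.empty_like(Wh)
    dWh[:, : 2 * H] = flat(Hp).T @ flat(dA[..., : 2 * H])
    dWh[:, 2 * H:] = flat(Rs * Hp).T @ flat(dA[..., 2 * H:])
    dX = dA @ Wx.T
    return dX, dWx, dWh, db


# ---------------------------------------------------------------------------
# dilation folding

def _dilate(X: np.ndarray, d: int):
    """Fold (B, T, C) into (B*d, ceil(T/d), C): interleaved chains -> batch."""
    B, T, C = X.shape
    pad = (-T) % d
    if pad:
        X = np.concatenate([np.zeros((B, pad, C), dtype=X.dtype), X], axis=1)
    K = (T + pad) // d
    Xf = X.reshape(B, K, d, C).transpose(0, 2, 1, 3).reshape(B * d, K, C)
    return Xf, pad


def _undilate(Y: np.ndarray, d: int, pad: int, B: int) -> np.ndarray:
    Bd, K, C = Y.shape
    Y = Y.reshape(B, d, K, C).transpose(0, 2, 1, 3).reshape(B, K * d, C)
    return Y[:, pad:, :]


def dilated_forward(X: np.ndarray, params: dict, dilations,
                    return_cache: bool = False):
    """Run the dilated GRU stack and linear readout.

    ``X`` is (B, T, input_size).  Returns the feature matrix (B,
    feature_dim), plus caches when requested.  With all dilations equal to 1
    this is exactly a plain stacked GRU.
    """
    B, T, _ = X.shape
    if T < max(dilations):
        raise ValueError("sequence shorter than the largest dilation")
    caches = []
    cur = X
    for l, d in enumerate(dilations):
        Xf, pad = _dilate(cur, d)
        Y, cache = gru_forward(Xf, params[f"l{l}_Wx"], params[f"l{l}_Wh"],
                               params[f"l{l}_b"])
        cur = _undilate(Y, d, pad, B)
        caches.append((cache, d, pad))
    # readout: final state of each of the top layer's d interleaved chains
    d_top = dilations[-1]
    hT = cur[:, -d_top:, :].mean(axis=1)
    f = hT @ params["Wf"] + params["bf"]
    if return_cache:
        return f, (caches, hT, T)
    return f


def dilated_backward(df: np.ndarray, cache, params: dict, dilations) -> dict:
    """Backprop from feature gradients to all network parameters."""
    caches, hT, T = cache
    B = df.shape[0]
    grads = {"Wf": hT.T @ df, "bf": df.sum(axis=0)}
    dhT = df @ params["Wf"].T
    H = dhT.shape[1]
    d_top = dilations[-1]
    dY = np.zeros((B, T, H), dtype=df.dtype)
    dY[:, -d_top:, :] = dhT[:, None, :] / d_top
    for l in range(len(dilations) - 1, -1, -1):
        gcache, d, pad = caches[l]
        dYf, _ = _dilate(dY, d)
        dXf, dWx, dWh, db = gru_backward(dYf, gcache, params[f"l{l}_Wx"],
                                         params[f"l{l}_Wh"])
        grads[f"l{l}_Wx"], grads[f"l{l}_Wh"], grads[f"l{l}_b"] = dWx, dWh, db
        dY = _undilate(dXf, d, pad, B)
    grads["dX"] = dY
    return grads


# ---------------------------------------------------------------------------
# heads

def prototype_logits(f: np.ndarray, M: np.ndarray, gamma: float = 1.0):
    """Class log-scores ``-gamma * ||f - m_k||^2`` and squared distances."""
    if f.shape[-1] != M.shape[-1]:
        raise ShapeMismatchError("feature and prototype dimensions differ")
    if M.shape[0] == 0:
        raise ValueError("need at least one prototype")
    d2 = (np.sum(f ** 2, axis=-1, keepdims=True)
          - 2.0 * f @ M.T + np.sum(M ** 2, axis=-1))
    d2 = np.maximum(d2, 0.0)
    return -gamma * d2, d2


def softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def head_forward(f: np.ndarray, params: dict, head: str, gamma: float = 1.0):
    if head == "prototype":
        logits, _ = prototype_logits(f, params["M"], gamma)
    else:
        logits = f @ params["Wc"] + params["bc"]
    return softmax(logits), logits


def loss_and_grads(f: np.ndarray, y: np.ndarray, params: dict, head: str,
                   gamma: float = 1.0, lam: float = 0.01):
    """Mean loss over a batch plus gradients w.r.t. ``f`` and head params.

    Prototype head: distance-based cross-entropy plus the prototype pull
    term ``lam * ||f - m_y||^2``; with ``lam = 0`` it reduces to the
    distance-based cross-entropy alone.  Softmax head: ordinary
    cross-entropy of the linear classification layer.
    """
    B = f.shape[0]
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("labels must be non-negative class indices")
    probs, logits = head_forward(f, params, head, gamma)
    K = probs.shape[1]
    if np.any(y >= K):
        raise ValueError("label out of range")
    onehot = np.zeros_like(probs)
    onehot[np.arange(B), y] = 1.0
    ce = -np.mean(np.log(np.maximum(probs[np.arange(B), y], 1e-300)))
    dlogits = (probs - onehot) / B
    hgrads: dict = {}
    if head == "prototype":
        M = params["M"]
        diff_y = f - M[y]                             # (B, F)
        loss = ce + lam * np.mean(np.sum(diff_y ** 2, axis=1))
        # d logits_bk / d f_b = -2 gamma (f_b - m_k); rows of dlogits sum to 0
        df = 2.0 * gamma * (dlogits @ M) + (2.0 * lam / B) * diff_y
        dM = 2.0 * gamma * (dlogits.T @ f) \
            - 2.0 * gamma * dlogits.sum(axis=0)[:, None] * M
        np.add.at(dM, y, -(2.0 * lam / B) * diff_y)
        hgrads["M"] = dM
    else:
        loss = ce
        df = dlogits @ params["Wc"].T
        hgrads["Wc"] = f.T @ dlogits
        hgrads["bc"] = dlogits.sum(axis=0)
    return loss, df, hgrads


# ---------------------------------------------------------------------------
# optimiser

class Adam:
    """Adaptive moment estimation over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            if k not in params:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)
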