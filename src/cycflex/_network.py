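"""Minimal numpy neural-network engine for 50-bp sequence regression.

Topology: one-hot input → stacked (1D conv → ReLU → max pool) blocks → simple
tanh recurrent layer (last hidden state) → dropout → dense ReLU → linear
output.  Trained with Adam on MSE, manual backpropagation.  Deterministic for
a fixed seed on one platform.
"""

from __future__ import annotations

import numpy as np


def _conv_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray, K: int):
    # X: (B, L, C); W: (C*K, F)
    B, L, C = X.shape
    T = L - K + 1
    Xc = np.lib.stride_tricks.sliding_window_view(X, K, axis=1)  # (B,T,C,K)
    Xc = np.ascontiguousarray(Xc).reshape(B, T, C * K)
    return Xc @ W + b, Xc


def _conv_backward(dY, Xc, W, K, C, L):
    B, T, F = dY.shape
    M = C * K
    dW = Xc.reshape(B * T, M).T @ dY.reshape(B * T, F)
    db = dY.sum(axis=(0, 1))
    dXc = (dY @ W.T).reshape(B, T, C, K)
    dX = np.zeros((B, L, C))
    for k in range(K):
        dX[:, k:k + T, :] += dXc[:, :, :, k]
    return dX, dW, db


def _pool_forward(X: np.ndarray, pool: int):
    B, T, F = X.shape
    T2 = T // pool
    Xr = X[:, :T2 * pool].reshape(B, T2, pool, F)
    idx = Xr.argmax(axis=2)
    out = np.take_along_axis(Xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return out, idx, T


def _pool_backward(dY, idx, pool, T):
    B, T2, F = dY.shape
    dXr = np.zeros((B, T2, pool, F))
    np.put_along_axis(dXr, idx[:, :, None, :], dY[:, :, None, :], axis=2)
    dX = np.zeros((B, T, F))
    dX[:, :T2 * pool] = dXr.reshape(B, T2 * pool, F)
    return dX


class SequenceRegressor:
    """Conv/recurrent regressor over one-hot encoded fixed-length sequences."""

    def __init__(self, seq_len: int, conv_blocks, rnn_units: int,
                 dense_units: int, dropout: float, seed: int):
        self.seq_len = seq_len
        self.conv_blocks = [tuple(cb) for cb in conv_blocks]
        self.rnn_units = rnn_units
        self.dense_units = dense_units
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        C = 4
        T = seq_len
        for i, (F, K, P) in enumerate(self.conv_blocks):
            if T - K + 1 < 1:
                raise ValueError("conv kernel larger than remaining length")
            scale = np.sqrt(2.0 / (C * K))
            self.params[f"Wc{i}"] = rng.normal(0, scale, size=(C * K, F))
            self.params[f"bc{i}"] = np.zeros(F)
            T = (T - K + 1) // P
            C = F
        if T < 1:
            raise ValueError("pooling consumed the whole sequence")
        H = rnn_units
        self.params["Wx"] = rng.normal(0, np.sqrt(1.0 / C), size=(C, H))
        self.params["Wh"] = rng.normal(0, np.sqrt(1.0 / H), size=(H, H))
        self.params["bh"] = np.zeros(H)
        self.params["W1"] = rng.normal(0, np.sqrt(2.0 / H), size=(H, dense_units))
        self.params["b1"] = np.zeros(dense_units)
        self.params["W2"] = rng.normal(0, np.sqrt(2.0 / dense_units),
                                       size=(dense_units, 1))
        self.params["b2"] = np.zeros(1)

    # -- forward ------------------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False,
                drop_rng: np.random.Generator | None = None):
        """Return predictions (B,) and, when ``train``, a backprop cache."""
        cache = {"conv": []}
        A = X
        for i, (F, K, P) in enumerate(self.conv_blocks):
            Z, Xc = _conv_forward(A, self.params[f"Wc{i}"],
                                  self.params[f"bc{i}"], K)
            R = np.maximum(Z, 0.0)
            Pout, idx, T = _pool_forward(R, P)
            cache["conv"].append((Xc, Z, idx, T, A.shape))
            A = Pout
        # recurrent layer over remaining timesteps
        B, Tr, C = A.shape
        H = self.rnn_units
        hs = np.zeros((Tr + 1, B, H))
        Wx, Wh, bh = self.params["Wx"], self.params["Wh"], self.params["bh"]
        for t in range(Tr):
            hs[t + 1] = np.tanh(A[:, t] @ Wx + hs[t] @ Wh + bh)
        h = hs[-1]
        cache["rnn"] = (A, hs)
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = (drop_rng.random(h.shape) < keep) / keep
            h = h * mask
            cache["drop_mask"] = mask
        Z1 = h @ self.params["W1"] + self.params["b1"]
        A1 = np.maximum(Z1, 0.0)
        out = (A1 @ self.params["W2"] + self.params["b2"])[:, 0]
        cache.update(h=h, Z1=Z1, A1=A1)
        return (out, cache) if train else (out, None)

    # -- backward -----------------------------------------------------------

    def backward(self, dout: np.ndarray, cache) -> dict[str, np.ndarray]:
        g = {}
        A1, Z1, h = cache["A1"], cache["Z1"], cache["h"]
        dout = dout[:, None]
        g["W2"] = A1.T @ dout
        g["b2"] = dout.sum(axis=0)
        dA1 = dout @ self.params["W2"].T
        dZ1 = dA1 * (Z1 > 0)
        g["W1"] = h.T @ dZ1
        g["b1"] = dZ1.sum(axis=0)
        dh = dZ1 @ self.params["W1"].T
        if "drop_mask" in cache:
            dh = dh * cache["drop_mask"]

        A, hs = cache["rnn"]
        B, Tr, C = A.shape
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        g["Wx"] = np.zeros_like(Wx)
        g["Wh"] = np.zeros_like(Wh)
        g["bh"] = np.zeros_like(self.params["bh"])
        dA = np.zeros_like(A)
        for t in range(Tr - 1, -1, -1):
            dpre = dh * (1.0 - hs[t + 1] ** 2)
            g["Wx"] += A[:, t].T @ dpre
            g["Wh"] += hs[t].T @ dpre
            g["bh"] += dpre.sum(axis=0)
            dA[:, t] = dpre @ Wx.T
            dh = dpre @ Wh.T

        dP = dA
        for i in range(len(self.conv_blocks) - 1, -1, -1):
            F, K, P = self.conv_blocks[i]
            Xc, Z, idx, T, in_shape = cache["conv"][i]
            dR = _pool_backward(dP, idx, P, T)
            dZ = dR * (Z > 0)
            dX, dW, db = _conv_backward(dZ, Xc, self.params[f"Wc{i}"], K,
                                        in_shape[2], in_shape[1])
            g[f"Wc{i}"] = dW
            g[f"bc{i}"] = db
            dP = dX
        return g

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "seq_len": self.seq_len,
            "conv_blocks": [list(cb) for cb in self.conv_blocks],
            "rnn_units": self.rnn_units,
            "dense_units": self.dense_units,
            "dropout": self.dropout,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "SequenceRegressor":
        net = cls(state["seq_len"], state["conv_blocks"], state["rnn_units"],
                  state["dense_units"], state["dropout"], seed=0)
        for k, v in state["params"].items():
            net.params[k] = np.asarray(v, dtype=np.float64)
        return net


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, gk in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * gk
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * gk ** 2
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)
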