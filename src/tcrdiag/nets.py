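"""NumPy neural networks for clonotype-frequency classification.

Three architectures, mirroring the deep-learning families of the
diagnostic benchmark:

``MLPNet``
    Feed-forward network over the raw feature vector.
``CNNNet``
    1-D convolutional network reading the feature vector as a signal over
    vocabulary rank (features are ordered by global clone frequency).
``TransformerNet``
    Self-attention encoder in which each selected clonotype is one token:
    token *j* is a learned identity embedding plus the sample's scalar
    frequency for clonotype *j* passed through a learned value projection.
    Encoder layers are post-norm (attention → residual → LayerNorm →
    feed-forward → residual → LayerNorm); the mean-pooled representation
    feeds an affine head and a sigmoidal link.

All three train with minibatch Adam on the binary cross-entropy,
use inverted dropout during training only, and are exactly reproducible
under a fixed seed.  Gradients are computed analytically; the test suite
verifies them against central finite differences.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _bce_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy with logits and its gradient d/dlogits."""
    p = _sigmoid(logits)
    # softplus(z) - y z, computed stably
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    return loss, (p - y) / len(y)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: Mapping[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _NumpyNet:
    """Shared fit/predict loop; subclasses define parameters and
    forward/backward."""

    def __init__(self, lr: float, epochs: int, batch_size: int, dropout: float,
                 seed: int):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        self.lr = float(lr)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.dropout = float(dropout)
        self.seed = int(seed)
        self.params: dict[str, np.ndarray] = {}
        self._built = False

    # subclass API ---------------------------------------------------------
    def _build(self, n_features: int, rng: np.random.Generator) -> None:
        raise NotImplementedError

    def _forward(self, X: np.ndarray, train: bool,
                 rng: np.random.Generator | None) -> tuple[np.ndarray, dict]:
        """Return (logits, cache)."""
        raise NotImplementedError

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        raise NotImplementedError

    # ----------------------------------------------------------------------
    def _dropout_mask(self, shape, rng: np.random.Generator) -> np.ndarray:
        if self.dropout == 0.0:
            return np.ones(shape)
        return (rng.random(shape) >= self.dropout) / (1.0 - self.dropout)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_NumpyNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.isnan(X).any():
            raise ValueError("nan in input")
        rng = np.random.default_rng(self.seed)
        if not self._built:
            self._build(X.shape[1], rng)
            self._built = True
        opt = _Adam(self.params, self.lr)
        n = len(X)
        bs = min(self.batch_size, n)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                logits, cache = self._forward(X[idx], train=True, rng=rng)
                _, dlogits = _bce_grad(logits, y[idx])
                grads = self._backward(dlogits, cache)
                opt.step(self.params, grads)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("nan in input")
        if not self._built:
            raise RuntimeError("model is not fitted")
        logits, _ = self._forward(X, train=False, rng=None)
        return logits

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])


# ---------------------------------------------------------------------------
class MLPNet(_NumpyNet):
    """Fully connected ReLU network with dropout after each hidden layer."""

    def __init__(self, hidden_sizes=(64,), dropout=0.1, learning_rate=1e-3,
                 epochs=60, batch_size=32, seed=0):
        super().__init__(learning_rate, epochs, batch_size, dropout, seed)
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)

    def _build(self, n_features, rng):
        sizes = (n_features, *self.hidden_sizes, 1)
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            scale = math.sqrt(2.0 / a)
            self.params[f"W{i}"] = rng.normal(0.0, scale, size=(a, b))
            self.params[f"b{i}"] = np.zeros(b)
        self.n_layers = len(sizes) - 1

    def _forward(self, X, train, rng):
        cache = {"h": [X], "mask": []}
        h = X
        for i in range(self.n_layers):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if i < self.n_layers - 1:
                h = np.maximum(z, 0.0)
                mask = self._dropout_mask(h.shape, rng) if train else 1.0
                h = h * mask
                cache["mask"].append(mask)
                cache["h"].append(h)
            else:
                h = z
        return h[:, 0], cache

    def _backward(self, dlogits, cache):
        grads = {}
        dh = dlogits[:, None]
        for i in range(self.n_layers - 1, -1, -1):
            h_in = cache["h"][i]
            grads[f"W{i}"] = h_in.T @ dh
            grads[f"b{i}"] = dh.sum(axis=0)
            if i > 0:
                dh = dh @ self.params[f"W{i}"].T
                dh = dh * cache["mask"][i - 1]
                dh = dh * (cache["h"][i] > 0)
        return grads


# ---------------------------------------------------------------------------
class CNNNet(_NumpyNet):
    """1-D convolutional network over the frequency vector.

    ``conv_layers`` valid convolutions (ReLU) followed by global max or
    average pooling over positions, dropout, and a dense head.
    """

    def __init__(self, conv_layers=1, filters=8, kernel_size=5, pooling="max",
                 dropout=0.1, learning_rate=1e-3, epochs=60, batch_size=32,
                 seed=0):
        super().__init__(learning_rate, epochs, batch_size, dropout, seed)
        if pooling not in ("max", "avg"):
            raise ValueError("pooling must be 'max' or 'avg'")
        self.conv_layers = int(conv_layers)
        self.filters = int(filters)
        self.kernel_size = int(kernel_size)
        self.pooling = pooling

    def _build(self, n_features, rng):
        if n_features < self.conv_layers * (self.kernel_size - 1) + 1:
            raise ValueError("feature vector shorter than the receptive field")
        c_in = 1
        for l in range(self.conv_layers):
            scale = math.sqrt(2.0 / (self.kernel_size * c_in))
            self.params[f"K{l}"] = rng.normal(
                0.0, scale, size=(self.kernel_size, c_in, self.filters)
            )
            self.params[f"kb{l}"] = np.zeros(self.filters)
            c_in = self.filters
        self.params["Wd"] = rng.normal(0.0, math.sqrt(1.0 / c_in), size=(c_in, 1))
        self.params["bd"] = np.zeros(1)

    @staticmethod
    def _conv_valid(A, K, b):
        # A: (B, L, Cin), K: (k, Cin, Cout) -> (B, L-k+1, Cout)
        k = K.shape[0]
        L_out = A.shape[1] - k + 1
        out = np.zeros((A.shape[0], L_out, K.shape[2]))
        for o in range(k):
            out += A[:, o : o + L_out, :] @ K[o]
        return out + b

    def _forward(self, X, train, rng):
        A = X[:, :, None]
        cache = {"acts": [A], "pre": []}
        for l in range(self.conv_layers):
            Z = self._conv_valid(A, self.params[f"K{l}"], self.params[f"kb{l}"])
            cache["pre"].append(Z)
            A = np.maximum(Z, 0.0)
            cache["acts"].append(A)
        if self.pooling == "max":
            arg = A.argmax(axis=1)
            pooled = np.take_along_axis(A, arg[:, None, :], axis=1)[:, 0, :]
            cache["arg"] = arg
        else:
            pooled = A.mean(axis=1)
        mask = self._dropout_mask(pooled.shape, rng) if train else 1.0
        pooled_d = pooled * mask
        cache["mask"] = mask
        cache["pooled_d"] = pooled_d
        logits = pooled_d @ self.params["Wd"] + self.params["bd"]
        return logits[:, 0], cache

    def _backward(self, dlogits, cache):
        grads = {}
        dlog = dlogits[:, None]
        grads["Wd"] = cache["pooled_d"].T @ dlog
        grads["bd"] = dlog.sum(axis=0)
        dpooled = (dlog @ self.params["Wd"].T) * cache["mask"]
        A_last = cache["acts"][-1]
        dA = np.zeros_like(A_last)
        if self.pooling == "max":
            B, _, C = A_last.shape
            bi = np.arange(B)[:, None]
            ci = np.arange(C)[None, :]
            dA[bi, cache["arg"], ci] = dpooled
        else:
            dA += dpooled[:, None, :] / A_last.shape[1]
        for l in range(self.conv_layers - 1, -1, -1):
            dZ = dA * (cache["pre"][l] > 0)
            A_in = cache["acts"][l]
            K = self.params[f"K{l}"]
            k = K.shape[0]
            L_out = dZ.shape[1]
            gK = np.zeros_like(K)
            dA_in = np.zeros_like(A_in)
            for o in range(k):
                gK[o] = np.einsum("blc,blf->cf", A_in[:, o : o + L_out, :], dZ)
                dA_in[:, o : o + L_out, :] += dZ @ K[o].T
            grads[f"K{l}"] = gK
            grads[f"kb{l}"] = dZ.sum(axis=(0, 1))
            dA = dA_in
        return grads


# ---------------------------------------------------------------------------
def _layernorm_forward(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_backward(dout, cache):
    xhat, inv, g = cache
    d = xhat.shape[-1]
    dg = (dout * xhat).sum(axis=tuple(range(dout.ndim - 1)))
    db = dout.sum(axis=tuple(range(dout.ndim - 1)))
    dxhat = dout * g
    dx = inv / d * (
        d * dxhat
        - dxhat.sum(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
    )
    return dx, dg, db


def _softmax(x):
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class TransformerNet(_NumpyNet):
    """Self-attention encoder over clonotype tokens.

    Each of the *m* features is one token: identity embedding plus the
    scalar frequency through a learned value projection.  ``d_model`` must
    be divisible by ``nhead``.
    """

    def __init__(self, d_model=16, nhead=2, num_layers=1, dim_feedforward=32,
                 dropout=0.1, learning_rate=3e-3, epochs=40, batch_size=32,
                 seed=0):
        super().__init__(learning_rate, epochs, batch_size, dropout, seed)
        if d_model % nhead != 0:
            raise ValueError(
                f"d_model={d_model} is not divisible by nhead={nhead}"
            )
        self.d_model = int(d_model)
        self.nhead = int(nhead)
        self.num_layers = int(num_layers)
        self.dim_feedforward = int(dim_feedforward)

    def _build(self, n_features, rng):
        d, ff = self.d_model, self.dim_feedforward
        self.n_tokens = n_features
        self.params["E"] = rng.normal(0.0, 0.02, size=(n_features, d))
        self.params["val_w"] = rng.normal(0.0, 0.5, size=(d,))
        for l in range(self.num_layers):
            for nm in ("Wq", "Wk", "Wv", "Wo"):
                self.params[f"{nm}{l}"] = rng.normal(
                    0.0, math.sqrt(1.0 / d), size=(d, d)
                )
            self.params[f"F1_{l}"] = rng.normal(0.0, math.sqrt(2.0 / d), size=(d, ff))
            self.params[f"F1b_{l}"] = np.zeros(ff)
            self.params[f"F2_{l}"] = rng.normal(0.0, math.sqrt(1.0 / ff), size=(ff, d))
            self.params[f"F2b_{l}"] = np.zeros(d)
            self.params[f"g1_{l}"] = np.ones(d)
            self.params[f"b1_{l}"] = np.zeros(d)
            self.params[f"g2_{l}"] = np.ones(d)
            self.params[f"b2_{l}"] = np.zeros(d)
        self.params["head_w"] = rng.normal(0.0, math.sqrt(1.0 / d), size=(d, 1))
        self.params["head_b"] = np.zeros(1)

    def _attention_forward(self, T, l):
        B, L, d = T.shape
        h, dh = self.nhead, self.d_model // self.nhead
        Q = T @ self.params[f"Wq{l}"]
        K = T @ self.params[f"Wk{l}"]
        V = T @ self.params[f"Wv{l}"]

        def split(M):
            return M.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

        Qh, Kh, Vh = split(Q), split(K), split(V)
        S = Qh @ Kh.transpose(0, 1, 3, 2) / math.sqrt(dh)
        P = _softmax(S)
        Ah = P @ Vh
        A = Ah.transpose(0, 2, 1, 3).reshape(B, L, d)
        out = A @ self.params[f"Wo{l}"]
        return out, (T, Qh, Kh, Vh, P, A)

    def _attention_backward(self, dout, cache, l, grads):
        T, Qh, Kh, Vh, P, A = cache
        B, L, d = T.shape
        h, dh = self.nhead, self.d_model // self.nhead
        grads[f"Wo{l}"] = A.reshape(-1, d).T @ dout.reshape(-1, d)
        dA = dout @ self.params[f"Wo{l}"].T
        dAh = dA.reshape(B, L, h, dh).transpose(0, 2, 1, 3)
        dP = dAh @ Vh.transpose(0, 1, 3, 2)
        dVh = P.transpose(0, 1, 3, 2) @ dAh
        dS = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
        dS /= math.sqrt(dh)
        dQh = dS @ Kh
        dKh = dS.transpose(0, 1, 3, 2) @ Qh

        def merge(Mh):
            return Mh.transpose(0, 2, 1, 3).reshape(B, L, d)

        dQ, dK, dV = merge(dQh), merge(dKh), merge(dVh)
        T2 = T.reshape(-1, d)
        grads[f"Wq{l}"] = T2.T @ dQ.reshape(-1, d)
        grads[f"Wk{l}"] = T2.T @ dK.reshape(-1, d)
        grads[f"Wv{l}"] = T2.T @ dV.reshape(-1, d)
        dT = (
            dQ @ self.params[f"Wq{l}"].T
            + dK @ self.params[f"Wk{l}"].T
            + dV @ self.params[f"Wv{l}"].T
        )
        return dT

    def _forward(self, X, train, rng):
        B, m = X.shape
        if m != self.n_tokens:
            raise ValueError(f"expected {self.n_tokens} features, got {m}")
        T = self.params["E"][None, :, :] + X[:, :, None] * self.params["val_w"]
        cache = {"X": X, "layers": []}
        for l in range(self.num_layers):
            att, att_cache = self._attention_forward(T, l)
            mask1 = self._dropout_mask(att.shape, rng) if train else 1.0
            res1 = T + att * mask1
            n1, ln1_cache = _layernorm_forward(
                res1, self.params[f"g1_{l}"], self.params[f"b1_{l}"]
            )
            z1 = n1 @ self.params[f"F1_{l}"] + self.params[f"F1b_{l}"]
            a1 = np.maximum(z1, 0.0)
            z2 = a1 @ self.params[f"F2_{l}"] + self.params[f"F2b_{l}"]
            mask2 = self._dropout_mask(z2.shape, rng) if train else 1.0
            res2 = n1 + z2 * mask2
            n2, ln2_cache = _layernorm_forward(
                res2, self.params[f"g2_{l}"], self.params[f"b2_{l}"]
            )
            cache["layers"].append(
                (att_cache, mask1, ln1_cache, n1, z1, a1, mask2, ln2_cache)
            )
            T = n2
        pooled = T.mean(axis=1)
        cache["T_final_shape"] = T.shape
        cache["pooled"] = pooled
        logits = pooled @ self.params["head_w"] + self.params["head_b"]
        return logits[:, 0], cache

    def _backward(self, dlogits, cache):
        grads = {}
        dlog = dlogits[:, None]
        grads["head_w"] = cache["pooled"].T @ dlog
        grads["head_b"] = dlog.sum(axis=0)
        B, L, d = cache["T_final_shape"]
        dT = np.broadcast_to(
            (dlog @ self.params["head_w"].T)[:, None, :] / L, (B, L, d)
        ).copy()
        for l in range(self.num_layers - 1, -1, -1):
            att_cache, mask1, ln1_cache, n1, z1, a1, mask2, ln2_cache = cache[
                "layers"
            ][l]
            dres2, dg2, db2 = _layernorm_backward(dT, ln2_cache)
            grads[f"g2_{l}"] = dg2
            grads[f"b2_{l}"] = db2
            dz2 = dres2 * mask2
            dn1_ff = dres2
            grads[f"F2_{l}"] = a1.reshape(-1, a1.shape[-1]).T @ dz2.reshape(-1, d)
            grads[f"F2b_{l}"] = dz2.sum(axis=(0, 1))
            da1 = dz2 @ self.params[f"F2_{l}"].T
            dz1 = da1 * (z1 > 0)
            grads[f"F1_{l}"] = n1.reshape(-1, d).T @ dz1.reshape(-1, dz1.shape[-1])
            grads[f"F1b_{l}"] = dz1.sum(axis=(0, 1))
            dn1 = dn1_ff + dz1 @ self.params[f"F1_{l}"].T
            dres1, dg1, db1 = _layernorm_backward(dn1, ln1_cache)
            grads[f"g1_{l}"] = dg1
            grads[f"b1_{l}"] = db1
            datt = dres1 * mask1
            dT = dres1 + self._attention_backward(datt, att_cache, l, grads)
        # token embedding and value projection
        grads["E"] = dT.sum(axis=0)
        grads["val_w"] = (dT * cache["X"][:, :, None]).sum(axis=(0, 1))
        return grads
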