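"""Minimal numpy neural-network core: dense/conv1d layers with Adam.

Sized for the small tabular networks this package trains (a one-hidden-layer
GAN pair and a two-convolution-layer 1-D CNN); everything is explicit
forward/backward with float64 arithmetic so results are bit-reproducible for
a fixed seed on a single CPU.
"""

from __future__ import annotations

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def drelu(x: np.ndarray) -> np.ndarray:
    return (x > 0.0).astype(x.dtype)


def leaky_relu(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x > 0.0, x, slope * x)


def dleaky_relu(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x > 0.0, 1.0, slope)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam over a list of parameter arrays, updated in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


_ACTS = {
    "relu": (relu, drelu),
    "leaky": (leaky_relu, dleaky_relu),
    "linear": (lambda x: x, lambda x: np.ones_like(x)),
}


class MLP:
    """Fully connected net with per-layer activations ('relu'/'leaky'/'linear').

    The final layer is typically 'linear'; losses that need a sigmoid or
    softmax apply it on top so gradients can be fused.
    """

    def __init__(self, sizes: list[int], activations: list[str],
                 rng: np.random.Generator):
        assert len(activations) == len(sizes) - 1
        self.activations = activations
        self.W = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._cache: list[tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.W, *self.b]

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        states = []
        h = x
        for W, b, act in zip(self.W, self.b, self.activations):
            z = h @ W + b
            if cache:
                states.append((h, z))
            h = _ACTS[act][0](z)
        if cache:
            self._cache = states
        return h

    def backward(self, grad_out: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Gradients for the last cached forward; returns (param grads, dL/dx)."""
        assert self._cache is not None, "forward(cache=True) required before backward"
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        g = grad_out
        for i in range(len(self.W) - 1, -1, -1):
            h_in, z = self._cache[i]
            g = g * _ACTS[self.activations[i]][1](z)
            gW[i] = h_in.T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return [*gW, *gb], g


class ResidualMLP(MLP):
    """MLP with an identity skip: forward(x) = x + MLP(x).

    Input and output widths must match.  With the last layer initialised near
    zero the net starts as the identity map, which suits generators whose
    latent distribution already mimics the target's marginals.
    """

    def __init__(self, sizes: list[int], activations: list[str],
                 rng: np.random.Generator, init_scale: float = 0.01):
        assert sizes[0] == sizes[-1], "residual net needs matching in/out widths"
        super().__init__(sizes, activations, rng)
        self.W[-1] *= init_scale

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        return x + super().forward(x, cache=cache)

    def backward(self, grad_out: np.ndarray):
        grads, dx = super().backward(grad_out)
        return grads, dx + grad_out


# --------------------------------------------------------------------------
# conv / pooling primitives (1-D, valid padding, ceil-mode max pool)

def conv1d_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """X (N, C_in, L), W (C_out, C_in, K) -> out (N, C_out, L-K+1) plus cache."""
    K = W.shape[2]
    win = np.lib.stride_tricks.sliding_window_view(X, K, axis=2)  # N,Cin,Lout,K
    cols = win.transpose(0, 2, 1, 3).reshape(X.shape[0], -1, W.shape[1] * K)
    out = cols @ W.reshape(W.shape[0], -1).T + b                  # N,Lout,Cout
    return out.transpose(0, 2, 1), cols


def conv1d_backward(dout: np.ndarray, cols: np.ndarray, W: np.ndarray,
                    in_shape: tuple[int, int, int]):
    """dout (N, C_out, L_out) -> (dW, db, dX)."""
    N, C_in, L = in_shape
    C_out, _, K = W.shape
    d = dout.transpose(0, 2, 1)                                    # N,Lout,Cout
    dWmat = np.einsum("nlo,nlk->ok", d, cols)
    dW = dWmat.reshape(W.shape)
    db = d.sum(axis=(0, 1))
    dcols = (d @ W.reshape(C_out, -1)).reshape(N, -1, C_in, K)     # N,Lout,Cin,K
    L_out = dcols.shape[1]
    dX = np.zeros(in_shape)
    for k in range(K):
        dX[:, :, k:k + L_out] += dcols[:, :, :, k].transpose(0, 2, 1)
    return dW, db, dX


def maxpool1d_forward(X: np.ndarray, size: int = 2):
    """Ceil-mode max pooling: a trailing partial window is kept."""
    N, C, L = X.shape
    out_len = -(-L // size)
    pad = out_len * size - L
    if pad:
        X = np.concatenate([X, np.full((N, C, pad), -np.inf)], axis=2)
    Xr = X.reshape(N, C, out_len, size)
    idx = Xr.argmax(axis=3)
    out = np.take_along_axis(Xr, idx[..., None], axis=3)[..., 0]
    return out, (idx, (N, C, L), size)


def maxpool1d_backward(dout: np.ndarray, cache) -> np.ndarray:
    idx, (N, C, L), size = cache
    out_len = dout.shape[2]
    dXr = np.zeros((N, C, out_len, size))
    np.put_along_axis(dXr, idx[..., None], dout[..., None], axis=3)
    return dXr.reshape(N, C, out_len * size)[:, :, :L]


class Conv1DNet:
    """Two conv+pool stages, a dense hidden layer and a softmax head.

    Architecture (valid padding, ceil-mode pool of size `pool`):
    input (1, m) -> conv(filters[0], k) -> ReLU -> pool
                 -> conv(filters[1], k) -> ReLU -> pool
                 -> flatten -> dense(dense_units) -> ReLU -> dense(n_classes)
    """

    MIN_LENGTH = 13

    def __init__(self, m: int, rng: np.random.Generator,
                 filters: tuple[int, int] = (20, 40), kernel_size: int = 5,
                 pool: int = 2, dense_units: int = 64, n_classes: int = 4):
        need = self.min_input_length(kernel_size, pool)
        if m < need:
            raise ValueError(
                f"input length {m} too small for two conv(k={kernel_size})+pool "
                f"stages; minimum is {need}"
            )
        self.m, self.pool = m, pool
        f1, f2 = filters
        l1 = m - kernel_size + 1
        p1 = -(-l1 // pool)
        l2 = p1 - kernel_size + 1
        p2 = -(-l2 // pool)
        flat = f2 * p2

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)

        self.W1 = he((f1, 1, kernel_size), kernel_size)
        self.b1 = np.zeros(f1)
        self.W2 = he((f2, f1, kernel_size), f1 * kernel_size)
        self.b2 = np.zeros(f2)
        self.W3 = he((flat, dense_units), flat)
        self.b3 = np.zeros(dense_units)
        self.W4 = he((dense_units, n_classes), dense_units)
        self.b4 = np.zeros(n_classes)

    @classmethod
    def min_input_length(cls, kernel_size: int = 5, pool: int = 2) -> int:
        # smallest m with >=1 position left after the second conv
        m = kernel_size
        while True:
            l1 = m - kernel_size + 1
            p1 = -(-l1 // pool)
            if p1 - kernel_size + 1 >= 1:
                return m
            m += 1

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3, self.W4, self.b4]

    def forward(self, X: np.ndarray, cache: bool = False):
        """X (N, m) -> logits (N, n_classes)."""
        x0 = X[:, None, :]
        z1, cols1 = conv1d_forward(x0, self.W1, self.b1)
        a1 = relu(z1)
        p1, pc1 = maxpool1d_forward(a1, self.pool)
        z2, cols2 = conv1d_forward(p1, self.W2, self.b2)
        a2 = relu(z2)
        p2, pc2 = maxpool1d_forward(a2, self.pool)
        flat = p2.reshape(X.shape[0], -1)
        z3 = flat @ self.W3 + self.b3
        a3 = relu(z3)
        logits = a3 @ self.W4 + self.b4
        if cache:
            self._cache = (x0, z1, cols1, p1, pc1, z2, cols2, p2, pc2, flat, z3, a3)
        return logits

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        x0, z1, cols1, p1, pc1, z2, cols2, p2, pc2, flat, z3, a3 = self._cache
        dW4 = a3.T @ dlogits
        db4 = dlogits.sum(axis=0)
        da3 = dlogits @ self.W4.T
        dz3 = da3 * drelu(z3)
        dW3 = flat.T @ dz3
        db3 = dz3.sum(axis=0)
        dflat = dz3 @ self.W3.T
        dp2 = dflat.reshape(p2.shape)
        da2 = maxpool1d_backward(dp2, pc2)
        dz2 = da2 * drelu(z2)
        dW2, db2, dp1 = conv1d_backward(dz2, cols2, self.W2, p1.shape)
        da1 = maxpool1d_backward(dp1, pc1)
        dz1 = da1 * drelu(z1)
        dW1, db1, _ = conv1d_backward(dz1, cols1, self.W1, x0.shape)
        return [dW1, db1, dW2, db2, dW3, db3, dW4, db4]
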