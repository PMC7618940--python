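"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the compute core used to train the mixture-of-modes model: a small
tape of :class:`Tensor` nodes supporting the handful of operations the model
needs (elementwise maths, matmul, softmax, an LSTM kernel with hand-derived
backpropagation-through-time, and a fused mixture-Gaussian negative
log-likelihood whose gradients are computed analytically). Gradients of every
custom kernel are validated against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "div",
    "matmul",
    "log",
    "exp",
    "tanh",
    "sigmoid",
    "softplus",
    "softmax",
    "tsum",
    "concatenate",
    "lstm",
    "build_cholesky",
    "gaussian_mixture_nll",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, n in enumerate(shape):
        if n == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, value, requires_grad: bool = False, parents=(), vjp=None):
        self.value = _as_array(value)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._vjp = vjp if self.requires_grad else None

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.value)

    def zero_grad(self):
        self.grad = None

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- backward pass -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without a gradient needs a scalar")
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                g = _unbroadcast(np.asarray(g, dtype=float), parent.value.shape)
                parent.grad = g if parent.grad is None else parent.grad + g


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise and structural operations
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return Tensor(a.value + b.value, parents=(a, b), vjp=lambda g: (g, g))


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return Tensor(
        a.value * b.value,
        parents=(a, b),
        vjp=lambda g: (g * b.value, g * a.value),
    )


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = a.value / b.value
    return Tensor(
        out,
        parents=(a, b),
        vjp=lambda g: (g / b.value, -g * a.value / b.value**2),
    )


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def vjp(g):
        ga = g @ np.swapaxes(b.value, -1, -2)
        gb = np.swapaxes(a.value, -1, -2) @ g
        return ga, gb

    return Tensor(a.value @ b.value, parents=(a, b), vjp=vjp)


def log(a) -> Tensor:
    a = _wrap(a)
    return Tensor(np.log(a.value), parents=(a,), vjp=lambda g: (g / a.value,))


def exp(a) -> Tensor:
    a = _wrap(a)
    out = np.exp(a.value)
    return Tensor(out, parents=(a,), vjp=lambda g: (g * out,))


def tanh(a) -> Tensor:
    a = _wrap(a)
    out = np.tanh(a.value)
    return Tensor(out, parents=(a,), vjp=lambda g: (g * (1.0 - out**2),))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    out = _sigmoid(a.value)
    return Tensor(out, parents=(a,), vjp=lambda g: (g * out * (1.0 - out),))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def softplus(a) -> Tensor:
    a = _wrap(a)
    return Tensor(
        _softplus(a.value), parents=(a,), vjp=lambda g: (g * _sigmoid(a.value),)
    )


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stabilised softmax along ``axis``."""
    a = _wrap(a)
    z = a.value - a.value.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - dot),)

    return Tensor(out, parents=(a,), vjp=vjp)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out = a.value.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.value.shape),)

    return Tensor(out, parents=(a,), vjp=vjp)


def getitem(a, idx) -> Tensor:
    a = _wrap(a)

    def vjp(g):
        full = np.zeros_like(a.value)
        np.add.at(full, idx, g)
        return (full,)

    return Tensor(a.value[idx], parents=(a,), vjp=vjp)


def transpose_last2(a) -> Tensor:
    a = _wrap(a)
    return Tensor(
        np.swapaxes(a.value, -1, -2),
        parents=(a,),
        vjp=lambda g: (np.swapaxes(g, -1, -2),),
    )


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.value for t in tensors], axis=axis),
        parents=tuple(tensors),
        vjp=vjp,
    )


# ---------------------------------------------------------------------------
# LSTM kernel with hand-derived BPTT
# ---------------------------------------------------------------------------


def _lstm_forward(x, W, b):
    """Run an LSTM over time. Gate order i, f, g, o; h0 = c0 = 0."""
    B, T, I = x.shape
    H = W.shape[1] // 4
    xW = x.reshape(B * T, I) @ W[:I] + b  # input contribution, all steps
    xW = xW.reshape(B, T, 4 * H)
    Wh = W[I:]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.empty((B, T, H))
    cache = []
    for t in range(T):
        zbar = xW[:, t] + h @ Wh
        i = _sigmoid(zbar[:, :H])
        f = _sigmoid(zbar[:, H : 2 * H])
        g = np.tanh(zbar[:, 2 * H : 3 * H])
        o = _sigmoid(zbar[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache.append((h, c, i, f, g, o, tc))
        h, c = h_new, c_new
        hs[:, t] = h
    return hs, cache


def _lstm_backward(dh_seq, x, W, cache):
    B, T, I = x.shape
    H = W.shape[1] // 4
    Wh = W[I:]
    dW = np.zeros_like(W)
    db = np.zeros(4 * H)
    dx = np.empty_like(x)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        h_prev, c_prev, i, f, g, o, tc = cache[t]
        dh = dh_seq[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc**2) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dW[:I] += x[:, t].T @ dz
        dW[I:] += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ W[:I].T
        dh_next = dz @ Wh.T
        dc_next = dc * f
    return dx, dW, db


def lstm(x, W, b, reverse: bool = False) -> Tensor:
    """LSTM layer over a (batch, time, features) sequence.

    ``W`` stacks input and recurrent kernels, shape (I + H, 4H); ``b`` is the
    gate bias (4H,). With ``reverse=True`` the sequence is processed from the
    last time step to the first (the backward half of a bidirectional layer);
    outputs are returned in original time order.
    """
    x, W, b = _wrap(x), _wrap(W), _wrap(b)
    xv = x.value[:, ::-1] if reverse else x.value
    hs, cache = _lstm_forward(xv, W.value, b.value)

    def vjp(g):
        gv = g[:, ::-1] if reverse else g
        dx, dW, db = _lstm_backward(gv, xv, W.value, cache)
        if reverse:
            dx = dx[:, ::-1]
        return dx, dW, db

    out = hs[:, ::-1] if reverse else hs
    return Tensor(out, parents=(x, W, b), vjp=vjp)


# ---------------------------------------------------------------------------
# Cholesky-parameterised covariances
# ---------------------------------------------------------------------------


def build_cholesky(flat, n_channels: int, epsilon: float = 1e-6) -> Tensor:
    """Fill lower-triangular Cholesky factors from flat parameter vectors.

    ``flat`` has shape (J, n(n+1)/2). The diagonal passes through a softplus
    plus ``epsilon`` so the reconstructed covariance L L' is strictly positive
    definite regardless of the raw parameter values.
    """
    flat = _wrap(flat)
    n = n_channels
    if flat.value.shape[-1] != n * (n + 1) // 2:
        raise ValueError(
            f"expected {n * (n + 1) // 2} Cholesky parameters per mode, "
            f"got {flat.value.shape[-1]}"
        )
    rows, cols = np.tril_indices(n)
    diag_mask = rows == cols
    J = flat.value.shape[0]
    L = np.zeros((J, n, n))
    vals = flat.value.copy()
    vals[:, diag_mask] = _softplus(vals[:, diag_mask]) + epsilon
    L[:, rows, cols] = vals

    def vjp(g):
        gflat = g[:, rows, cols].copy()
        gflat[:, diag_mask] *= _sigmoid(flat.value[:, diag_mask])
        return (gflat,)

    return Tensor(L, parents=(flat,), vjp=vjp)


# ---------------------------------------------------------------------------
# fused mixture-Gaussian negative log-likelihood
# ---------------------------------------------------------------------------


def gaussian_mixture_nll(x: np.ndarray, alpha, means, covs) -> Tensor:
    """Negative log-likelihood of ``x`` under N(m_t, C_t) summed over (b, t).

    The instantaneous moments are the mode mixture m_t = sum_j alpha_jt mu_j
    and C_t = sum_j alpha_jt D_j. Gradients with respect to the mixing
    coefficients, mode means and mode covariances are computed analytically
    (C is inverted once per time point and reused in the backward pass).
    """
    alpha, means, covs = _wrap(alpha), _wrap(means), _wrap(covs)
    x = np.asarray(x, dtype=float)
    a, mu, D = alpha.value, means.value, covs.value
    n = x.shape[-1]
    C = np.einsum("btj,jmn->btmn", a, D)
    sign, logdet = np.linalg.slogdet(C)
    if np.any(sign <= 0):
        bad = np.argwhere(sign <= 0)
        raise FloatingPointError(
            f"mixed covariance not positive definite at (batch, time) {bad[:5]}"
        )
    Cinv = np.linalg.inv(C)
    r = x - a @ mu
    Cr = np.einsum("btmn,btn->btm", Cinv, r)
    quad = np.einsum("btm,btm->bt", r, Cr)
    nll = 0.5 * float(np.sum(logdet + quad + n * np.log(2.0 * np.pi)))

    def vjp(g):
        g = float(g)
        dm = -g * Cr  # d nll / d m_t
        # d nll / d C_t contracted against D_j without materialising (b,t,n,n)
        tr_term = np.einsum("btmn,jmn->btj", Cinv, D)
        DCr = np.einsum("jmn,btn->btjm", D, Cr)
        quad_term = np.einsum("btjm,btm->btj", DCr, Cr)
        galpha = 0.5 * g * (tr_term - quad_term) + np.einsum("btn,jn->btj", dm, mu)
        gmeans = np.einsum("btj,btn->jn", a, dm)
        gcovs = 0.5 * g * (
            np.einsum("btj,btmn->jmn", a, Cinv)
            - np.einsum("btj,btm,btn->jmn", a, Cr, Cr)
        )
        return galpha, gmeans, gcovs

    return Tensor(nll, parents=(alpha, means, covs), vjp=vjp)
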