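"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The 3D network in this package is small (three convolution stages per
branch, a latent bottleneck and a short FC head), so instead of a large
deep-learning framework it runs on this self-contained tape: every
operation returns a :class:`Tensor` holding the forward value and a
closure that accumulates gradients into its parents. All arithmetic is
float32; the convolution inner loops are expressed as batched BLAS
matmuls so a single CPU core is enough for phantom-scale volumes.

Gradients of every op are checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import itertools

import numpy as np

DTYPE = np.float32


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> np.ndarray:
        return self.data

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad for t in tensors)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        # copy only when g aliases another array (e.g. a reshaped view)
        if isinstance(g, np.ndarray) and g.base is None and g.dtype == DTYPE:
            t.grad = g
        else:
            t.grad = np.array(g, dtype=DTYPE)
    else:
        t.grad += g


def _node(data, parents, backward) -> Tensor:
    if any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=parents, backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------------------
# convolution / pooling / resampling


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same'-padded 3D convolution.

    x: (N, Cin, D, H, W); w: (Cout, Cin, k, k, k) with odd k; b: (Cout,).
    Implemented as a sum of kernel-offset shifts, each a batched matmul,
    which keeps the work inside BLAS.
    """
    k = w.data.shape[2]
    if k % 2 != 1:
        raise ValueError(f"kernel size must be odd, got {k}")
    p = k // 2
    n, ci, d, h, wd = x.data.shape
    co = w.data.shape[0]
    offsets = list(itertools.product(range(k), repeat=3))
    nk = len(offsets)
    nv = n * d * h * wd
    # im2col in a channels-first flattened layout (Ci*k^3, N*V): the
    # whole convolution is a single BLAS gemm and the output is written
    # exactly once
    xpt = np.pad(x.data.transpose(1, 0, 2, 3, 4),
                 ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    w2 = w.data.reshape(co, ci * nk)

    def im2col() -> np.ndarray:
        cols = np.empty((ci, nk, n, d, h, wd), dtype=DTYPE)
        for o, (i, j, l) in enumerate(offsets):
            cols[:, o] = xpt[:, :, i : i + d, j : j + h, l : l + wd]
        return cols.reshape(ci * nk, nv)

    cols = im2col()
    out2 = w2 @ cols
    out2 += b.data[:, None]
    out = np.ascontiguousarray(
        out2.reshape(co, n, d, h, wd).transpose(1, 0, 2, 3, 4))
    # keep the column matrix for the weight gradient unless it is huge
    cached = cols if cols.nbytes <= 128 * 2 ** 20 else None
    del cols

    def backward(gout: np.ndarray) -> None:
        gt = np.ascontiguousarray(
            gout.transpose(1, 0, 2, 3, 4)).reshape(co, nv)
        if b.requires_grad:
            _accum(b, gt.sum(axis=1))
        if w.requires_grad:
            c = cached if cached is not None else im2col()
            _accum(w, (gt @ c.T).reshape(w.data.shape))
        if x.requires_grad:
            gcols = (w2.T @ gt).reshape(ci, nk, n, d, h, wd)
            gxpt = np.zeros_like(xpt)
            for o, (i, j, l) in enumerate(offsets):
                gxpt[:, :, i : i + d, j : j + h, l : l + wd] += gcols[:, o]
            core = gxpt[:, :, p:-p, p:-p, p:-p] if p else gxpt
            _accum(x, np.ascontiguousarray(core.transpose(1, 0, 2, 3, 4)))

    return _node(out, (x, w, b), backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2; spatial dims must be even."""
    n, c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(d, h, w)}")
    xr = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5, 7))

    def backward(gout: np.ndarray) -> None:
        oexp = out.reshape(n, c, d // 2, 1, h // 2, 1, w // 2, 1)
        mask = xr == oexp
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        gexp = gout.reshape(n, c, d // 2, 1, h // 2, 1, w // 2, 1)
        gx = (mask * (gexp / counts)).reshape(n, c, d, h, w)
        _accum(x, gx)

    return _node(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour doubling of all three spatial dims."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(gout: np.ndarray) -> None:
        n, c, d, h, w = x.data.shape
        gx = gout.reshape(n, c, d, 2, h, 2, w, 2).sum(axis=(3, 5, 7))
        _accum(x, gx)

    return _node(out, (x,), backward)


# ---------------------------------------------------------------------------
# pointwise / affine


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0)

    def backward(gout: np.ndarray) -> None:
        _accum(x, gout * (x.data > 0))

    return _node(out, (x,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x (N, F) @ w (F, O) + b (O,)."""
    out = x.data @ w.data + b.data

    def backward(gout: np.ndarray) -> None:
        if w.requires_grad:
            _accum(w, x.data.T @ gout)
        if b.requires_grad:
            _accum(b, gout.sum(axis=0))
        if x.requires_grad:
            _accum(x, gout @ w.data.T)

    return _node(out, (x, w, b), backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over all axes except the channel axis (1).

    Works for (N, C, D, H, W) maps and (N, C) features. `running_mean`
    and `running_var` are updated in place during training.
    """
    axes = (0,) + tuple(range(2, x.data.ndim))
    bshape = [1] * x.data.ndim
    bshape[1] = x.data.shape[1]
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    std = np.sqrt(var + eps).astype(DTYPE)
    xhat = (x.data - mean.reshape(bshape)) / std.reshape(bshape)
    out = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)

    def backward(gout: np.ndarray) -> None:
        if gamma.requires_grad:
            _accum(gamma, (gout * xhat).sum(axis=axes))
        if beta.requires_grad:
            _accum(beta, gout.sum(axis=axes))
        if x.requires_grad:
            g = gamma.data.reshape(bshape) / std.reshape(bshape)
            if training:
                m = gout.mean(axis=axes, keepdims=True)
                mx = (gout * xhat).mean(axis=axes, keepdims=True)
                _accum(x, g * (gout - m - xhat * mx))
            else:
                _accum(x, g * gout)

    return _node(out, (x, gamma, beta), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate == 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate).astype(DTYPE) / DTYPE(1.0 - rate)
    out = x.data * mask

    def backward(gout: np.ndarray) -> None:
        _accum(x, gout * mask)

    return _node(out, (x,), backward)


# ---------------------------------------------------------------------------
# shape plumbing


def reshape(x: Tensor, shape) -> Tensor:
    out = x.data.reshape(shape)

    def backward(gout: np.ndarray) -> None:
        _accum(x, gout.reshape(x.data.shape))

    return _node(out, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(gout: np.ndarray) -> None:
        for t, g in zip(tensors, np.split(gout, splits, axis=axis)):
            if t.requires_grad:
                _accum(t, g)

    return _node(out, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# losses and scalar algebra


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray, eps: float = 1e-12):
    """Mean cross-entropy of integer `labels` under softmax of `logits`.

    Returns (scalar loss Tensor, probability array (N, K)).
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    p_true = np.clip(probs[np.arange(n), labels], eps, 1.0)
    loss_val = -np.log(p_true).mean()

    def backward(gout: np.ndarray) -> None:
        g = probs.copy()
        g[np.arange(n), labels] -= 1.0
        _accum(logits, gout * g / n)

    return _node(np.asarray(loss_val), (logits,), backward), probs


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target."""
    target = np.asarray(target, dtype=DTYPE)
    if pred.data.shape != target.shape:
        raise ValueError(
            f"shape mismatch: {pred.data.shape} vs {target.shape}"
        )
    diff = pred.data - target
    out = np.asarray((diff ** 2).mean())

    def backward(gout: np.ndarray) -> None:
        _accum(pred, gout * 2.0 * diff / diff.size)

    return _node(out, (pred,), backward)


def weighted_sum(tensors: list[Tensor], weights: list[float]) -> Tensor:
    """Scalar combination sum_i w_i * t_i of same-shape tensors."""
    out = sum(w * t.data for t, w in zip(tensors, weights))

    def backward(gout: np.ndarray) -> None:
        for t, w in zip(tensors, weights):
            if t.requires_grad:
                _accum(t, gout * DTYPE(w))

    return _node(out, tuple(tensors), backward)
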