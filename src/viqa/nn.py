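"""Minimal reverse-mode autodiff and neural-network layers on numpy.

Everything downstream (temporal-aggregation convolution, the affine spatial
transformer, the score classifier) is built from the ops here.  The engine is
deliberately small: dense float32 tensors, a tape of backward closures, and
the handful of layers the trajectory-descriptor pipeline needs -- 2D
convolution (via im2col + BLAS matmul), max pooling, batch normalization,
fully connected layers, ReLU, bilinear grid sampling, and plain SGD.

Conventions: feature maps are ``(N, C, H, W)``; convolution is
cross-correlation (no kernel flip), stride 1 unless stated; gradients are
accumulated into ``Tensor.grad`` by :func:`backward`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "backward",
    "conv2d",
    "linear",
    "relu",
    "max_pool2d",
    "batch_norm2d",
    "grid_sample",
    "adaptive_avg_pool2d",
    "global_avg_pool2d",
    "softmax_cross_entropy",
    "Module",
    "Parameter",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "SGD",
]

_DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=_DTYPE, order="C")


class Tensor:
    """A numpy array plus the closures needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None  # callable(grad_out) -> None, set by ops
        self._parents: tuple[Tensor, ...] = ()

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic (only what the layers need) ----------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __mul__(self, other) -> "Tensor":
        if not isinstance(other, Tensor):  # scalar
            c = _DTYPE(other)
            out = Tensor(self.data * c, self.requires_grad)
            out._parents = (self,)

            def bwd_scalar(g):
                if self.requires_grad:
                    self._accumulate(g * c)

            out._backward = bwd_scalar
            return out
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        out._parents = (self,)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def mean(self) -> "Tensor":
        out = Tensor(self.data.mean(), self.requires_grad)
        out._parents = (self,)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, g / self.data.size))

        out._backward = bwd
        return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def backward(loss: Tensor) -> None:
    """Run reverse-mode accumulation from a scalar ``loss`` tensor."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, iter(loss._parents))]
    seen.add(id(loss))
    # iterative DFS (training graphs can exceed the recursion limit)
    while stack:
        node, it = stack[-1]
        advanced = False
        for p in it:
            if id(p) not in seen:
                seen.add(id(p))
                stack.append((p, iter(p._parents)))
                advanced = True
                break
        if not advanced:
            stack.pop()
            topo.append(node)
    grads: dict[int, np.ndarray] = {id(loss): np.ones_like(loss.data)}
    for node in reversed(topo):
        g = grads.pop(id(node), None)
        if g is None or node._backward is None:
            continue
        # route through per-node closures, which write into .grad of parents;
        # intermediate nodes carry their gradient in .grad transiently
        node._backward(g)
        for p in node._parents:
            if p._backward is not None and p.grad is not None:
                grads[id(p)] = grads.get(id(p), 0) + p.grad
                p.grad = None
            # leaves (parameters/inputs) keep .grad accumulated


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, ho, wo, kh, kw)
    ho, wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw
    )
    return cols, ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh, kw, stride, pad, ho, wo):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += dcols[
                :, :, :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2D cross-correlation. ``x``: (N,C,H,W); ``w``: (F,C/groups,kh,kw)."""
    n, c, h, wd = x.data.shape
    f, cg, kh, kw = w.data.shape
    if c != cg * groups:
        raise ValueError(f"channel mismatch: input {c}, weight {cg}x{groups} groups")
    if groups == 1 and c >= 4:
        # shift-and-add path: cheaper than im2col when the channel dim is
        # wide enough to amortize the per-offset tensordot
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
            if padding else x.data
        hp, wp = xp.shape[2], xp.shape[3]
        ho = (hp - kh) // stride + 1
        wo = (wp - kw) // stride + 1
        y = np.zeros((n, ho, wo, f), dtype=xp.dtype)
        for i in range(kh):
            for j in range(kw):
                sl = xp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride]
                y += np.tensordot(sl, w.data[:, :, i, j], axes=([1], [1]))
        yt = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
        if b is not None:
            yt += b.data[None, :, None, None]
        res = Tensor(yt, x.requires_grad or w.requires_grad or (b is not None and b.requires_grad))
        res._parents = (x, w) if b is None else (x, w, b)

        def bwd_shift(g):
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            gt = None
            if w.requires_grad:
                dw = np.empty_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        sl = xp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride]
                        dw[:, :, i, j] = np.tensordot(g, sl, axes=([0, 2, 3], [0, 2, 3]))
                w._accumulate(dw)
            if x.requires_grad:
                gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (N,Ho,Wo,F)
                dxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
                for i in range(kh):
                    for j in range(kw):
                        d = np.tensordot(gt, w.data[:, :, i, j], axes=([3], [0]))
                        dxp[:, :, i : i + ho * stride : stride,
                            j : j + wo * stride : stride] += d.transpose(0, 3, 1, 2)
                x._accumulate(dxp[:, :, padding : hp - padding, padding : wp - padding]
                              if padding else dxp)

        res._backward = bwd_shift
        return res
    if groups == 1:
        cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
        wm = w.data.reshape(f, -1)
        out = cols @ wm.T  # (n*ho*wo, f)
        y = np.ascontiguousarray(out.reshape(n, ho, wo, f).transpose(0, 3, 1, 2))
        if b is not None:
            y += b.data[None, :, None, None]
        res = Tensor(y, x.requires_grad or w.requires_grad or (b is not None and b.requires_grad))
        parents = (x, w) if b is None else (x, w, b)
        res._parents = parents

        def bwd(g):
            gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, f)
            if b is not None and b.requires_grad:
                b._accumulate(gm.sum(axis=0))
            if w.requires_grad:
                w._accumulate((gm.T @ cols).reshape(w.data.shape))
            if x.requires_grad:
                dcols = gm @ wm
                x._accumulate(_col2im(dcols, x.data.shape, kh, kw, stride, padding, ho, wo))

        res._backward = bwd
        return res
    # grouped convolution: run each group through the dense path on detached
    # slices, then stitch gradients back into the full tensors
    fg = f // groups
    pieces = []  # (out, x_slice, w_slice, b_slice) per group
    for gi in range(groups):
        xgi = Tensor(x.data[:, gi * cg : (gi + 1) * cg], x.requires_grad)
        wgi = Tensor(w.data[gi * fg : (gi + 1) * fg], w.requires_grad)
        bgi = None if b is None else Tensor(b.data[gi * fg : (gi + 1) * fg], b.requires_grad)
        pieces.append((conv2d(xgi, wgi, bgi, stride, padding), xgi, wgi, bgi))
    y = np.concatenate([p[0].data for p in pieces], axis=1)
    res = Tensor(y, x.requires_grad or w.requires_grad or (b is not None and b.requires_grad))
    res._parents = (x, w) if b is None else (x, w, b)

    def bwd_grouped(g):
        for gi, (o, xgi, wgi, bgi) in enumerate(pieces):
            o._backward(g[:, gi * fg : (gi + 1) * fg])
            if x.requires_grad and xgi.grad is not None:
                if x.grad is None:
                    x.grad = np.zeros_like(x.data)
                x.grad[:, gi * cg : (gi + 1) * cg] += xgi.grad
                xgi.grad = None
            if w.requires_grad and wgi.grad is not None:
                if w.grad is None:
                    w.grad = np.zeros_like(w.data)
                w.grad[gi * fg : (gi + 1) * fg] += wgi.grad
                wgi.grad = None
            if bgi is not None and b is not None and b.requires_grad and bgi.grad is not None:
                if b.grad is None:
                    b.grad = np.zeros_like(b.data)
                b.grad[gi * fg : (gi + 1) * fg] += bgi.grad
                bgi.grad = None

    res._backward = bwd_grouped
    return res


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w.T + b`` with ``x``: (N,D), ``w``: (F,D)."""
    y = x.data @ w.data.T
    if b is not None:
        y = y + b.data
    res = Tensor(y, x.requires_grad or w.requires_grad or (b is not None and b.requires_grad))
    res._parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))
        if w.requires_grad:
            w._accumulate(g.T @ x.data)
        if x.requires_grad:
            x._accumulate(g @ w.data)

    res._backward = bwd
    return res


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    res = Tensor(x.data * mask, x.requires_grad)
    res._parents = (x,)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    res._backward = bwd
    return res


def max_pool2d(x: Tensor, kernel: int = 2, stride: int | None = None, padding: int = 0) -> Tensor:
    """Max pooling; ties send gradient to the first maximal position."""
    stride = stride or kernel
    n, c, h, w = x.data.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    res = Tensor(y, x.requires_grad)
    res._parents = (x,)

    def bwd(g):
        if not x.requires_grad:
            return
        dxp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=g.dtype)
        ki, kj = np.divmod(arg, kernel)
        ii = (np.arange(ho)[None, None, :, None] * stride + ki)
        jj = (np.arange(wo)[None, None, None, :] * stride + kj)
        nn_ = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        if stride >= kernel:
            # windows do not overlap: target cells are unique, plain scatter
            dxp[nn_, cc, ii, jj] = g
        else:
            np.add.at(dxp, (nn_, cc, ii, jj), g)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)

    res._backward = bwd
    return res


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Channel-wise batch normalization over (N,H,W).

    In training mode uses per-batch statistics and updates the running
    buffers in place; in evaluation mode uses the running averages.
    """
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    res = Tensor(y, x.requires_grad or gamma.requires_grad or beta.requires_grad)
    res._parents = (x, gamma, beta)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bwd(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = g * gamma.data[None, :, None, None]
            if training:
                dxhat = gi
                dx = (inv[None, :, None, None] / m) * (
                    m * dxhat
                    - dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
                    - xhat * (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
                )
            else:
                dx = gi * inv[None, :, None, None]
            x._accumulate(dx.astype(g.dtype))

    res._backward = bwd
    return res


def grid_sample(x: Tensor, grid: Tensor) -> Tensor:
    """Differentiable bilinear sampling at normalized grid points.

    ``x``: (N, C, H, W); ``grid``: (N, Ho, Wo, 2) with (x, y) coordinates in
    [-1, 1] mapped so that -1/+1 are the centers of the border pixels
    (align-corners convention, which makes the identity grid an exact
    identity map).  Source points outside [-1, 1] contribute zero.
    Differentiable with respect to both the input map and the grid.
    """
    n, c, h, w = x.data.shape
    gx = (grid.data[..., 0] + 1) * 0.5 * (w - 1)  # (N,Ho,Wo) pixel coords
    gy = (grid.data[..., 1] + 1) * 0.5 * (h - 1)
    x0 = np.floor(gx).astype(np.int64)
    y0 = np.floor(gy).astype(np.int64)
    x1, y1 = x0 + 1, y0 + 1
    wx1 = gx - x0
    wy1 = gy - y0
    wx0 = 1.0 - wx1
    wy0 = 1.0 - wy1

    def gather(yy, xx):
        valid = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        yc = np.clip(yy, 0, h - 1)
        xc = np.clip(xx, 0, w - 1)
        nn_ = np.arange(n)[:, None, None]
        v = x.data[nn_, :, yc, xc]  # (N,Ho,Wo,C)
        v = v * valid[..., None]
        return v, valid, yc, xc

    v00, m00, y00, x00 = gather(y0, x0)
    v01, m01, y01, x01 = gather(y0, x1)
    v10, m10, y10, x10 = gather(y1, x0)
    v11, m11, y11, x11 = gather(y1, x1)
    out = (
        v00 * (wy0 * wx0)[..., None]
        + v01 * (wy0 * wx1)[..., None]
        + v10 * (wy1 * wx0)[..., None]
        + v11 * (wy1 * wx1)[..., None]
    )
    y = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    res = Tensor(y, x.requires_grad or grid.requires_grad)
    res._parents = (x, grid)

    def bwd(g):
        gt = g.transpose(0, 2, 3, 1)  # (N,Ho,Wo,C)
        if x.requires_grad:
            dx_nhwc = np.zeros((n, h, w, c), dtype=x.data.dtype)
            dxf = dx_nhwc.reshape(n * h * w, c)
            nn_ = np.broadcast_to(np.arange(n)[:, None, None], gx.shape)
            for (wgt, msk, yy, xx) in (
                (wy0 * wx0, m00, y00, x00),
                (wy0 * wx1, m01, y01, x01),
                (wy1 * wx0, m10, y10, x10),
                (wy1 * wx1, m11, y11, x11),
            ):
                contrib = gt * (wgt * msk)[..., None]
                flat_idx = (nn_ * h + yy) * w + xx  # scatter on (N*H*W, C) view
                np.add.at(dxf, flat_idx.ravel(), contrib.reshape(-1, c))
            x._accumulate(np.ascontiguousarray(dx_nhwc.transpose(0, 3, 1, 2)))
        if grid.requires_grad:
            dgx = (
                (v01 - v00) * (wy0)[..., None] + (v11 - v10) * (wy1)[..., None]
            )
            dgy = (
                (v10 - v00) * (wx0)[..., None] + (v11 - v01) * (wx1)[..., None]
            )
            dgrid = np.zeros_like(grid.data)
            dgrid[..., 0] = (gt * dgx).sum(-1) * 0.5 * (w - 1)
            dgrid[..., 1] = (gt * dgy).sum(-1) * 0.5 * (h - 1)
            grid._accumulate(dgrid)

    res._backward = bwd
    return res


def global_avg_pool2d(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    res = Tensor(x.data.mean(axis=(2, 3)), x.requires_grad)
    res._parents = (x,)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).copy())

    res._backward = bwd
    return res


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Average pooling onto a fixed output size with area-partition bins."""
    n, c, h, w = x.data.shape
    oh, ow = out_hw
    hs = [(int(np.floor(i * h / oh)), int(np.ceil((i + 1) * h / oh))) for i in range(oh)]
    ws = [(int(np.floor(j * w / ow)), int(np.ceil((j + 1) * w / ow))) for j in range(ow)]
    y = np.empty((n, c, oh, ow), dtype=x.data.dtype)
    for i, (h0, h1) in enumerate(hs):
        for j, (w0, w1) in enumerate(ws):
            y[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
    res = Tensor(y, x.requires_grad)
    res._parents = (x,)

    def bwd(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hs):
            for j, (w0, w1) in enumerate(ws):
                dx[:, :, h0:h1, w0:w1] += (
                    g[:, :, i : i + 1, j : j + 1] / ((h1 - h0) * (w1 - w0))
                )
        x._accumulate(dx)

    res._backward = bwd
    return res


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``.

    ``logits``: (N, K); ``labels``: (N,) ints in [0, K).  Numerically stable
    log-sum-exp formulation.
    """
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    n = z.shape[0]
    picked = z[np.arange(n), labels]
    loss = float((lse - picked).mean())
    res = Tensor(loss, logits.requires_grad)
    res._parents = (logits,)

    def bwd(g):
        if logits.requires_grad:
            p = np.exp(z - zmax)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(n), labels] -= 1.0
            logits._accumulate(g * p / n)

    res._backward = bwd
    return res


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with named parameters, buffers and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, np.ndarray):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_buffers(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{name}.{i}.")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({f"buf::{name}": b.copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for k, v in d.items():
            if k.startswith("buf::"):
                tgt = bufs[k[5:]]
                if tgt.shape != v.shape:
                    raise ValueError(f"buffer shape mismatch for {k}")
                tgt[...] = v
            else:
                if params[k].data.shape != v.shape:
                    raise ValueError(f"parameter shape mismatch for {k}")
                params[k].data[...] = _as_array(v)

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, groups=1,
                 bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch // groups, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=_DTYPE)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class Linear(Module):
    def __init__(self, in_f, out_f, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (out_f, in_f), in_f))
        self.bias = Parameter(np.zeros(out_f, dtype=_DTYPE))

    def forward(self, x):
        return linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, ch, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(ch, dtype=_DTYPE))
        self.beta = Parameter(np.zeros(ch, dtype=_DTYPE))
        self.running_mean = np.zeros(ch, dtype=_DTYPE)
        self.running_var = np.ones(ch, dtype=_DTYPE)
        self.momentum, self.eps = momentum, eps
        self.bypass = False  # oracle switch: identity pass-through

    def forward(self, x):
        if self.bypass:
            return x
        return batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class SGD:
    """Plain stochastic gradient descent (no momentum, no weight decay)."""

    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= (self.lr * p.grad).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
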