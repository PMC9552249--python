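"""Minimal reverse-mode autodiff on NumPy arrays.

Supports exactly the operations the nested encoder-decoder needs:
2-D convolution (via im2col), ReLU, 2x2 max-pooling, nearest-neighbour
2x upsampling and channel concatenation.  Tensors are NCHW float32.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "parents", "backfn", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backfn: Callable[[np.ndarray], tuple[np.ndarray | None, ...]] | None = None,
        requires_grad: bool = True,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.backfn = backfn
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape


def backward(seeds: dict[Tensor, np.ndarray]) -> None:
    """Backpropagate from the seeded tensors through the recorded graph."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(t, False) for t in seeds]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    for t, g in seeds.items():
        t.grad = np.asarray(g, dtype=np.float32) if t.grad is None else t.grad + g
    for node in reversed(topo):
        if node.grad is None or node.backfn is None:
            continue
        grads = node.backfn(node.grad)
        for parent, g in zip(node.parents, grads):
            if g is None or not parent.requires_grad:
                continue
            parent.grad = g.astype(np.float32) if parent.grad is None else parent.grad + g


def zero_grads(params: Sequence[Tensor]) -> None:
    for p in params:
        p.grad = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding convolution; ``w`` is (Cout, Cin, k, k), k odd."""
    N, C, H, W = x.data.shape
    Cout, Cin, k, _ = w.data.shape
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    view = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(N, H, W, C * k * k)
    wmat = w.data.reshape(Cout, C * k * k)
    out = cols @ wmat.T + b.data  # (N, H, W, Cout)
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backfn(gout: np.ndarray):
        gm = gout.transpose(0, 2, 3, 1)  # (N, H, W, Cout)
        gw = np.einsum("nhwk,nhwc->kc", gm, cols, optimize=True).reshape(w.data.shape)
        gb = gm.sum(axis=(0, 1, 2))
        gcols = (gm @ wmat).reshape(N, H, W, C, k, k)
        gxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                gxp[:, :, di : di + H, dj : dj + W] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        gx = gxp[:, :, pad : pad + H, pad : pad + W] if pad else gxp
        return gx, gw, gb

    return Tensor(out, parents=(x, w, b), backfn=backfn)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, parents=(x,), backfn=lambda g: (g * mask,))


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling; spatial dims must be even."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2 needs even spatial dims")
    blocks = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(N, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backfn(gout: np.ndarray):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], gout[..., None], axis=-1)
        gx = gflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        return (gx,)

    return Tensor(out, parents=(x,), backfn=backfn)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    N, C, H, W = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backfn(gout: np.ndarray):
        gx = gout.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5))
        return (gx,)

    return Tensor(out, parents=(x,), backfn=backfn)


def concat(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    sizes = [t.data.shape[1] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=1)
    splits = np.cumsum(sizes)[:-1]

    def backfn(gout: np.ndarray):
        return tuple(np.split(gout, splits, axis=1))

    return Tensor(out, parents=tuple(tensors), backfn=backfn)
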