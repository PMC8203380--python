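"""2-D convolution primitive with tape-op VJPs.

Forward is im2col + a single GEMM (BLAS).  The input- and weight-gradients
are themselves expressed through :func:`conv2d` plus pad/dilate/flip tape
ops, so convolutions are differentiable to arbitrary order.

Layout is NCHW; kernels are (C_out, C_in, kH, kW).  The implementation
assumes ``(H + 2p - k)`` is divisible by the stride, which holds for every
architecture in this package (even sizes, k=4/s=2/p=1 or odd kernels at
stride 1).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor, dilate2d, flip, pad2d, transpose


def _conv2d_forward(x: np.ndarray, w: np.ndarray, stride: int, padding: int) -> np.ndarray:
    n, c, h, wd = x.shape
    if padding:
        xp = np.zeros((n, c, h + 2 * padding, wd + 2 * padding), dtype=x.dtype)
        xp[:, :, padding:padding + h, padding:padding + wd] = x
        x = xp
        h += 2 * padding
        wd += 2 * padding
    co, ci, kh, kw = w.shape
    ho = (h - kh) // stride + 1
    wo = (wd - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    win = as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )
    cols = win.reshape(n, c * kh * kw, ho * wo)  # one copy
    out = np.matmul(w.reshape(co, ci * kh * kw), cols)  # (n, co, ho*wo)
    return out.reshape(n, co, ho, wo)


def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of ``x`` (N,C,H,W) with kernels ``w`` (Co,Ci,kH,kW)."""
    data = _conv2d_forward(x.data, w.data, stride, padding)
    k = w.shape[2]
    h, w_in = x.shape[2], x.shape[3]
    ho, wo = data.shape[2], data.shape[3]
    # rows/cols of the padded input never covered by a window (non-divisible
    # geometry); the VJPs pad asymmetrically to restore the exact input size
    rm_h = (h + 2 * padding - k) - (ho - 1) * stride
    rm_w = (w_in + 2 * padding - k) - (wo - 1) * stride

    def vjp_x(g: Tensor) -> Tensor:
        # full correlation of the stride-dilated output grad with the
        # spatially flipped, channel-transposed kernel
        wt = transpose(flip(w, (2, 3)), (1, 0, 2, 3))
        q = k - 1 - padding
        gd = pad2d(dilate2d(g, stride), (q, q + rm_h, q, q + rm_w))
        return conv2d(gd, wt, stride=1, padding=0)

    def vjp_w(g: Tensor) -> Tensor:
        # correlate input (channels as batch) with the dilated output grad
        xp = pad2d(x, padding)
        if rm_h or rm_w:
            xp = xp[:, :, :xp.shape[2] - rm_h, :xp.shape[3] - rm_w]
        xt = transpose(xp, (1, 0, 2, 3))
        gt = transpose(dilate2d(g, stride), (1, 0, 2, 3))
        return transpose(conv2d(xt, gt, stride=1, padding=0), (1, 0, 2, 3))

    return Tensor._make(data, [(x, vjp_x), (w, vjp_w)])


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour spatial upsampling by an integer factor."""
    n, c, h, w = x.shape
    data = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def vjp(g: Tensor) -> Tensor:
        gr = g.reshape((n, c, h, factor, w, factor))
        return gr.sum(axis=(3, 5))

    return Tensor._make(data, [(x, vjp)])
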