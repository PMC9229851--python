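"""Spatial operations (convolution, pooling, resampling) for the autodiff engine.

Convolution is implemented with ``sliding_window_view`` patches plus einsum;
its adjoint scatters gradients back with the usual col2im loop over kernel
offsets.  Adaptive average pooling follows the floor/ceil region convention,
with a reshape fast path when the input side divides evenly.  Bilinear
resampling is expressed as two constant interpolation matrices so its adjoint
is simply the transposed matrices.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "conv2d",
    "adaptive_avg_pool2d",
    "avg_pool2d",
    "interpolate_bilinear",
    "crisscross_attention",
]


def _conv_patches(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    # (N, C, Ho, Wo, kh, kw) view of the padded input
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    n, c, h, wdt = x.data.shape
    o, cg, kh, kw = w.data.shape
    if c % groups or o % groups or cg != c // groups:
        raise ValueError("inconsistent channel/group configuration")
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    patches = _conv_patches(xp, kh, kw, stride)  # (N, C, Ho, Wo, kh, kw)
    ho, wo = patches.shape[2], patches.shape[3]
    og = o // groups
    if groups == 1:
        out_data = np.einsum("ncijuv,ocuv->noij", patches, w.data, optimize=True)
    else:
        pg = patches.reshape(n, groups, cg, ho, wo, kh, kw)
        wg = w.data.reshape(groups, og, cg, kh, kw)
        out_data = np.einsum("ngcijuv,gocuv->ngoij", pg, wg, optimize=True)
        out_data = out_data.reshape(n, o, ho, wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, o, 1, 1)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, req, parents)

    def _bw(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if groups == 1:
            if w.requires_grad:
                w._accumulate(np.einsum("noij,ncijuv->ocuv", g, patches, optimize=True))
            if x.requires_grad:
                dpatch = np.einsum("noij,ocuv->ncijuv", g, w.data, optimize=True)
                x._accumulate(_col2im(dpatch, (n, c, h, wdt), kh, kw, stride, padding))
        else:
            gg = g.reshape(n, groups, og, ho, wo)
            pg = patches.reshape(n, groups, cg, ho, wo, kh, kw)
            if w.requires_grad:
                dw = np.einsum("ngoij,ngcijuv->gocuv", gg, pg, optimize=True)
                w._accumulate(dw.reshape(o, cg, kh, kw))
            if x.requires_grad:
                wg = w.data.reshape(groups, og, cg, kh, kw)
                dpatch = np.einsum("ngoij,gocuv->ngcijuv", gg, wg, optimize=True)
                dpatch = dpatch.reshape(n, c, ho, wo, kh, kw)
                x._accumulate(_col2im(dpatch, (n, c, h, wdt), kh, kw, stride, padding))

    out._backward = _bw if req else None
    return out


def _col2im(dpatch, x_shape, kh, kw, stride, padding):
    n, c, h, w = x_shape
    gx = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=dpatch.dtype)
    ho, wo = dpatch.shape[2], dpatch.shape[3]
    for u in range(kh):
        for v in range(kw):
            gx[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride] += dpatch[
                :, :, :, :, u, v
            ]
    if padding:
        gx = gx[:, :, padding:-padding, padding:-padding]
    return gx


def _crisscross_weights(m: np.ndarray, nf: np.ndarray) -> np.ndarray:
    """Softmax criss-cross affinities, (N, H, W, H+W); the duplicate row
    slot at b == j is masked so the softmax runs over H+W-1 positions."""
    n, c, h, w = m.shape
    e_col = np.einsum("ncij,ncaj->nija", m, nf, optimize=True)
    e_row = np.einsum("ncij,ncib->nijb", m, nf, optimize=True)
    e_row[:, :, np.arange(w), np.arange(w)] = -1e9
    energy = np.concatenate([e_col, e_row], axis=3)
    energy -= energy.max(axis=3, keepdims=True)
    np.exp(energy, out=energy)
    energy /= energy.sum(axis=3, keepdims=True)
    return energy


def crisscross_attention(m: Tensor, nf: Tensor, v: Tensor, x: Tensor) -> Tensor:
    """One criss-cross pass, fused: softmax affinities of each pixel against
    its row and column, aggregation of the value map, residual add of x.

    Equivalent to building the (N, H, W, H+W) attention tensor with
    primitive ops, but with a hand-derived adjoint that avoids the large
    intermediate gradient buffers.
    """
    n, c, h, w = m.data.shape
    attn = _crisscross_weights(m.data, nf.data)
    a_col, a_row = attn[..., :h], attn[..., h:]
    out_data = (
        np.einsum("nija,ncaj->ncij", a_col, v.data, optimize=True)
        + np.einsum("nijb,ncib->ncij", a_row, v.data, optimize=True)
        + x.data
    )
    req = any(t.requires_grad for t in (m, nf, v, x))
    out = Tensor(out_data, req, (m, nf, v, x))

    def _bw(g):
        if x.requires_grad:
            x._accumulate(g)
        if v.requires_grad:
            dv = np.einsum("nija,ncij->ncaj", a_col, g, optimize=True)
            dv += np.einsum("nijb,ncij->ncib", a_row, g, optimize=True)
            v._accumulate(dv)
        if m.requires_grad or nf.requires_grad:
            d_attn = np.concatenate(
                [
                    np.einsum("ncij,ncaj->nija", g, v.data, optimize=True),
                    np.einsum("ncij,ncib->nijb", g, v.data, optimize=True),
                ],
                axis=3,
            )
            # softmax adjoint over the slot axis
            de = attn * (d_attn - (d_attn * attn).sum(axis=3, keepdims=True))
            de_col, de_row = de[..., :h], de[..., h:]
            if m.requires_grad:
                dm = np.einsum("nija,ncaj->ncij", de_col, nf.data, optimize=True)
                dm += np.einsum("nijb,ncib->ncij", de_row, nf.data, optimize=True)
                m._accumulate(dm)
            if nf.requires_grad:
                dn = np.einsum("nija,ncij->ncaj", de_col, m.data, optimize=True)
                dn += np.einsum("nijb,ncij->ncib", de_row, m.data, optimize=True)
                nf._accumulate(dn)

    out._backward = _bw if req else None
    return out


def _pool_bounds(n_in: int, n_out: int):
    starts = [(i * n_in) // n_out for i in range(n_out)]
    ends = [-(-((i + 1) * n_in) // n_out) for i in range(n_out)]
    return starts, ends


def adaptive_avg_pool2d(x: Tensor, output_size: tuple[int, int]) -> Tensor:
    """Average pooling onto an ``oh x ow`` grid of (possibly uneven) regions."""
    n, c, h, w = x.data.shape
    oh, ow = output_size
    if oh == h and ow == w:
        return x
    if h % oh == 0 and w % ow == 0:
        kh, kw = h // oh, w // ow
        out_data = x.data.reshape(n, c, oh, kh, ow, kw).mean(axis=(3, 5))
        out = Tensor(out_data, x.requires_grad, (x,))

        def _bw_fast(g):
            if x.requires_grad:
                ge = np.broadcast_to(
                    g[:, :, :, None, :, None] / (kh * kw), (n, c, oh, kh, ow, kw)
                )
                x._accumulate(ge.reshape(n, c, h, w).copy())

        out._backward = _bw_fast if x.requires_grad else None
        return out

    rs, re = _pool_bounds(h, oh)
    cs, ce = _pool_bounds(w, ow)
    out_data = np.empty((n, c, oh, ow), dtype=x.data.dtype)
    for i in range(oh):
        for j in range(ow):
            out_data[:, :, i, j] = x.data[:, :, rs[i] : re[i], cs[j] : ce[j]].mean(axis=(2, 3))
    out = Tensor(out_data, x.requires_grad, (x,))

    def _bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros((n, c, h, w), dtype=g.dtype)
        for i in range(oh):
            for j in range(ow):
                area = (re[i] - rs[i]) * (ce[j] - cs[j])
                gx[:, :, rs[i] : re[i], cs[j] : ce[j]] += (
                    g[:, :, i, j][:, :, None, None] / area
                )
        x._accumulate(gx)

    out._backward = _bw if x.requires_grad else None
    return out


def avg_pool2d(x: Tensor, kernel: int = 2) -> Tensor:
    """Non-overlapping mean pooling with a square kernel (side must divide)."""
    n, c, h, w = x.data.shape
    if h % kernel or w % kernel:
        raise ValueError("avg_pool2d requires the side to divide by the kernel")
    return adaptive_avg_pool2d(x, (h // kernel, w // kernel))


def _interp_matrix(n_out: int, n_in: int, dtype=np.float64) -> np.ndarray:
    """Bilinear interpolation weights (half-pixel centers, edges clamped)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = src - i0
    for r in range(n_out):
        m[r, i0[r]] += 1.0 - f[r]
        m[r, i1[r]] += f[r]
    return m


def interpolate_bilinear(x: Tensor, output_size: tuple[int, int]) -> Tensor:
    n, c, h, w = x.data.shape
    oh, ow = output_size
    wr = _interp_matrix(oh, h, x.data.dtype)
    wc = _interp_matrix(ow, w, x.data.dtype)
    out_data = np.einsum("ah,nchw,bw->ncab", wr, x.data, wc, optimize=True)
    out = Tensor(out_data, x.requires_grad, (x,))

    def _bw(g):
        if x.requires_grad:
            x._accumulate(np.einsum("ah,ncab,bw->nchw", wr, g, wc, optimize=True))

    out._backward = _bw if x.requires_grad else None
    return out
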