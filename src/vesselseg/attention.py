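"""Transformer-side blocks of the segmentation network.

A TPA block is the replacement for standard multi-head self-attention used
throughout the model: a depthwise-convolutional positional-encoding gate,
TMSA (multi-head self-attention with queries at full resolution, keys/values
from a spatially reduced map, and a 1x1 convolution mixing the per-head
logit stack), a residual feed-forward network, and a criss-cross position
attention applied twice with shared projection weights.  One criss-cross
pass lets every pixel attend to the H+W-1 positions in its own row and
column; the second pass propagates information between every pair of pixels.

Patch embedding halves the spatial side and doubles the channel count
between stages via a stride-2 projection with a sigmoid convolutional gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, Conv2d, LayerNorm, Linear, Module
from .nn.tensor import Tensor, relu, sigmoid, softmax

__all__ = [
    "AttentionConfig",
    "PatchEmbed",
    "PositionalEncoding",
    "TMSA",
    "PositionAttention",
    "TPABlock",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Shape of one attention stage.

    ``d_m`` embedding channels, ``heads`` attention heads (must divide
    ``d_m``), ``sr_ratio`` spatial-reduction factor for keys/values,
    ``ffn_expansion`` hidden-width multiplier of the feed-forward network,
    ``depth`` number of TPA blocks in the stage.
    """

    d_m: int
    heads: int = 1
    sr_ratio: int = 1
    ffn_expansion: int = 4
    depth: int = 1

    def validate(self) -> "AttentionConfig":
        if self.d_m % self.heads:
            raise ValueError(f"d_m={self.d_m} must be divisible by heads={self.heads}")
        if self.sr_ratio < 1 or self.ffn_expansion < 1 or self.depth < 1:
            raise ValueError("sr_ratio, ffn_expansion and depth must all be >= 1")
        return self


class PatchEmbed(Module):
    """Halve the spatial side and double the channels between stages.

    ``x' = Proj(BN(x))`` with Proj a stride-2 convolution (kernel size
    configurable), then a sigmoid gate ``Sigmoid(Conv3x3(x')) * x'``.
    """

    def __init__(self, in_channels: int, proj_kernel: int = 3, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        out_channels = 2 * in_channels
        self.bn = BatchNorm2d(in_channels)
        self.proj = Conv2d(
            in_channels, out_channels, proj_kernel, stride=2, padding=proj_kernel // 2, rng=rng
        )
        self.gate = Conv2d(out_channels, out_channels, 3, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("patch embedding requires even spatial dimensions")
        xp = self.proj(self.bn(x))
        return sigmoid(self.gate(xp)) * xp


class PositionalEncoding(Module):
    """Depthwise 3x3 convolutional gate: ``Sigmoid(DWConv(x)) * x``."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.dw = Conv2d(channels, channels, 3, padding=1, groups=channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return sigmoid(self.dw(x)) * x


def _to_tokens(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    return x.reshape(n, c, h * w).transpose(0, 2, 1)


class TMSA(Module):
    """Spatially-reduced multi-head self-attention with head mixing.

    Queries come from the full-resolution token grid; keys and values from a
    map reduced by a stride-``s`` convolution (plus layer norm) when s > 1.
    The per-head logit stack Q.K^T/sqrt(d_k) is mixed across the head axis by
    a learned 1x1 convolution before the softmax over keys.
    """

    def __init__(self, cfg: AttentionConfig, rng=None):
        super().__init__()
        cfg.validate()
        rng = rng or np.random.default_rng(0)
        d, s = cfg.d_m, cfg.sr_ratio
        self.cfg = cfg
        self.q_proj = Conv2d(d, d, 1, rng=rng)
        self.k_proj = Conv2d(d, d, 1, rng=rng)
        self.v_proj = Conv2d(d, d, 1, rng=rng)
        if s > 1:
            self.sr = Conv2d(d, d, s, stride=s, rng=rng)
            self.sr_norm = LayerNorm(d)
        self.head_mix_weight = Tensor(np.eye(cfg.heads), requires_grad=True)
        self.head_mix_bias = Tensor(np.zeros(cfg.heads), requires_grad=True)
        self.attn_norm = LayerNorm(d)
        self.out_proj = Linear(d, d, rng=rng)
        hidden = cfg.ffn_expansion * d
        self.ffn_norm = LayerNorm(d)
        self.ffn_in = Linear(d, hidden, rng=rng)
        self.ffn_out = Linear(hidden, d, rng=rng)

    def core(self, x: Tensor) -> Tensor:
        """The attention operator itself (no residual, no FFN)."""
        n, d, h, w = x.shape
        heads = self.cfg.heads
        dk = d // heads
        s = self.cfg.sr_ratio
        q = _to_tokens(self.q_proj(x))  # (N, n, d)
        if s > 1:
            if h % s or w % s:
                raise ValueError("spatial dims must divide by sr_ratio")
            red = self.sr(x)
            kv_src = red
            k = _to_tokens(self.k_proj(kv_src))
            v = _to_tokens(self.v_proj(kv_src))
            k = self.sr_norm(k)
            v = self.sr_norm(v)
        else:
            k = _to_tokens(self.k_proj(x))
            v = _to_tokens(self.v_proj(x))
        ntok, mtok = h * w, k.shape[1]
        q = q.reshape(n, ntok, heads, dk).transpose(0, 2, 1, 3)  # (N, H, n, dk)
        k = k.reshape(n, mtok, heads, dk).transpose(0, 2, 1, 3)
        v = v.reshape(n, mtok, heads, dk).transpose(0, 2, 1, 3)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dk))  # (N, H, n, m)
        mixed = self.head_mix_weight @ logits.reshape(n, heads, ntok * mtok)
        mixed = mixed + self.head_mix_bias.reshape(1, heads, 1)
        attn = softmax(mixed.reshape(n, heads, ntok, mtok), axis=-1)
        ctx = attn @ v  # (N, H, n, dk)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(n, ntok, d)
        ctx = self.attn_norm(ctx)
        ctx = self.out_proj(ctx)
        return ctx.transpose(0, 2, 1).reshape(n, d, h, w)

    def attention_map(self, x: Tensor) -> np.ndarray:
        """Post-softmax attention weights (N, heads, n_query, n_key); for inspection."""
        n, d, h, w = x.shape
        heads, dk, s = self.cfg.heads, d // self.cfg.heads, self.cfg.sr_ratio
        q = _to_tokens(self.q_proj(x))
        src = self.sr(x) if s > 1 else x
        k = _to_tokens(self.k_proj(src))
        if s > 1:
            k = self.sr_norm(k)
        ntok, mtok = h * w, k.shape[1]
        q = q.reshape(n, ntok, heads, dk).transpose(0, 2, 1, 3)
        k = k.reshape(n, mtok, heads, dk).transpose(0, 2, 1, 3)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dk))
        mixed = self.head_mix_weight @ logits.reshape(n, heads, ntok * mtok)
        mixed = mixed + self.head_mix_bias.reshape(1, heads, 1)
        return softmax(mixed.reshape(n, heads, ntok, mtok), axis=-1).data

    def forward(self, x: Tensor) -> Tensor:
        z = x + self.core(x)  # residual around the attention operator
        tok = _to_tokens(z)
        ffn = self.ffn_out(relu(self.ffn_in(self.ffn_norm(tok))))
        n, d, h, w = z.shape
        return z + ffn.transpose(0, 2, 1).reshape(n, d, h, w)


class PositionAttention(Module):
    """Criss-cross position attention (one call = one pass).

    For each position, affinities of its query vector against the H+W-1
    feature vectors sharing its row or column are softmax-normalized and used
    to aggregate the value map; the result is added residually to the input.
    """

    def __init__(self, channels: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.m_proj = Conv2d(channels, channels, 1, rng=rng)
        self.n_proj = Conv2d(channels, channels, 1, rng=rng)
        self.v_proj = Conv2d(channels, channels, 1, rng=rng)

    def attention_map(self, x: Tensor) -> np.ndarray:
        """(N, H, W, H+W) post-softmax weights; the masked slot is ~0."""
        from .nn.functional import _crisscross_weights

        return _crisscross_weights(self.m_proj(x).data, self.n_proj(x).data)

    def forward(self, x: Tensor) -> Tensor:
        from .nn.functional import crisscross_attention

        return crisscross_attention(self.m_proj(x), self.n_proj(x), self.v_proj(x), x)


class TPABlock(Module):
    """Positional encoding -> TMSA (+FFN) -> position attention applied twice.

    The two criss-cross passes share one set of projection weights (a
    recurrent application), which is what lets two passes reach every pixel
    pair while keeping the parameter count low.
    """

    def __init__(self, cfg: AttentionConfig, rng=None):
        super().__init__()
        cfg.validate()
        rng = rng or np.random.default_rng(0)
        self.pos_enc = PositionalEncoding(cfg.d_m, rng=rng)
        self.tmsa = TMSA(cfg, rng=rng)
        self.pos_attn = PositionAttention(cfg.d_m, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.pos_enc(x)
        x = self.tmsa(x)
        x = self.pos_attn(x)
        return self.pos_attn(x)
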