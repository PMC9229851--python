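"""The MTPA-UNet backbone: serial Transformer stages feeding a CNN U-Net.

Four Transformer stages consume a multi-resolution pyramid of one 64x64
patch (64/32/16/8): stage 1 embeds the full patch through a convolutional
stem and a TPA block; stages 2-4 halve the side and double the channels with
a patch embedding, fuse in a projection of the matching pyramid level, and
run their own TPA blocks.  Each stage's output feeds a feature-extraction
(FE) block; downsampling (DS) blocks chain the encoder levels together.
All four encoder outputs are pooled, concatenated and fused (shallow-
information fusion) into a pyramid-pooling bottom module; a final DS halves
it to 4x4.  The decoder mirrors the encoder with bilinear upsampling,
additive residual skips from the FE outputs, and FE refinement, ending in a
1x1 convolution + sigmoid probability head at 64x64.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .attention import AttentionConfig, PatchEmbed, TPABlock
from .nn import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Identity,
    Module,
    ModuleList,
)
from .nn.functional import adaptive_avg_pool2d, interpolate_bilinear
from .nn.tensor import Tensor, concat, relu, sigmoid
from .preprocessing import PatchPyramid

__all__ = [
    "ModelConfig",
    "SegmentationResult",
    "FEBlock",
    "DSBlock",
    "MultilayerPool",
    "SCIFuse",
    "DecoderBlock",
    "MTPAUnet",
    "count_parameters",
    "reference_config",
    "desk_config",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameter ledger of the assembled network.

    The defaults are the reference configuration: channel schedule
    32/64/128/256 over input sides 64/32/16/8, one TPA block per stage with
    heads 1/2/4/8 and key/value spatial reduction 8/4/2/1, pyramid-pooling
    bottom with grids 1/2/3/6, and a heavy descending decoder whose widths
    put the assembled model at 11.8 M trainable parameters.
    """

    channels: tuple[int, ...] = (32, 64, 128, 256)
    input_sizes: tuple[int, ...] = (64, 32, 16, 8)
    heads: tuple[int, ...] = (1, 2, 4, 8)
    sr_ratios: tuple[int, ...] = (8, 4, 2, 1)
    ffn_expansion: int = 4
    depth: int = 1
    decoder_channels: tuple[int, ...] = (608, 576, 512, 480)
    pool_scales: tuple[int, ...] = (1, 2, 3, 6)
    proj_kernel: int = 3
    ds_triple_norm: bool = False
    foreground_prior: float = 0.1  # head bias starts at logit(prior)
    seed: int = 0

    def validate(self) -> "ModelConfig":
        if len(self.channels) != 4 or len(self.input_sizes) != 4:
            raise ValueError("the model has exactly four stages")
        for a, b in zip(self.input_sizes, self.input_sizes[1:]):
            if b * 2 != a:
                raise ValueError("input sizes must halve stage by stage")
        for a, b in zip(self.channels, self.channels[1:]):
            if b != 2 * a:
                raise ValueError("channels must double stage by stage")
        if len(self.decoder_channels) != 4:
            raise ValueError("decoder_channels must list four widths")
        for c, h, s in zip(self.channels, self.heads, self.sr_ratios):
            AttentionConfig(c, h, s, self.ffn_expansion, self.depth).validate()
        return self

    def attention_config(self, stage: int) -> AttentionConfig:
        return AttentionConfig(
            d_m=self.channels[stage],
            heads=self.heads[stage],
            sr_ratio=self.sr_ratios[stage],
            ffn_expansion=self.ffn_expansion,
            depth=self.depth,
        )


def reference_config() -> ModelConfig:
    """The frozen full-size configuration (~11.8 M trainable parameters)."""
    return ModelConfig()


def desk_config(seed: int = 0) -> ModelConfig:
    """A narrow configuration for CPU-scale training and tests."""
    return ModelConfig(channels=(8, 16, 32, 64), decoder_channels=(64, 32, 16, 8), seed=seed)


@dataclass
class SegmentationResult:
    """A probability map with its thresholded binary mask."""

    prob_map: np.ndarray
    threshold: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def bin_mask(self) -> np.ndarray:
        return (self.prob_map >= self.threshold).astype(np.uint8)


class FEBlock(Module):
    """Feature extraction: 1x1 reduce, parallel 3x3 conv + 3x3 transposed
    conv, concat-fuse through a 1x1 bottleneck, BN, ReLU, residual add."""

    def __init__(self, in_channels: int, out_channels: int, reduce: int | None = None, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        r = reduce if reduce is not None else max(1, out_channels // 2)
        self.reduce = Conv2d(in_channels, r, 1, rng=rng)
        self.conv = Conv2d(r, r, 3, padding=1, rng=rng)
        self.tconv = ConvTranspose2d(r, r, 3, padding=1, rng=rng)
        self.bottleneck = Conv2d(2 * r, out_channels, 1, rng=rng)
        self.bn = BatchNorm2d(out_channels)
        self.skip = (
            Conv2d(in_channels, out_channels, 1, rng=rng)
            if in_channels != out_channels
            else Identity()
        )

    def forward(self, x: Tensor) -> Tensor:
        z = self.reduce(x)
        fused = concat([self.conv(z), self.tconv(z)], axis=1)
        out = relu(self.bn(self.bottleneck(fused)))
        return out + self.skip(x)


class DSBlock(Module):
    """Downsampling: adaptive pooling to half the side, norm(s), ReLU, conv."""

    def __init__(self, channels: int, triple_norm: bool = False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.norms = ModuleList(
            [BatchNorm2d(channels) for _ in range(3 if triple_norm else 1)]
        )
        self.conv = Conv2d(channels, channels, 3, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("DS block requires even spatial dimensions")
        z = adaptive_avg_pool2d(x, (h // 2, w // 2))
        for norm in self.norms:
            z = norm(z)
        return self.conv(relu(z))


class MultilayerPool(Module):
    """Pyramid pooling: parallel adaptive poolings at fixed grids, 1x1
    convs, upsampling back, concatenation with the input, 1x1 fusion."""

    def __init__(self, channels: int, scales: tuple[int, ...] = (1, 2, 3, 6), rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.scales = tuple(scales)
        branch_ch = max(1, channels // len(self.scales))
        self.branches = ModuleList(
            [Conv2d(channels, branch_ch, 1, rng=rng) for _ in self.scales]
        )
        self.fuse = Conv2d(channels + branch_ch * len(self.scales), channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        if max(self.scales) > min(h, w):
            raise ValueError(
                f"pool scale {max(self.scales)} exceeds the spatial side {min(h, w)}"
            )
        outs = [x]
        for scale, conv in zip(self.scales, self.branches):
            z = conv(adaptive_avg_pool2d(x, (scale, scale)))
            outs.append(interpolate_bilinear(z, (h, w)))
        return self.fuse(concat(outs, axis=1))


class SCIFuse(Module):
    """Shallow-information fusion: pool all encoder outputs to the deepest
    size, concatenate, and fuse to the deepest channel width by 1x1 conv."""

    def __init__(self, channels: tuple[int, ...], rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fuse = Conv2d(sum(channels), channels[-1], 1, rng=rng)

    def forward(self, encoder_outputs: list[Tensor]) -> Tensor:
        if len(encoder_outputs) != 4:
            raise ValueError("expected four encoder outputs")
        sizes = [t.shape[2] for t in encoder_outputs]
        if sizes != sorted(sizes, reverse=True):
            raise ValueError("encoder outputs must come at descending resolutions")
        th, tw = encoder_outputs[-1].shape[2], encoder_outputs[-1].shape[3]
        pooled = [adaptive_avg_pool2d(t, (th, tw)) for t in encoder_outputs]
        return self.fuse(concat(pooled, axis=1))


class DecoderBlock(Module):
    """Upsample x2, 1x1 channel alignment, additive skip merge, FE refine."""

    def __init__(self, in_channels: int, skip_channels: int, out_channels: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.align = Conv2d(in_channels, skip_channels, 1, rng=rng)
        self.refine = FEBlock(skip_channels, out_channels, rng=rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        _, _, h, w = x.shape
        _, _, sh, sw = skip.shape
        if (sh, sw) != (2 * h, 2 * w):
            raise ValueError("skip must be exactly twice the spatial size of x")
        up = interpolate_bilinear(x, (sh, sw))
        return self.refine(self.align(up) + skip)


class MTPAUnet(Module):
    """The assembled multi-scale Transformer + CNN segmentation network."""

    def __init__(self, cfg: ModelConfig | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        cfg = (cfg or ModelConfig()).validate()
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        ch = cfg.channels
        self.stem = Conv2d(1, ch[0], 3, padding=1, rng=rng)
        self.tpa_stages = ModuleList(
            [
                ModuleList(
                    [TPABlock(cfg.attention_config(i), rng=rng) for _ in range(cfg.depth)]
                )
                for i in range(4)
            ]
        )
        self.patch_embeds = ModuleList(
            [PatchEmbed(ch[i], cfg.proj_kernel, rng=rng) for i in range(3)]
        )
        self.inject_projs = ModuleList([Conv2d(1, ch[i + 1], 1, rng=rng) for i in range(3)])
        self.inject_fuses = ModuleList(
            [Conv2d(2 * ch[i + 1], ch[i + 1], 1, rng=rng) for i in range(3)]
        )
        self.fe_blocks = ModuleList(
            [FEBlock(ch[0], ch[0], rng=rng)]
            + [FEBlock(ch[i - 1] + ch[i], ch[i], rng=rng) for i in range(1, 4)]
        )
        self.ds_blocks = ModuleList(
            [DSBlock(ch[i], cfg.ds_triple_norm, rng=rng) for i in range(3)]
        )
        self.sci = SCIFuse(ch, rng=rng)
        self.bottom_pool = MultilayerPool(ch[3], cfg.pool_scales, rng=rng)
        self.bottom_ds = DSBlock(ch[3], cfg.ds_triple_norm, rng=rng)
        dc = cfg.decoder_channels
        skips = (ch[3], ch[2], ch[1], ch[0])
        ins = (ch[3], dc[0], dc[1], dc[2])
        self.decoders = ModuleList(
            [DecoderBlock(ins[i], skips[i], dc[i], rng=rng) for i in range(4)]
        )
        self.head = Conv2d(dc[3], 1, 1, rng=rng)
        # small-head initialization: start the output near the vessel-pixel
        # prior with low-variance logits.  Dice-only training is prone to
        # saturated all-foreground/all-background fixed points when early
        # logits overshoot; keeping them near the prior keeps gradients alive.
        p = cfg.foreground_prior
        self.head.weight.data *= 0.1
        self.head.bias.data[:] = np.log(p / (1.0 - p))

    # -- plumbing ------------------------------------------------------
    def _check_pyramid(self, levels: list[Tensor]):
        for lvl, side in zip(levels, self.cfg.input_sizes):
            if lvl.shape[2] != side or lvl.shape[3] != side:
                raise ValueError(
                    f"pyramid level {lvl.shape[2]}x{lvl.shape[3]} does not match "
                    f"the configured input size {side}"
                )

    def forward(self, levels: list[Tensor]) -> Tensor:
        """Map pyramid levels [(N,1,64,64), ..., (N,1,8,8)] to (N,1,64,64) probabilities."""
        self._check_pyramid(levels)
        # transformer stages
        t = self.stem(levels[0])
        for block in self.tpa_stages[0]:
            t = block(t)
        stage_outs = [t]
        for i in range(3):
            z = self.patch_embeds[i](stage_outs[-1])
            inj = self.inject_projs[i](levels[i + 1])
            z = self.inject_fuses[i](concat([z, inj], axis=1))
            for block in self.tpa_stages[i + 1]:
                z = block(z)
            stage_outs.append(z)
        # encoder chain
        enc = [self.fe_blocks[0](stage_outs[0])]
        chain = self.ds_blocks[0](enc[0])
        for i in range(1, 4):
            enc.append(self.fe_blocks[i](concat([chain, stage_outs[i]], axis=1)))
            if i < 3:
                chain = self.ds_blocks[i](enc[i])
        # bottom: shallow-information fusion + pyramid pooling + final halving
        bottom = self.bottom_ds(self.bottom_pool(self.sci(enc)))
        # decoder with additive residual skips
        d = bottom
        for dec, skip in zip(self.decoders, reversed(enc)):
            d = dec(d, skip)
        return sigmoid(self.head(d))

    def forward_pyramids(self, pyramids: list[PatchPyramid]) -> Tensor:
        """Forward a batch of numpy patch pyramids."""
        levels = []
        for idx in range(4):
            stack = np.stack([p.levels()[idx] for p in pyramids])[:, None, :, :]
            levels.append(Tensor(stack))
        return self.forward(levels)

    def predict_pyramids(self, pyramids: list[PatchPyramid]) -> np.ndarray:
        """Evaluation-mode probabilities for a batch of pyramids, (B, 64, 64)."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward_pyramids(pyramids).data[:, 0]
        finally:
            self.train(was_training)
        return out


def count_parameters(cfg: ModelConfig | None = None, model: Module | None = None) -> int:
    """Total trainable scalars of the assembled model."""
    if model is None:
        model = MTPAUnet(cfg or ModelConfig())
    return model.num_parameters()


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(path, model: MTPAUnet):
    """Single-archive checkpoint embedding the ModelConfig."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    ).copy()
    np.savez_compressed(path, **state)


def _config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    for key in ("channels", "input_sizes", "heads", "sr_ratios", "decoder_channels", "pool_scales"):
        d[key] = tuple(d[key])
    return ModelConfig(**d)


def load_checkpoint(path) -> MTPAUnet:
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files}
    cfg = _config_from_dict(json.loads(bytes(state.pop("__config__")).decode()))
    model = MTPAUnet(cfg)
    model.load_state_dict(state)
    return model
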