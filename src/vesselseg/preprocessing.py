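"""Fundus image enhancement and multi-scale patch machinery.

The enhancement chain is the standard fundus recipe: weighted RGB channel
fusion (green-dominant), per-image standardization rescaled to [0, 1],
contrast-limited adaptive histogram equalization, and gamma correction, in
that order.  Patches of 64x64 pixels are cut from the enhanced image and
paired with 32/16/8 companions obtained by repeated 2x2 average pooling;
these pyramids are the multi-resolution input of the segmentation network.

Coordinates are 0-based and row-major; a patch at origin (r, c) covers the
half-open extent [r, r+64) x [c, c+64).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.exposure import equalize_adapthist

from .synthetic import FundusSample

__all__ = [
    "PreprocessConfig",
    "PatchPyramid",
    "fuse_channels",
    "normalize",
    "clahe",
    "gamma_correct",
    "preprocess",
    "extract_patches",
    "stitch",
]

PATCH = 64


@dataclass(frozen=True)
class PreprocessConfig:
    """Enhancement parameters.

    ``fusion_weights`` are the R/G/B coefficients (must sum to 1); the default
    0.299/0.587/0.114 puts the dominant weight on the green channel, which
    carries the vessel contrast in fundus photographs.  ``clahe_clip`` is the
    scikit-image clip limit in [0, 1]; ``gamma`` is the exponent applied to
    the [0, 1] image at the end of the chain.
    """

    fusion_weights: tuple[float, float, float] = (0.299, 0.587, 0.114)
    clahe_clip: float = 0.02
    clahe_tiles: tuple[int, int] = (8, 8)
    gamma: float = 1.2

    def validate(self) -> "PreprocessConfig":
        if abs(sum(self.fusion_weights) - 1.0) > 1e-9:
            raise ValueError("fusion weights must sum to 1")
        if self.clahe_clip <= 0:
            raise ValueError("CLAHE clip limit must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        return self


@dataclass
class PatchPyramid:
    """One 64x64 patch with its 2x-downsampled 32/16/8 companions."""

    level64: np.ndarray
    level32: np.ndarray
    level16: np.ndarray
    level8: np.ndarray
    origin: tuple[int, int]

    def levels(self) -> list[np.ndarray]:
        return [self.level64, self.level32, self.level16, self.level8]


def fuse_channels(image: np.ndarray, weights=(0.299, 0.587, 0.114)) -> np.ndarray:
    """Weighted sum of the R, G, B channels; weights must sum to 1."""
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("fusion weights must sum to 1")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    wr, wg, wb = weights
    return wr * img[..., 0] + wg * img[..., 1] + wb * img[..., 2]


def normalize(gray: np.ndarray) -> np.ndarray:
    """Standardize (zero mean, unit sd) then min-max rescale to [0, 1]."""
    g = np.asarray(gray, dtype=np.float64)
    sd = g.std()
    if sd == 0:
        warnings.warn("constant image: normalize returns all zeros", stacklevel=2)
        return np.zeros_like(g)
    z = (g - g.mean()) / sd
    return (z - z.min()) / (z.max() - z.min())


def clahe(gray: np.ndarray, clip: float = 0.02, tiles: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 1] image."""
    if clip <= 0:
        raise ValueError("CLAHE clip limit must be positive")
    g = np.asarray(gray, dtype=np.float64)
    if g.min() < 0 or g.max() > 1:
        raise ValueError("clahe expects intensities in [0, 1]")
    kernel = (max(1, g.shape[0] // tiles[0]), max(1, g.shape[1] // tiles[1]))
    return equalize_adapthist(g, kernel_size=kernel, clip_limit=clip)


def gamma_correct(gray: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law transform out = in**gamma on a [0, 1] image."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    g = np.asarray(gray, dtype=np.float64)
    return g**gamma


def preprocess(sample: FundusSample, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Full chain: fuse -> normalize -> CLAHE -> gamma, returning [0, 1]."""
    cfg = (cfg or PreprocessConfig()).validate()
    g = fuse_channels(sample.image, cfg.fusion_weights)
    g = normalize(g)
    g = clahe(g, cfg.clahe_clip, cfg.clahe_tiles)
    return gamma_correct(g, cfg.gamma)


def _avg_pool(a: np.ndarray) -> np.ndarray:
    h, w = a.shape
    return a.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def build_pyramid(patch: np.ndarray, origin: tuple[int, int]) -> PatchPyramid:
    l64 = np.asarray(patch, dtype=np.float64)
    if l64.shape != (PATCH, PATCH):
        raise ValueError("pyramid base must be a 64x64 patch")
    l32 = _avg_pool(l64)
    l16 = _avg_pool(l32)
    l8 = _avg_pool(l16)
    return PatchPyramid(l64, l32, l16, l8, origin)


def grid_origins(shape: tuple[int, int], stride: int = 32) -> list[tuple[int, int]]:
    """Origins tiling the image so every pixel is covered at least once."""
    h, w = shape
    rows = list(range(0, h - PATCH + 1, stride))
    cols = list(range(0, w - PATCH + 1, stride))
    if rows[-1] != h - PATCH:
        rows.append(h - PATCH)
    if cols[-1] != w - PATCH:
        cols.append(w - PATCH)
    return [(r, c) for r in rows for c in cols]


def extract_patches(
    gray: np.ndarray,
    vessel_mask: np.ndarray | None = None,
    fov_mask: np.ndarray | None = None,
    n: int = 200,
    mode: str = "random",
    seed: int = 0,
    stride: int = 32,
) -> list[tuple[PatchPyramid, np.ndarray | None]]:
    """Cut (pyramid, label) pairs from an enhanced image.

    ``random`` mode draws ``n`` origins uniformly among positions whose patch
    center lies inside the FOV; ``grid`` mode tiles the image with ``stride``
    so that every pixel is covered at least once.
    """
    g = np.asarray(gray, dtype=np.float64)
    h, w = g.shape
    if h < PATCH or w < PATCH:
        raise ValueError(f"image must be at least {PATCH}x{PATCH}")
    if mode == "grid":
        origins = grid_origins((h, w), stride)
    elif mode == "random":
        fov = np.ones((h, w), dtype=bool) if fov_mask is None else fov_mask.astype(bool)
        half = PATCH // 2
        centers = fov[half : h - PATCH + 1 + half, half : w - PATCH + 1 + half]
        cand = np.argwhere(centers)
        if len(cand) == 0:
            raise ValueError("no candidate patch position has its center inside the FOV")
        rng = np.random.default_rng(seed)
        origins = [tuple(cand[i]) for i in rng.integers(0, len(cand), size=n)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for r, c in origins:
        pyr = build_pyramid(g[r : r + PATCH, c : c + PATCH], (int(r), int(c)))
        label = None
        if vessel_mask is not None:
            label = np.asarray(vessel_mask[r : r + PATCH, c : c + PATCH], dtype=np.float64)
        out.append((pyr, label))
    return out


def stitch(
    patch_probs: list[np.ndarray],
    origins: list[tuple[int, int]],
    size: tuple[int, int],
) -> np.ndarray:
    """Average overlapping 64x64 probability patches into a full-size map."""
    h, w = size
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    for p, (r, c) in zip(patch_probs, origins):
        p = np.asarray(p, dtype=np.float64)
        if p.shape != (PATCH, PATCH):
            raise ValueError("each probability patch must be 64x64")
        acc[r : r + PATCH, c : c + PATCH] += p
        cnt[r : r + PATCH, c : c + PATCH] += 1
    if (cnt == 0).any():
        raise ValueError("patches do not cover the full image")
    return acc / cnt
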