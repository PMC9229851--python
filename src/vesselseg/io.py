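"""Dataset directory layouts and raster I/O.

Synthetic and real data share one on-disk convention so the same loaders
serve both: a DRIVE-style tree with ``images/``, ``mask/`` (field-of-view)
and ``1st_manual/`` (first-expert vessel labels).  Readers are also provided
for CHASE DB1- and STARE-style trees, which differ only in folder names and
file suffixes.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .synthetic import FundusSample

__all__ = ["write_dataset", "read_dataset", "write_probability_png", "write_mask_png"]

_LAYOUTS = {
    "drive": {"images": "images", "fov": "mask", "manual": "1st_manual"},
    "chase": {"images": "images", "fov": "mask", "manual": "1st_label"},
    "stare": {"images": "stare-images", "fov": "mask", "manual": "labels-ah"},
}
_RASTER_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".gif", ".ppm")


def _to_binary(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > arr.max() / 2).astype(np.uint8) if arr.max() > 1 else arr.astype(np.uint8)


def write_dataset(samples: list[FundusSample], root) -> Path:
    """Write samples as a DRIVE-style tree of PNGs; returns the root path."""
    root = Path(root)
    for sub in ("images", "mask", "1st_manual"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    for s in samples:
        iio.imwrite(root / "images" / f"{s.sample_id}.png", s.image)
        iio.imwrite(root / "mask" / f"{s.sample_id}_mask.png", (s.fov_mask * 255).astype(np.uint8))
        iio.imwrite(
            root / "1st_manual" / f"{s.sample_id}_manual1.png",
            (s.vessel_mask * 255).astype(np.uint8),
        )
    return root


def _find_match(folder: Path, stem: str) -> Path | None:
    if not folder.is_dir():
        return None
    rasters = [p for p in folder.iterdir() if p.suffix.lower() in _RASTER_SUFFIXES]
    exact = sorted(p for p in rasters if p.stem.startswith(stem))
    if exact:
        return exact[0]
    # STARE-style names share only the leading token (e.g. im0001.ah.ppm)
    token = stem.split("_")[0].split(".")[0]
    loose = sorted(p for p in rasters if p.stem.split("_")[0].split(".")[0] == token)
    return loose[0] if loose else None


def read_dataset(root, layout: str = "drive") -> list[FundusSample]:
    """Read a dataset tree; FOV masks are optional (default: all ones)."""
    root = Path(root)
    names = _LAYOUTS.get(layout)
    if names is None:
        raise ValueError(f"unknown layout {layout!r}; expected one of {sorted(_LAYOUTS)}")
    image_dir = root / names["images"]
    if not image_dir.is_dir():
        raise FileNotFoundError(f"no image folder {image_dir}")
    samples = []
    for img_path in sorted(image_dir.iterdir()):
        if img_path.suffix.lower() not in _RASTER_SUFFIXES:
            continue
        image = np.asarray(iio.imread(img_path))
        if image.ndim == 2:
            image = np.stack([image] * 3, axis=-1)
        image = image[..., :3]
        stem = img_path.stem
        fov_path = _find_match(root / names["fov"], stem)
        manual_path = _find_match(root / names["manual"], stem)
        fov = (
            _to_binary(np.asarray(iio.imread(fov_path)))
            if fov_path
            else np.ones(image.shape[:2], dtype=np.uint8)
        )
        vessel = (
            _to_binary(np.asarray(iio.imread(manual_path)))
            if manual_path
            else np.zeros(image.shape[:2], dtype=np.uint8)
        )
        samples.append(
            FundusSample(
                image=image.astype(np.uint8),
                fov_mask=fov,
                vessel_mask=(vessel & fov).astype(np.uint8),
                sample_id=stem,
            ).validate()
        )
    if not samples:
        raise FileNotFoundError(f"no raster images found under {image_dir}")
    return samples


def write_probability_png(path, prob_map: np.ndarray):
    """16-bit PNG of a [0, 1] probability map."""
    arr = np.clip(np.asarray(prob_map, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))


def write_mask_png(path, mask: np.ndarray):
    iio.imwrite(Path(path), (np.asarray(mask).astype(np.uint8) * 255))
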