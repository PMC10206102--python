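"""Reading and writing image stacks as directories of PNG/TIFF files."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image", "read_image_stack", "write_image_stack"]

IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def read_image(path) -> np.ndarray:
    img = np.asarray(iio.imread(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    return img.astype(np.uint8)


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_image_stack(directory) -> np.ndarray:
    """Load all PNG/TIFF files in a directory, sorted by filename."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in IMAGE_SUFFIXES)
    if not files:
        raise FileNotFoundError(f"no images found in {directory}")
    return np.stack([read_image(p) for p in files])


def write_image_stack(directory, stack: np.ndarray, prefix: str = "frame") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(stack) - 1)))
    for i, frame in enumerate(stack):
        write_image(directory / f"{prefix}_{i:0{width}d}.png", frame)
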