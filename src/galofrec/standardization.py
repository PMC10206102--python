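"""Pixel-wise histogram specification (equalization against a reference).

Each pixel of the registered fiber-output stack sees, over many frames, the
same object statistics as any pixel of the reference objects. Matching the
pixel's empirical CDF to the pooled reference CDF therefore inverts the
pixel's unknown monotone transfer curve up to quantization. The result is a
per-pixel, per-channel 256-entry look-up table (LUT). Pixels that carry no
usable signal — stack maximum below 10 or standard deviation below 2 — are
flagged defective and their LUT maps everything to 0, to be inpainted later.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PixelHistogramStack",
    "ReferenceDistribution",
    "LUTSet",
    "accumulate_pixel_histograms",
    "pooled_reference_histogram",
    "match_cdf",
    "build_lut_set",
    "apply_lut_set",
]

MAX_THRESHOLD = 10.0
STD_THRESHOLD = 2.0


@dataclass
class PixelHistogramStack:
    """Per-pixel per-channel 256-bin value counts over a registered stack.

    ``counts`` has shape ``(H, W, 3, 256)``; every histogram sums to
    ``n_frames``.
    """

    counts: np.ndarray
    n_frames: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]


@dataclass
class ReferenceDistribution:
    """Pooled per-channel PMF/CDF of the reference objects, ``(3, 256)``."""

    pmf: np.ndarray
    cdf: np.ndarray


@dataclass
class LUTSet:
    """The calibrated standardization transform.

    ``lut`` is ``(H, W, 3, 256)`` uint8; ``defective`` is ``(H, W, 3)`` bool.
    Non-defective LUTs are monotone non-decreasing; defective LUTs are all
    zero.
    """

    lut: np.ndarray
    defective: np.ndarray
    thresholds: tuple[float, float] = (MAX_THRESHOLD, STD_THRESHOLD)
    n_frames: int = 0


def accumulate_pixel_histograms(stack: np.ndarray) -> PixelHistogramStack:
    """Count, per pixel/channel, the occurrences of each 8-bit value."""
    stack = np.asarray(stack)
    if stack.ndim != 4 or len(stack) == 0 or stack.dtype != np.uint8:
        raise ValueError("expected a non-empty uint8 (N, H, W, 3) stack")
    n, h, w, c = stack.shape
    n_cells = h * w * c
    counts = np.zeros(n_cells * 256, dtype=np.int64)
    base = np.arange(n_cells, dtype=np.int64) * 256
    # chunked bincount keeps the index buffer modest for 1000-frame stacks
    chunk = max(1, int(2**26 // n_cells))
    for start in range(0, n, chunk):
        vals = stack[start:start + chunk].reshape(-1, n_cells).astype(np.int64)
        counts += np.bincount((base[None, :] + vals).ravel(), minlength=n_cells * 256)
    return PixelHistogramStack(counts.reshape(h, w, c, 256), n_frames=n)


def pooled_reference_histogram(references: np.ndarray) -> ReferenceDistribution:
    """Pool all pixels of all reference frames into one PMF/CDF per channel."""
    references = np.asarray(references)
    if references.ndim != 4 or len(references) == 0:
        raise ValueError("expected a non-empty (N, H, W, 3) stack")
    pmf = np.empty((3, 256), dtype=np.float64)
    cdf = np.empty((3, 256), dtype=np.float64)
    for ch in range(3):
        counts = np.bincount(references[..., ch].ravel(), minlength=256)
        total = counts.sum()
        pmf[ch] = counts / total
        cdf[ch] = counts.cumsum() / total
    return ReferenceDistribution(pmf=pmf, cdf=cdf)


def match_cdf(pixel_cdf: np.ndarray, reference_cdf: np.ndarray) -> np.ndarray:
    """Histogram-specification LUT: smallest v with reference_cdf[v] >= pixel_cdf[u].

    Accepts a single 256-vector or a batch ``(..., 256)`` of pixel CDFs against
    one reference CDF. The result is monotone non-decreasing because both CDFs
    are.
    """
    pixel_cdf = np.asarray(pixel_cdf, dtype=np.float64)
    reference_cdf = np.asarray(reference_cdf, dtype=np.float64)
    if pixel_cdf.shape[-1] != 256 or reference_cdf.shape != (256,):
        raise ValueError("CDFs must have 256 entries")
    # both CDFs end at 1 up to float rounding; clamp so the top bin matches
    pixel_cdf = np.minimum(pixel_cdf, reference_cdf[-1])
    lut = np.searchsorted(reference_cdf, pixel_cdf, side="left")
    return np.minimum(lut, 255).astype(np.uint8)


def build_lut_set(histos: PixelHistogramStack,
                  reference: ReferenceDistribution,
                  max_threshold: float = MAX_THRESHOLD,
                  std_threshold: float = STD_THRESHOLD) -> LUTSet:
    """Build the per-pixel LUTs, zeroing defective pixels.

    A pixel/channel is defective when its stack maximum is below
    ``max_threshold`` or the population standard deviation of its stack values
    is below ``std_threshold`` (each channel judged independently).
    """
    counts = histos.counts
    n = histos.n_frames
    h, w, c, _ = counts.shape
    values = np.arange(256, dtype=np.float64)

    nonzero = counts > 0
    max_obs = 255 - np.argmax(nonzero[..., ::-1], axis=-1)
    mean = counts @ values / n
    second = counts @ (values * values) / n
    std = np.sqrt(np.maximum(second - mean * mean, 0.0))
    defective = (max_obs < max_threshold) | (std < std_threshold)

    pixel_cdf = counts.cumsum(axis=-1) / n
    lut = np.empty((h, w, c, 256), dtype=np.uint8)
    for ch in range(c):
        lut[:, :, ch] = match_cdf(pixel_cdf[:, :, ch], reference.cdf[ch])
    lut[defective] = 0
    return LUTSet(lut=lut, defective=defective,
                  thresholds=(max_threshold, std_threshold), n_frames=n)


def apply_lut_set(image: np.ndarray, luts: LUTSet) -> np.ndarray:
    """Map every pixel value through its own LUT: out[p, c] = lut[p, c][in[p, c]]."""
    image = np.asarray(image)
    if image.shape != luts.lut.shape[:3]:
        raise ValueError(
            f"image shape {image.shape} does not match LUTSet {luts.lut.shape[:3]}")
    idx = image.astype(np.intp)[..., None]
    return np.take_along_axis(luts.lut, idx, axis=-1)[..., 0]
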