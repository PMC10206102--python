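"""Translation-only intensity-based registration of fiber output frames.

The fiber's static mode pattern (pixel-scale gain texture and dark defects)
is common to every frame, so cross-correlating grayscale frames recovers the
mechanical drift even though each frame carries a different unknown object.
Translations are integer-valued: the downstream look-up tables are defined
per discrete pixel, and subpixel resampling would smear per-pixel statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .synthetic import translate_image

__all__ = [
    "Translation",
    "to_grayscale",
    "estimate_translation",
    "apply_translation",
    "register_stack",
    "fill_mask",
]

#: Rec. 601 luma weights used for the RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class Translation:
    dx: int
    dy: int

    def __neg__(self) -> "Translation":
        return Translation(-self.dx, -self.dy)

    def as_tuple(self) -> tuple[int, int]:
        return (self.dx, self.dy)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luma (0.299 R + 0.587 G + 0.114 B), rounded half-up to uint8."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    w = np.asarray(LUMA_WEIGHTS, dtype=np.float64)
    gray = image.astype(np.float64) @ w
    return np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)


def apply_translation(image: np.ndarray, translation: Translation) -> np.ndarray:
    """Shift an image by (dx, dy) with zero fill outside the source."""
    return translate_image(np.asarray(image), translation.dx, translation.dy)


def fill_mask(shape: tuple[int, int], translation: Translation) -> np.ndarray:
    """Boolean (H, W) mask of pixels with no source data after the shift."""
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    dx, dy = translation.dx, translation.dy
    if dy > 0:
        mask[:dy, :] = True
    elif dy < 0:
        mask[dy:, :] = True
    if dx > 0:
        mask[:, :dx] = True
    elif dx < 0:
        mask[:, dx:] = True
    return mask


def _overlap_views(fixed: np.ndarray, moving: np.ndarray, dx: int, dy: int):
    h, w = fixed.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    return fixed[ys, xs], moving[ys_src, xs_src]


def estimate_translation(moving: np.ndarray, fixed: np.ndarray,
                         max_shift: int = 10,
                         highpass_sigma: float = 1.5) -> Translation:
    """Integer translation aligning ``moving`` onto ``fixed``.

    Scores every (dx, dy) in the +/- ``max_shift`` window with the zero-mean
    cross-correlation over the valid overlap region, normalized by the overlap
    area (covariance per pixel), so the zero fill never enters the score.
    Both images are high-pass filtered first (Gaussian background of scale
    ``highpass_sigma`` subtracted; 0 disables): drift must be read off the
    static pixel-scale fiber pattern, and the filter suppresses the slowly
    varying object content that differs from frame to frame. Ties go to the
    smallest |dx| + |dy|, then lexicographically on (dx, dy). A constant fixed
    image is degenerate: a warning is issued and (0, 0) returned.
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must have equal shapes")
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if np.ptp(fixed) == 0:
        warnings.warn("fixed image is constant; registration is degenerate",
                      RuntimeWarning, stacklevel=2)
        return Translation(0, 0)
    if highpass_sigma > 0:
        moving = moving - gaussian_filter(moving, highpass_sigma)
        fixed = fixed - gaussian_filter(fixed, highpass_sigma)

    candidates = [(abs(dx) + abs(dy), dx, dy)
                  for dx in range(-max_shift, max_shift + 1)
                  for dy in range(-max_shift, max_shift + 1)]
    candidates.sort()  # tie-break order: |dx|+|dy|, then (dx, dy)
    best_score = -np.inf
    best = Translation(0, 0)
    for _, dx, dy in candidates:
        a, b = _overlap_views(fixed, moving, dx, dy)
        if a.size == 0:
            continue
        score = float(np.mean(a * b) - a.mean() * b.mean())
        if score > best_score:
            best_score = score
            best = Translation(dx, dy)
    return best


def register_stack(stack: np.ndarray, reference_index: int = 0,
                   max_shift: int = 10) -> tuple[np.ndarray, list[Translation]]:
    """Align every frame of a stack to an arbitrarily chosen reference frame.

    Returns the registered stack (zero fill outside the source frames) and the
    per-frame translations, which are reused at test time.
    """
    stack = np.asarray(stack)
    if stack.ndim != 4 or len(stack) == 0:
        raise ValueError("expected a non-empty (N, H, W, 3) stack")
    if not (0 <= reference_index < len(stack)):
        raise ValueError("reference_index out of range")
    reference_gray = to_grayscale(stack[reference_index])
    registered = np.empty_like(stack)
    translations: list[Translation] = []
    for i, frame in enumerate(stack):
        t = estimate_translation(to_grayscale(frame), reference_gray, max_shift)
        translations.append(t)
        registered[i] = apply_translation(frame, t)
    return registered, translations
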