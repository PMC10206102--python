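"""Synthetic objects and a GALOF forward model.

A glass-air Anderson-localizing optical fiber (GALOF) transports an image
nearly point-to-point: each output pixel is a monotone, pixel-specific
distortion of the corresponding object pixel, with a population of defective
(dark, static) pixels, small mechanical drift between frames, defocus blur at
non-zero working distance, and optional illumination/noise stress regimes.
This module emulates exactly that, so the whole calibrate/reconstruct/evaluate
cycle can run without experimental data.

Images are ``numpy`` arrays of shape ``(H, W, 3)`` dtype ``uint8``; stacks are
``(N, H, W, 3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "ObjectSpec",
    "FiberParams",
    "FiberModel",
    "generate_objects",
    "sample_fiber_model",
    "transmit",
]

# Bright-field stained-cell palette: erythrocyte reds/pinks plus darker
# basophilic (nuclear) purples, on a pale background.
DEFAULT_PALETTE = (
    (183, 58, 56),
    (199, 93, 89),
    (214, 130, 121),
    (148, 33, 106),
    (114, 52, 138),
    (96, 78, 158),
)
DEFAULT_BACKGROUND = (231, 227, 219)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Quantize to uint8 with round-half-up (not banker's rounding)."""
    return np.clip(np.floor(np.asarray(x, dtype=np.float64) + 0.5), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class ObjectSpec:
    """Parameters of the synthetic cell-like object generator.

    Cells are anti-aliased filled ellipses with random centers, semi-axes,
    orientations and palette colors, composited over a uniform background,
    plus per-pixel Gaussian texture noise. With equal seeds generation is
    bit-identical.
    """

    image_size: int = 128
    cell_count_range: tuple[int, int] = (4, 12)
    cell_axes_range: tuple[float, float] = (6.0, 16.0)
    cell_color_palette: tuple[tuple[int, int, int], ...] = DEFAULT_PALETTE
    background_color: tuple[int, int, int] = DEFAULT_BACKGROUND
    texture_noise_sd: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not self.cell_color_palette:
            raise ValueError("cell_color_palette must not be empty")
        for color in tuple(self.cell_color_palette) + (tuple(self.background_color),):
            if any(not (0 <= int(v) <= 255) for v in color):
                raise ValueError("palette values must lie in [0, 255]")
        lo, hi = self.cell_count_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid cell_count_range")
        lo, hi = self.cell_axes_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid cell_axes_range")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be >= 0")


def _draw_ellipse(canvas: np.ndarray, cy: float, cx: float, a: float, b: float,
                  theta: float, color: np.ndarray) -> None:
    """Alpha-composite an anti-aliased filled ellipse onto ``canvas`` (float)."""
    size = canvas.shape[0]
    r = int(np.ceil(max(a, b))) + 2
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, size)
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, size)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dx + st * dy) / a
    v = (-st * dx + ct * dy) / b
    rho = np.sqrt(u * u + v * v)
    # ~1 px soft edge: alpha falls from 1 inside to 0 outside across the rim.
    alpha = np.clip((1.0 - rho) * min(a, b) + 0.5, 0.0, 1.0)
    patch = canvas[y0:y1, x0:x1]
    patch += alpha[..., None] * (color[None, None, :] - patch)


def generate_objects(spec: ObjectSpec, n: int) -> np.ndarray:
    """Generate ``n`` synthetic object images.

    Cells are placed uniformly at random over the frame so that, across a
    long stack, every pixel position samples the full object statistics —
    the ergodicity the per-pixel calibration relies on.
    """
    spec.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    palette = np.asarray(spec.cell_color_palette, dtype=np.float64)
    background = np.asarray(spec.background_color, dtype=np.float64)
    lo_n, hi_n = spec.cell_count_range
    lo_ax, hi_ax = spec.cell_axes_range
    stack = np.empty((n, size, size, 3), dtype=np.uint8)
    for i in range(n):
        canvas = np.tile(background, (size, size, 1))
        k = int(rng.integers(lo_n, hi_n + 1))
        for _ in range(k):
            cy, cx = rng.uniform(0, size, size=2)
            a, b = rng.uniform(lo_ax, hi_ax, size=2)
            theta = rng.uniform(0, np.pi)
            color = palette[rng.integers(len(palette))]
            _draw_ellipse(canvas, cy, cx, a, b, theta, color)
        if spec.texture_noise_sd > 0:
            canvas += rng.normal(0.0, spec.texture_noise_sd, size=canvas.shape)
        stack[i] = _round_half_up(canvas)
    return stack


@dataclass(frozen=True)
class FiberParams:
    """Forward-model settings for :func:`sample_fiber_model`.

    ``gamma_range``/``gain ranges`` parameterize the per-pixel monotone
    transfer curves ``255 * gain * (u/255)**gamma``; ``identity_curves``
    forces gamma = gain = 1 everywhere.
    """

    defect_fraction: float = 0.05
    drift_max: int = 3
    n_frames: int = 1200
    blur_sigma: float = 0.0
    visibility: float = 1.0
    noise_variance: float = 0.0
    uneven_illumination: bool = False
    gamma_range: tuple[float, float] = (0.7, 1.4)
    gain_smooth_range: tuple[float, float] = (0.7, 1.0)
    gain_fine_range: tuple[float, float] = (0.35, 1.0)
    identity_curves: bool = False

    def validate(self) -> None:
        if not (0.0 <= self.defect_fraction < 1.0):
            raise ValueError("defect_fraction must lie in [0, 1)")
        if not (0.0 < self.visibility <= 1.0):
            raise ValueError("visibility must lie in (0, 1]")
        if self.drift_max < 0 or self.n_frames < 1:
            raise ValueError("invalid drift/frame settings")
        if self.blur_sigma < 0 or self.noise_variance < 0:
            raise ValueError("blur_sigma and noise_variance must be >= 0")


@dataclass
class FiberModel:
    """A sampled GALOF forward model.

    ``gamma``/``gain`` are ``(H, W, 3)`` float fields defining the per-pixel
    monotone transfer curves; ``defect_mask`` is ``(H, W, 3)`` boolean with
    static ``defect_values`` in [0, 9]; ``drift_schedule`` is ``(n_frames, 2)``
    integer ``(dx, dy)`` with entry 0 fixed at (0, 0).
    """

    image_size: int
    gamma: np.ndarray
    gain: np.ndarray
    defect_mask: np.ndarray
    defect_values: np.ndarray
    defect_fraction: float
    drift_schedule: np.ndarray
    blur_sigma: float
    illumination_field: np.ndarray | None
    visibility: float
    noise_variance: float
    seed: int
    params: FiberParams = field(default_factory=FiberParams)

    @property
    def transfer_luts(self) -> np.ndarray:
        """Per-pixel per-channel 256-entry curves, ``(H, W, 3, 256)`` uint8.

        Monotone non-decreasing by construction (positive gain and exponent).
        """
        u = np.arange(256, dtype=np.float64) / 255.0
        curves = 255.0 * self.gain[..., None] * u[None, None, None, :] ** self.gamma[..., None]
        return _round_half_up(curves)

    def apply_curves(self, x: np.ndarray) -> np.ndarray:
        """Apply the continuous transfer curves to a float image in [0, 255]."""
        xn = np.clip(np.asarray(x, dtype=np.float64), 0.0, 255.0) / 255.0
        return 255.0 * self.gain * xn**self.gamma


def _smooth_field(rng: np.random.Generator, size: int, sigma: float,
                  lo: float, hi: float) -> np.ndarray:
    """Smooth random field mapped to [lo, hi] per channel, ``(size, size, 3)``."""
    noise = rng.standard_normal((size, size, 3))
    sm = np.stack([gaussian_filter(noise[..., c], sigma, mode="reflect")
                   for c in range(3)], axis=-1)
    mn = sm.min(axis=(0, 1), keepdims=True)
    mx = sm.max(axis=(0, 1), keepdims=True)
    span = np.where(mx - mn > 0, mx - mn, 1.0)
    return lo + (hi - lo) * (sm - mn) / span


def sample_fiber_model(image_size: int, params: FiberParams | None = None,
                       seed: int = 0) -> FiberModel:
    """Draw a random fiber model.

    Transfer curves are gamma-family, ``255 * gain * (u/255)**gamma``, with the
    exponent drawn from a smooth spatial field and the gain from the product of
    a smooth field (slow mode-loss variation) and a fine-grained field (the
    pixel-scale static mode pattern that registration locks onto).
    """
    params = params or FiberParams()
    params.validate()
    rng = np.random.default_rng(seed)
    if params.identity_curves:
        gamma = np.ones((image_size, image_size, 3))
        gain = np.ones((image_size, image_size, 3))
    else:
        g_lo, g_hi = params.gamma_range
        gamma = _smooth_field(rng, image_size, image_size / 8.0, g_lo, g_hi)
        gain = _smooth_field(rng, image_size, image_size / 8.0, *params.gain_smooth_range)
        gain = gain * _smooth_field(rng, image_size, 1.0, *params.gain_fine_range)
    defect_mask = rng.random((image_size, image_size, 3)) < params.defect_fraction
    defect_values = rng.integers(0, 10, size=(image_size, image_size, 3)).astype(np.uint8)
    drift = rng.integers(-params.drift_max, params.drift_max + 1,
                         size=(params.n_frames, 2)) if params.drift_max > 0 else \
        np.zeros((params.n_frames, 2), dtype=np.int64)
    drift[0] = 0  # drift is measured relative to the first frame
    illum = None
    if params.uneven_illumination:
        illum = _smooth_field(rng, image_size, image_size / 4.0, 0.4, 1.0)
    return FiberModel(
        image_size=image_size, gamma=gamma, gain=gain,
        defect_mask=defect_mask, defect_values=defect_values,
        defect_fraction=params.defect_fraction, drift_schedule=np.asarray(drift),
        blur_sigma=params.blur_sigma, illumination_field=illum,
        visibility=params.visibility, noise_variance=params.noise_variance,
        seed=seed, params=params,
    )


def translate_image(image: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Shift right by ``dx`` and down by ``dy`` with zero fill."""
    out = np.zeros_like(image)
    h, w = image.shape[:2]
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = image[ys_src, xs_src]
    return out


def transmit(obj: np.ndarray, model: FiberModel, frame_index: int = 0) -> np.ndarray:
    """Push an object image through the fiber model for one frame.

    Order of operations: defocus blur, illumination and visibility scaling,
    per-pixel transfer curves, defect forcing (< 10), additive Gaussian noise,
    the frame's drift translation, clip, round-half-up quantization.
    """
    obj = np.asarray(obj)
    if obj.shape != (model.image_size, model.image_size, 3):
        raise ValueError(
            f"object shape {obj.shape} does not match model size {model.image_size}")
    x = obj.astype(np.float64)
    if model.blur_sigma > 0:
        x = np.stack([gaussian_filter(x[..., c], model.blur_sigma, mode="reflect")
                      for c in range(3)], axis=-1)
    if model.illumination_field is not None:
        x = x * model.illumination_field
    x = x * model.visibility
    x = model.apply_curves(x)
    x[model.defect_mask] = model.defect_values[model.defect_mask]
    if model.noise_variance > 0:
        noise_rng = np.random.default_rng([model.seed, 7919, int(frame_index)])
        x = x + noise_rng.normal(0.0, np.sqrt(model.noise_variance), size=x.shape)
    dx, dy = (int(v) for v in model.drift_schedule[frame_index])
    x = translate_image(x, dx, dy)
    return _round_half_up(x)


def transmit_stack(objects: np.ndarray, model: FiberModel,
                   first_frame: int = 0) -> np.ndarray:
    """Transmit a whole object stack; frame ``i`` uses drift entry
    ``first_frame + i``."""
    return np.stack([transmit(objects[i], model, first_frame + i)
                     for i in range(len(objects))])
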