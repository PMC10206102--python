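"""Harmonic region fill for defective pixels.

Pixels flagged defective by the standardization step (values below a
threshold after the LUTs, default 10) are filled per channel by interpolating
inward from the values on the outer boundary of each region: the filled values
solve the discrete Laplace equation with 4-neighbor connectivity and Dirichlet
data from the boundary pixels. At the image border only in-image neighbors are
used (a Neumann condition). Arithmetic is floating point throughout; the
result is quantized to 8 bits once, at the end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

__all__ = ["DefectMask", "make_defect_mask", "harmonic_fill", "inpaint"]

DEFAULT_THRESHOLD = 10


@dataclass
class DefectMask:
    """Boolean per-pixel mask of one channel; True marks pixels to fill."""

    mask: np.ndarray
    source_threshold: float = DEFAULT_THRESHOLD


def make_defect_mask(channel: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> DefectMask:
    """Mask true exactly where the channel value is below ``threshold``."""
    channel = np.asarray(channel)
    if channel.ndim != 2:
        raise ValueError("expected a single-channel (H, W) image")
    return DefectMask(mask=channel < threshold, source_threshold=threshold)


def harmonic_fill(channel: np.ndarray, mask: DefectMask | np.ndarray) -> np.ndarray:
    """Fill masked pixels with the discrete harmonic extension of the boundary.

    Each filled value equals the mean of its available 4-neighbors; the linear
    system is solved exactly (sparse direct solve). Unmasked pixels are
    returned unchanged. Raises ``ValueError`` if every pixel is masked.
    """
    m = mask.mask if isinstance(mask, DefectMask) else np.asarray(mask, dtype=bool)
    channel = np.asarray(channel, dtype=np.float64)
    if channel.shape != m.shape:
        raise ValueError("channel and mask shapes differ")
    if m.all():
        raise ValueError("degenerate fill: mask covers the entire image")
    if not m.any():
        return channel.copy()

    h, w = channel.shape
    idx = -np.ones((h, w), dtype=np.int64)
    ys, xs = np.nonzero(m)
    n_unknown = len(ys)
    idx[ys, xs] = np.arange(n_unknown)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    data: list[np.ndarray] = []
    rhs = np.zeros(n_unknown)
    degree = np.zeros(n_unknown)
    eye = np.arange(n_unknown)

    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ny, nx = ys + dy, xs + dx
        valid = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        degree += valid
        nm = np.zeros(n_unknown, dtype=bool)
        nm[valid] = m[ny[valid], nx[valid]]
        coupled = valid & nm
        rows.append(eye[coupled])
        cols.append(idx[ny[coupled], nx[coupled]])
        data.append(-np.ones(coupled.sum()))
        dirichlet = valid & ~nm
        np.add.at(rhs, eye[dirichlet], channel[ny[dirichlet], nx[dirichlet]])

    rows.append(eye)
    cols.append(eye)
    data.append(degree)
    system = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unknown, n_unknown))
    solution = spsolve(system, rhs)

    out = channel.copy()
    out[ys, xs] = solution
    return out


def inpaint(image: np.ndarray, threshold: float = DEFAULT_THRESHOLD,
            extra_mask: np.ndarray | None = None,
            on_full_mask: str = "raise") -> np.ndarray:
    """Fill sub-threshold pixels of each RGB channel independently.

    ``extra_mask`` (boolean, (H, W)) optionally adds pixels known to carry no
    data — e.g. the zero-fill border introduced by registration — to every
    channel's mask. A channel that is masked everywhere has no boundary to
    interpolate from; ``on_full_mask`` selects the degenerate-fill policy:
    ``"raise"`` (default) or ``"zero"`` (the whole channel carries no signal,
    as happens in extreme low-light regimes, and is zeroed like any other
    defective region).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if on_full_mask not in ("raise", "zero"):
        raise ValueError("on_full_mask must be 'raise' or 'zero'")
    out = np.empty(image.shape, dtype=np.uint8)
    for ch in range(3):
        channel = image[..., ch]
        m = make_defect_mask(channel, threshold).mask
        if extra_mask is not None:
            m = m | extra_mask
        if m.all() and on_full_mask == "zero":
            out[..., ch] = 0
            continue
        filled = harmonic_fill(channel, m)
        out[..., ch] = np.clip(np.floor(filled + 0.5), 0, 255).astype(np.uint8)
    return out
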