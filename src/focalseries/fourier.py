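"""Small Fourier-layout helpers shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["friedel_mate", "pad_with_mean"]


def friedel_mate(a: np.ndarray) -> np.ndarray:
    """conj(a(−k)) for the trailing two axes of an FFT-layout array."""
    flipped = a[..., ::-1, ::-1]
    return np.conj(np.roll(flipped, 1, axis=(-2, -1)))


def pad_with_mean(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Embed ``image`` centrally in an array of ``shape`` filled with its mean."""
    ny, nx = image.shape
    py, px = shape
    if py < ny or px < nx:
        raise ValueError(f"target shape {shape} smaller than image {image.shape}")
    out = np.full(shape, image.mean(), dtype=image.dtype)
    oy, ox = (py - ny) // 2, (px - nx) // 2
    out[oy : oy + ny, ox : ox + nx] = image
    return out
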