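"""Nonlocal-means filtering of the enhanced likeness map.

Each output pixel is a weighted average over a square search window, with
weights from patch-intensity similarity:

    NL(i) = sum_{j in N(i)} w(i, j) VL(j),
    w(i, j) = exp(-||v(N_i) - v(N_j)||^2 / h^2) / Z(i),

where ``v(N_i)`` is the patch of pixel values around i, ||.||^2 the plain
sum of squared differences over the patch, ``h`` the filtering strength,
and Z(i) normalizes the weights to sum to 1 (the center j = i contributes
weight 1 before normalization).  Because the output is a convex combination
of window values, structure edges survive while uncorrelated noise averages
out.

Boundary handling: the image is reflect-padded by ``search_radius +
patch_radius``; search windows and similarity patches near the border read
from the reflected extension.  The implementation accumulates one shifted
SSD map per window offset (a box filter of the squared difference image),
exactly equivalent to the quadruple-loop definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage

from .io_fixtures import Image2D


@dataclass(frozen=True)
class NlmParams:
    """Search window half-size, similarity patch half-size, and strength h.

    ``h`` is in intensity units; a practical default is about 10x the noise
    standard deviation of the map being filtered.
    """

    search_radius: int = 7
    patch_radius: int = 2
    h: float = 0.1

    def __post_init__(self) -> None:
        if not (self.search_radius >= self.patch_radius >= 0):
            raise ValueError("need search_radius >= patch_radius >= 0")
        if self.h <= 0:
            raise ValueError("h must be positive")


def nlm_weight(patch_i: np.ndarray, patch_j: np.ndarray, h: float) -> float:
    """Unnormalized similarity weight exp(-SSD/h^2) between two patches."""
    patch_i = np.asarray(patch_i, dtype=np.float64)
    patch_j = np.asarray(patch_j, dtype=np.float64)
    if patch_i.shape != patch_j.shape:
        raise ValueError(
            f"patch shapes differ: {patch_i.shape} vs {patch_j.shape}")
    if h <= 0:
        raise ValueError("h must be positive")
    ssd = float(np.sum((patch_i - patch_j) ** 2))
    return float(np.exp(-ssd / h**2))


def estimate_noise_sigma(pixels: np.ndarray) -> float:
    """Robust noise-sd estimate via the median absolute deviation of the
    diagonal Laplacian pseudo-residual (immune to smooth structure)."""
    pixels = np.asarray(pixels, dtype=np.float64)
    resid = (pixels[:-1, :-1] - pixels[:-1, 1:]
             - pixels[1:, :-1] + pixels[1:, 1:]) / 2.0
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(1.4826 * mad)


def nlm_denoise(image: Union[Image2D, np.ndarray],
                params: NlmParams) -> np.ndarray:
    """Nonlocal-means filter; returns the denoised array.

    Per pixel the normalized weights sum to 1, so the output at each pixel
    lies within the [min, max] of the (padded) search window — a convex
    combination; a constant image is a fixed point.
    """
    pixels = image.pixels if isinstance(image, Image2D) else np.asarray(
        image, dtype=np.float64)
    R, P, h = params.search_radius, params.patch_radius, params.h
    pad = R + P
    padded = np.pad(pixels, pad, mode="reflect")
    H, W = pixels.shape
    patch_size = 2 * P + 1

    num = np.zeros((H, W), dtype=np.float64)
    den = np.zeros((H, W), dtype=np.float64)
    base = padded[pad - P: pad + P + H, pad - P: pad + P + W]
    for dr in range(-R, R + 1):
        for dc in range(-R, R + 1):
            shifted = padded[pad + dr - P: pad + dr + P + H,
                             pad + dc - P: pad + dc + P + W]
            sq = (base - shifted) ** 2
            # box sum over the (2P+1)^2 patch = mean * count
            ssd = ndimage.uniform_filter(sq, size=patch_size,
                                         mode="constant")[P:P + H, P:P + W]
            ssd *= patch_size**2
            wmap = np.exp(-ssd / h**2)
            values = padded[pad + dr: pad + dr + H, pad + dc: pad + dc + W]
            num += wmap * values
            den += wmap
    return num / den
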