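"""Multiscale Hessian vessel-likeness enhancement.

Tubular structures are detected from the eigenvalues of the scale-space
Hessian: at a pixel on an ideal tube, |lambda1| ~ 0 << |lambda2| (weak
curvature along the vessel, strong curvature across it).  The per-scale
vessel-likeness function is

    V(s) = |l1|^2 * exp(|c - |l1|/sqrt(l1^2+l2^2)|)
         + |l2|^2 * exp(||l2|/sqrt(l1^2+l2^2) - c|)

with c = sqrt(2)/2, an anisotropy set-point: the exponents vanish when the
eigenvalue magnitudes are balanced (|l1| = |l2|) and grow as the pair
becomes tube-like, while the quadratic factors reward structure strength.
The enhanced image VL(X) is the maximum of V(s) over a scale list, and the
argmax scale map s(p) tracks vessel half-width (wide vessels peak at large
scales).  Flat regions (l1 = l2 = 0) are assigned V = 0 by convention.

V(s) as defined carries no sign test on lambda2, so it responds to both
dark and bright ridges; ``dark_only=True`` restricts the response to
lambda2 > 0 (dark vessels on a bright background, the fundus polarity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import ndimage

from .io_fixtures import Image2D

#: Default anisotropy constant of the likeness function.
DEFAULT_C = float(np.sqrt(2.0) / 2.0)

#: Default scale list (pixels), covering fundus vessel half-widths.
DEFAULT_SCALES = (1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0)


@dataclass
class HessianField:
    """Scale-normalized second derivatives and ordered eigenvalues.

    ``lambda1``/``lambda2`` are ordered by magnitude, |lambda1| <=
    |lambda2|, at every pixel; their sum equals Ixx + Iyy (trace).
    """

    scale: float
    Ixx: np.ndarray
    Ixy: np.ndarray
    Iyy: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray


@dataclass
class ScaleSpaceResult:
    """Multiscale maximum likeness ``vl`` and per-pixel argmax ``opt_scale``
    over the searched ``scales`` (smallest scale wins ties)."""

    vl: np.ndarray
    opt_scale: np.ndarray
    scales: tuple[float, ...]


def _as_pixels(image: Union[Image2D, np.ndarray]) -> np.ndarray:
    if isinstance(image, Image2D):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def compute_hessian(image: Union[Image2D, np.ndarray], s: float,
                    gamma: float = 2.0) -> HessianField:
    """Gaussian-derivative Hessian at scale ``s`` with s^gamma normalization.

    Second derivatives are Gaussian-derivative convolutions at standard
    deviation ``s`` (reflective boundaries), each multiplied by ``s**gamma``
    so responses are comparable across scales.  Eigenvalues of the
    symmetric 2x2 matrix are computed in closed form per pixel and ordered
    by absolute value.
    """
    if s <= 0:
        raise ValueError(f"scale must be positive, got {s}")
    pixels = _as_pixels(image)
    # the sampled derivative kernels do not annihilate constants exactly
    # (their sum is ~1e-4 off zero); removing the DC component first makes
    # flat regions and intensity offsets exactly neutral
    pixels = pixels - pixels.mean()
    norm = float(s) ** gamma
    # order=(d_row, d_col): axis 0 is the row (y) axis, axis 1 the column (x)
    Iyy = ndimage.gaussian_filter(pixels, s, order=(2, 0), mode="reflect") * norm
    Ixy = ndimage.gaussian_filter(pixels, s, order=(1, 1), mode="reflect") * norm
    Ixx = ndimage.gaussian_filter(pixels, s, order=(0, 2), mode="reflect") * norm

    # closed-form eigenvalues of [[Ixx, Ixy], [Ixy, Iyy]]
    half_trace = 0.5 * (Ixx + Iyy)
    root = np.sqrt((0.5 * (Ixx - Iyy)) ** 2 + Ixy**2)
    mu_hi = half_trace + root
    mu_lo = half_trace - root
    swap = np.abs(mu_hi) < np.abs(mu_lo)
    lambda2 = np.where(swap, mu_lo, mu_hi)
    lambda1 = np.where(swap, mu_hi, mu_lo)
    return HessianField(scale=float(s), Ixx=Ixx, Ixy=Ixy, Iyy=Iyy,
                        lambda1=lambda1, lambda2=lambda2)


def vessel_likeness(lambda1, lambda2, c: float = DEFAULT_C,
                    dark_only: bool = False, flat_eps: float = 1e-12):
    """The per-scale vessel-likeness V for eigenvalues ordered by magnitude.

    Evaluates the two-term exponential form exactly as defined in the
    module docstring; the degenerate case lambda1 = lambda2 = 0 returns 0
    (a flat patch is maximally non-vessel).  Eigenvalue norms below
    ``flat_eps`` — double-precision noise on unit-range images — count as
    that degenerate flat case.  Accepts scalars or arrays.

    With ``dark_only`` the response is zeroed where lambda2 <= 0, keeping
    only dark-ridge responses.
    """
    if c <= 0:
        raise ValueError(f"c must be positive, got {c}")
    l1 = np.asarray(lambda1, dtype=np.float64)
    l2 = np.asarray(lambda2, dtype=np.float64)
    a1 = np.abs(l1)
    a2 = np.abs(l2)
    norm = np.sqrt(l1 * l1 + l2 * l2)
    degenerate = norm <= flat_eps
    safe_norm = np.where(degenerate, 1.0, norm)
    v = (a1**2 * np.exp(np.abs(c - a1 / safe_norm))
         + a2**2 * np.exp(np.abs(a2 / safe_norm - c)))
    v = np.where(degenerate, 0.0, v)
    if dark_only:
        v = np.where(l2 > 0.0, v, 0.0)
    if np.isscalar(lambda1) and np.isscalar(lambda2):
        return float(v)
    return v


def multiscale_enhance(image: Union[Image2D, np.ndarray],
                       scales: Sequence[float] = DEFAULT_SCALES,
                       c: float = DEFAULT_C,
                       gamma: float = 2.0,
                       dark_only: bool = False) -> ScaleSpaceResult:
    """Maximum vessel likeness over a scale sweep, with the argmax scale.

    ``scales`` must be nonempty, strictly increasing and positive.  Ties in
    the maximum are resolved to the smallest scale, which stabilizes the
    optimal-scale map on plateaus (flat regions score 0 at every scale).
    """
    scales = tuple(float(s) for s in scales)
    if len(scales) == 0:
        raise ValueError("scale list must be nonempty")
    if any(s <= 0 for s in scales):
        raise ValueError("all scales must be positive")
    if any(b <= a for a, b in zip(scales, scales[1:])):
        raise ValueError("scales must be strictly increasing")

    pixels = _as_pixels(image)
    vl = np.full(pixels.shape, -np.inf)
    opt_scale = np.full(pixels.shape, scales[0])
    for s in scales:
        h = compute_hessian(pixels, s, gamma=gamma)
        v = vessel_likeness(h.lambda1, h.lambda2, c=c, dark_only=dark_only)
        better = v > vl  # strict: earlier (smaller) scale wins ties
        opt_scale = np.where(better, s, opt_scale)
        vl = np.where(better, v, vl)
    return ScaleSpaceResult(vl=vl, opt_scale=opt_scale, scales=scales)
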