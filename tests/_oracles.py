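"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written the slow, literal way (explicit
loops, exhaustive enumeration, dense sampling) and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_nlm(pixels: np.ndarray, search_radius: int, patch_radius: int,
              h: float) -> np.ndarray:
    """Quadruple-loop nonlocal means on a reflect-padded image."""
    R, P = search_radius, patch_radius
    pad = R + P
    padded = np.pad(pixels, pad, mode="reflect")
    H, W = pixels.shape
    out = np.empty((H, W))
    for i in range(H):
        for j in range(W):
            ci, cj = pad + i, pad + j
            patch_i = padded[ci - P:ci + P + 1, cj - P:cj + P + 1]
            num = 0.0
            den = 0.0
            for di in range(-R, R + 1):
                for dj in range(-R, R + 1):
                    ni, nj = ci + di, cj + dj
                    patch_j = padded[ni - P:ni + P + 1, nj - P:nj + P + 1]
                    w = np.exp(-np.sum((patch_i - patch_j) ** 2) / h**2)
                    num += w * padded[ni, nj]
                    den += w
            out[i, j] = num / den
    return out


def enumerate_min_energy(u_s: np.ndarray, u_t: np.ndarray, nlinks: dict
                         ) -> tuple[float, np.ndarray]:
    """Exhaustive minimum of the labeling energy over all 2^(H*W) binary
    labelings.  Energy of a labeling: u_t on foreground pixels, u_s on
    background pixels, plus each n-link whose endpoints disagree."""
    H, W = u_s.shape
    n = H * W
    pairs = []
    for (dr, dc), cap in nlinks.items():
        for r in range(H):
            for c in range(W):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < H and 0 <= c2 < W and cap[r, c] > 0:
                    pairs.append((r * W + c, r2 * W + c2, cap[r, c]))
    us_flat = u_s.ravel()
    ut_flat = u_t.ravel()
    best = np.inf
    best_lab = None
    for bits in itertools.product((False, True), repeat=n):
        lab = np.array(bits)
        e = ut_flat[lab].sum() + us_flat[~lab].sum()
        for p, q, cap in pairs:
            if lab[p] != lab[q]:
                e += cap
        if e < best:
            best = e
            best_lab = lab
    return float(best), best_lab.reshape(H, W)


def polyline_band_mask(shape: tuple[int, int], points, half_width: float,
                       oversample: int = 400) -> np.ndarray:
    """Vessel-band mask from dense point sampling of the polyline: a pixel
    is inside iff its distance to the nearest sampled centerline point is
    <= half_width.  Sampling is fine enough (step << 0.01 px on test-sized
    segments) that the discrete band matches the exact one."""
    samples = []
    for (r0, c0), (r1, c1) in zip(points[:-1], points[1:]):
        t = np.linspace(0.0, 1.0, oversample * 100)
        samples.append(np.column_stack([r0 + t * (r1 - r0),
                                        c0 + t * (c1 - c0)]))
    samples = np.vstack(samples)
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    pts = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    # chunked nearest-point distance to keep memory flat
    dmin = np.full(len(pts), np.inf)
    for start in range(0, len(samples), 5000):
        chunk = samples[start:start + 5000]
        d = np.min(
            np.hypot(pts[:, None, 0] - chunk[None, :, 0],
                     pts[:, None, 1] - chunk[None, :, 1]), axis=1)
        np.minimum(dmin, d, out=dmin)
    return (dmin <= half_width).reshape(shape)


def gaussian_derivative_kernel(sigma: float, order: int,
                               truncate: float = 4.0) -> np.ndarray:
    """Sampled 1-D Gaussian (or its exact derivative) kernel, built from
    the analytic formula."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(x**2) / (2 * sigma**2))
    g /= g.sum()
    if order == 0:
        return g
    if order == 1:
        return -x / sigma**2 * g
    if order == 2:
        return (x**2 - sigma**2) / sigma**4 * g
    raise ValueError(order)


def direct_hessian(pixels: np.ndarray, sigma: float, gamma: float
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hessian by explicit separable convolution with analytic kernels,
    reflect boundaries; returns (Ixx, Ixy, Iyy) scale-normalized.  The DC
    component is removed first, matching the operator definition."""
    from scipy.ndimage import correlate1d

    pixels = pixels - pixels.mean()

    def sep(img, order_row, order_col):
        out = correlate1d(img, gaussian_derivative_kernel(sigma, order_row),
                          axis=0, mode="reflect")
        # correlate with the flipped derivative kernel == convolution
        return correlate1d(out, gaussian_derivative_kernel(sigma, order_col),
                           axis=1, mode="reflect")

    norm = sigma**gamma
    Iyy = sep(pixels, 2, 0) * norm
    Ixy = sep(pixels, 1, 1) * norm
    Ixx = sep(pixels, 0, 2) * norm
    return Ixx, Ixy, Iyy
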