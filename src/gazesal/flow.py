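"""Dense optical-flow magnitude from a local orientation (structure) tensor.

Classic dense Lucas-Kanade: image gradients are pooled over a Gaussian
neighborhood into a 2x2 orientation tensor per pixel, and the flow vector
solves the pooled normal equations. Only the vector magnitude is
returned.
"""

from __future__ import annotations

import numpy as np

from gazesal.kernels import gaussian_blur

STRUCTURE_EPS = 1e-8
TEXTURE_FLOOR = 1e-6  # tensor trace below which flow is defined as zero


def flow_magnitude(prev: np.ndarray, curr: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Per-pixel optical-flow magnitude between two grayscale frames."""
    prev = np.asarray(prev, dtype=float)
    curr = np.asarray(curr, dtype=float)
    if prev.shape != curr.shape:
        raise ValueError(f"frame shapes differ: {prev.shape} vs {curr.shape}")
    mid = 0.5 * (prev + curr)
    iy, ix = np.gradient(mid)
    it = curr - prev
    a11 = gaussian_blur(ix * ix, sigma)
    a12 = gaussian_blur(ix * iy, sigma)
    a22 = gaussian_blur(iy * iy, sigma)
    b1 = -gaussian_blur(ix * it, sigma)
    b2 = -gaussian_blur(iy * it, sigma)
    det = a11 * a22 - a12**2
    trace = a11 + a22
    det_safe = det + STRUCTURE_EPS
    u = (a22 * b1 - a12 * b2) / det_safe
    v = (a11 * b2 - a12 * b1) / det_safe
    mag = np.hypot(u, v)
    mag[trace < TEXTURE_FLOOR] = 0.0
    return mag
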