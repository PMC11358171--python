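"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with naive loops and closed
formulas, sharing no code path with the package implementation.
"""

from itertools import combinations

import numpy as np


def dense_convolve(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Naive same-size true convolution with symmetric (edge-repeat) padding."""
    kh, kw = kernel.shape
    ry, rx = kh // 2, kw // 2
    padded = np.pad(image, ((ry, ry), (rx, rx)), mode="symmetric")
    flipped = kernel[::-1, ::-1]
    out = np.zeros(image.shape, dtype=np.result_type(image, kernel))
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = np.sum(padded[i : i + kh, j : j + kw] * flipped)
    return out


def gaussian_kernel_formula(sigma: float) -> np.ndarray:
    radius = max(int(3.0 * sigma + 0.5), 1)
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


def block_match_shift(prev: np.ndarray, curr: np.ndarray, max_shift: int = 3):
    """Integer (dx, dy) minimizing SSD between shifted prev and curr."""
    best, best_ssd = (0, 0), np.inf
    h, w = prev.shape
    m = max_shift
    for dy in range(-m, m + 1):
        for dx in range(-m, m + 1):
            a = prev[m - dy : h - m - dy, m - dx : w - m - dx]
            b = curr[m : h - m, m : w - m]
            ssd = float(np.sum((a - b) ** 2))
            if ssd < best_ssd:
                best_ssd, best = ssd, (dx, dy)
    return best


def pearson_formula(a: np.ndarray, b: np.ndarray) -> float:
    """Covariance-ratio Pearson r computed from the definition."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float(np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2)))


def mean_pairwise_r(rows: np.ndarray) -> float:
    vals = [pearson_formula(rows[i], rows[j]) for i, j in combinations(range(len(rows)), 2)]
    return float(np.mean(vals))


def one_sample_t(values: np.ndarray, mu: float) -> float:
    values = np.asarray(values, float)
    n = len(values)
    se = values.std(ddof=1) / np.sqrt(n)
    return float((values.mean() - mu) / se)
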