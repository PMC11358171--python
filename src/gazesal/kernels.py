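"""Analytic filter kernels and 2-D convolution with symmetric boundaries.

All kernels are built from closed-form expressions so that responses can
be checked against naive dense-convolution implementations. Convolution
is true convolution (kernel flipped) over a symmetrically padded image
(edge pixels mirrored without repetition is NOT used; the pad repeats the
edge sample, i.e. numpy's ``mode="symmetric"`` / scipy.ndimage
``mode="reflect"``).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import ndimage, signal


@lru_cache(maxsize=256)
def _gaussian_kernel1d_cached(sigma: float, radius: int | None) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    k = k / k.sum()
    k.flags.writeable = False
    return k


def gaussian_kernel1d(sigma: float, radius: int | None = None) -> np.ndarray:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if radius is None:
        radius = max(int(3.0 * sigma + 0.5), 1)
    return _gaussian_kernel1d_cached(float(sigma), int(radius))


@lru_cache(maxsize=256)
def _gaussian_kernel2d_cached(sigma: float, radius: int | None) -> np.ndarray:
    k = gaussian_kernel1d(sigma, radius)
    k2 = np.outer(k, k)
    k2.flags.writeable = False
    return k2


def gaussian_kernel2d(sigma: float, radius: int | None = None) -> np.ndarray:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return _gaussian_kernel2d_cached(float(sigma), radius if radius is None else int(radius))


@lru_cache(maxsize=256)
def _log_kernel_cached(sigma: float, radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    k = -(r2 - 2.0 * sigma**2) / sigma**4 * np.exp(-r2 / (2.0 * sigma**2))
    k = k - k.mean()
    k.flags.writeable = False
    return k


def log_kernel(sigma: float, radius: int | None = None) -> np.ndarray:
    """Laplacian-of-Gaussian ("Mexican hat"), adjusted to exact zero sum.

    Positive at the center is obtained by negating the raw LoG, so a
    bright blob on a dark ground yields a positive center response.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if radius is None:
        radius = max(int(4.0 * sigma + 0.5), 2)
    return _log_kernel_cached(float(sigma), int(radius))


@lru_cache(maxsize=256)
def _gabor_kernel_cached(wavelength: float, theta: float, sigma: float, gamma: float) -> np.ndarray:
    radius = max(int(3.0 * sigma + 0.5), 1)
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    xr = xx * np.cos(theta) + yy * np.sin(theta)
    yr = -xx * np.sin(theta) + yy * np.cos(theta)
    envelope = np.exp(-(xr**2 + gamma**2 * yr**2) / (2.0 * sigma**2))
    carrier = np.exp(1j * 2.0 * np.pi * xr / wavelength)
    k = envelope * carrier
    k = k - k.real.mean()  # remove DC so uniform regions respond zero
    k.flags.writeable = False
    return k


def gabor_kernel(
    wavelength: float,
    theta: float,
    sigma: float | None = None,
    gamma: float = 1.0,
) -> np.ndarray:
    """Complex Gabor kernel; the real part is made zero-mean (no DC response)."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if sigma is None:
        sigma = 0.56 * wavelength
    return _gabor_kernel_cached(float(wavelength), float(theta), float(sigma), float(gamma))


_FFT_THRESHOLD = 12  # kernel side above which FFT convolution is used


def convolve2d(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size true convolution with symmetric (edge-mirrored) padding.

    Dispatches between direct and FFT paths on kernel size; both compute
    the identical sum, so results agree to floating-point accuracy.
    """
    image = np.asarray(image, dtype=float)
    kh, kw = kernel.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel sides must be odd")
    if np.iscomplexobj(kernel) or max(kh, kw) > _FFT_THRESHOLD:
        padded = _pad_symmetric(image, kh // 2, kw // 2)
        return signal.fftconvolve(padded, kernel, mode="valid")
    return ndimage.convolve(image, kernel, mode="reflect")


def _pad_symmetric(image: np.ndarray, ry: int, rx: int) -> np.ndarray:
    """Symmetric padding tiled in steps so the pad may exceed the image size."""
    padded = image
    py, px = ry, rx
    while py > 0 or px > 0:
        sy = min(py, padded.shape[-2])
        sx = min(px, padded.shape[-1])
        pad = [(0, 0)] * (padded.ndim - 2) + [(sy, sy), (sx, sx)]
        padded = np.pad(padded, pad, mode="symmetric")
        py -= sy
        px -= sx
    return padded


def convolve_stack(stack: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Apply `convolve2d` to each slice of a (n, h, w) stack in one call."""
    stack = np.asarray(stack, dtype=float)
    kh, kw = kernel.shape
    if np.iscomplexobj(kernel) or max(kh, kw) > _FFT_THRESHOLD:
        padded = _pad_symmetric(stack, kh // 2, kw // 2)
        return signal.fftconvolve(padded, kernel[None], mode="valid", axes=(1, 2))
    return ndimage.convolve(stack, kernel[None], mode="reflect")


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    return convolve2d(image, gaussian_kernel2d(sigma))
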