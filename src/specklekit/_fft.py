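"""Centred FFT helpers and Friedel-symmetry index maps."""

from __future__ import annotations

import numpy as np

__all__ = ["fft2c", "ifft2c", "friedel_partner", "radius_grid"]


def fft2c(x: np.ndarray) -> np.ndarray:
    """2-D DFT with the zero-frequency pixel at the grid centre (N//2)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x)))


def ifft2c(X: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(X)))


def friedel_partner(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays mapping each centred-spectrum pixel to its Friedel partner.

    With the DC pixel at ``(N//2, M//2)``, the partner of index ``(i, j)`` is
    ``((N - i) % N, (M - j) % M)``; pixels on the aliased negative-Nyquist
    row/column of an even grid map to themselves.
    """
    n, m = shape
    i = (n - np.arange(n)) % n
    j = (m - np.arange(m)) % m
    return np.ix_(i, j)


def radius_grid(shape: tuple[int, int]) -> np.ndarray:
    """Distance of each pixel from the DC pixel, in pixels."""
    n, m = shape
    rows = np.arange(n) - n // 2
    cols = np.arange(m) - m // 2
    return np.hypot(rows[:, None], cols[None, :])
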