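"""Critically-sampled two-channel reference DWT.

This is the in-repo comparison oracle for the shift-invariance claims of
the oversampled transform: an orthonormal Daubechies wavelet of matching
vanishing moments, decimated in both channels, run under the same
zero-padded full-convolution boundary convention.

Taps are computed by spectral factorization of the Daubechies half-band
product filter rather than transcribed, and are validated by the test
suite against published db2 values and the orthonormality conditions.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

import numpy as np

__all__ = ["daubechies_taps", "dwt_forward"]


@lru_cache(maxsize=None)
def daubechies_taps(moments: int) -> np.ndarray:
    """Orthonormal Daubechies scaling filter with ``moments`` vanishing
    moments (length ``2 * moments``), min-phase factor, ``sum h = sqrt(2)``."""
    if moments < 1:
        raise ValueError("moments must be >= 1")
    if moments == 1:
        return np.array([1.0, 1.0]) / np.sqrt(2.0)
    # P(y) = sum_{k<K} C(K-1+k, k) y^k ; roots in y, then map to z with
    # y = (2 - z - 1/z)/4 keeping the root inside the unit circle.
    p = np.array([comb(moments - 1 + k, k) for k in range(moments)], float)
    y_roots = np.roots(p[::-1])
    z_roots = []
    for y in y_roots:
        # z^2 - (2 - 4y) z + 1 = 0
        b = 2.0 - 4.0 * y
        disc = np.sqrt(b * b - 4.0 + 0j)
        z1, z2 = (b + disc) / 2.0, (b - disc) / 2.0
        z_roots.append(z1 if abs(z1) < 1.0 else z2)
    q = np.array([1.0 + 0j])
    for z0 in z_roots:
        q = np.convolve(q, [1.0, -z0])
    q = np.real(q)
    q /= q.sum()  # Q(1) = 1
    h = np.sqrt(2.0) * q
    for _ in range(moments):
        h = np.convolve(h, [0.5, 0.5])
    return h


def dwt_forward(
    signal: np.ndarray, moments: int, levels: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Critically-sampled DWT with zero-padded full convolution.

    Returns (detail subbands for scales 1..levels, final approximation).
    """
    h0 = daubechies_taps(moments)
    h1 = ((-1.0) ** np.arange(h0.size)) * h0[::-1]
    a = np.asarray(signal, dtype=float)
    if a.size < h0.size * 2**levels:
        raise ValueError("signal too short for requested levels")
    details = []
    for _ in range(levels):
        details.append(np.convolve(a, h1)[::2])
        a = np.convolve(a, h0)[::2]
    return details, a
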