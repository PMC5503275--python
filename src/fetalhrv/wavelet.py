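"""Dyadic high-pass filtering with the 4-tap Daubechies wavelet.

The filter removes the low-frequency content of a short window by running a
multi-level orthonormal discrete wavelet transform, zeroing the final
approximation band, and inverting.  At 8 Hz with 5 levels the approximation
band spans 0-0.125 Hz, the closest dyadic realization of a 0.15 Hz cutoff.

The transform is periodized (circular), which keeps it exactly orthogonal and
therefore perfectly invertible for even-length inputs.  Boundary handling is
selectable: ``"symmetric"`` (default) mirrors the window to twice its length
before transforming, which removes the wrap-around discontinuity of plain
periodization; ``"periodic"`` transforms the window as-is.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "DB2_LO",
    "DB2_HI",
    "dwt_periodic",
    "idwt_periodic",
    "wavedec_periodic",
    "waverec_periodic",
    "highpass",
    "highpass_operator",
]

_S3 = np.sqrt(3.0)

#: Orthonormal 4-tap Daubechies analysis low-pass filter (2 vanishing moments).
DB2_LO = np.array([1.0 + _S3, 3.0 + _S3, 3.0 - _S3, 1.0 - _S3]) / (4.0 * np.sqrt(2.0))

#: Quadrature-mirror high-pass: hi[j] = (-1)^j * lo[L-1-j].
DB2_HI = DB2_LO[::-1] * np.array([1.0, -1.0, 1.0, -1.0])


def _tap_index(n_out: int, m: int, taps: int) -> np.ndarray:
    return (2 * np.arange(n_out)[:, None] + np.arange(taps)[None, :]) % m


def dwt_periodic(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One level of the periodized orthonormal transform.

    Returns ``(approx, detail)`` coefficient arrays of length ``len(x) // 2``.
    """
    x = np.asarray(x, dtype=float)
    m = x.shape[-1]
    if m % 2:
        raise ValueError(f"periodized DWT needs an even length, got {m}")
    xs = x[..., _tap_index(m // 2, m, DB2_LO.size)]
    return xs @ DB2_LO, xs @ DB2_HI


def idwt_periodic(approx: np.ndarray, detail: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`dwt_periodic` (transpose of the orthogonal map)."""
    approx = np.asarray(approx, dtype=float)
    detail = np.asarray(detail, dtype=float)
    if approx.shape != detail.shape:
        raise ValueError("approx/detail length mismatch")
    m = 2 * approx.shape[-1]
    idx = _tap_index(m // 2, m, DB2_LO.size)
    contrib = approx[..., :, None] * DB2_LO + detail[..., :, None] * DB2_HI
    x = np.zeros(approx.shape[:-1] + (m,))
    np.add.at(x, (..., idx), contrib)
    return x


def wavedec_periodic(x: np.ndarray, levels: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Multi-level decomposition: final approximation + details (coarse last)."""
    m = np.asarray(x).shape[-1]
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if m % (1 << levels):
        raise ValueError(f"length {m} not divisible by 2^{levels}")
    details: list[np.ndarray] = []
    approx = np.asarray(x, dtype=float)
    for _ in range(levels):
        approx, det = dwt_periodic(approx)
        details.append(det)
    return approx, details


def waverec_periodic(approx: np.ndarray, details: list[np.ndarray]) -> np.ndarray:
    x = approx
    for det in reversed(details):
        x = idwt_periodic(x, det)
    return x


def highpass(x: np.ndarray, levels: int = 5, extension: str = "symmetric") -> np.ndarray:
    """High-pass a window by zeroing the level-`levels` approximation band.

    Parameters
    ----------
    x : array
        Window samples; length must be divisible by ``2**levels`` (and, for
        the symmetric extension, ``2 * len(x)`` must be too, which any
        power-of-two length satisfies).
    levels : int
        Decomposition depth; at rate ``fs`` the removed band is
        ``[0, fs / 2**(levels+1))``.
    extension : {"symmetric", "periodic"}
        Boundary handling (see module docstring).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("highpass expects a 1-D window")
    n = x.size
    if n < (1 << levels) or (n & (n - 1)):
        raise ValueError(f"window length must be a power of two >= 2^{levels}, got {n}")
    if extension == "symmetric":
        ext = np.concatenate([x, x[::-1]])
    elif extension == "periodic":
        ext = x
    else:
        raise ValueError(f"unknown extension {extension!r}")
    approx, details = wavedec_periodic(ext, levels)
    out = waverec_periodic(np.zeros_like(approx), details)
    return out[:n]


@lru_cache(maxsize=8)
def highpass_operator(n: int, levels: int = 5, extension: str = "symmetric") -> np.ndarray:
    """The ``n x n`` matrix H with ``H @ x == highpass(x)``; cached.

    Lets sliding-window pipelines filter thousands of windows with one BLAS
    call instead of repeated transforms.
    """
    eye = np.eye(n)
    cols = [highpass(eye[:, j], levels=levels, extension=extension) for j in range(n)]
    return np.asarray(cols).T
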