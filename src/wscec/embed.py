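"""Sliding-window Fourier embedding of heartbeats into R^d.

A beat of length n is cut into windows of length ``l`` advanced by ``tau``
samples; each window is mapped to the leading DFT coefficients
``(a_0, a_1, b_1, ..., a_{(d-1)/2}, b_{(d-1)/2})`` (real/imaginary parts of
``C_k = sum_i t_i exp(-2 pi j k i / l)``), scaled by a configurable factor.
With the default scale ``2/l`` the (a_1, b_1) coordinates of a sinusoid
commensurate with the window equal its amplitude.

The window index runs k = 1 .. nhat-1 with nhat = floor((n - l) / tau), the
k-th window starting at offset k*tau — the first possible window (offset 0)
is deliberately not emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EmbedConfig", "sliding_windows", "fft_coeffs", "embed_beat"]


@dataclass(frozen=True)
class EmbedConfig:
    """Parameters of the short-time Fourier embedding.

    l : window length in samples (default 10, the width of a sharp QRS).
    tau : sliding step in samples (default 1).
    d : embedding dimension, odd, at most l (default 3).
    scale : multiplier applied to the coefficient vector; None means 2/l.
    """

    l: int = 10
    tau: int = 1
    d: int = 3
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.l < 2:
            raise ValueError("window length l must be >= 2")
        if self.tau < 1:
            raise ValueError("sliding speed tau must be >= 1")
        if self.d % 2 == 0 or self.d < 1:
            raise ValueError("embedding dimension d must be odd")
        if self.d > self.l:
            raise ValueError("embedding dimension d must not exceed l")

    @property
    def effective_scale(self) -> float:
        return 2.0 / self.l if self.scale is None else self.scale


def sliding_windows(samples: np.ndarray, l: int, tau: int) -> np.ndarray:
    """Windows k = 1 .. nhat-1 of length ``l``, window k starting at k*tau.

    Returns an array of shape (nhat - 1, l) with nhat = floor((n - l)/tau).
    Raises ``ValueError`` when fewer than one window fits (n < l + tau).
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    nhat = (n - l) // tau
    if n < l + tau or nhat < 2:
        raise ValueError(
            f"signal of length {n} too short for windows l={l}, tau={tau}"
        )
    starts = np.arange(1, nhat) * tau
    return np.stack([samples[s : s + l] for s in starts])


def fft_coeffs(window: np.ndarray, d: int, scale: float = 1.0) -> np.ndarray:
    """Leading DFT coefficients (a_0, a_1, b_1, ...) of one window.

    ``a_k`` and ``b_k`` are the real and imaginary parts of
    ``C_k = sum_i t_i exp(-2 pi j k i / l)``; the first d entries
    (a_0, then interleaved a_k, b_k) are returned multiplied by ``scale``.
    """
    window = np.asarray(window, dtype=float)
    if d % 2 == 0 or d > window.size:
        raise ValueError("d must be odd and at most the window length")
    C = np.fft.fft(window)  # numpy uses the same e^{-2 pi j k i / n} sign
    half = (d - 1) // 2
    out = np.empty(d)
    out[0] = C[0].real
    for k in range(1, half + 1):
        out[2 * k - 1] = C[k].real
        out[2 * k] = C[k].imag
    return scale * out


def embed_beat(samples: np.ndarray, config: EmbedConfig | None = None) -> np.ndarray:
    """Point cloud in R^d for one beat: sliding windows composed with DFT.

    Returns an array of shape (nhat - 1, d), row order following the window
    index.
    """
    if config is None:
        config = EmbedConfig()
    windows = sliding_windows(samples, config.l, config.tau)
    s = config.effective_scale
    return np.stack([fft_coeffs(w, config.d, s) for w in windows])
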