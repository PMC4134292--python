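"""Continuous Morlet wavelet transform of cross-correlograms.

The correlogram is treated as a discrete series x_n sampled at ``bin_width``
and convolved with scaled, translated, normalized copies of the complex
Morlet mother wavelet

    psi0(eta) = pi**(-1/4) * exp(i * omega0 * eta) * exp(-eta**2 / 2)

with non-dimensional frequency ``omega0 = 4``.  The convolution is carried
out in the frequency domain following the standard continuous-wavelet
framework: daughter wavelets are Gaussians in angular frequency,
``(2*pi*s/dt)**0.5 * pi**(-1/4) * exp(-(s*w - omega0)**2 / 2)`` on ``w > 0``,
and ``W = ifft(fft(x) * daughter)``.  The wavelet power is ``|W|**2``.

A wavelet scale ``s`` maps to an equivalent Fourier period
``T = 4*pi*s / (omega0 + sqrt(2 + omega0**2))``, so analysis frequencies
(log-spaced, endpoints included) convert directly to scales.

Before transforming, both ends of the series are padded with the mean of
the 100 edge bins so the total length is a power of two; only the original
window is returned, which keeps pad effects away from the peak window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import scipy.fft as _fft

from .correlogram import Correlogram, lag_grid

__all__ = [
    "WaveletConfig",
    "WaveletPower",
    "SCALE1",
    "SCALE2",
    "preset",
    "morlet",
    "fourier_period",
    "matching_scale",
    "transform",
    "batch_max_power",
]

_EDGE_BINS = 100  # bins averaged at each end to build the pad value


@dataclass(frozen=True)
class WaveletConfig:
    """Parameters of one analysis scale.

    ``transform_window`` / ``peak_window`` are half-widths in seconds; the
    lag grid spans ``+-transform_window`` at ``bin_width`` resolution, and
    peaks are only accepted within ``+-peak_window``.  ``n_freq``
    frequencies run log-spaced from ``freq_lo`` to ``freq_hi`` inclusive.
    """

    bin_width: float
    transform_window: float
    peak_window: float
    freq_lo: float
    freq_hi: float
    n_freq: int = 101
    omega0: float = 4.0

    @property
    def n_lags(self) -> int:
        return 2 * int(round(self.transform_window / self.bin_width)) + 1

    @property
    def freqs(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.freq_lo), np.log10(self.freq_hi), self.n_freq
        )

    @property
    def lags(self) -> np.ndarray:
        return lag_grid(self.bin_width, self.transform_window)

    @property
    def scales(self) -> np.ndarray:
        return matching_scale(self.freqs, self.omega0)

    def fingerprint(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


#: scale 1: 50 us bins, +-70 ms window, peaks within +-20 ms, 20-1000 Hz
SCALE1 = WaveletConfig(50e-6, 70e-3, 20e-3, 20.0, 1000.0)
#: scale 2: 500 us bins, +-700 ms window, peaks within +-200 ms, 2-100 Hz
SCALE2 = WaveletConfig(500e-6, 700e-3, 200e-3, 2.0, 100.0)


def preset(scale: int) -> WaveletConfig:
    """Return the built-in configuration for analysis scale 1 or 2."""
    if scale == 1:
        return SCALE1
    if scale == 2:
        return SCALE2
    raise ValueError(f"unknown scale preset {scale!r}; use 1 or 2")


@dataclass(frozen=True)
class WaveletPower:
    """Time x frequency wavelet power plane of one correlogram."""

    pair: tuple[int, int]
    freqs: np.ndarray        # ascending, log-spaced (Hz)
    lags: np.ndarray         # seconds, the transformed window
    power: np.ndarray        # (n_freq, n_lags), |W|^2 >= 0
    config: WaveletConfig
    n_spikes: float


def morlet(eta, omega0: float = 4.0):
    """Complex Morlet mother wavelet at non-dimensional time ``eta``."""
    eta = np.asarray(eta, dtype=float)
    out = np.pi ** -0.25 * np.exp(1j * omega0 * eta) * np.exp(-0.5 * eta**2)
    return out if out.ndim else complex(out)


def fourier_period(freq, omega0: float = 4.0):
    """Fourier period (s) of the wavelet analysed at frequency ``freq`` (Hz)."""
    freq = np.asarray(freq, dtype=float)
    if np.any(freq <= 0):
        raise ValueError("frequency must be positive")
    out = 1.0 / freq
    return out if out.ndim else float(out)


def matching_scale(freq, omega0: float = 4.0):
    """Wavelet scale whose Fourier period equals ``1/freq``.

    For the Morlet wavelet ``T = 4*pi*s / (omega0 + sqrt(2 + omega0**2))``.
    """
    freq = np.asarray(freq, dtype=float)
    if np.any(freq <= 0):
        raise ValueError("frequency must be positive")
    out = (1.0 / freq) * (omega0 + np.sqrt(2.0 + omega0**2)) / (4.0 * np.pi)
    return out if out.ndim else float(out)


def _pad_layout(n: int) -> tuple[int, int, int]:
    """(padded length, left pad, right pad): next power of two, split evenly."""
    p = 1
    while p < n:
        p *= 2
    total = p - n
    left = total // 2
    return p, left, total - left


def _pad_edges(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Pad both ends with the 100-bin edge averages up to a power of two."""
    n = x.shape[-1]
    if n < _EDGE_BINS:
        raise ValueError(f"series shorter than the {_EDGE_BINS} edge bins used for padding")
    p, left, right = _pad_layout(n)
    out = np.empty(x.shape[:-1] + (p,), dtype=x.dtype)
    out[..., left : left + n] = x
    out[..., :left] = x[..., :_EDGE_BINS].mean(axis=-1, keepdims=True)
    out[..., left + n :] = x[..., -_EDGE_BINS:].mean(axis=-1, keepdims=True)
    return out, left


def _daughters(cfg: WaveletConfig, n_padded: int, dtype=np.complex128) -> np.ndarray:
    """Frequency-domain daughter wavelets, one row per analysis frequency."""
    w = 2.0 * np.pi * _fft.fftfreq(n_padded, cfg.bin_width)
    s = cfg.scales[:, None]
    psi = np.where(
        w[None, :] > 0,
        np.pi ** -0.25 * np.exp(-0.5 * (s * w[None, :] - cfg.omega0) ** 2),
        0.0,
    )
    psi *= np.sqrt(2.0 * np.pi * s / cfg.bin_width)
    return psi.astype(dtype)


def transform(c: Correlogram, cfg: WaveletConfig) -> WaveletPower:
    """Wavelet power plane of a correlogram on the configured scale.

    The correlogram must share ``cfg.bin_width`` and span the configured
    transform window.  The output covers exactly the input lag grid.
    """
    if abs(c.bin_width - cfg.bin_width) > 1e-12 * cfg.bin_width:
        raise ValueError("correlogram bin width does not match wavelet config")
    if c.lags.size != cfg.n_lags or abs(c.window - cfg.transform_window) > 1e-9:
        raise ValueError("correlogram does not span the configured transform window")

    x, left = _pad_edges(c.counts.astype(float))
    xh = _fft.fft(x)
    psi = _daughters(cfg, x.size)
    W = _fft.ifft(xh[None, :] * psi, axis=1)[:, left : left + cfg.n_lags]
    power = (W.real**2 + W.imag**2)
    return WaveletPower(
        pair=c.pair,
        freqs=cfg.freqs,
        lags=c.lags.copy(),
        power=power,
        config=cfg,
        n_spikes=c.n_spikes,
    )


def batch_max_power(
    counts: np.ndarray,
    cfg: WaveletConfig,
    window: str = "peak",
    dtype=np.complex64,
) -> np.ndarray:
    """Per-frequency maximum wavelet power for a batch of correlograms.

    Parameters
    ----------
    counts : (n_series, n_lags) array
        Correlogram counts on the configured lag grid, one row per series.
    window : {"peak", "transform"}
        Lag range the maximum is taken over; the significance calibration
        uses the peak-identification window so the null statistic matches
        where peaks are accepted.
    dtype : complex dtype
        Single precision is the Monte-Carlo default (the order statistics
        are far above round-off); pass ``complex128`` for exact agreement
        with :func:`transform`.

    Returns
    -------
    (n_series, n_freq) array of max |W|^2.
    """
    counts = np.atleast_2d(np.asarray(counts))
    if counts.shape[1] != cfg.n_lags:
        raise ValueError("counts rows must match the configured lag grid")
    real_dt = np.float32 if dtype == np.complex64 else np.float64
    x, left = _pad_edges(counts.astype(real_dt))
    xh = _fft.fft(x, axis=1)
    psi = _daughters(cfg, x.shape[1], dtype=dtype)

    if window == "peak":
        half = int(round(cfg.peak_window / cfg.bin_width))
    elif window == "transform":
        half = (cfg.n_lags - 1) // 2
    else:
        raise ValueError("window must be 'peak' or 'transform'")
    c0 = left + (cfg.n_lags - 1) // 2
    sl = slice(c0 - half, c0 + half + 1)

    out = np.empty((counts.shape[0], cfg.n_freq), dtype=np.float64)
    for i in range(cfg.n_freq):
        W = _fft.ifft(xh * psi[i], axis=1)[:, sl]
        out[:, i] = (W.real**2 + W.imag**2).max(axis=1)
    return out
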