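"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (double loops, explicit O(N^2) DFT
sums, BFS shortest paths) and shares no code with the package's
implementations.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- correlogram
def brute_cch(times_a, times_b, bin_width: float, window: float) -> np.ndarray:
    """Binary-state CCH via a double loop over occupied bins."""
    half = int(round(window / bin_width))
    bins_a = sorted({math.floor(t / bin_width + 0.5) for t in times_a})
    bins_b = sorted({math.floor(t / bin_width + 0.5) for t in times_b})
    counts = np.zeros(2 * half + 1, dtype=int)
    for ia in bins_a:
        for ib in bins_b:
            d = ib - ia
            if -half <= d <= half:
                counts[d + half] += 1
    return counts


# -------------------------------------------------------------------- wavelet
def direct_wavelet_power(counts: np.ndarray, cfg) -> np.ndarray:
    """Morlet wavelet power by explicit O(N^2) DFT sums (no FFT).

    Implements the same frequency-domain definition as the package
    transform — pad both ends with 100-bin edge averages to a power of two,
    multiply the spectrum by Gaussian daughter wavelets on positive
    frequencies with (2*pi*s/dt)^(1/2) normalization — but evaluates both
    the forward and inverse transforms as direct summations.
    """
    n = counts.size
    p = 1
    while p < n:
        p *= 2
    left = (p - n) // 2
    x = np.empty(p, dtype=float)
    x[:left] = counts[:100].mean()
    x[left : left + n] = counts
    x[left + n :] = counts[-100:].mean()

    dt = cfg.bin_width
    k = np.arange(p)
    # direct forward DFT: xh[m] = sum_n x[n] exp(-2 pi i m n / p)
    ang = -2j * np.pi * np.outer(k, k) / p
    xh = (np.exp(ang) @ x.astype(complex))

    w = 2.0 * np.pi * np.fft.fftfreq(p, dt)
    freqs = cfg.freqs
    om0 = cfg.omega0
    scales = (1.0 / freqs) * (om0 + np.sqrt(2.0 + om0**2)) / (4.0 * np.pi)
    power = np.empty((freqs.size, n))
    inv = np.exp(2j * np.pi * np.outer(k, k) / p)
    for i, s in enumerate(scales):
        psi = np.where(w > 0, np.pi**-0.25 * np.exp(-0.5 * (s * w - om0) ** 2), 0.0)
        psi = psi * np.sqrt(2.0 * np.pi * s / dt)
        W = (inv @ (xh * psi)) / p
        Wn = W[left : left + n]
        power[i] = np.abs(Wn) ** 2
    return power


# --------------------------------------------------------------- graph theory
def brute_clustering(adj: np.ndarray) -> float:
    """Mean local clustering over nodes with degree >= 2 (NaN if none)."""
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a], nbrs[b]]:
                    links += 1
        vals.append(links / (k * (k - 1) / 2))
    return float(np.mean(vals)) if vals else float("nan")


def brute_efficiency(adj: np.ndarray) -> float:
    """Mean 1/shortest-path over ordered pairs via BFS; 0 for unreachable."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] and v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        for t in range(n):
            if t != s and t in dist:
                total += 1.0 / dist[t]
    return total / (n * (n - 1))


def brute_assortativity(adj: np.ndarray) -> float:
    """Pearson correlation of end degrees over the doubled edge list."""
    n = adj.shape[0]
    deg = adj.sum(axis=1)
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    if len(xs) < 2:
        return float("nan")
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    sx = xs.std()
    if sx < 1e-12 or ys.std() < 1e-12:
        return float("nan")
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * ys.std()))
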