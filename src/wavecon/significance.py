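"""Monte-Carlo significance thresholds for wavelet power under Poisson noise.

The null model for a cross-correlogram with ``n`` total pair counts is
white noise: ``n`` counts placed uniformly at random over the bins of the
transformed window (bin collisions allowed, giving Poisson statistics per
bin).  Each surrogate is wavelet-transformed and the maximum power over the
peak-identification window is recorded at every analysis frequency; the
significance threshold at probability ``p_level`` is the
``p_level * n_reps``-th highest of those maxima.

No closed form is available for the wavelet-power distribution of Poisson
(as opposed to Gaussian) white noise, hence the Monte-Carlo calibration.
Thresholds are tabulated on a logarithmic spike-count grid ``10**k`` and
interpolated linearly in ``k = log10(n)`` between grid points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .wavelet import WaveletConfig, batch_max_power

__all__ = ["ThresholdTable", "calibrate", "lookup", "lookup_vector", "default_count_grid"]

_BATCH = 2000  # surrogate correlograms transformed per FFT batch


def default_count_grid(k_lo: float = 0.0, k_hi: float = 6.0, k_step: float = 0.1) -> np.ndarray:
    """Exponents ``k`` of the spike-count grid ``10**k`` (default 0.0 .. 6.0 by 0.1)."""
    n = int(round((k_hi - k_lo) / k_step))
    return k_lo + k_step * np.arange(n + 1)


@dataclass(frozen=True)
class ThresholdTable:
    """Per-frequency power thresholds indexed by total spike count.

    ``thresholds[i, j]`` is the power threshold at spike count
    ``10**k_grid[i]`` and frequency ``freqs[j]``.  Thresholds are
    non-decreasing in spike count at every frequency.
    """

    k_grid: np.ndarray          # exponents of the spike-count grid
    freqs: np.ndarray
    thresholds: np.ndarray      # (n_counts, n_freq)
    p_level: float
    n_reps: int
    config_fingerprint: str
    seed: int

    @property
    def spike_count_grid(self) -> np.ndarray:
        return 10.0 ** self.k_grid

    def save(self, path: str | Path) -> None:
        """Write the table as an ``.npz`` array container plus JSON sidecar."""
        path = Path(path)
        np.savez(path, k_grid=self.k_grid, freqs=self.freqs, thresholds=self.thresholds)
        meta = {
            "p_level": self.p_level,
            "n_reps": self.n_reps,
            "config_fingerprint": self.config_fingerprint,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ThresholdTable":
        path = Path(path)
        arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        meta = json.loads(Path(path).with_suffix(".json").read_text())
        return cls(
            k_grid=arrays["k_grid"],
            freqs=arrays["freqs"],
            thresholds=arrays["thresholds"],
            **meta,
        )


def null_correlograms(
    n_spikes: int, n_lags: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Poisson white-noise correlograms: ``n_spikes`` uniform over ``n_lags`` bins."""
    return rng.multinomial(n_spikes, np.full(n_lags, 1.0 / n_lags), size=n_reps).astype(
        np.float64
    )


def null_max_power(
    n_spikes: int,
    cfg: WaveletConfig,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_reps, n_freq) per-frequency maxima of surrogate wavelet power."""
    out = np.empty((n_reps, cfg.n_freq))
    done = 0
    while done < n_reps:
        m = min(_BATCH, n_reps - done)
        counts = null_correlograms(n_spikes, cfg.n_lags, m, rng)
        out[done : done + m] = batch_max_power(counts, cfg, window="peak")
        done += m
    return out


def calibrate(
    cfg: WaveletConfig,
    n_reps: int = 100_000,
    p_level: float = 0.001,
    seed: int = 0,
    k_grid: np.ndarray | None = None,
) -> ThresholdTable:
    """Build a :class:`ThresholdTable` for one wavelet configuration.

    For each grid spike count the order statistic used is the
    ``round(p_level * n_reps)``-th highest per-frequency maximum (the 100th
    of 1e5 at the defaults).  Each grid point draws from an independent
    seed stream, so results do not depend on evaluation order and the grid
    is trivially parallelizable.

    ``k_grid`` may be overridden (e.g. a coarser or narrower grid) when the
    spike counts to be looked up are known in advance; the full-fidelity
    default covers ``10**0 .. 10**6``.
    """
    rank = int(round(p_level * n_reps))
    if rank < 1:
        raise ValueError("p_level * n_reps must be at least 1")
    k_grid = default_count_grid() if k_grid is None else np.asarray(k_grid, dtype=float)
    thresholds = np.empty((k_grid.size, cfg.n_freq))
    for i, k in enumerate(k_grid):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        maxima = null_max_power(int(round(10.0**k)), cfg, n_reps, rng)
        # rank-th highest value per frequency
        part = np.partition(maxima, n_reps - rank, axis=0)
        thresholds[i] = part[n_reps - rank]
    # Monte-Carlo noise can leave tiny non-monotonicities between adjacent
    # grid counts; enforce the structural monotonicity in spike count
    thresholds = np.maximum.accumulate(thresholds, axis=0)
    return ThresholdTable(
        k_grid=k_grid,
        freqs=cfg.freqs,
        thresholds=thresholds,
        p_level=p_level,
        n_reps=n_reps,
        config_fingerprint=cfg.fingerprint(),
        seed=seed,
    )


def lookup_vector(table: ThresholdTable, n_spikes: float) -> np.ndarray:
    """Thresholds at every table frequency for ``n_spikes`` total counts.

    Linear interpolation in ``k = log10(n_spikes)`` between the bracketing
    grid counts; exact at grid points.  No extrapolation: ``n_spikes`` must
    lie within the tabulated range (``[1, 1e6]`` for the default grid).
    """
    if n_spikes < 10.0 ** table.k_grid[0] - 1e-9 or n_spikes > 10.0 ** table.k_grid[-1] + 1e-9:
        raise ValueError(
            f"n_spikes={n_spikes} outside tabulated range "
            f"[{10.0**table.k_grid[0]:g}, {10.0**table.k_grid[-1]:g}]"
        )
    k = np.log10(n_spikes)
    out = np.empty(table.freqs.size)
    for j in range(table.freqs.size):
        out[j] = np.interp(k, table.k_grid, table.thresholds[:, j])
    return out


def lookup(table: ThresholdTable, n_spikes: float, freq: float) -> float:
    """Threshold for one spike count and frequency (snapped to nearest table frequency)."""
    j = int(np.argmin(np.abs(table.freqs - freq)))
    return float(lookup_vector(table, n_spikes)[j])
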