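"""Peak detection, band assignment, direction classification, and
band-specific network assembly.

A significant wavelet-power peak in a pair's power plane defines a
functional connection.  Peaks are strict local maxima over their 8
neighbours in the time-frequency plane, above the Monte-Carlo threshold for
the pair's spike count, and within the peak-identification window.  Peaks
are classified as *directed* (delayed) when the lag exceeds a quarter of
the wavelet's Fourier period, the offset at which the wavelet's primary
lobe no longer overlaps zero lag.  Frequency bands follow the standard
electrophysiological ranges: high-frequency 100-1000 Hz (scale 1), gamma
30-80 Hz, beta 12-30 Hz, theta 4-12 Hz (scale 2).

Networks at a target connectivity density are built by ranking connections
by significance (peak power over threshold power) and keeping unordered
pairs until the density is reached; edges are binary thereafter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.ndimage as ndi

from .spike_io import Recording, SpikeTrain
from .significance import ThresholdTable, lookup_vector
from .wavelet import WaveletPower, fourier_period

__all__ = [
    "BANDS",
    "Connection",
    "FunctionalNetwork",
    "detect_peaks",
    "classify_direction",
    "assign_band",
    "connections_from_power",
    "build_band_network",
    "match_density_across_bands",
    "jitter",
]

#: band name -> (analysis scale, f_lo, f_hi); intervals are half-open
#: [lo, hi) except the top of HFC which closes the covered range at 1000 Hz
BANDS: dict[str, tuple[int, float, float]] = {
    "HFC": (1, 100.0, 1000.0),
    "GFC": (2, 30.0, 80.0),
    "BFC": (2, 12.0, 30.0),
    "TFC": (2, 4.0, 12.0),
}


@dataclass(frozen=True)
class Connection:
    """One significant band-specific functional connection of a neuron pair.

    ``peak_delay`` uses the package lag convention: positive delay means J
    (the second neuron of the pair) fires after I, so a directed connection
    with positive delay points I -> J.
    """

    pair: tuple[int, int]
    band: str
    peak_freq: float
    peak_delay: float
    peak_power: float
    threshold_power: float
    directed: bool
    direction: str  # "I->J", "J->I", or "bidirectional"

    @property
    def significance_ratio(self) -> float:
        return self.peak_power / self.threshold_power

    @property
    def source_target(self) -> tuple[int, int]:
        """(source, target) for directed edges; pair order for bidirectional."""
        if self.direction == "J->I":
            return (self.pair[1], self.pair[0])
        return self.pair


@dataclass(frozen=True)
class FunctionalNetwork:
    """Binary band-specific graph over a fixed node set.

    ``edges`` hold at most one connection per unordered pair (the most
    significant peak of the pair in this band).  ``density`` is the
    fraction of connected unordered pairs among all possible pairs.
    """

    nodes: tuple[int, ...]
    edges: tuple[Connection, ...]
    band: str
    positions: dict[int, Optional[tuple[float, float]]] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        n = len(self.nodes)
        return n * (n - 1) // 2

    @property
    def density(self) -> float:
        return len(self.edges) / self.n_pairs if self.n_pairs else 0.0


def detect_peaks(
    p: WaveletPower, table: ThresholdTable
) -> list[tuple[float, float, float, float]]:
    """Significant local maxima of a power plane.

    Returns ``(freq, delay, power, threshold)`` tuples for every point that
    strictly exceeds its 8 neighbours, exceeds the per-frequency threshold
    for the plane's spike count, and lies inside the peak-identification
    window.  A single correlogram may yield several peaks at different
    frequencies and delays.
    """
    if p.freqs.size != table.freqs.size or not np.allclose(p.freqs, table.freqs):
        raise ValueError("power plane and threshold table use different frequency grids")
    if p.n_spikes < 1:
        return []  # no spikes in window: nothing to test (power is ~0)

    thr = lookup_vector(table, p.n_spikes)
    power = p.power
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neigh = ndi.maximum_filter(power, footprint=footprint, mode="constant", cval=np.inf)
    # borders get cval=inf neighbours, which also excludes non-interior points
    is_peak = power > neigh
    in_window = np.abs(p.lags) <= p.config.peak_window + 1e-12
    is_peak &= in_window[None, :]
    is_peak &= power > thr[:, None]

    out = []
    for i, j in zip(*np.nonzero(is_peak)):
        out.append((float(p.freqs[i]), float(p.lags[j]), float(power[i, j]), float(thr[i])))
    return out


def classify_direction(freq: float, delay: float) -> tuple[bool, str]:
    """Directed/non-directed call for a peak at ``freq`` Hz and signed ``delay`` s.

    Directed iff ``|delay|`` strictly exceeds a quarter of the Fourier
    period ``1/freq``; direction follows the sign of the delay (positive:
    I -> J).  At the boundary the call is non-directed ("more than" is
    strict).
    """
    if abs(delay) > fourier_period(freq) / 4.0:
        return True, ("I->J" if delay > 0 else "J->I")
    return False, "bidirectional"


def assign_band(freq: float, scale: int) -> Optional[str]:
    """Band name for a peak frequency observed at an analysis scale.

    Frequencies in covered-but-unbanded gaps (e.g. 80-100 Hz at scale 2, or
    20-100 Hz at scale 1) return ``None``.
    """
    for name, (band_scale, lo, hi) in BANDS.items():
        if band_scale != scale:
            continue
        if lo <= freq < hi or (name == "HFC" and freq == hi):
            return name
    return None


def connections_from_power(
    p: WaveletPower, table: ThresholdTable, scale: int
) -> list[Connection]:
    """All band-assigned significant connections of one pair at one scale."""
    out = []
    for freq, delay, power, thr in detect_peaks(p, table):
        band = assign_band(freq, scale)
        if band is None:
            continue
        directed, direction = classify_direction(freq, delay)
        out.append(
            Connection(
                pair=p.pair,
                band=band,
                peak_freq=freq,
                peak_delay=delay,
                peak_power=power,
                threshold_power=thr,
                directed=directed,
                direction=direction,
            )
        )
    return out


def _ordered_pair(c: Connection) -> tuple[int, int]:
    return (min(c.pair), max(c.pair))


def _rank_connections(connections: Iterable[Connection]) -> list[Connection]:
    """One connection per unordered pair, sorted by significance (desc).

    Ties in significance break deterministically on lexicographic pair id.
    """
    best: dict[tuple[int, int], Connection] = {}
    for c in connections:
        key = _ordered_pair(c)
        prev = best.get(key)
        if prev is None or c.significance_ratio > prev.significance_ratio:
            best[key] = c
    return sorted(
        best.values(), key=lambda c: (-c.significance_ratio, _ordered_pair(c))
    )


def build_band_network(
    connections: Iterable[Connection],
    band: str,
    density_target: float,
    nodes: Sequence[int],
    positions: Optional[dict[int, Optional[tuple[float, float]]]] = None,
) -> FunctionalNetwork:
    """Density-controlled binary network from a band's candidate connections.

    Keeps the ``floor(density_target * n*(n-1)/2)`` most significant
    unordered pairs.  When the band supplies fewer significant pairs than
    the target, all of them are kept and the achieved density is simply
    lower (such networks stay in the analysis; the target is an upper
    limit).
    """
    if not 0.0 < density_target <= 1.0:
        raise ValueError("density_target must be in (0, 1]")
    nodes = tuple(sorted(nodes))
    node_set = set(nodes)
    ranked = _rank_connections(
        c for c in connections if c.band == band and set(c.pair) <= node_set
    )
    n = len(nodes)
    cap = int(np.floor(density_target * n * (n - 1) / 2))
    return FunctionalNetwork(
        nodes=nodes,
        edges=tuple(ranked[:cap]),
        band=band,
        positions=positions or {},
    )


def match_density_across_bands(
    networks: Sequence[FunctionalNetwork], density_target: float
) -> list[FunctionalNetwork]:
    """Equalize achieved density across bands of one data set.

    Every band is re-truncated (by significance order) to the minimum of the
    target density and the lowest achieved density among the bands, so
    band-to-band comparisons are not biased by unequal edge counts.
    """
    if not networks:
        return []
    n_pairs = networks[0].n_pairs
    if any(net.n_pairs != n_pairs for net in networks):
        raise ValueError("all band networks must share the same node set size")
    d_min = min(density_target, min(net.density for net in networks))
    cap = int(np.floor(d_min * n_pairs))
    out = []
    for net in networks:
        ranked = _rank_connections(net.edges)
        out.append(replace(net, edges=tuple(ranked[:cap])))
    return out


def jitter(rec: Recording, sigma: float = 0.05, seed: int = 0) -> Recording:
    """Gaussian spike-time jitter emulating low temporal resolution.

    Each spike is displaced by independent Gaussian noise of standard
    deviation ``sigma`` seconds (50 ms default, the typical resolution of
    population calcium imaging), then clipped to the recording interval and
    re-sorted.  Spike counts per neuron are conserved.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return rec
    rng = np.random.default_rng(seed)
    trains = []
    for tr in rec.trains:
        t = tr.times + rng.normal(0.0, sigma, size=tr.n_spikes)
        t = np.sort(np.clip(t, 0.0, rec.duration))
        trains.append(SpikeTrain(tr.neuron_id, t, tr.position))
    return rec.with_trains(trains)
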