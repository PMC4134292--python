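"""Synthetic spike populations with known ground-truth connectivity.

The generators emulate the statistical structure the analysis pipeline is
designed to detect in cultured cortico-hippocampal tissue on a large
multielectrode array:

* lognormal firing rates (default ``10**(-0.16 +- 0.64) Hz``, the observed
  cortical distribution),
* neuron positions on a hexagonal 60 um lattice inside a 0.9 x 1.9 mm
  recording area, with small uniform scatter,
* *synaptic-like* couplings: each presynaptic spike elicits, with a fixed
  efficacy, a delayed (a few ms) and slightly jittered postsynaptic spike,
  producing an offset high-frequency correlogram peak,
* *common-drive* couplings: member neurons share a sinusoidal rate
  modulation (gamma/beta/theta frequencies), producing zero-centered
  oscillatory correlograms.

All generators are deterministic given a seed, and the returned
:class:`GroundTruth` is exhaustive: no pairwise dependence exists beyond
the recorded edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .spike_io import Recording, SpikeTrain

__all__ = [
    "GroundTruthEdge",
    "GroundTruth",
    "hexagonal_positions",
    "generate_population",
    "inject_synaptic",
    "inject_common_drive",
    "make_synaptic_population",
]

#: hexagonal electrode lattice geometry (um)
LATTICE_PITCH_UM = 60.0
ARRAY_X_UM = 900.0
ARRAY_Y_UM = 1900.0


@dataclass(frozen=True)
class GroundTruthEdge:
    source: int
    target: int
    mechanism: str                  # "synaptic" or "common_drive"
    delay_ms: float = 0.0
    strength: float = 0.0           # efficacy (synaptic) / modulation depth
    freq_hz: Optional[float] = None  # oscillation frequency for common drive

    def __post_init__(self) -> None:
        if self.mechanism == "synaptic" and self.delay_ms <= 0:
            raise ValueError("synaptic delay must be positive")
        if self.mechanism == "common_drive":
            if self.freq_hz is None or not (2.0 < self.freq_hz < 100.0):
                raise ValueError("common-drive frequency must lie in (2, 100) Hz")


@dataclass
class GroundTruth:
    """Exhaustive list of injected pairwise dependencies."""

    edges: list[GroundTruthEdge] = field(default_factory=list)

    def pairs(self, mechanism: Optional[str] = None) -> set[tuple[int, int]]:
        return {
            (min(e.source, e.target), max(e.source, e.target))
            for e in self.edges
            if mechanism is None or e.mechanism == mechanism
        }


def hexagonal_positions(
    n: int, rng: np.random.Generator, scatter_um: float = 10.0
) -> np.ndarray:
    """``n`` positions on the hexagonal array lattice with uniform scatter.

    Lattice sites are 60 um apart in staggered rows spanning the
    0.9 x 1.9 mm recording area; ``n`` distinct sites are drawn without
    replacement and each is displaced uniformly by up to ``scatter_um``
    per axis (scatter < 30 um keeps distance bins distinct).
    """
    row_pitch = LATTICE_PITCH_UM * np.sqrt(3.0) / 2.0
    sites = []
    j = 0
    y = 0.0
    while y <= ARRAY_Y_UM:
        x0 = (LATTICE_PITCH_UM / 2.0) if (j % 2) else 0.0
        x = x0
        while x <= ARRAY_X_UM:
            sites.append((x, y))
            x += LATTICE_PITCH_UM
        j += 1
        y = j * row_pitch
    sites = np.asarray(sites)
    if n > len(sites):
        raise ValueError(f"cannot place {n} neurons on {len(sites)} lattice sites")
    chosen = sites[rng.choice(len(sites), size=n, replace=False)]
    return chosen + rng.uniform(-scatter_um, scatter_um, size=chosen.shape)


def generate_population(
    n_neurons: int,
    duration: float,
    rate_log10_mean: float = -0.16,
    rate_log10_sd: float = 0.64,
    seed: int = 0,
    region_label: str = "synthetic",
) -> Recording:
    """Independent Poisson population with lognormal rates on the array.

    Rates are ``10**N(rate_log10_mean, rate_log10_sd)`` Hz; spike times of
    each neuron are homogeneous Poisson over ``[0, duration]``.
    """
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    rates = 10.0 ** rng.normal(rate_log10_mean, rate_log10_sd, size=n_neurons)
    pos = hexagonal_positions(n_neurons, rng)
    trains = []
    for i in range(n_neurons):
        count = rng.poisson(rates[i] * duration)
        times = np.sort(rng.uniform(0.0, duration, size=count))
        trains.append(SpikeTrain(i, times, (float(pos[i, 0]), float(pos[i, 1]))))
    return Recording(trains=tuple(trains), duration=duration, region_label=region_label)


def inject_synaptic(
    rec: Recording,
    source: int,
    target: int,
    delay_ms: float = 3.0,
    jitter_ms: float = 1.0,
    efficacy: float = 0.5,
    seed: int = 0,
    ground_truth: Optional[GroundTruth] = None,
) -> tuple[Recording, GroundTruth]:
    """Add a synaptic-like coupling from ``source`` onto ``target``.

    Each source spike elicits, with probability ``efficacy``, a target spike
    at ``t + delay + N(0, jitter)``; elicited spikes falling outside the
    recording are dropped.  The resulting correlogram acquires a peak
    offset by roughly ``delay_ms`` with width ``jitter_ms``.
    """
    if not 0.0 <= efficacy <= 1.0:
        raise ValueError("efficacy must lie in [0, 1]")
    if delay_ms <= 0:
        raise ValueError("delay_ms must be positive")
    src = rec[source]  # KeyError for unknown ids
    tgt = rec[target]
    gt = ground_truth if ground_truth is not None else GroundTruth()
    rng = np.random.default_rng(seed)
    fired = rng.random(src.n_spikes) < efficacy if efficacy < 1.0 else np.ones(
        src.n_spikes, dtype=bool
    )
    new = src.times[fired] + delay_ms * 1e-3
    if jitter_ms > 0:
        new = new + rng.normal(0.0, jitter_ms * 1e-3, size=new.size)
    new = new[(new >= 0.0) & (new <= rec.duration)]
    merged = np.sort(np.concatenate([tgt.times, new]))
    trains = [
        SpikeTrain(tr.neuron_id, merged, tr.position) if tr.neuron_id == target else tr
        for tr in rec.trains
    ]
    gt.edges.append(
        GroundTruthEdge(source, target, "synaptic", delay_ms=delay_ms, strength=efficacy)
    )
    return rec.with_trains(trains), gt


def inject_common_drive(
    rec: Recording,
    members: Sequence[int],
    freq_hz: float,
    modulation_depth: float,
    seed: int = 0,
    ground_truth: Optional[GroundTruth] = None,
) -> tuple[Recording, GroundTruth]:
    """Rebuild ``members`` as inhomogeneous Poisson with shared oscillation.

    Member rates are preserved, but spikes are regenerated (by thinning)
    from ``r * (1 + depth * sin(2*pi*f*t + phi))`` with a common random
    phase ``phi``, so every member pair acquires a zero-centered
    correlogram oscillating at ``freq_hz``.
    """
    if freq_hz <= 0:
        raise ValueError("freq_hz must be positive")
    if not 0.0 <= modulation_depth <= 1.0:
        raise ValueError("modulation_depth must lie in [0, 1]")
    for m in members:
        rec[m]  # KeyError for unknown ids
    gt = ground_truth if ground_truth is not None else GroundTruth()
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    new_trains = {}
    for m in members:
        r = rec[m].n_spikes / rec.duration
        r_max = r * (1.0 + modulation_depth)
        count = rng.poisson(r_max * rec.duration)
        t = rng.uniform(0.0, rec.duration, size=count)
        accept = rng.random(count) * r_max <= r * (
            1.0 + modulation_depth * np.sin(2.0 * np.pi * freq_hz * t + phase)
        )
        new_trains[m] = np.sort(t[accept])
    trains = [
        SpikeTrain(tr.neuron_id, new_trains[tr.neuron_id], tr.position)
        if tr.neuron_id in new_trains
        else tr
        for tr in rec.trains
    ]
    members = list(members)
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            gt.edges.append(
                GroundTruthEdge(
                    members[i],
                    members[j],
                    "common_drive",
                    strength=modulation_depth,
                    freq_hz=freq_hz,
                )
            )
    return rec.with_trains(trains), gt


def make_synaptic_population(
    n_neurons: int = 40,
    n_edges: int = 20,
    duration: float = 3600.0,
    rate_hz: float = 2.0,
    delay_ms: float = 3.0,
    jitter_ms: float = 1.0,
    efficacy: float = 0.5,
    seed: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Homogeneous-rate population wired with ``n_edges`` random synaptic couplings.

    A convenience generator for end-to-end recovery experiments: every
    neuron fires at ``rate_hz`` (so all couplings are statistically
    detectable in a one-hour recording) and couplings connect distinct
    random pairs.
    """
    rng = np.random.default_rng(seed)
    pos = hexagonal_positions(n_neurons, rng)
    trains = []
    for i in range(n_neurons):
        count = rng.poisson(rate_hz * duration)
        trains.append(
            SpikeTrain(i, np.sort(rng.uniform(0.0, duration, size=count)),
                       (float(pos[i, 0]), float(pos[i, 1])))
        )
    rec = Recording(trains=tuple(trains), duration=duration, region_label="synthetic")
    pairs = [(i, j) for i in range(n_neurons) for j in range(i + 1, n_neurons)]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    gt = GroundTruth()
    for idx in chosen:
        s, t = pairs[idx]
        if rng.random() < 0.5:
            s, t = t, s
        rec, gt = inject_synaptic(
            rec, s, t, delay_ms=delay_ms, jitter_ms=jitter_ms,
            efficacy=efficacy, seed=int(rng.integers(2**31)), ground_truth=gt,
        )
    return rec, gt
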