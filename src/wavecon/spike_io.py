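"""Spike-recording data model, delimited-text I/O, and preprocessing filters.

A recording is a set of sorted spike-time vectors (seconds), one per neuron,
optionally annotated with a 2-D soma position in micrometres.  Files are
comma- or tab-delimited text with a header row:

* spike file:    ``neuron_id, time_s``
* position file: ``neuron_id, x_um, y_um``
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "Recording",
    "ParseError",
    "SpikeValidationError",
    "read_spikes",
    "write_spikes",
    "filter_low_rate",
    "require_min_population",
]


class ParseError(ValueError):
    """A delimited spike/position file contained a malformed row."""


class SpikeValidationError(ValueError):
    """Spike data violated a structural invariant (ordering, range, ids)."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one neuron.

    Parameters
    ----------
    neuron_id : int
        Identifier, unique within a :class:`Recording`.
    times : ndarray
        Spike times in seconds, sorted ascending.  Ties are tolerated (they
        can arise from boundary clipping after time jittering) and collapse
        to a single binary bin state downstream.
    position : (float, float) or None
        Soma position in micrometres, or ``None`` when unknown.
    """

    neuron_id: int
    times: np.ndarray
    position: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise SpikeValidationError("spike times must be a 1-D array")
        if np.any(np.diff(t) < 0):
            t = np.sort(t)
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def rate(self, duration: float) -> float:
        """Mean firing rate in Hz over ``duration`` seconds."""
        return self.n_spikes / float(duration)


@dataclass(frozen=True)
class Recording:
    """A population of spike trains recorded over a common interval.

    Invariants: ``duration > 0``; every spike time lies in
    ``[0, duration]``; neuron ids are unique.
    """

    trains: tuple[SpikeTrain, ...]
    duration: float
    region_label: str = ""

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise SpikeValidationError("recording duration must be positive")
        trains = tuple(self.trains)
        ids = [tr.neuron_id for tr in trains]
        if len(set(ids)) != len(ids):
            raise SpikeValidationError("duplicate neuron ids in recording")
        for tr in trains:
            if tr.n_spikes and (tr.times[0] < 0 or tr.times[-1] > self.duration):
                raise SpikeValidationError(
                    f"neuron {tr.neuron_id}: spike times outside [0, duration]"
                )
        object.__setattr__(self, "trains", trains)

    def __iter__(self) -> Iterator[SpikeTrain]:
        return iter(self.trains)

    def __len__(self) -> int:
        return len(self.trains)

    @property
    def neuron_ids(self) -> list[int]:
        return [tr.neuron_id for tr in self.trains]

    def __getitem__(self, neuron_id: int) -> SpikeTrain:
        for tr in self.trains:
            if tr.neuron_id == neuron_id:
                return tr
        raise KeyError(neuron_id)

    def positions(self) -> dict[int, Optional[tuple[float, float]]]:
        return {tr.neuron_id: tr.position for tr in self.trains}

    def with_trains(self, trains: Iterable[SpikeTrain]) -> "Recording":
        return replace(self, trains=tuple(trains))


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ParseError(f"{path}: could not parse delimited text ({exc})") from exc
    if df.shape[1] < len(columns):
        raise ParseError(
            f"{path}: expected columns {list(columns)}, found {list(df.columns)}"
        )
    df = df.iloc[:, : len(columns)]
    df.columns = list(columns)
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header row, one for 1-based line numbers
            line = int(bad.idxmax()) + 2
            raise ParseError(f"{path}: malformed value in column '{col}' at line {line}")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ParseError(f"{path}: missing value in column '{col}' at line {line}")
        df[col] = coerced
    return df


def read_spikes(
    spike_path: str | Path,
    position_path: str | Path | None,
    duration: float,
    region_label: str = "",
) -> Recording:
    """Read a spike file plus optional position file into a :class:`Recording`.

    Spike times are sorted per neuron.  Neurons present in the spike file but
    absent from the position file get ``position=None``.  Times outside
    ``[0, duration]`` raise :class:`SpikeValidationError`.
    """
    spikes = _read_table(spike_path, ("neuron_id", "time_s"))
    if np.any(spikes["time_s"] < 0) or np.any(spikes["time_s"] > duration):
        bad = spikes.loc[
            (spikes["time_s"] < 0) | (spikes["time_s"] > duration)
        ].iloc[0]
        raise SpikeValidationError(
            f"{spike_path}: neuron {int(bad['neuron_id'])} has spike time "
            f"{bad['time_s']} outside [0, {duration}]"
        )
    positions: dict[int, tuple[float, float]] = {}
    if position_path is not None:
        pos = _read_table(position_path, ("neuron_id", "x_um", "y_um"))
        positions = {
            int(r.neuron_id): (float(r.x_um), float(r.y_um))
            for r in pos.itertuples()
        }
    trains = []
    for nid, group in spikes.groupby("neuron_id", sort=True):
        trains.append(
            SpikeTrain(
                neuron_id=int(nid),
                times=np.sort(group["time_s"].to_numpy(dtype=float)),
                position=positions.get(int(nid)),
            )
        )
    return Recording(trains=tuple(trains), duration=float(duration), region_label=region_label)


def write_spikes(
    rec: Recording,
    spike_path: str | Path,
    position_path: str | Path | None = None,
) -> None:
    """Write a recording back to the spike/position file dialect it is read from."""
    rows = [
        (tr.neuron_id, t) for tr in rec.trains for t in tr.times
    ]
    pd.DataFrame(rows, columns=["neuron_id", "time_s"]).to_csv(spike_path, index=False)
    if position_path is not None:
        prow = [
            (tr.neuron_id, tr.position[0], tr.position[1])
            for tr in rec.trains
            if tr.position is not None
        ]
        pd.DataFrame(prow, columns=["neuron_id", "x_um", "y_um"]).to_csv(
            position_path, index=False
        )


def filter_low_rate(rec: Recording, min_spikes_per_hour: float = 100.0) -> Recording:
    """Drop neurons firing fewer than ``min_spikes_per_hour`` spikes per hour.

    The boundary is kept: a neuron at exactly the threshold rate survives
    (exclusion applies strictly below it).  Idempotent.
    """
    hours = rec.duration / 3600.0
    kept = [tr for tr in rec.trains if tr.n_spikes / hours >= min_spikes_per_hour]
    return rec.with_trains(kept)


def require_min_population(rec: Recording, min_neurons: int = 100) -> bool:
    """True when the recording holds at least ``min_neurons`` neurons.

    Populations below the cutoff are too small for subsampling-controlled
    network statistics and are excluded from analysis.
    """
    return len(rec) >= min_neurons
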