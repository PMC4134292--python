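"""End-to-end convenience layer: recording -> correlograms -> power -> connections.

Thin glue over the stage modules so scripts, tests and the CLI can run the
whole inference with one call per analysis scale.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import numpy as np

from .correlogram import (
    ARTIFACT_DISTANCE_UM,
    Correlogram,
    compute_cch,
    interpolate_artifact,
)
from .connectivity import Connection, connections_from_power
from .significance import ThresholdTable
from .spike_io import Recording
from .wavelet import WaveletConfig, preset, transform

__all__ = ["pair_correlograms", "scale_connections", "pair_distance"]


def pair_distance(rec: Recording, i: int, j: int) -> Optional[float]:
    pi, pj = rec[i].position, rec[j].position
    if pi is None or pj is None:
        return None
    return float(np.hypot(pi[0] - pj[0], pi[1] - pj[1]))


def pair_correlograms(
    rec: Recording,
    cfg: WaveletConfig,
    pairs: Optional[Iterable[tuple[int, int]]] = None,
    artifact_interpolation: bool = True,
) -> Iterator[Correlogram]:
    """CCHs of all (or selected) unordered pairs on a scale's lag grid.

    Close pairs (< 180 um) get the central artifact segment interpolated
    away when positions are available.
    """
    if pairs is None:
        ids = rec.neuron_ids
        pairs = ((ids[a], ids[b]) for a in range(len(ids)) for b in range(a + 1, len(ids)))
    for i, j in pairs:
        c = compute_cch(
            rec[i], rec[j], cfg.bin_width, cfg.transform_window,
            pair_distance=pair_distance(rec, i, j),
        )
        if (
            artifact_interpolation
            and c.pair_distance is not None
            and c.pair_distance < ARTIFACT_DISTANCE_UM
        ):
            c = interpolate_artifact(c)
        yield c


def scale_connections(
    rec: Recording,
    scale: int,
    table: ThresholdTable,
    pairs: Optional[Iterable[tuple[int, int]]] = None,
    artifact_interpolation: bool = True,
) -> list[Connection]:
    """All significant band-assigned connections of a recording at one scale.

    Pairs whose spike count falls outside the threshold table's tabulated
    range are skipped (they carry either no counts or more than the
    calibrated maximum).
    """
    cfg = preset(scale)
    lo = 10.0 ** table.k_grid[0]
    hi = 10.0 ** table.k_grid[-1]
    out: list[Connection] = []
    for c in pair_correlograms(rec, cfg, pairs, artifact_interpolation):
        if not lo <= c.n_spikes <= hi:
            continue
        out.extend(connections_from_power(transform(c, cfg), table, scale))
    return out
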