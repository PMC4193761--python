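"""Spike raster container and plain-text / JSON serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np


@dataclass
class SpikeData:
    """Per-neuron ordered spike times plus population labelling.

    ``trains`` maps a global neuron id to a strictly increasing array of
    spike times in ms.  ``populations`` maps a population name to the
    half-open global-id range ``(start, stop)`` of its members, so slicing
    a population out of a raster is O(1) bookkeeping.
    """

    trains: Dict[int, np.ndarray]
    populations: Dict[str, Tuple[int, int]]
    duration: float

    def __post_init__(self) -> None:
        for nid, t in self.trains.items():
            arr = np.asarray(t, dtype=float)
            self.trains[nid] = arr
            if arr.size and (np.any(np.diff(arr) <= 0)):
                raise ValueError(f"spike times of neuron {nid} not strictly increasing")
            if arr.size and (arr[0] < 0 or arr[-1] > self.duration):
                raise ValueError(f"spike times of neuron {nid} outside [0, duration]")

    # -- access ---------------------------------------------------------

    def neuron_ids(self, population: str | None = None) -> range:
        if population is None:
            stop = max((s for _, s in self.populations.values()), default=0)
            return range(stop)
        start, stop = self.populations[population]
        return range(start, stop)

    def train(self, neuron_id: int) -> np.ndarray:
        return self.trains.get(neuron_id, np.empty(0))

    def population_spikes(self, population: str) -> np.ndarray:
        """All spike times of one population, pooled and sorted."""
        ids = self.neuron_ids(population)
        parts = [self.trains[i] for i in ids if i in self.trains]
        if not parts:
            return np.empty(0)
        return np.sort(np.concatenate(parts))

    def n_spikes(self, population: str | None = None) -> int:
        ids = self.neuron_ids(population)
        return sum(self.trains[i].size for i in ids if i in self.trains)

    def subset(self, population: str) -> "SpikeData":
        start, stop = self.populations[population]
        trains = {i: self.trains[i] for i in range(start, stop) if i in self.trains}
        return SpikeData(trains, {population: (start, stop)}, self.duration)

    def rates(self, population: str, t_start: float = 0.0,
              t_stop: float | None = None) -> np.ndarray:
        """Per-neuron firing rates in Hz over [t_start, t_stop]."""
        t_stop = self.duration if t_stop is None else t_stop
        window = (t_stop - t_start) / 1000.0
        ids = self.neuron_ids(population)
        out = np.zeros(len(ids))
        for k, i in enumerate(ids):
            t = self.train(i)
            if t.size:
                out[k] = np.count_nonzero((t >= t_start) & (t < t_stop)) / window
        return out

    def last_spike_time(self) -> float | None:
        last = [t[-1] for t in self.trains.values() if t.size]
        return max(last) if last else None

    # -- serialization --------------------------------------------------

    def to_pairs(self) -> np.ndarray:
        """(time_ms, neuron_id) pairs sorted by time — gdf-like layout."""
        times, ids = [], []
        for nid, t in self.trains.items():
            times.append(t)
            ids.append(np.full(t.size, nid, dtype=float))
        if not times:
            return np.empty((0, 2))
        pairs = np.column_stack([np.concatenate(times), np.concatenate(ids)])
        return pairs[np.argsort(pairs[:, 0], kind="stable")]

    def write_raster(self, path: str | Path) -> None:
        np.savetxt(path, self.to_pairs(), fmt="%.4f %d")

    def write_json(self, path: str | Path) -> None:
        doc = {
            "duration": self.duration,
            "populations": {k: list(v) for k, v in self.populations.items()},
            "trains": {str(k): v.tolist() for k, v in self.trains.items()},
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def read_json(cls, path: str | Path) -> "SpikeData":
        doc = json.loads(Path(path).read_text())
        return cls(
            trains={int(k): np.asarray(v) for k, v in doc["trains"].items()},
            populations={k: tuple(v) for k, v in doc["populations"].items()},
            duration=doc["duration"],
        )

    @classmethod
    def from_pairs(cls, pairs: np.ndarray,
                   populations: Mapping[str, Tuple[int, int]],
                   duration: float) -> "SpikeData":
        trains: Dict[int, List[float]] = {}
        for t, nid in pairs:
            trains.setdefault(int(nid), []).append(float(t))
        return cls({k: np.asarray(sorted(v)) for k, v in trains.items()},
                   dict(populations), duration)


def merge_spike_data(parts: Sequence[SpikeData], duration: float) -> SpikeData:
    trains: Dict[int, np.ndarray] = {}
    pops: Dict[str, Tuple[int, int]] = {}
    for p in parts:
        trains.update(p.trains)
        pops.update(p.populations)
    return SpikeData(trains, pops, duration)
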