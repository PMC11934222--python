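"""Core containers: spike trains and labeled epoch sets.

Times are in seconds throughout. Epoch intervals follow the half-open
convention ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

STATE_LABELS = ("WAKE", "NREM", "REM")
UPDOWN_LABELS = ("UP", "DOWN")


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit over a recording.

    Parameters
    ----------
    unit_id : hashable
        Unit identifier.
    times : ndarray
        Spike times in seconds, nondecreasing, within ``[t_start, t_end]``.
    t_start, t_end : float
        Recording bounds in seconds.
    """

    unit_id: object
    times: np.ndarray
    t_start: float = 0.0
    t_end: float = float("nan")

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        t_end = self.t_end
        if np.isnan(t_end):
            t_end = float(times[-1]) if times.size else float(self.t_start)
            object.__setattr__(self, "t_end", t_end)
        if times.size:
            if np.any(np.diff(times) < 0):
                raise ValueError(f"unit {self.unit_id}: spike times not sorted")
            if times[0] < self.t_start - 1e-9 or times[-1] > self.t_end + 1e-9:
                raise ValueError(
                    f"unit {self.unit_id}: spike times outside [t_start, t_end]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def rate(self) -> float:
        dur = self.t_end - self.t_start
        return self.n_spikes / dur if dur > 0 else 0.0

    def restrict(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Spike times falling inside any of the half-open intervals."""
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        if starts.size == 0:
            return np.empty(0)
        lo = np.searchsorted(self.times, starts, side="left")
        hi = np.searchsorted(self.times, ends, side="left")
        return np.concatenate([self.times[a:b] for a, b in zip(lo, hi)])


@dataclass
class EpochSet:
    """Labeled half-open time intervals (sleep states or UP/DOWN).

    Intervals sharing a label must not overlap; intervals are stored sorted
    by start time.
    """

    starts: np.ndarray
    ends: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (self.starts.size == self.ends.size == self.labels.size):
            raise ValueError("starts, ends, labels must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("every epoch must satisfy start < end")
        order = np.argsort(self.starts, kind="stable")
        self.starts = self.starts[order]
        self.ends = self.ends[order]
        self.labels = self.labels[order]
        for lab in set(self.labels.tolist()):
            s, e = self.select(lab)
            if np.any(s[1:] < e[:-1] - 1e-9):
                raise ValueError(f"overlapping epochs within label {lab!r}")

    @classmethod
    def from_tuples(cls, intervals: Iterable[tuple]) -> "EpochSet":
        ivs = list(intervals)
        if not ivs:
            return cls(np.empty(0), np.empty(0), np.empty(0, dtype=object))
        s, e, l = zip(*ivs)
        return cls(np.array(s, float), np.array(e, float), np.array(l, dtype=object))

    def __len__(self) -> int:
        return int(self.starts.size)

    def select(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) of all epochs carrying ``label``."""
        m = self.labels == label
        return self.starts[m], self.ends[m]

    def total_duration(self, label: str) -> float:
        s, e = self.select(label)
        return float(np.sum(e - s))

    def label_set(self) -> set:
        return set(self.labels.tolist())

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(self.starts[mask], self.ends[mask], self.labels[mask])

    def intersect_window(self, w_start: float, w_end: float) -> "EpochSet":
        """Clip all epochs to a time window, dropping empty remainders."""
        s = np.maximum(self.starts, w_start)
        e = np.minimum(self.ends, w_end)
        keep = e > s
        return EpochSet(s[keep], e[keep], self.labels[keep])

    def to_tuples(self) -> list[tuple]:
        return list(zip(self.starts.tolist(), self.ends.tolist(), self.labels.tolist()))


def pair_key(a, b) -> tuple:
    """Canonical unordered pair key (sorted by string form of the ids)."""
    return (a, b) if str(a) <= str(b) else (b, a)


def all_pairs(unit_ids: Sequence) -> list[tuple]:
    out = []
    for i in range(len(unit_ids)):
        for j in range(i + 1, len(unit_ids)):
            out.append((unit_ids[i], unit_ids[j]))
    return out
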