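"""Containers for idealized single-channel records.

An :class:`EventList` is one recording reduced to the alternating sequence of
class sojourns (0 = shut, 1 = open) with durations in seconds and, optionally,
a per-event amplitude in pA.  A :class:`BurstSet` is the same record carved
into bursts by a critical shut duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

SHUT_CLASS = 0
OPEN_CLASS = 1


@dataclass
class EventList:
    classes: np.ndarray          # int, 0 = shut, 1 = open
    durations: np.ndarray        # float seconds, > 0
    amplitudes: np.ndarray | None = None   # pA; NaN where unknown
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int8)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.classes.shape != self.durations.shape:
            raise ValueError("classes and durations must have equal length")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
            if self.amplitudes.shape != self.durations.shape:
                raise ValueError("amplitudes length mismatch")
        if np.any(self.durations <= 0):
            raise ValueError("all event durations must be > 0")
        if not np.all(np.isin(self.classes, (SHUT_CLASS, OPEN_CLASS))):
            raise ValueError("classes must be 0 (shut) or 1 (open)")

    def __len__(self) -> int:
        return len(self.classes)

    def __getitem__(self, sl) -> "EventList":
        if not isinstance(sl, slice):
            raise TypeError("EventList supports slice indexing only")
        return EventList(
            self.classes[sl],
            self.durations[sl],
            None if self.amplitudes is None else self.amplitudes[sl],
            dict(self.meta),
        )

    @property
    def is_alternating(self) -> bool:
        return bool(np.all(np.diff(self.classes) != 0))

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    def open_durations(self) -> np.ndarray:
        return self.durations[self.classes == OPEN_CLASS]

    def shut_durations(self) -> np.ndarray:
        return self.durations[self.classes == SHUT_CLASS]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"class": self.classes.astype(int), "duration_s": self.durations}
        )
        if self.amplitudes is not None:
            df["amplitude_pA"] = self.amplitudes
        return df

    def __eq__(self, other) -> bool:  # value equality, meta excluded
        if not isinstance(other, EventList):
            return NotImplemented
        if len(self) != len(other):
            return False
        same = np.array_equal(self.classes, other.classes) and np.allclose(
            self.durations, other.durations, rtol=0, atol=0
        )
        if self.amplitudes is None or other.amplitudes is None:
            return same and (self.amplitudes is None) == (other.amplitudes is None)
        return same and np.allclose(
            self.amplitudes, other.amplitudes, rtol=0, atol=0, equal_nan=True
        )


def concat_events(parts: Sequence[EventList]) -> EventList:
    """Concatenate event fragments (metadata taken from the first)."""
    if not parts:
        raise ValueError("nothing to concatenate")
    amps = None
    if all(p.amplitudes is not None for p in parts):
        amps = np.concatenate([p.amplitudes for p in parts])
    return EventList(
        np.concatenate([p.classes for p in parts]),
        np.concatenate([p.durations for p in parts]),
        amps,
        dict(parts[0].meta),
    )


def burst_popen(burst: EventList) -> float:
    """Fraction of the burst's duration spent open."""
    tot = burst.total_duration
    return float(burst.open_durations().sum() / tot) if tot > 0 else np.nan


def burst_amplitude(burst: EventList) -> float:
    """Open-level minus shut-level mean amplitude within one burst (pA).

    With no amplitude annotation on shut events (the usual case for
    baseline-subtracted records) the mean open amplitude is returned.
    """
    if burst.amplitudes is None:
        return np.nan
    opens = burst.amplitudes[burst.classes == OPEN_CLASS]
    shuts = burst.amplitudes[burst.classes == SHUT_CLASS]
    open_mean = np.nanmean(opens) if opens.size else np.nan
    shut_mean = np.nanmean(shuts) if shuts.size and not np.all(np.isnan(shuts)) else 0.0
    return float(open_mean - shut_mean)


@dataclass
class BurstSet:
    """Events partitioned into bursts by a critical shut duration."""

    bursts: list[EventList]
    tau_crit: float              # seconds; inf = single burst
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.bursts)

    def __iter__(self) -> Iterator[EventList]:
        return iter(self.bursts)

    @property
    def popen(self) -> np.ndarray:
        return np.array([burst_popen(b) for b in self.bursts])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([burst_amplitude(b) for b in self.bursts])

    @property
    def n_events(self) -> np.ndarray:
        return np.array([len(b) for b in self.bursts])

    def openings_per_burst(self) -> np.ndarray:
        return np.array(
            [int((b.classes == OPEN_CLASS).sum()) for b in self.bursts]
        )

    def all_events(self) -> EventList:
        return concat_events(self.bursts)

    def table(self) -> pd.DataFrame:
        """Per-burst summary (duration, P_open, amplitude, event count)."""
        return pd.DataFrame(
            {
                "duration_s": [b.total_duration for b in self.bursts],
                "p_open": self.popen,
                "amplitude_pA": self.amplitudes,
                "n_events": self.n_events,
            }
        )
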