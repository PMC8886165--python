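"""Phase segmentation of the horizontal trajectory signal.

The horizontal (X) coordinate of the greater tuberosity relative to the
acromial edge traces a roughly sinusoidal pattern during repeated arm
abduction/adduction: each peak marks the moment the tuberosity rotates
underneath the acromion, each trough its return to the start position.
The interval after a trough and before the next peak is an abduction
phase; after a peak and before the next trough, an adduction phase.
Recordings typically contain five repetitions of which the middle three
cycles are analysed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import find_peaks

from .exceptions import InsufficientCyclesError
from .landmarks import RelativeTrajectory

__all__ = [
    "PeakSet",
    "PhaseSegment",
    "detect_extrema",
    "segment_phases",
    "trim_middle_cycles",
]

Direction = Literal["abduction", "adduction"]

#: Default minimum extremum prominence, as a fraction of signal range.
DEFAULT_PROMINENCE_FRACTION = 0.2


@dataclass(frozen=True)
class PeakSet:
    """Indices of detected peaks and troughs on the X signal.

    Merged in time order, peaks and troughs strictly alternate.
    """

    peak_indices: np.ndarray
    trough_indices: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "peak_indices", np.asarray(self.peak_indices, dtype=int)
        )
        object.__setattr__(
            self, "trough_indices", np.asarray(self.trough_indices, dtype=int)
        )

    def merged(self) -> list[tuple[int, str]]:
        """All extrema in time order as (index, 'peak'|'trough') pairs."""
        events = [(int(i), "peak") for i in self.peak_indices] + [
            (int(i), "trough") for i in self.trough_indices
        ]
        return sorted(events)


@dataclass(frozen=True)
class PhaseSegment:
    """One abduction or adduction half-cycle (inclusive frame range)."""

    direction: Direction
    start_index: int
    end_index: int
    cycle: int

    def __post_init__(self) -> None:
        if self.start_index >= self.end_index:
            raise ValueError("start_index must be < end_index")


def _alternating(x: np.ndarray, peaks: np.ndarray, troughs: np.ndarray) -> PeakSet:
    """Merge candidate extrema, collapsing same-type runs to the strongest.

    Ties keep the earliest index.
    """
    events = sorted([(int(i), "peak") for i in peaks] + [(int(i), "trough") for i in troughs])
    kept: list[tuple[int, str]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = x[idx] > x[prev] if kind == "peak" else x[idx] < x[prev]
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    return PeakSet(
        peak_indices=[i for i, k in kept if k == "peak"],
        trough_indices=[i for i, k in kept if k == "trough"],
    )


def detect_extrema(
    x_signal: np.ndarray,
    min_prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
    min_separation: int | None = None,
) -> PeakSet:
    """Detect alternating peaks and troughs on the X signal.

    Prominence-thresholded peak picking (on the signal and its negation),
    followed by an alternation pass that collapses consecutive same-type
    extrema to the strongest one.  When ``min_separation`` is None, a second
    detection pass enforces a minimum spacing of half the median
    inter-extremum interval from the first pass, suppressing noise-induced
    twin extrema.

    A constant signal, or one without any sufficiently prominent extremum,
    yields an empty :class:`PeakSet`; the caller decides whether that is an
    error.
    """
    x = np.asarray(x_signal, dtype=float)
    if x.size < 5:
        raise ValueError(f"signal too short for extremum detection: {x.size}")
    if not 0 < min_prominence_fraction < 1:
        raise ValueError("min_prominence_fraction must be in (0, 1)")
    rng = float(np.max(x) - np.min(x))
    if rng == 0:
        return PeakSet(peak_indices=[], trough_indices=[])
    prom = min_prominence_fraction * rng

    def _detect(distance):
        p, _ = find_peaks(x, prominence=prom, distance=distance)
        t, _ = find_peaks(-x, prominence=prom, distance=distance)
        return p, t

    peaks, troughs = _detect(min_separation)
    if min_separation is None and (peaks.size + troughs.size) >= 3:
        spacing = np.diff(np.sort(np.concatenate([peaks, troughs])))
        sep = max(1, int(np.median(spacing) // 2))
        peaks, troughs = _detect(sep)
    return _alternating(x, peaks, troughs)


def segment_phases(
    traj: RelativeTrajectory, peaks: PeakSet
) -> list[PhaseSegment]:
    """Partition the recording into abduction/adduction segments.

    Each trough-to-next-peak interval becomes an abduction segment and each
    peak-to-next-trough interval an adduction segment.  Troughs delimit
    cycles: the cycle counter starts at 1 and increments at every trough
    after the first extremum.
    """
    events = peaks.merged()
    if len(events) < 2:
        raise InsufficientCyclesError(
            "need at least one trough and one peak to form a phase"
        )
    n = traj.n
    segments: list[PhaseSegment] = []
    cycle = 1
    for (i0, k0), (i1, k1) in zip(events[:-1], events[1:]):
        if not (0 <= i0 < i1 < n):
            raise ValueError("extremum indices out of trajectory bounds")
        if k0 == "trough" and segments:
            cycle += 1
        direction: Direction = "abduction" if k0 == "trough" else "adduction"
        segments.append(
            PhaseSegment(direction=direction, start_index=i0, end_index=i1, cycle=cycle)
        )
    if not segments:
        raise InsufficientCyclesError("no complete phase found")
    return segments


def trim_middle_cycles(
    segments: list[PhaseSegment], keep: int = 3
) -> list[PhaseSegment]:
    """Keep the middle ``keep`` complete cycles, renumbered from 1.

    A complete cycle contains both an abduction and an adduction segment.
    With an odd surplus of cycles, one more leading than trailing cycle is
    dropped (later-biased middle): e.g. 4 complete cycles with ``keep=3``
    retain cycles 2-4.  Fewer than ``keep`` complete cycles is not fatal:
    all complete cycles are returned with a warning, so short recordings
    still produce (flagged) results.
    """
    if keep < 1:
        raise ValueError("keep must be >= 1")
    by_cycle: dict[int, set[str]] = {}
    for s in segments:
        by_cycle.setdefault(s.cycle, set()).add(s.direction)
    complete = sorted(c for c, dirs in by_cycle.items() if len(dirs) == 2)
    if len(complete) < keep:
        warnings.warn(
            f"only {len(complete)} complete cycle(s) available; "
            f"requested middle {keep} — returning all complete cycles",
            stacklevel=2,
        )
        retained = complete
    else:
        surplus = len(complete) - keep
        drop_lead = surplus - surplus // 2  # later-biased middle
        retained = complete[drop_lead : drop_lead + keep]
    if not retained:
        raise InsufficientCyclesError("no complete cycles to retain")
    renumber = {c: i + 1 for i, c in enumerate(retained)}
    return [
        PhaseSegment(
            direction=s.direction,
            start_index=s.start_index,
            end_index=s.end_index,
            cycle=renumber[s.cycle],
        )
        for s in segments
        if s.cycle in renumber
    ]
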