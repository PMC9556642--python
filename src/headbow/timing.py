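"""Take length, tempo, tempo variability and local metrical frequencies.

The beat grid annotates half-note steps only, so each step duration
yields two identical inter-beat (quarter-note) intervals.  Metrical
frequencies follow the exact x2 ladder: f_half = 2 f_whole,
f_quarter = 4 f_whole, f_eighth = 8 f_whole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LEVEL_BEATS, LEVELS, BeatGrid


@dataclass(frozen=True)
class TempoSummary:
    take_length: float  # s
    mean_ibi: float  # ms
    bpm: float  # beats per minute, 60000 / mean_ibi
    cv: float  # sd / mean of the IBI series (sample sd)


@dataclass(frozen=True)
class MetricalFrequencySet:
    """Frequencies (Hz) of the four metrical levels; P1-P4 labels."""

    f_whole: float
    f_half: float
    f_quarter: float
    f_eighth: float
    fallback: bool = False  # True when a window had no IBIs and the
    # take-level mean was substituted

    def __getitem__(self, level: str) -> float:
        return getattr(self, f"f_{level}")

    @classmethod
    def from_quarter(cls, f_quarter: float, fallback: bool = False
                     ) -> "MetricalFrequencySet":
        return cls(
            f_whole=f_quarter / 4.0,
            f_half=f_quarter / 2.0,
            f_quarter=f_quarter,
            f_eighth=f_quarter * 2.0,
            fallback=fallback,
        )


def derive_ibis(grid: BeatGrid, with_onsets: bool = False):
    """Inter-beat intervals (ms) from half-note step durations.

    Each step duration is divided by two and contributes two equal IBIs
    (the grid does not resolve individual beats).  Step pairs spanning a
    pause are excluded.  With ``with_onsets=True`` the onset time (s) of
    each IBI is returned alongside, for window-local tempo estimates.
    """
    onsets = grid.onsets
    durations = np.diff(onsets)
    if np.any(durations <= 0):
        raise ValueError("step onsets must be strictly increasing")
    keep = grid.played[:-1] & grid.played[1:]
    if keep.sum() < 1:
        raise ValueError("need at least two consecutive played steps")
    ibi_ms = np.repeat(durations[keep] / 2.0 * 1000.0, 2)
    if not with_onsets:
        return ibi_ms
    starts = onsets[:-1][keep]
    half = durations[keep] / 2.0
    ibi_onsets = np.empty(ibi_ms.size)
    ibi_onsets[0::2] = starts
    ibi_onsets[1::2] = starts + half
    return ibi_ms, ibi_onsets


def tempo_summary(grid: BeatGrid) -> TempoSummary:
    """Take length, mean IBI, tempo in bpm and IBI coefficient of variation."""
    ibis = derive_ibis(grid)
    mean_ibi = float(ibis.mean())
    cv = float(ibis.std(ddof=1) / mean_ibi) if ibis.size > 1 else 0.0
    return TempoSummary(
        take_length=grid.take_length,
        mean_ibi=mean_ibi,
        bpm=60000.0 / mean_ibi,
        cv=cv,
    )


def local_metrical_frequencies(
    grid: BeatGrid, window: tuple[float, float]
) -> MetricalFrequencySet:
    """Metrical frequencies matched to the local tempo of a time window.

    IBIs whose onsets fall in ``[start, end)`` are averaged and inverted
    to the quarter-note frequency; the other levels follow the exact x2
    ladder.  An empty window falls back to the take-level mean IBI and is
    flagged.
    """
    start, end = window
    ibis, onsets = derive_ibis(grid, with_onsets=True)
    inside = (onsets >= start) & (onsets < end)
    if inside.any():
        mean_ibi = ibis[inside].mean()
        fallback = False
    else:
        mean_ibi = ibis.mean()
        fallback = True
    return MetricalFrequencySet.from_quarter(1000.0 / mean_ibi, fallback=fallback)
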