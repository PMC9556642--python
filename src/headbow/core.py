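"""Core data containers shared across the analysis pipeline.

The pipeline studies how an orchestral string player's *ancillary* head
motion coordinates with the *instrumental* bow motion.  Raw inputs are
3D marker trajectories (mm, 100 Hz) and a beat grid: manually annotated
onsets of half-note "steps" of the score, with bar indices and a flag
marking whether the player is actually playing during each step.

Missing motion-capture samples are encoded as NaN rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Metrical levels of the score, slowest to fastest.  In the spectral
#: analysis their frequency components are conventionally labelled P1-P4.
LEVELS: tuple[str, ...] = ("whole", "half", "quarter", "eighth")

#: Number of beats (quarter notes) spanned by one note of each level.
LEVEL_BEATS: dict[str, float] = {
    "whole": 4.0,
    "half": 2.0,
    "quarter": 1.0,
    "eighth": 0.5,
}

#: Spectral-peak labels for the metrical levels.
LEVEL_LABELS: dict[str, str] = {
    "whole": "P1",
    "half": "P2",
    "quarter": "P3",
    "eighth": "P4",
}


@dataclass
class MarkerTrajectory:
    """Timestamped 3D positions (mm) of a single marker.

    Parameters
    ----------
    positions : ndarray, shape (n, 3)
        Marker coordinates in mm.  A missing sample is a row containing
        NaN (any NaN in a row marks the whole sample missing).
    rate : float
        Sampling rate in Hz.
    name : str
        Marker label (e.g. ``"head1"``, ``"bow"``).
    """

    positions: np.ndarray
    rate: float = 100.0
    name: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        if np.isinf(self.positions).any():
            raise ValueError("coordinates must be finite where present")

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the sample is missing."""
        return np.isnan(self.positions).any(axis=1)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def copy(self) -> "MarkerTrajectory":
        return MarkerTrajectory(self.positions.copy(), self.rate, self.name)


@dataclass
class SpeedSeries:
    """Scalar speed series on the trial clock.

    Values are mm/s straight after differentiation and unitless once the
    per-passage z-scoring has been applied.  Sample ``t`` carries the
    timestamp of position ``t`` (left-aligned first difference), so the
    series is one sample shorter than its source trajectory.  Missing
    samples are NaN.
    """

    values: np.ndarray
    rate: float = 100.0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("speed values must be one-dimensional")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class BeatGrid:
    """Half-note step onsets with bar indices and played flags.

    ``onsets`` are the starts of half-note steps in seconds (strictly
    increasing).  Each step spans two beats (quarter notes); the grid is
    the source of inter-beat intervals and of the local metrical
    frequencies used by the tempo-adaptive spectral analysis.
    """

    onsets: np.ndarray
    bar: np.ndarray
    played: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.bar = np.asarray(self.bar, dtype=int)
        self.played = np.asarray(self.played, dtype=bool)
        if self.onsets.ndim != 1 or self.onsets.size < 2:
            raise ValueError("a beat grid needs at least two step onsets")
        if not (self.onsets.shape == self.bar.shape == self.played.shape):
            raise ValueError("onsets, bar and played must have equal length")
        if not np.all(np.isfinite(self.onsets)):
            raise ValueError("step onsets must be finite")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("step onsets must be strictly increasing")
        if self.played.sum() < 2:
            raise ValueError("a beat grid needs at least two played steps")

    @property
    def n_steps(self) -> int:
        return self.onsets.size

    def step_durations(self) -> np.ndarray:
        """Duration of each step; the last one borrows the mean of the others."""
        d = np.diff(self.onsets)
        return np.append(d, d.mean())

    def beat_times(self) -> np.ndarray:
        """Quarter-note (beat) onsets: step onsets interleaved with midpoints.

        One extra beat is appended at the end of the last step so the
        grid brackets the full take extent.
        """
        dur = self.step_durations()
        beats = np.empty(2 * self.n_steps + 1)
        beats[0::2][:-1] = self.onsets
        beats[1::2] = self.onsets + dur / 2.0
        beats[-1] = self.onsets[-1] + dur[-1]
        return beats

    def beat_phase(self, t: np.ndarray) -> np.ndarray:
        """Continuous beat phase (rad): advances by 2*pi per quarter note.

        Piecewise linear through the beat grid, linearly extrapolated at
        the edges with the first/last inter-beat slope.
        """
        t = np.asarray(t, dtype=float)
        beats = self.beat_times()
        phase_knots = 2.0 * np.pi * np.arange(beats.size)
        # pad one interval on each side for linear extrapolation
        bt = np.concatenate(
            [[2 * beats[0] - beats[1]], beats, [2 * beats[-1] - beats[-2]]]
        )
        ph = np.concatenate(
            [[phase_knots[0] - 2 * np.pi], phase_knots, [phase_knots[-1] + 2 * np.pi]]
        )
        return np.interp(t, bt, ph)

    def level_phase(self, t: np.ndarray, level: str) -> np.ndarray:
        """Phase at a metrical level: beat phase divided by beats per note."""
        return self.beat_phase(t) / LEVEL_BEATS[level]

    @property
    def take_length(self) -> float:
        """First onset to the end of the last step, in seconds."""
        dur = self.step_durations()
        return float(self.onsets[-1] + dur[-1] - self.onsets[0])


@dataclass(frozen=True)
class Passage:
    """A contiguous run of played half-note steps with one note value.

    ``note_value`` is the metrical level at which the bow reverses
    direction within the passage (the prevailing written note value).
    Steps are inclusive indices into the beat grid.
    """

    start_step: int
    end_step: int
    note_value: str = "eighth"

    def __post_init__(self) -> None:
        if self.end_step < self.start_step:
            raise ValueError("end_step must be >= start_step")
        if self.note_value not in LEVELS:
            raise ValueError(f"unknown note value {self.note_value!r}")


@dataclass
class PassageSet:
    """Ordered, non-overlapping passages within one take."""

    passages: Sequence[Passage]

    def __post_init__(self) -> None:
        self.passages = list(self.passages)
        if not self.passages:
            raise ValueError("passage set must not be empty")
        prev_end = -1
        for p in self.passages:
            if p.start_step <= prev_end:
                raise ValueError("passages must be sorted and non-overlapping")
            prev_end = p.end_step

    def __iter__(self):
        return iter(self.passages)

    def __len__(self) -> int:
        return len(self.passages)

    def validate_against(self, grid: BeatGrid) -> None:
        if self.passages[-1].end_step >= grid.n_steps:
            raise ValueError("passage references steps outside the beat grid")

    def extents(self, grid: BeatGrid) -> list[tuple[float, float]]:
        """Time extents [start, end) of each passage in seconds."""
        self.validate_against(grid)
        dur = grid.step_durations()
        out = []
        for p in self.passages:
            start = float(grid.onsets[p.start_step])
            end = float(grid.onsets[p.end_step] + dur[p.end_step])
            out.append((start, end))
        return out

    def sample_slices(self, grid: BeatGrid, rate: float, n_samples: int | None = None
                      ) -> list[tuple[int, int]]:
        """Sample-index ranges [start, stop) of each passage at ``rate``.

        Times are taken relative to the first step onset (the trial clock
        starts there).
        """
        t0 = grid.onsets[0]
        out = []
        for start, end in self.extents(grid):
            a = int(round((start - t0) * rate))
            b = int(round((end - t0) * rate))
            if n_samples is not None:
                b = min(b, n_samples)
            out.append((a, b))
        return out

    def played_flags(self, grid: BeatGrid) -> np.ndarray:
        """Step-level played flags implied by the passage set."""
        flags = np.zeros(grid.n_steps, dtype=bool)
        for p in self.passages:
            flags[p.start_step:p.end_step + 1] = True
        return flags


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval (-pi, pi]."""
    return -(np.mod(-np.asarray(a) + np.pi, 2.0 * np.pi) - np.pi)
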