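"""Marker preprocessing: averaging, gap filling, speed, z-score, band-pass.

The fixed pipeline order is: average the three head-cap markers, fill
short gaps (< 50 ms) by cubic interpolation, differentiate into scalar
speed, z-score each passage, band-pass filter 0.5-12 Hz (zero-phase
second-order Butterworth).  :func:`preprocess_trial` enforces the order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .core import BeatGrid, MarkerTrajectory, PassageSet, SpeedSeries


def average_head_markers(
    m1: MarkerTrajectory, m2: MarkerTrajectory, m3: MarkerTrajectory
) -> MarkerTrajectory:
    """Coordinate-wise mean of the three head-cap markers.

    A sample is missing in the output iff it is missing in any input.
    """
    if not (m1.n_samples == m2.n_samples == m3.n_samples):
        raise ValueError("head markers must have equal length")
    if not (m1.rate == m2.rate == m3.rate):
        raise ValueError("head markers must share the sampling rate")
    mean = (m1.positions + m2.positions + m3.positions) / 3.0
    missing = m1.missing_mask | m2.missing_mask | m3.missing_mask
    mean[missing] = np.nan
    return MarkerTrajectory(mean, m1.rate, name="head")


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) half-open index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[0::2], idx[1::2]))


def fill_short_gaps(traj: MarkerTrajectory, max_gap_ms: float = 50.0) -> MarkerTrajectory:
    """Cubically interpolate missing runs strictly shorter than ``max_gap_ms``.

    At 100 Hz and the default threshold this fills runs of up to 4
    samples; runs of 5 samples (exactly 50 ms) or longer stay missing, as
    do runs touching the edges of the recording.  Present samples are
    never altered.
    """
    out = traj.positions.copy()
    mask = traj.missing_mask
    if not mask.any():
        return MarkerTrajectory(out, traj.rate, traj.name)
    max_len = int(np.ceil(max_gap_ms / 1000.0 * traj.rate)) - 1
    present = np.flatnonzero(~mask)
    if present.size < 2:
        return MarkerTrajectory(out, traj.rate, traj.name)
    fill_idx: list[np.ndarray] = []
    for start, stop in _missing_runs(mask):
        if stop - start > max_len:
            continue
        if start == 0 or stop == traj.n_samples:  # edge gaps stay missing
            continue
        fill_idx.append(np.arange(start, stop))
    if fill_idx:
        targets = np.concatenate(fill_idx)
        if present.size >= 4:
            spline = CubicSpline(present, traj.positions[present], axis=0)
            out[targets] = spline(targets)
        else:  # too few support points for a cubic: fall back to linear
            for c in range(3):
                out[targets, c] = np.interp(targets, present, traj.positions[present, c])
    return MarkerTrajectory(out, traj.rate, traj.name)


def compute_speed(traj: MarkerTrajectory) -> SpeedSeries:
    """Scalar speed: Euclidean step length times the sampling rate (mm/s).

    ``speed[t] = ||p[t+1] - p[t]|| * rate``; sample ``t`` keeps the
    timestamp of position ``t`` and is missing if either endpoint is.
    """
    if traj.n_samples < 2:
        raise ValueError("need at least two samples to compute speed")
    step = np.diff(traj.positions, axis=0)
    speed = np.linalg.norm(step, axis=1) * traj.rate
    return SpeedSeries(speed, traj.rate, label=traj.name)


def zscore(values: np.ndarray) -> np.ndarray:
    """Z-score over present samples (NaN preserved); sample (n-1) sd.

    Raises on zero variance or fewer than two present samples.
    """
    values = np.asarray(values, dtype=float)
    present = ~np.isnan(values)
    if present.sum() < 2:
        raise ValueError("need at least two present samples to z-score")
    mu = values[present].mean()
    sd = values[present].std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: segment cannot be z-scored")
    out = values.copy()
    out[present] = (values[present] - mu) / sd
    return out


def bandpass(
    values: np.ndarray, low: float = 0.5, high: float = 12.0, rate: float = 100.0
) -> np.ndarray:
    """Zero-phase second-order Butterworth band-pass (forward-backward).

    The input must not contain missing samples; callers split series at
    missing runs first.  Raises if the segment is shorter than the
    filtfilt padding requirement.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("bandpass input must not contain missing samples")
    b, a = butter(2, [low, high], btype="bandpass", fs=rate)
    padlen = 3 * max(len(a), len(b))
    if values.size <= padlen:
        raise ValueError(
            f"segment of {values.size} samples is too short to filter "
            f"(needs more than {padlen})"
        )
    return filtfilt(b, a, values)


def _present_runs(values: np.ndarray) -> list[tuple[int, int]]:
    return _missing_runs(~np.isnan(values))


def normalize_passage(
    values: np.ndarray,
    low: float = 0.5,
    high: float = 12.0,
    rate: float = 100.0,
    warnings_out: list[str] | None = None,
) -> np.ndarray:
    """Per-passage z-score followed by band-pass of each present run.

    Runs too short to filter are left missing (and reported), so that
    residual long gaps simply exclude their samples from the window
    grids downstream.
    """
    z = zscore(values)
    out = np.full_like(z, np.nan)
    for start, stop in _present_runs(z):
        try:
            out[start:stop] = bandpass(z[start:stop], low, high, rate)
        except ValueError as err:
            if warnings_out is not None:
                warnings_out.append(f"run [{start}:{stop}) dropped: {err}")
    return out


@dataclass
class PreprocessedTrial:
    """Cleaned series of one take, ready for the analysis stages.

    ``head_speed`` / ``bow_speed`` are lists of per-passage z-scored,
    band-passed speed arrays (NaN where missing).  ``head_center`` and
    ``bow_filled`` are the gap-filled raw trajectories used by the
    spatial descriptors.  ``passage_slices`` are sample ranges of the
    passages in the full trajectory.
    """

    head_speed: list[np.ndarray]
    bow_speed: list[np.ndarray]
    head_center: MarkerTrajectory
    bow_filled: MarkerTrajectory
    passage_slices: list[tuple[int, int]]
    rate: float = 100.0
    warnings: list[str] = field(default_factory=list)


def preprocess_trial(
    head_markers: list[MarkerTrajectory],
    bow_marker: MarkerTrajectory,
    grid: BeatGrid,
    passages: PassageSet,
    low: float = 0.5,
    high: float = 12.0,
) -> PreprocessedTrial:
    """Run the fixed preprocessing chain on one take.

    average -> fill short gaps -> speed -> per-passage z-score ->
    band-pass.  Filtering is applied within passages only (pauses are
    excised first), and missing runs split the filtered segments.
    """
    head_center = fill_short_gaps(average_head_markers(*head_markers))
    bow_filled = fill_short_gaps(bow_marker)
    rate = bow_marker.rate
    head_speed_full = compute_speed(head_center).values
    bow_speed_full = compute_speed(bow_filled).values
    slices = passages.sample_slices(grid, rate, bow_marker.n_samples)
    warns: list[str] = []
    head_out, bow_out = [], []
    for i, (a, b) in enumerate(slices):
        stop = min(b - 1, head_speed_full.size)  # speed is one sample shorter
        for src, dst in ((head_speed_full, head_out), (bow_speed_full, bow_out)):
            seg = src[a:stop]
            try:
                dst.append(normalize_passage(seg, low, high, rate, warns))
            except ValueError as err:
                warns.append(f"passage {i} dropped: {err}")
                dst.append(np.full(seg.shape, np.nan))
    return PreprocessedTrial(
        head_speed=head_out,
        bow_speed=bow_out,
        head_center=head_center,
        bow_filled=bow_filled,
        passage_slices=slices,
        rate=rate,
        warnings=warns,
    )
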