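"""Head-bow phase coupling at each metrical timescale.

Within the same 3-s windows used for the spectral analysis, both speed
series are zero-padded (to at least 512 points), band-pass filtered in
+/-0.5 Hz bands around each locally matched metrical frequency
(two-pass second-order Butterworth), and passed through the Hilbert
transform to obtain instantaneous phase.  The relative phase is

    d_phi = phase(bow) - phase(head),  wrapped to (-pi, pi]

so a NEGATIVE relative phase means the head precedes the bow.  Relative
phase samples are collected only over the real-data extent of each
window (never over the zero padding) and pooled across all windows of a
take before the circular statistics are computed:

* VL — vector length (modulus of the mean unit phasor), phase-locking
  consistency in [0, 1];
* MA — mean angle (argument of the mean phasor), the average lead/lag;
* MAA — mean absolute angle, arithmetic mean of |d_phi| in [0, pi],
  tightness of the phase relation regardless of direction (pi/2 under
  circular uniformity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, hilbert

from .core import LEVELS, BeatGrid, PassageSet, wrap_angle
from .spectral import NFFT_MIN, segment_psd_windows
from .timing import MetricalFrequencySet, local_metrical_frequencies

MIN_SAMPLES_PER_LEVEL = 10


@dataclass(frozen=True)
class LevelCoupling:
    vl: float
    ma: float
    maa: float
    n_samples: int


@dataclass
class PhaseCouplingSummary:
    """Per-take circular statistics of the head-bow relative phase."""

    levels: dict[str, LevelCoupling]

    def __getitem__(self, level: str) -> LevelCoupling:
        return self.levels[level]


def metrical_bandpass(
    x: np.ndarray, f0: float, halfwidth: float = 0.5, rate: float = 100.0
) -> np.ndarray:
    """Two-pass second-order Butterworth band-pass [f0-hw, f0+hw]."""
    low, high = f0 - halfwidth, f0 + halfwidth
    if low <= 0 or high >= rate / 2.0:
        raise ValueError(f"invalid band [{low:.3f}, {high:.3f}] Hz")
    b, a = butter(2, [low, high], btype="bandpass", fs=rate)
    return filtfilt(b, a, np.asarray(x, dtype=float))


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Phase angle of the analytic signal (radians, wrapped)."""
    x = np.asarray(x, dtype=float)
    if not np.any(x):
        raise ValueError("phase undefined for an all-zero signal")
    return np.angle(hilbert(x))


def relative_phase(head_phase: np.ndarray, bow_phase: np.ndarray) -> np.ndarray:
    """Relative phase bow - head, wrapped to (-pi, pi].

    Negative values mean the head precedes the bow: a bow delayed by
    ``dt`` on a shared component at ``f0`` gives a constant
    ``-2*pi*f0*dt``.
    """
    head_phase = np.asarray(head_phase, dtype=float)
    bow_phase = np.asarray(bow_phase, dtype=float)
    if head_phase.shape != bow_phase.shape:
        raise ValueError("phase series must have equal length")
    return wrap_angle(bow_phase - head_phase)


def circular_summary(samples: np.ndarray) -> LevelCoupling:
    """VL, MA and MAA of a pooled set of relative-phase samples."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < MIN_SAMPLES_PER_LEVEL:
        raise ValueError(
            f"need at least {MIN_SAMPLES_PER_LEVEL} samples, got {samples.size}"
        )
    phasor = np.exp(1j * samples).mean()
    return LevelCoupling(
        vl=float(np.abs(phasor)),
        ma=float(np.angle(phasor)),
        maa=float(np.abs(samples).mean()),
        n_samples=samples.size,
    )


def window_relative_phase(
    head: np.ndarray,
    bow: np.ndarray,
    f0: float,
    rate: float = 100.0,
    nfft_min: int = NFFT_MIN,
) -> np.ndarray:
    """Relative-phase samples of one complete window at one band.

    The window is zero-padded to the spectral-analysis length before
    filtering (matching the PSD windows), but the returned samples are
    restricted to the real-data extent, since the analytic-signal phase
    over the padding is meaningless.
    """
    n = head.size
    if bow.size != n:
        raise ValueError("head and bow windows must have equal length")
    nfft = max(nfft_min, n)
    hp = np.zeros(nfft)
    bp = np.zeros(nfft)
    hp[:n] = head
    bp[:n] = bow
    h_band = metrical_bandpass(hp, f0, rate=rate)
    b_band = metrical_bandpass(bp, f0, rate=rate)
    ph_h = instantaneous_phase(h_band)[:n]
    ph_b = instantaneous_phase(b_band)[:n]
    return relative_phase(ph_h, ph_b)


def phase_coupling_take(
    head_passages: list[np.ndarray],
    bow_passages: list[np.ndarray],
    grid: BeatGrid,
    passages: PassageSet,
    rate: float = 100.0,
) -> PhaseCouplingSummary:
    """Pooled circular statistics per metrical level for one take.

    Relative-phase samples from all complete 3-s windows of all passages
    are pooled per level; windows with missing samples, an all-zero band
    or an out-of-range band are skipped.  Levels with too few samples are
    flagged by their absence from the result.
    """
    extents = passages.extents(grid)
    pooled: dict[str, list[np.ndarray]] = {lvl: [] for lvl in LEVELS}
    for h, b, (p_start, _p) in zip(head_passages, bow_passages, extents):
        for a, bb in segment_psd_windows(h.size, rate):
            hw, bw = h[a:bb], b[a:bb]
            if np.isnan(hw).any() or np.isnan(bw).any():
                continue
            fset = local_metrical_frequencies(
                grid, (p_start + a / rate, p_start + bb / rate)
            )
            for lvl in LEVELS:
                try:
                    pooled[lvl].append(
                        window_relative_phase(hw, bw, fset[lvl], rate)
                    )
                except ValueError:
                    continue
    levels = {}
    for lvl in LEVELS:
        if pooled[lvl]:
            samples = np.concatenate(pooled[lvl])
            try:
                levels[lvl] = circular_summary(samples)
            except ValueError:
                pass
    return PhaseCouplingSummary(levels)
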