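"""Tempo-adaptive power spectral analysis of the speed series.

Each passage is cut into non-overlapping 3-s windows (the trailing
remainder is appended to the last window, so window lengths range from
300 to 599 samples at 100 Hz).  Every window gets a single modified
periodogram: Hamming taper over the actual samples, zero-padding to at
least 512 points, density scaling.  Power is then extracted at the
frequency bins that locally match the metrical levels — the local tempo
is estimated from the inter-beat intervals inside the window, so the
extraction follows tempo drift instead of sitting on fixed nominal bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

from .core import LEVELS, BeatGrid, PassageSet
from .timing import MetricalFrequencySet, local_metrical_frequencies

NFFT_MIN = 512
WINDOW_S = 3.0


@dataclass
class PsdWindow:
    """One window's periodogram with its time extent on the take clock."""

    passage: int
    start_s: float
    end_s: float
    freqs: np.ndarray
    power: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class MetricalPowerSeries:
    """Per metrical level: power values across windows, with the locally
    matched frequency recorded per window."""

    power: dict[str, np.ndarray]
    matched_freq: dict[str, np.ndarray]
    window_extents: list[tuple[float, float]] = field(default_factory=list)

    def take_means(self) -> dict[str, float]:
        return {lvl: float(np.mean(v)) if v.size else float("nan")
                for lvl, v in self.power.items()}


def segment_psd_windows(n_samples: int, rate: float = 100.0,
                        window_s: float = WINDOW_S) -> list[tuple[int, int]]:
    """Non-overlapping 3-s windows; the final remainder joins the last one.

    A passage shorter than one window yields a single whole-passage
    window (flagged upstream by its short length).
    """
    win = int(round(window_s * rate))
    if n_samples <= 0:
        return []
    if n_samples < win:
        return [(0, n_samples)]
    n_full = n_samples // win
    slices = [(i * win, (i + 1) * win) for i in range(n_full)]
    start, stop = slices[-1]
    slices[-1] = (start, n_samples)  # remainder < 3 s appended to the last window
    return slices


def estimate_psd(x: np.ndarray, rate: float = 100.0, nfft_min: int = NFFT_MIN
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Single modified periodogram: Hamming taper, zero-padded to
    ``max(nfft_min, len(x))`` points, density scaling."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("PSD input must be finite")
    if x.size < 64:
        raise ValueError("window too short for a meaningful periodogram")
    nfft = max(nfft_min, x.size)
    freqs, power = periodogram(
        x, fs=rate, window="hamming", nfft=nfft, detrend=False, scaling="density"
    )
    return freqs, power


def extract_metrical_power(
    freqs: np.ndarray, power: np.ndarray, fset: MetricalFrequencySet
) -> dict[str, tuple[float, float]]:
    """Power at the bin whose center is nearest each metrical frequency.

    Returns ``{level: (power, matched_bin_frequency)}``.
    """
    df = freqs[1] - freqs[0]
    nyquist = freqs[-1]
    out = {}
    for lvl in LEVELS:
        target = fset[lvl]
        if target >= nyquist:
            raise ValueError(f"target {target:.2f} Hz at or above Nyquist")
        idx = int(round(target / df))
        idx = min(idx, freqs.size - 1)
        out[lvl] = (float(power[idx]), float(freqs[idx]))
    return out


def metrical_power_series(
    speed_passages: list[np.ndarray],
    grid: BeatGrid,
    passages: PassageSet,
    rate: float = 100.0,
    fixed_fset: MetricalFrequencySet | None = None,
    companion_passages: list[np.ndarray] | None = None,
) -> MetricalPowerSeries:
    """Metrical power across all PSD windows of a take.

    Windows containing missing samples are skipped.  By default the
    extraction frequencies follow the local tempo of each window
    (averaged IBIs inside the window's extent); passing ``fixed_fset``
    pins them to one set instead, which is only useful as a comparison
    baseline for the tempo-adaptive behaviour.  When the power series is
    later correlated against another effector's series, pass that
    effector as ``companion_passages`` so both series skip the same
    windows.
    """
    extents = passages.extents(grid)
    power = {lvl: [] for lvl in LEVELS}
    matched = {lvl: [] for lvl in LEVELS}
    win_extents = []
    for pi, (values, (p_start, _p_end)) in enumerate(zip(speed_passages, extents)):
        for a, b in segment_psd_windows(values.size, rate):
            seg = values[a:b]
            if np.isnan(seg).any():
                continue
            if companion_passages is not None and np.isnan(
                companion_passages[pi][a:b]
            ).any():
                continue
            t0, t1 = p_start + a / rate, p_start + b / rate
            fset = fixed_fset or local_metrical_frequencies(grid, (t0, t1))
            freqs, pxx = estimate_psd(seg, rate)
            for lvl, (pw, fb) in extract_metrical_power(freqs, pxx, fset).items():
                power[lvl].append(pw)
                matched[lvl].append(fb)
            win_extents.append((t0, t1))
    return MetricalPowerSeries(
        power={lvl: np.array(v) for lvl, v in power.items()},
        matched_freq={lvl: np.array(v) for lvl, v in matched.items()},
        window_extents=win_extents,
    )


def power_correlation(
    a: MetricalPowerSeries, b: MetricalPowerSeries
) -> dict[str, float]:
    """Pearson correlation of the two power series, per metrical level.

    The series must cover the same windows (same take, all passages
    concatenated).  A constant series yields NaN for that level.
    """
    out = {}
    for lvl in LEVELS:
        x, y = a.power[lvl], b.power[lvl]
        if x.size != y.size:
            raise ValueError("power series cover different window sets")
        if x.size < 3:
            out[lvl] = float("nan")
            continue
        if x.std() == 0 or y.std() == 0:
            out[lvl] = float("nan")
            continue
        out[lvl] = float(np.corrcoef(x, y)[0, 1])
    return out
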