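"""Windowed lagged cross-correlation between head and bow speed.

Correlations are computed in 1-s windows (50% overlap, slid within each
passage separately) on a lag grid of -60..+60 ms in 10 ms steps.  The
sign convention is fixed so that a NEGATIVE lag means the head series is
advanced relative to the bow (the head leads).  Per-window peak
correlations are Fisher z-transformed before any averaging and reported
back through the hyperbolic tangent.

Four per-take coordination indices summarize the windows: peak
correlation (strength irrespective of delay), mean peak lag (lead/lag
direction), mean absolute peak lag (temporal tightness) and the standard
deviation of peak lags across windows (coordination stability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class LagGrid:
    """Symmetric lag grid in ms; default -60..+60 in steps of 10."""

    max_lag_ms: float = 60.0
    step_ms: float = 10.0
    rate: float = 100.0

    def __post_init__(self) -> None:
        if self.max_lag_ms <= 0 or self.step_ms <= 0:
            raise ValueError("lag grid extents must be positive")
        step = self.step_ms / 1000.0 * self.rate
        if abs(step - round(step)) > 1e-9 or round(step) < 1:
            raise ValueError("lag step must be a whole number of samples")
        if abs(self.max_lag_ms / self.step_ms - round(self.max_lag_ms / self.step_ms)) > 1e-9:
            raise ValueError("max lag must be a multiple of the step")

    @property
    def lags_ms(self) -> np.ndarray:
        n = int(round(self.max_lag_ms / self.step_ms))
        return np.arange(-n, n + 1) * self.step_ms

    @property
    def lags_samples(self) -> np.ndarray:
        return np.round(self.lags_ms / 1000.0 * self.rate).astype(int)


@dataclass
class WindowCorrFunction:
    """Correlation across lags for one 1-s window."""

    window_id: tuple[int, int]  # (passage index, start sample)
    lags_ms: np.ndarray
    r: np.ndarray

    @property
    def z(self) -> np.ndarray:
        return fisher_z(self.r)


@dataclass(frozen=True)
class CoordIndices:
    """Per-take coordination summary."""

    peak_r: float
    mean_lag: float  # ms
    mean_abs_lag: float  # ms
    lag_sd: float  # ms; NaN when fewer than two windows
    n_windows: int = 0


def slide_windows(
    values: np.ndarray,
    window_samples: int = 100,
    overlap: float = 0.5,
) -> list[int]:
    """Start indices of sliding windows within one passage segment.

    Windows start at 0 and advance by ``window * (1 - overlap)``; a
    trailing remainder shorter than one window is discarded, and windows
    containing missing samples are dropped.
    """
    n = np.asarray(values).shape[0]
    if n < window_samples:
        return []
    hop = int(round(window_samples * (1.0 - overlap)))
    starts = range(0, n - window_samples + 1, hop)
    missing = np.isnan(values)
    return [s for s in starts if not missing[s:s + window_samples].any()]


def fisher_z(r):
    """Variance-stabilizing atanh with |r| clipped below 1."""
    return np.arctanh(np.clip(r, -_CLIP, _CLIP))


def fisher_z_inv(z):
    return np.tanh(z)


def lagged_correlation(
    head: np.ndarray, bow: np.ndarray, grid: LagGrid | None = None
) -> np.ndarray:
    """Pearson correlation of head vs bow at each lag of the grid.

    For lag ``l`` (in samples) the overlapping pairs ``head[t], bow[t-l]``
    are correlated after re-centering both sub-segments within the
    overlap; a negative lag therefore advances the head relative to the
    bow.  Lags where either sub-segment has zero variance are NaN.
    """
    grid = grid or LagGrid()
    head = np.asarray(head, dtype=float)
    bow = np.asarray(bow, dtype=float)
    if head.shape != bow.shape:
        raise ValueError("head and bow windows must have equal length")
    if np.isnan(head).any() or np.isnan(bow).any():
        raise ValueError("windows must be complete (no missing samples)")
    n = head.size
    out = np.empty(grid.lags_samples.size)
    for i, l in enumerate(grid.lags_samples):
        if abs(l) >= n:
            out[i] = np.nan
            continue
        if l < 0:
            a, b = head[: n + l], bow[-l:]
        elif l > 0:
            a, b = head[l:], bow[: n - l]
        else:
            a, b = head, bow
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        out[i] = (a @ b) / denom if denom > 0 else np.nan
    return out


def correlate_windows(
    head_wins: np.ndarray, bow_wins: np.ndarray, grid: LagGrid | None = None
) -> np.ndarray:
    """Vectorized :func:`lagged_correlation` over a stack of windows.

    ``head_wins`` and ``bow_wins`` have shape (n_windows, window_len);
    returns (n_windows, n_lags).
    """
    grid = grid or LagGrid()
    H = np.asarray(head_wins, dtype=float)
    B = np.asarray(bow_wins, dtype=float)
    n = H.shape[1]
    out = np.empty((H.shape[0], grid.lags_samples.size))
    for i, l in enumerate(grid.lags_samples):
        if l < 0:
            a, b = H[:, : n + l], B[:, -l:]
        elif l > 0:
            a, b = H[:, l:], B[:, : n - l]
        else:
            a, b = H, B
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt(np.einsum("ij,ij->i", a, a) * np.einsum("ij,ij->i", b, b))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, i] = np.where(denom > 0, np.einsum("ij,ij->i", a, b) / denom, np.nan)
    return out


def peak_pick(r: np.ndarray, lags_ms: np.ndarray) -> tuple[float, float]:
    """Peak correlation (as Fisher z) and its lag.

    Ties on r are broken by the smallest absolute lag, then by the
    negative lag.  Raises if every lag is undefined.
    """
    r = np.asarray(r, dtype=float)
    defined = ~np.isnan(r)
    if not defined.any():
        raise ValueError("correlation undefined at every lag")
    rmax = np.nanmax(r)
    candidates = np.flatnonzero(defined & (r == rmax))
    order = sorted(candidates, key=lambda i: (abs(lags_ms[i]), lags_ms[i]))
    best = order[0]
    return float(fisher_z(r[best])), float(lags_ms[best])


def take_window_functions(
    head_passages: list[np.ndarray],
    bow_passages: list[np.ndarray],
    grid: LagGrid | None = None,
    window_samples: int = 100,
    overlap: float = 0.5,
) -> list[WindowCorrFunction]:
    """All per-window correlation functions of one take.

    Windows are slid within each passage independently; windows with
    missing samples in either effector are dropped.
    """
    grid = grid or LagGrid()
    out: list[WindowCorrFunction] = []
    for pi, (h, b) in enumerate(zip(head_passages, bow_passages)):
        missing = np.isnan(h) | np.isnan(b)
        joint = np.where(missing, np.nan, 0.0)
        starts = slide_windows(joint, window_samples, overlap)
        if not starts:
            continue
        H = np.stack([h[s:s + window_samples] for s in starts])
        B = np.stack([b[s:s + window_samples] for s in starts])
        rmat = correlate_windows(H, B, grid)
        for s, row in zip(starts, rmat):
            out.append(WindowCorrFunction((pi, s), grid.lags_ms, row))
    return out


def aggregate_take(functions: list[WindowCorrFunction]) -> CoordIndices:
    """Average the per-window peaks into the four coordination indices.

    Peak correlations are averaged on the Fisher z scale and transformed
    back; lags are averaged arithmetically.  With fewer than two windows
    the lag SD is undefined (NaN).
    """
    peaks = []
    for f in functions:
        try:
            peaks.append(peak_pick(f.r, f.lags_ms))
        except ValueError:
            continue
    if not peaks:
        raise ValueError("no window yielded a defined correlation peak")
    zs = np.array([p[0] for p in peaks])
    lags = np.array([p[1] for p in peaks])
    return CoordIndices(
        peak_r=float(np.tanh(zs.mean())),
        mean_lag=float(lags.mean()),
        mean_abs_lag=float(np.abs(lags).mean()),
        lag_sd=float(lags.std(ddof=1)) if lags.size >= 2 else float("nan"),
        n_windows=len(peaks),
    )


def average_corr_function(functions: list[WindowCorrFunction]) -> np.ndarray:
    """Average correlation function across windows (z-averaged per lag,
    transformed back); used for the figure-style overview."""
    if not functions:
        raise ValueError("no windows to average")
    Z = np.stack([fisher_z(f.r) for f in functions])
    with np.errstate(invalid="ignore"):
        return np.tanh(np.nanmean(Z, axis=0))
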