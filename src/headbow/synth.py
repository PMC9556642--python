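"""Seed-deterministic synthetic motion-capture trials with known ground truth.

The generator emulates one ~1-minute take of a first-section violinist in
an up-tempo ensemble piece (~229 bpm, inter-beat-interval CV ~0.06): four
playable passages separated by pauses, a bow that reverses direction at
the passage's prevailing note value, and head motion carrying components
at the metrical frequencies of the score (whole/half/quarter/eighth
note), phase-locked to the bow with a configurable lead/lag of a few tens
of milliseconds plus von-Mises phase noise.

Kinematic construction
----------------------
The analysis pipeline consumes *speed* series (norm of the first
difference of position), so the generator prescribes each effector's
speed profile directly and integrates it into a trajectory:

* speed profile = positive baseline + sum over metrical levels of
  cosines at the local (tempo-following) metrical frequencies;
* direction along a fixed axis alternates at metrically locked
  reversals (head: every whole note; bow: every note of the passage's
  note value), which keeps the trajectory bounded while leaving the
  speed profile untouched;
* the direction carrier is in exact quadrature with the speed
  modulation at the one frequency they share, so the noiseless
  trajectory has no net drift, and the position is re-zeroed at each
  passage start (players reposition during pauses).

The head leads (or lags) the bow by evaluating its phase at ``t - lag``:
a negative ``head_bow_lag`` means the head precedes the bow.  Three head
markers are rigid offsets from the head centre, so averaging them
recovers the centre trajectory exactly (plus noise reduced by sqrt(3)).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .core import LEVELS, LEVEL_BEATS, BeatGrid, MarkerTrajectory, Passage, PassageSet

RATE = 100.0  # Hz, motion-capture sampling rate

#: Depth of the bow-speed modulation at each metrical level.  Strokes are
#: constant-speed between reversals but their pace is shaped at bar,
#: half-note, beat and eighth-note timescales, which gives the bow the
#: harmonically rich speed spectrum seen in ensemble recordings.
BOW_MODULATION: dict[str, float] = {
    "whole": 0.25,
    "half": 0.20,
    "quarter": 0.20,
    "eighth": 0.15,
}

#: Rigid offsets (mm) of the three head-cap markers from the head centre,
#: an ~80 mm triangle (crown and two frontal positions).
HEAD_MARKER_OFFSETS = np.array(
    [
        [0.0, -45.0, 25.0],
        [-40.0, 25.0, -10.0],
        [40.0, 25.0, -10.0],
    ]
)

_HEAD_AXIS = np.array([0.15, 0.95, 0.30])
_BOW_AXIS = np.array([0.90, 0.30, 0.25])
_HEAD_BASE = np.array([0.0, 0.0, 1500.0])
_BOW_BASE = np.array([350.0, 250.0, 1200.0])

#: Ratio of the baseline speed to the summed modulation amplitudes; > 1
#: keeps the prescribed speed profile strictly positive.
_BASELINE_HEADROOM = 1.15

#: Spacing (s) of the knots of the slowly varying von-Mises phase noise.
_PHASE_NOISE_KNOT_S = 0.5

#: Transverse postural sway: relative amplitude (fraction of the main-axis
#: displacement SD) and low-pass corner (Hz).  Sway sits below the 0.5 Hz
#: analysis band; it gives trajectories genuine 3D extent (hull volume)
#: without touching the metrical speed components.
_SWAY_REL_SD = 0.3
_SWAY_CUTOFF_HZ = 0.25


@dataclass
class TempoConfig:
    """Tempo process of one take.

    Parameters
    ----------
    mean_ibi : float
        Mean inter-beat (quarter-note) interval in ms.
    cv : float
        Target coefficient of variation of the inter-beat intervals
        (multiplicative lognormal jitter on step durations).
    drift_amplitude : float
        Relative amplitude of a slow sinusoidal tempo drift over the
        take (one period per take, random phase).
    n_steps : int
        Number of half-note steps in the take.
    """

    mean_ibi: float = 263.0
    cv: float = 0.06
    drift_amplitude: float = 0.0
    n_steps: int = 110

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean_ibi) and self.mean_ibi > 0):
            raise ValueError("mean_ibi must be positive and finite")
        if not (math.isfinite(self.cv) and self.cv >= 0):
            raise ValueError("cv must be non-negative and finite")
        if not math.isfinite(self.drift_amplitude) or abs(self.drift_amplitude) >= 1:
            raise ValueError("drift_amplitude must be finite with |a| < 1")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")


@dataclass
class ConditionProfile:
    """Kinematic regime of one experimental condition.

    ``level_amplitudes`` are displacement-equivalent amplitudes (mm) of
    the head components at the four metrical levels; the speed
    contribution of level L is ``amplitude * 2*pi*f_L``, so faster levels
    contribute proportionally more speed for the same excursion.
    ``head_bow_lag`` is in ms, negative when the head leads the bow.
    ``phase_noise_kappa`` is the von-Mises concentration of the slowly
    varying head phase noise (larger = tighter coupling); ``noise_sd`` is
    the white positional marker noise (mm); ``amplitude_scale`` scales
    the whole head speed profile (spatial extent) without changing its
    relative spectral composition.
    """

    level_amplitudes: Mapping[str, float]
    bow_amplitude: float = 150.0
    head_bow_lag: float = -5.0
    phase_noise_kappa: float = 1.0
    noise_sd: float = 0.3
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        amps = {lvl: float(self.level_amplitudes.get(lvl, 0.0)) for lvl in LEVELS}
        unknown = set(self.level_amplitudes) - set(LEVELS)
        if unknown:
            raise ValueError(f"unknown metrical levels: {sorted(unknown)}")
        if any(a < 0 or not math.isfinite(a) for a in amps.values()):
            raise ValueError("level amplitudes must be non-negative and finite")
        self.level_amplitudes = amps
        if self.bow_amplitude < 0 or not math.isfinite(self.bow_amplitude):
            raise ValueError("bow_amplitude must be non-negative")
        if abs(self.head_bow_lag) > 60:
            raise ValueError("|head_bow_lag| must be <= 60 ms")
        if self.phase_noise_kappa < 0 or not math.isfinite(self.phase_noise_kappa):
            raise ValueError("phase_noise_kappa must be non-negative")
        if self.noise_sd < 0 or self.amplitude_scale < 0:
            raise ValueError("noise_sd and amplitude_scale must be non-negative")

    def scaled(self, factor: float) -> "ConditionProfile":
        """Copy with head and bow amplitudes multiplied by ``factor``."""
        return ConditionProfile(
            level_amplitudes={k: v * factor for k, v in self.level_amplitudes.items()},
            bow_amplitude=self.bow_amplitude * factor,
            head_bow_lag=self.head_bow_lag,
            phase_noise_kappa=self.phase_noise_kappa,
            noise_sd=self.noise_sd,
            amplitude_scale=self.amplitude_scale,
        )


@dataclass
class GapSpec:
    """Missing-data injection: gap count per second and length range (ms)."""

    gap_rate: float = 0.2
    gap_length_range: tuple[float, float] = (10.0, 80.0)

    def __post_init__(self) -> None:
        lo, hi = self.gap_length_range
        if self.gap_rate < 0:
            raise ValueError("gap_rate must be non-negative")
        if not (0 < lo <= hi):
            raise ValueError("gap length range must satisfy 0 < min <= max")


def normal_profile() -> ConditionProfile:
    """Regime with the conductor in view: head motion dominated by a
    single component at the whole-note (bar) frequency near 1 Hz."""
    return ConditionProfile(
        level_amplitudes={"whole": 25.0, "half": 0.0, "quarter": 0.0, "eighth": 0.0},
        bow_amplitude=150.0,
        head_bow_lag=-3.0,
        phase_noise_kappa=1.0,
        noise_sd=0.3,
        amplitude_scale=1.0,
    )


def perturbed_profile() -> ConditionProfile:
    """Perturbed-coupling regime: smaller head excursions that spread
    across all four metrical levels (components near 1, 2, 4 and 8 Hz)
    with tighter phase locking to the bow."""
    return ConditionProfile(
        level_amplitudes={"whole": 12.0, "half": 5.0, "quarter": 3.0, "eighth": 1.5},
        bow_amplitude=150.0,
        head_bow_lag=-7.0,
        phase_noise_kappa=2.0,
        noise_sd=0.3,
        amplitude_scale=0.3,
    )


DEFAULT_PROFILES = {"normal": normal_profile, "perturbed": perturbed_profile}


def default_passages() -> PassageSet:
    """Four playable passages separated by pauses, spanning a 110-step
    (55-bar) take, with durations from ~4 to ~15 s."""
    return PassageSet(
        [
            Passage(0, 8, "quarter"),
            Passage(13, 20, "eighth"),
            Passage(25, 52, "eighth"),
            Passage(76, 109, "quarter"),
        ]
    )


@dataclass
class SyntheticTrial:
    """One generated take: three head markers, one bow marker, the beat
    grid with played flags, the passage set, and the ground truth."""

    head_markers: list[MarkerTrajectory]
    bow_marker: MarkerTrajectory
    beat_grid: BeatGrid
    passages: PassageSet
    ground_truth: dict

    @property
    def n_samples(self) -> int:
        return self.bow_marker.n_samples


def generate_beat_grid(cfg: TempoConfig, seed: int) -> BeatGrid:
    """Generate half-note step onsets with lognormal tempo jitter.

    Step durations are ``2 * mean_ibi`` with i.i.d. multiplicative
    lognormal jitter targeting the requested CV on the derived inter-beat
    intervals, times one slow sinusoidal drift of relative amplitude
    ``drift_amplitude`` with random phase.  Deterministic for fixed seed.
    """
    rng = np.random.default_rng(seed)
    base = 2.0 * cfg.mean_ibi / 1000.0  # step duration, s
    if cfg.cv > 0:
        sigma = math.sqrt(math.log(1.0 + cfg.cv**2))
        jitter = np.exp(rng.normal(0.0, sigma, cfg.n_steps) - sigma**2 / 2.0)
    else:
        jitter = np.ones(cfg.n_steps)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    drift = 1.0 + cfg.drift_amplitude * np.sin(
        2.0 * np.pi * np.arange(cfg.n_steps) / cfg.n_steps + phase0
    )
    durations = base * jitter * drift
    onsets = np.concatenate([[0.0], np.cumsum(durations[:-1])])
    return BeatGrid(
        onsets=onsets,
        bar=np.arange(cfg.n_steps) // 2,
        played=np.ones(cfg.n_steps, dtype=bool),
    )


def _direction_carrier(phase: np.ndarray) -> np.ndarray:
    """+/-1 carrier flipping at every 2*pi crossing of ``phase``.

    Equal to sign(sin(phase/2)) for ideal phases, i.e. the square wave in
    quadrature with cos(phase/2): the modulation at the shared frequency
    then integrates to zero and the trajectory does not drift.
    """
    return np.where(np.floor(phase / (2.0 * np.pi)).astype(int) % 2 == 0, 1.0, -1.0)


def _phase_noise(n: int, rate: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Slowly varying phase noise: von-Mises knots linearly interpolated."""
    n_knots = max(2, int(math.ceil(n / rate / _PHASE_NOISE_KNOT_S)) + 1)
    knots = rng.vonmises(0.0, kappa, n_knots)
    kt = np.arange(n_knots) * _PHASE_NOISE_KNOT_S
    return np.interp(np.arange(n) / rate, kt, knots)


def _transverse_sway(
    main_x: np.ndarray,
    axis: np.ndarray,
    rate: float,
    slices: Sequence[tuple[int, int]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Slow drift on the two axes orthogonal to the movement axis.

    Low-pass filtered white noise scaled to a fraction of the main-axis
    displacement SD, re-zeroed at each passage start and held at zero
    during pauses (like the main displacement).
    """
    from scipy.signal import butter, filtfilt

    n = main_x.shape[0]
    played = np.zeros(n, dtype=bool)
    for a, b in slices:
        played[a:b] = True
    sd = main_x[played].std() if played.any() else 0.0
    out = np.zeros((n, 3))
    if sd == 0 or n < 40:
        return out
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    b, a = butter(2, _SWAY_CUTOFF_HZ, btype="lowpass", fs=rate)
    for vec in (u, v):
        raw = filtfilt(b, a, rng.normal(0.0, 1.0, n))
        raw_sd = raw.std()
        if raw_sd == 0:
            continue
        sway = raw / raw_sd * (_SWAY_REL_SD * sd)
        shaped = np.zeros(n)
        for s0, s1 in slices:
            shaped[s0:s1] = sway[s0:s1] - sway[s0]
        out += np.outer(shaped, vec)
    return out


def _integrate_with_reset(
    velocity: np.ndarray, rate: float, slices: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Cumulative displacement, re-zeroed at each passage start and held
    at zero during pauses."""
    x = np.cumsum(velocity) / rate
    out = np.zeros_like(x)
    for a, b in slices:
        out[a:b] = x[a:b] - x[a]
    return out


def _inject_gaps(
    positions: np.ndarray, gaps: GapSpec, rate: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Set NaN runs in-place; returns the injected (start, length) list.

    The number of gaps is ``round(gap_rate * duration)`` and gaps do not
    overlap or touch, so the injected missing-sample budget is exact.
    """
    n = positions.shape[0]
    duration_s = n / rate
    n_gaps = int(round(gaps.gap_rate * duration_s))
    placed: list[tuple[int, int]] = []
    attempts = 0
    while len(placed) < n_gaps and attempts < 50 * max(n_gaps, 1):
        attempts += 1
        lo, hi = gaps.gap_length_range
        length = int(round(rng.uniform(lo, hi) / 1000.0 * rate))
        length = max(1, length)
        start = int(rng.integers(1, max(2, n - length - 1)))
        if any(start < s + l + 1 and s < start + length + 1 for s, l in placed):
            continue
        placed.append((start, length))
    for s, l in placed:
        positions[s:s + l] = np.nan
    return sorted(placed)


def generate_trial(
    profile: ConditionProfile,
    grid: BeatGrid,
    passages: PassageSet,
    gaps: GapSpec | None = None,
    seed: int = 0,
    rate: float = RATE,
) -> SyntheticTrial:
    """Generate one synthetic take with known ground truth.

    The head speed profile is evaluated at ``t - head_bow_lag`` so a
    negative lag makes the head precede the bow at every shared metrical
    component.  Gaps (missing samples) are injected into the bow marker,
    mirroring the fact that bow markers are the ones that get masked in
    real recordings.
    """
    passages.validate_against(grid)
    gaps = gaps or GapSpec(gap_rate=0.0)
    rng = np.random.default_rng(seed)
    n = int(round(grid.take_length * rate)) + 1
    t = np.arange(n) / rate + grid.onsets[0]
    slices = passages.sample_slices(grid, rate, n)
    played = np.zeros(n, dtype=bool)
    for a, b in slices:
        played[a:b] = True

    mean_ibi_s = np.diff(grid.onsets).mean() / 2.0
    omega = {lvl: 2.0 * np.pi / (mean_ibi_s * LEVEL_BEATS[lvl]) for lvl in LEVELS}

    # --- head centre ---------------------------------------------------
    tau = profile.head_bow_lag / 1000.0
    phase_lag = {lvl: grid.level_phase(t - tau, lvl) for lvl in LEVELS}
    scale = profile.amplitude_scale
    amps = {
        lvl: profile.level_amplitudes[lvl] * omega[lvl] * scale for lvl in LEVELS
    }
    eps = {
        lvl: _phase_noise(n, rate, profile.phase_noise_kappa, rng) for lvl in LEVELS
    }
    total_amp = sum(amps.values())
    baseline = _BASELINE_HEADROOM * total_amp
    m_head = baseline * np.ones(n)
    for lvl in LEVELS:
        if amps[lvl] > 0:
            m_head += amps[lvl] * np.cos(phase_lag[lvl] + eps[lvl])
    sigma_head = _direction_carrier(phase_lag["whole"])
    head_x = _integrate_with_reset(sigma_head * m_head * played, rate, slices)
    head_center = (
        _HEAD_BASE
        + np.outer(head_x, _HEAD_AXIS / np.linalg.norm(_HEAD_AXIS))
        + _transverse_sway(head_x, _HEAD_AXIS, rate, slices, rng)
    )

    head_markers = []
    for i in range(3):
        pos = head_center + HEAD_MARKER_OFFSETS[i]
        if profile.noise_sd > 0:
            pos = pos + rng.normal(0.0, profile.noise_sd, pos.shape)
        head_markers.append(MarkerTrajectory(pos, rate, name=f"head{i + 1}"))

    # --- bow ------------------------------------------------------------
    phase = {lvl: grid.level_phase(t, lvl) for lvl in LEVELS}
    v_bow = profile.bow_amplitude / mean_ibi_s  # quarter-note stroke length
    m_bow = np.ones(n)
    for lvl in LEVELS:
        m_bow += BOW_MODULATION[lvl] * np.cos(phase[lvl])
    m_bow *= v_bow
    sigma_bow = np.ones(n)
    for (a, b), passage in zip(slices, passages):
        sigma_bow[a:b] = _direction_carrier(phase[passage.note_value][a:b])
    bow_x = _integrate_with_reset(sigma_bow * m_bow * played, rate, slices)
    bow_pos = (
        _BOW_BASE
        + np.outer(bow_x, _BOW_AXIS / np.linalg.norm(_BOW_AXIS))
        + _transverse_sway(bow_x, _BOW_AXIS, rate, slices, rng)
    )
    if profile.noise_sd > 0:
        bow_pos = bow_pos + rng.normal(0.0, profile.noise_sd, bow_pos.shape)
    gap_list = _inject_gaps(bow_pos, gaps, rate, rng)
    bow_marker = MarkerTrajectory(bow_pos, rate, name="bow")

    grid_out = BeatGrid(
        onsets=grid.onsets.copy(),
        bar=grid.bar.copy(),
        played=passages.played_flags(grid),
    )
    noiseless_speed = {
        "head": m_head * played,
        "bow": m_bow * played * np.abs(sigma_bow),
    }
    truth = {
        "profile": {
            "level_amplitudes": dict(profile.level_amplitudes),
            "bow_amplitude": profile.bow_amplitude,
            "head_bow_lag": profile.head_bow_lag,
            "phase_noise_kappa": profile.phase_noise_kappa,
            "noise_sd": profile.noise_sd,
            "amplitude_scale": profile.amplitude_scale,
        },
        "head_bow_lag_ms": profile.head_bow_lag,
        "realized_ibi_ms": (np.repeat(np.diff(grid.onsets), 2) / 2.0 * 1000.0).tolist(),
        "gaps": [{"start": s, "length": l} for s, l in gap_list],
        "n_missing": int(sum(l for _, l in gap_list)),
        "seed": int(seed),
        "noiseless_head_speed": noiseless_speed["head"],
        "metrical_frequencies_hz": {
            lvl: 1.0 / (mean_ibi_s * LEVEL_BEATS[lvl]) for lvl in LEVELS
        },
    }
    return SyntheticTrial(head_markers, bow_marker, grid_out, passages, truth)


@dataclass
class StudyDesign:
    """Violinists x conditions x takes layout of a synthetic study.

    Per-violinist amplitude multipliers emulate idiosyncratic movement
    ranges; every take gets its own tempo realization.
    """

    n_violinists: int = 4
    takes_per_condition: int = 6
    conditions: Mapping[str, ConditionProfile] = field(
        default_factory=lambda: {k: f() for k, f in DEFAULT_PROFILES.items()}
    )
    tempo: TempoConfig = field(default_factory=lambda: TempoConfig(drift_amplitude=0.02))
    passages: PassageSet = field(default_factory=default_passages)
    gaps: GapSpec = field(default_factory=GapSpec)
    violinist_amplitude: Sequence[float] = (0.8, 1.0, 1.2, 1.4)

    def __post_init__(self) -> None:
        if self.n_violinists < 1 or self.takes_per_condition < 1:
            raise ValueError("design must have at least one violinist and take")
        if len(self.violinist_amplitude) < self.n_violinists:
            raise ValueError("need one amplitude multiplier per violinist")
        if len(self.conditions) < 1:
            raise ValueError("design lists no conditions")


@dataclass
class TrialRecord:
    violinist: int
    condition: str
    take: int
    trial: SyntheticTrial


def generate_dataset(design: StudyDesign, seed: int) -> list[TrialRecord]:
    """Generate the full study: one trial per violinist x condition x take.

    Seed-deterministic: child seeds are spawned from a single
    ``SeedSequence`` so the whole dataset is a pure function of ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    n_trials = design.n_violinists * len(design.conditions) * design.takes_per_condition
    children = ss.spawn(2 * n_trials)
    records = []
    i = 0
    for v in range(design.n_violinists):
        mult = design.violinist_amplitude[v]
        for cond, profile in design.conditions.items():
            prof_v = profile.scaled(mult)
            for take in range(design.takes_per_condition):
                grid_seed, trial_seed = children[2 * i], children[2 * i + 1]
                i += 1
                grid = generate_beat_grid(
                    design.tempo, np.random.default_rng(grid_seed).integers(2**31)
                )
                trial = generate_trial(
                    prof_v,
                    grid,
                    design.passages,
                    design.gaps,
                    seed=np.random.default_rng(trial_seed).integers(2**31),
                )
                records.append(TrialRecord(v + 1, cond, take + 1, trial))
    return records
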