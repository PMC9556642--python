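"""Preprocessing chain: marker averaging, gap filling, speed, z-score,
zero-phase band-pass."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headbow.core import MarkerTrajectory
from headbow.kinematics import (
    average_head_markers,
    bandpass,
    compute_speed,
    fill_short_gaps,
    normalize_passage,
    preprocess_trial,
    zscore,
)


def _traj(arr, rate=100.0):
    return MarkerTrajectory(np.asarray(arr, dtype=float), rate)


class TestAverage:
    def test_identity_for_identical_markers(self, rng):
        pos = rng.normal(size=(50, 3))
        t = _traj(pos)
        out = average_head_markers(t, _traj(pos.copy()), _traj(pos.copy()))
        assert np.allclose(out.positions, pos)

    def test_arithmetic_mean(self):
        a = _traj(np.tile([0.0, 0.0, 0.0], (5, 1)))
        b = _traj(np.tile([3.0, 0.0, 0.0], (5, 1)))
        c = _traj(np.tile([0.0, 3.0, 0.0], (5, 1)))
        out = average_head_markers(a, b, c)
        assert np.allclose(out.positions, [1.0, 1.0, 0.0])

    def test_missing_propagates(self, rng):
        pos = rng.normal(size=(10, 3))
        a = _traj(pos.copy())
        a.positions[4] = np.nan
        out = average_head_markers(a, _traj(pos.copy()), _traj(pos.copy()))
        assert out.missing_mask[4] and out.missing_mask.sum() == 1

    def test_length_mismatch_rejected(self, rng):
        a = _traj(rng.normal(size=(10, 3)))
        b = _traj(rng.normal(size=(11, 3)))
        with pytest.raises(ValueError):
            average_head_markers(a, b, a)


class TestGapFilling:
    def _line(self, n=60):
        t = np.arange(n, dtype=float)
        return np.stack([t, 2 * t, -t], axis=1)

    @pytest.mark.parametrize("gap_len,filled", [(3, True), (4, True),
                                                (5, False), (6, False)])
    def test_fill_threshold(self, gap_len, filled):
        """Gaps strictly shorter than 50 ms (5 samples at 100 Hz) are
        cubically interpolated; 50 ms and longer stay missing."""
        pos = self._line()
        pos[20:20 + gap_len] = np.nan
        out = fill_short_gaps(_traj(pos))
        if filled:
            assert not out.missing_mask.any()
            assert np.allclose(out.positions, self._line(), atol=1e-8)
        else:
            assert out.missing_mask.sum() == gap_len

    def test_present_samples_never_altered(self, rng):
        pos = rng.normal(size=(80, 3)).cumsum(axis=0)
        pos[10:13] = np.nan
        pos[40:46] = np.nan
        out = fill_short_gaps(_traj(pos.copy()))
        present = ~np.isnan(pos).any(axis=1)
        assert np.array_equal(out.positions[present], pos[present])

    def test_edge_gaps_stay_missing(self):
        pos = self._line()
        pos[:2] = np.nan
        pos[-2:] = np.nan
        out = fill_short_gaps(_traj(pos))
        assert out.missing_mask[:2].all() and out.missing_mask[-2:].all()


class TestSpeed:
    def test_unit_steps(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        out = compute_speed(_traj(pos))
        assert np.allclose(out.values, [100.0, 100.0])

    def test_constant_position_zero_speed(self):
        out = compute_speed(_traj(np.tile([5.0, 1.0, 2.0], (10, 1))))
        assert np.allclose(out.values, 0.0)

    def test_three_four_five(self):
        out = compute_speed(_traj([[0, 0, 0], [3, 4, 0]]))
        assert np.allclose(out.values, [500.0])

    def test_missing_endpoint_propagates(self):
        pos = np.zeros((5, 3))
        pos[2] = np.nan
        out = compute_speed(_traj(pos))
        assert np.isnan(out.values[1]) and np.isnan(out.values[2])
        assert not np.isnan(out.values[0])

    def test_nonnegative_before_normalization(self, rng):
        pos = rng.normal(size=(200, 3)).cumsum(axis=0)
        out = compute_speed(_traj(pos))
        assert (out.values >= 0).all()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_speed(_traj(np.zeros((1, 3))))


class TestZScore:
    def test_basic(self):
        assert np.allclose(zscore(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        x = zscore(rng.normal(size=500))
        assert np.allclose(zscore(x), x, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.full(10, 3.14))

    def test_missing_ignored(self):
        x = np.array([1.0, np.nan, 2.0, 3.0])
        out = zscore(x)
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2, 3]], [-1.0, 0.0, 1.0])


class TestBandpass:
    rate = 100.0

    def _sine(self, f, seconds=60.0):
        t = np.arange(int(seconds * self.rate)) / self.rate
        return np.sin(2 * np.pi * f * t)

    def test_passband_center_preserved(self):
        x = self._sine(4.0)
        y = bandpass(x, rate=self.rate)
        mid = slice(500, -500)
        gain = y[mid].std() / x[mid].std()
        assert abs(gain - 1.0) < 0.05

    def test_stopband_attenuated(self):
        x = self._sine(0.05, seconds=120.0)
        y = bandpass(x, rate=self.rate)
        mid = slice(1000, -1000)
        assert y[mid].std() < 0.1 * x[mid].std()

    def test_zero_phase_impulse_response_symmetric(self):
        x = np.zeros(4001)
        x[2000] = 1.0
        y = bandpass(x, rate=self.rate)
        assert np.allclose(y[2001:3000], y[1999:1000:-1], atol=1e-10)

    def test_time_reversed_input_gives_time_reversed_output(self, rng):
        """Away from the edge transients of the 0.5 Hz corner, filtering
        commutes with time reversal."""
        x = rng.normal(size=6000)
        fwd = bandpass(x, rate=self.rate)
        rev = bandpass(x[::-1], rate=self.rate)
        assert np.allclose(fwd[1000:-1000], rev[::-1][1000:-1000], atol=1e-7)

    def test_linearity(self, rng):
        x = rng.normal(size=1500)
        y = rng.normal(size=1500)
        lhs = bandpass(2.5 * x - 0.5 * y, rate=self.rate)
        rhs = 2.5 * bandpass(x, rate=self.rate) - 0.5 * bandpass(y, rate=self.rate)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(10), rate=self.rate)

    def test_missing_samples_rejected(self):
        x = np.zeros(100)
        x[3] = np.nan
        with pytest.raises(ValueError):
            bandpass(x, rate=self.rate)


class TestNormalizePassage:
    def test_missing_runs_split_segments(self, rng):
        x = rng.normal(size=400) + 10.0
        x[100:160] = np.nan
        out = normalize_passage(x)
        assert np.isnan(out[100:160]).all()
        assert np.isfinite(out[:100]).all() and np.isfinite(out[160:]).all()

    def test_short_run_left_missing(self, rng):
        x = rng.normal(size=60)
        x[10:50] = np.nan  # leaves a 10-sample head run, too short to filter
        warns: list[str] = []
        out = normalize_passage(x, warnings_out=warns)
        assert np.isnan(out[:10]).all()
        assert warns


class TestPreprocessTrial:
    def test_shapes_and_masks(self, short_trial, short_grid, short_passages):
        pre = preprocess_trial(short_trial.head_markers, short_trial.bow_marker,
                               short_grid, short_passages)
        assert len(pre.head_speed) == len(short_passages) == len(pre.bow_speed)
        for h, b in zip(pre.head_speed, pre.bow_speed):
            assert h.size == b.size
            # z-scored and band-passed: near-zero mean where present
            assert abs(np.nanmean(h)) < 0.2

    def test_long_gaps_survive_to_speed(self, short_trial, short_grid,
                                        short_passages):
        pre = preprocess_trial(short_trial.head_markers, short_trial.bow_marker,
                               short_grid, short_passages)
        n_missing_bow = sum(int(np.isnan(b).sum()) for b in pre.bow_speed)
        if short_trial.ground_truth["n_missing"] > 0:
            assert n_missing_bow > 0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(min_value=-1e3, max_value=1e3),
       st.floats(min_value=0.1, max_value=100.0))
def test_zscore_affine_invariance(shift, scale):
    x = np.arange(20.0)
    assert np.allclose(zscore(scale * x + shift), zscore(x), atol=1e-9)
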