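"""Generator contracts: determinism, tempo statistics, spectral ground
truth, amplitude ordering and gap budgets."""

import numpy as np
import pytest
from scipy.signal import periodogram

from headbow.core import LEVELS
from headbow.synth import (
    ConditionProfile,
    GapSpec,
    StudyDesign,
    TempoConfig,
    default_passages,
    generate_beat_grid,
    generate_dataset,
    generate_trial,
    normal_profile,
    perturbed_profile,
)
from headbow.timing import derive_ibis


def _noiseless_profile(**kw):
    defaults = dict(
        level_amplitudes={"whole": 12.0, "half": 5.0, "quarter": 3.0, "eighth": 1.5},
        head_bow_lag=-30.0,
        phase_noise_kappa=1000.0,
        noise_sd=0.0,
    )
    defaults.update(kw)
    return ConditionProfile(**defaults)


class TestBeatGrid:
    def test_zero_noise_gives_exact_ibis(self):
        grid = generate_beat_grid(
            TempoConfig(mean_ibi=250.0, cv=0.0, drift_amplitude=0.0, n_steps=20),
            seed=0,
        )
        ibis = derive_ibis(grid)
        assert np.all(ibis == 250.0)

    def test_cv_recovered_single_seed(self):
        grid = generate_beat_grid(TempoConfig(mean_ibi=263.0, cv=0.06, n_steps=110),
                                  seed=5)
        ibis = derive_ibis(grid)
        cv = ibis.std(ddof=1) / ibis.mean()
        assert abs(cv - 0.06) < 0.015

    def test_cv_recovered_over_seed_ensemble(self):
        """Requested CV is recovered within 3 standard errors over 25 seeds."""
        target = 0.06
        cvs = []
        for seed in range(25):
            grid = generate_beat_grid(
                TempoConfig(mean_ibi=263.0, cv=target, n_steps=110), seed=seed
            )
            ibis = derive_ibis(grid)
            cvs.append(ibis.std(ddof=1) / ibis.mean())
        # SE of a CV estimate at n~110 independent step durations
        se = target / np.sqrt(2 * 110) / np.sqrt(len(cvs))
        assert abs(np.mean(cvs) - target) < 3 * se + 1e-3

    def test_determinism(self):
        cfg = TempoConfig(drift_amplitude=0.02)
        a = generate_beat_grid(cfg, seed=99)
        b = generate_beat_grid(cfg, seed=99)
        assert np.array_equal(a.onsets, b.onsets)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TempoConfig(mean_ibi=-1)
        with pytest.raises(ValueError):
            TempoConfig(cv=float("nan"))
        with pytest.raises(ValueError):
            TempoConfig(n_steps=1)


class TestTrial:
    def test_determinism_byte_identical(self, short_grid, short_passages):
        prof = perturbed_profile()
        a = generate_trial(prof, short_grid, short_passages, GapSpec(), seed=11)
        b = generate_trial(prof, short_grid, short_passages, GapSpec(), seed=11)
        assert a.bow_marker.positions.tobytes() == b.bow_marker.positions.tobytes()
        for ma, mb in zip(a.head_markers, b.head_markers):
            assert ma.positions.tobytes() == mb.positions.tobytes()

    def test_ground_truth_records_lag(self, short_grid, short_passages):
        trial = generate_trial(_noiseless_profile(), short_grid, short_passages,
                               seed=1)
        assert trial.ground_truth["head_bow_lag_ms"] == -30.0

    def test_noiseless_speed_peaks_at_metrical_frequencies(self, short_passages):
        """At constant tempo, the periodogram of the noiseless head speed
        has a local maximum within one bin of every nonzero-amplitude
        metrical frequency."""
        grid = generate_beat_grid(TempoConfig(n_steps=40, cv=0.0), seed=0)
        trial = generate_trial(_noiseless_profile(), grid, short_passages, seed=2)
        speed = trial.ground_truth["noiseless_head_speed"]
        a, b = trial.passages.sample_slices(grid, 100.0, speed.size)[1]
        seg = speed[a:b] - speed[a:b].mean()
        freqs, pxx = periodogram(seg, fs=100.0, nfft=max(4096, seg.size))
        df = freqs[1] - freqs[0]
        for lvl in LEVELS:
            f0 = trial.ground_truth["metrical_frequencies_hz"][lvl]
            idx = int(round(f0 / df))
            window = pxx[idx - 1: idx + 2]
            near = window.max()
            # local maximum: stronger than the shoulders two bins out
            assert near >= pxx[idx - 2] and near >= pxx[idx + 2]
            assert near > 10 * np.median(pxx)

    def test_single_component_regime_is_monochromatic(
        self, short_grid, short_passages
    ):
        prof = _noiseless_profile(
            level_amplitudes={"whole": 25.0, "half": 0.0, "quarter": 0.0,
                              "eighth": 0.0}
        )
        trial = generate_trial(prof, short_grid, short_passages, seed=2)
        speed = trial.ground_truth["noiseless_head_speed"]
        a, b = trial.passages.sample_slices(short_grid, 100.0, speed.size)[1]
        seg = speed[a:b] - speed[a:b].mean()
        freqs, pxx = periodogram(seg, fs=100.0, nfft=4096)
        f0 = trial.ground_truth["metrical_frequencies_hz"]["whole"]
        inband = np.abs(freqs - f0) < 0.25
        assert pxx[inband].sum() > 0.95 * pxx.sum()

    def test_noiseless_head_leads_bow_by_injected_lag(
        self, short_grid, short_passages
    ):
        """With lag -30 ms the noiseless head speed is a 30 ms advanced
        copy of its zero-lag counterpart at every shared component."""
        lead = generate_trial(_noiseless_profile(head_bow_lag=-30.0),
                              short_grid, short_passages, seed=4)
        sync = generate_trial(_noiseless_profile(head_bow_lag=0.0),
                              short_grid, short_passages, seed=4)
        h_lead = lead.ground_truth["noiseless_head_speed"]
        h_sync = sync.ground_truth["noiseless_head_speed"]
        a, b = short_passages.sample_slices(short_grid, 100.0, h_lead.size)[1]
        # head(t) with lag tau equals head(t - tau) of the zero-lag trial:
        # -30 ms = 3 samples of advance
        adv = h_lead[a: b - 3]
        ref = h_sync[a + 3: b]
        err = np.abs(adv - ref).max() / h_sync[a:b].std()
        assert err < 0.05

    def test_gap_budget_exact(self, short_grid, short_passages):
        gaps = GapSpec(gap_rate=0.3, gap_length_range=(20.0, 70.0))
        trial = generate_trial(perturbed_profile(), short_grid, short_passages,
                               gaps, seed=8)
        n_nan = int(trial.bow_marker.missing_mask.sum())
        assert n_nan == trial.ground_truth["n_missing"]
        assert n_nan > 0

    def test_passage_outside_grid_rejected(self, short_grid):
        from headbow.core import Passage, PassageSet

        bad = PassageSet([Passage(0, 60, "quarter")])
        with pytest.raises(ValueError):
            generate_trial(perturbed_profile(), short_grid, bad, seed=0)


class TestDataset:
    def test_default_design_yields_48_trials(self):
        design = StudyDesign(
            tempo=TempoConfig(n_steps=30),
            passages=default_passages_small(),
        )
        records = generate_dataset(design, seed=0)
        assert len(records) == 4 * 2 * 6

    def test_master_seed_determinism(self):
        design = StudyDesign(
            n_violinists=1,
            takes_per_condition=1,
            tempo=TempoConfig(n_steps=30),
            passages=default_passages_small(),
        )
        a = generate_dataset(design, seed=123)
        b = generate_dataset(design, seed=123)
        assert a[0].trial.bow_marker.positions.tobytes() == \
            b[0].trial.bow_marker.positions.tobytes()

    def test_amplitude_multipliers_order_head_excursion(self):
        design = StudyDesign(
            takes_per_condition=1,
            tempo=TempoConfig(n_steps=30, cv=0.0),
            passages=default_passages_small(),
            gaps=GapSpec(gap_rate=0.0),
        )
        records = generate_dataset(design, seed=5)
        spans = []
        for v in range(1, 5):
            rec = next(r for r in records
                       if r.violinist == v and r.condition == "normal")
            head = rec.trial.head_markers[0].positions
            spans.append(np.ptp(head[:, 1]))
        assert spans == sorted(spans)


def default_passages_small():
    from headbow.core import Passage, PassageSet

    return PassageSet([Passage(0, 10, "quarter"), Passage(14, 28, "eighth")])
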