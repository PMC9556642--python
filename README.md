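# headbow

Intrapersonal head–bow coordination analysis for ensemble motion capture.

When a string player performs, the bow executes the *instrumental*
gesture while the head performs *ancillary* motion — expressive,
communicative, and, as it turns out, tightly interwoven with the
player's own timing.  `headbow` is a reusable pipeline for quantifying
how a violinist's head and bow movements coordinate within one body, and
how that coordination changes when the player's visual coupling to the
rest of the ensemble is manipulated (e.g. a normal, conductor-facing
configuration versus a perturbed one in which the first violins face the
second section instead).

The package operates on 3D marker trajectories (mm, 100 Hz; three
head-cap markers and one bow-tip marker per player) plus a beat grid:
annotated onsets of half-note "steps" of the score with bar indices and
played/pause flags.  Because such recordings are rarely public, a
first-class synthetic generator produces seed-deterministic trials with
the same statistical structure and known ground truth, so every stage of
the pipeline is testable end to end.

## What it computes

Preprocessing follows a fixed chain: average the head markers, cubically
interpolate missing runs shorter than 50 ms, differentiate positions
into scalar speed `v[t] = ||p[t+1] − p[t]|| · f_s` (mm/s), z-score each
played passage, and band-pass 0.5–12 Hz with a zero-phase second-order
Butterworth filter.  On the cleaned speed series:

* **Windowed lagged cross-correlation** — Pearson r between head and bow
  speed in 1-s windows (50% overlap, slid within passages) over lags
  −60…+60 ms in 10 ms steps; *negative lag = head leads*.  Per take:
  peak correlation `tanh(mean atanh r_peak)` (coupling strength), mean
  peak lag (lead/lag), mean |lag| (temporal tightness) and the SD of
  peak lags across windows (coordination stability).
* **Spatial dispersion** — mean pairwise Euclidean distance (mm) and 3D
  convex-hull volume (cm³) of the raw positions visited per 1-s window,
  per effector.
* **Tempo-adaptive spectral power** — one Hamming-tapered periodogram
  per non-overlapping 3-s window (zero-padded to ≥512 points,
  0.195 Hz bins); power is extracted at the bins matching the *local*
  metrical frequencies P1–P4 (whole/half/quarter/eighth note,
  f_quarter = 1/IBI from the beats inside the window, the other levels
  on the exact ×2 ladder), so the extraction follows tempo drift.
  Power series are correlated across windows between effectors.
* **Multiscale phase coupling** — per window and metrical level,
  band-pass ±0.5 Hz around the matched frequency, Hilbert transform,
  relative phase Δφ = φ_bow − φ_head wrapped to (−π, π] (negative =
  head precedes).  Pooled per take: vector length VL = |⟨e^{iΔφ}⟩|,
  mean angle MA = arg⟨e^{iΔφ}⟩, and the mean absolute angle
  MAA = ⟨|Δφ|⟩ ∈ [0, π] (π/2 under circular uniformity).
* **Replicated-block Friedman tests** — conditions are compared per
  measure on a complete blocks (violinists) × replicates (takes) ×
  conditions design: joint within-block ranking with mid-ranks, rank
  sums referred to χ² with k−1 df, reducing exactly to the classical
  Friedman statistic for one replicate and validated against a
  within-block permutation oracle.  No multiple-comparison correction is
  applied.

## Worked example

Generate the default synthetic study (4 violinists × 2 conditions ×
6 takes of ~58 s at ~228 bpm), analyze it and compare conditions:

```python
from headbow import (StudyConfig, generate_dataset, analyze_dataset,
                     condition_comparison)

cfg = StudyConfig()
records = generate_dataset(cfg.design, seed=1)
table = analyze_dataset(records, cfg)               # tidy per-take measures
results = condition_comparison(table).set_index("measure")
print(results.loc[["peak_r", "lag_sd_ms", "head_interdistance_mm",
                   "head_hull_cm3", "head_power_P3", "vl_P1",
                   "bow_hull_cm3"],
                  ["mean_normal", "mean_perturbed", "chi2", "p"]].round(4))
```

prints

```
                       mean_normal  mean_perturbed     chi2       p
measure
peak_r                      0.5266          0.8144  33.2308  0.0000
lag_sd_ms                  51.4857         11.4602  33.2308  0.0000
head_interdistance_mm      48.7051         26.1217  33.2308  0.0000
head_hull_cm3               2.7072          0.2061  33.2308  0.0000
head_power_P3               0.0011          0.2375  33.2308  0.0000
vl_P1                       0.6405          0.8368  31.4103  0.0000
bow_hull_cm3                3.1670          3.1080   0.4103  0.5218
```

Reading the rows: in the perturbed coupling regime the head–bow peak
correlation rises and the lag variability drops (stronger, more stable
intrapersonal coordination); head movements shrink in dispersion and
covered volume while gaining power at the faster metrical levels and a
higher whole-note vector length (smaller but multiscale,
metrically locked head motion); the bow is unaffected (χ² = 0.41,
p = 0.52).  A χ² of 33.23 is the design maximum for 4 blocks × 6
replicates × 2 conditions — every take of every violinist moved in the
same direction.

The same run is available from the shell:

```bash
headbow simulate --seed 1 --out sim/         # marker TSV + beat CSV + truth JSON
headbow analyze  --markers sim/ --out results/
headbow report   --results results/          # markdown summary + figures
```

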