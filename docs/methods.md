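# Methods

This note documents the models and numerical conventions behind
`headbow`: what each analysis stage assumes, what the synthetic
generator does and does not emulate, and the choices made where the
design was genuinely open.

## Data model

A *take* is ~1 minute of 100 Hz motion capture of one violinist: three
head-cap markers and one bow-tip marker (3D positions, mm; missing
samples are NaN rows), plus a *beat grid* — onsets of half-note steps of
the score, bar indices, and a played flag per step.  Four playable
*passages* (runs of played steps, each with a prevailing note value)
are separated by pauses.  The grid is the sole source of timing: each
step contributes two identical inter-beat intervals (IBIs; the
annotation does not resolve individual beats), tempo in bpm is
60000/IBI(ms), and the metrical frequencies obey the exact ladder
f_half = 2 f_whole, f_quarter = 4 f_whole, f_eighth = 8 f_whole
(labelled P1–P4).

## Preprocessing

Fixed order, enforced by `preprocess_trial`: marker averaging → gap
filling → speed → per-passage z-score → band-pass.

* Head markers are averaged coordinate-wise; a sample is missing iff any
  marker is missing.
* Missing runs strictly shorter than 50 ms (≤4 samples at 100 Hz) are
  filled by a cubic spline through the present samples; runs of exactly
  50 ms or longer, and runs touching the recording edges, stay missing.
  Windows that still overlap a missing sample are dropped from every
  downstream window grid — the simplest defensible rule, and cheap at
  the <1% missing-data rates the generator injects.
* Speed is the norm of the first difference times the rate (mm/s),
  left-aligned: speed sample *t* carries position *t*'s timestamp.  The
  10 ms half-sample ambiguity is identical for both effectors and
  cancels from every relative measure.
* z-scoring (sample SD, over present samples) and the zero-phase
  second-order Butterworth band-pass (0.5–12 Hz, `filtfilt`) are applied
  per passage, never across excised pauses.  Present-sample runs too
  short for the filter's padding are left missing and reported.

## Windowed cross-correlation

1-s windows, 50% overlap, slid within each passage; lags −60…+60 ms in
10 ms steps.  At lag ℓ the overlapping parts of the two windows are
re-centered and correlated (truncation, not wrap-around: data beyond an
excised passage may not exist).  Negative lag means the head series is
advanced — the head leads.  Peak picking breaks exact ties by smaller
|lag|, then by the negative lag.  Per-window peak correlations are
Fisher-z transformed before averaging; the take-level peak correlation
is reported through tanh.  The per-take indices are the peak
correlation, mean peak lag, mean |peak lag| and the SD of peak lags
across windows.

## Spatial descriptors

Mean pairwise distance and convex-hull volume are computed on the raw
(gap-filled, unfiltered) positions — z-scored, filtered speeds have no
spatial meaning — over the same 1-s window grid, then averaged per take.
Degenerate hulls (coplanar or collinear windows) count as volume 0
rather than an error: near-still windows are legitimate data.  With 100
points per window the exact O(n²) pair enumeration is trivially cheap.

## Spectral analysis

Each passage is cut into non-overlapping 3-s windows; the trailing
remainder joins the last window (window lengths 300–599 samples), so no
edge data is discarded.  Each window gets a single Hamming-tapered
periodogram, zero-padded to `max(512, len)` points with density scaling
(bin width 100/512 ≈ 0.195 Hz for 3-s windows).  A single periodogram —
not sub-windowed averaging — is the only estimator with usable
resolution at this window length; the `max(512, len)` rule exists
because the remainder policy can produce windows longer than 512
samples and data is never truncated.  Power is reported in linear
density units.

Power at each metrical level is read from the bin nearest the *locally*
matched frequency: the IBIs whose onsets fall in the window (half-open
interval) are averaged and inverted.  An empty window falls back to the
take-level mean IBI and is flagged.  This tempo-adaptive extraction is
what keeps the levels aligned when tempo drifts within a take.  Power
co-evolution between effectors is the Pearson correlation of the
per-level power series across all windows of a take; series from windows
skipped for either effector are skipped for both.

## Phase coupling

Within the same 3-s windows (zero-padded as in the spectral stage), both
speed series are band-passed ±0.5 Hz around each matched metrical
frequency (two-pass second-order Butterworth) and passed through the
Hilbert transform.  Relative phase is Δφ = φ_bow − φ_head wrapped to
(−π, π], so a head lead of Δt on a shared component at f₀ gives
Δφ = −2π f₀ Δt < 0.  Phase samples are kept only over the real-data
extent of the window — the analytic-signal phase over zero padding is
meaningless.  Samples are *pooled* across all windows of a take (rather
than averaging per-window summaries): pooling maximizes sample support
and weights windows by the data they contain; it is the declared
convention.  Per level: VL (mean resultant length), MA (mean angle) and
MAA (arithmetic mean of |Δφ|, range [0, π], π/2 under uniformity;
"tightness regardless of direction" is only well defined on wrapped
absolute angles).

## Group statistics

Conditions are compared per measure with a Friedman test generalized to
replicated blocks: within each block (violinist) all replicates ×
conditions values are jointly ranked (mid-ranks), and

    χ² = (k−1) Σ_j D_j² / (k Σ_b V_b),   V_b = r (m−r) v_b / (m−1)

where D_j is the deviation of condition j's rank sum from its null
expectation, m = rk, and v_b is the empirical population variance of the
block's mid-ranks (the tie correction).  For r = 1 this reduces exactly
to the classical Friedman formula (and matches an independent textbook
implementation, ties included).  Because replicated-Friedman conventions
vary across software, correctness is anchored to a within-block
permutation oracle rather than a citation: the oracle permutes each
block's fixed mid-ranks (ranking is permutation-invariant within a
block, and the variance term is permutation-invariant, so draws are
fully vectorized) and reports the add-one *mid*-p — the statistic is
discrete, and counting ties at the observed value half is the unbiased
comparator for the continuous χ² reference.  The χ² p agrees with the
oracle to ~0.005 at 2·10⁵ draws on the 4×6×2 design.  Incomplete
designs are refused; in the pipeline report, measures with undefined
values (e.g. degenerate power correlations) are skipped rather than
silently imputed.  No multiple-comparison correction is applied, and the
report header says so.

## Synthetic generator

The generator emulates the study conditions: ~1-minute takes at
~228 bpm (mean IBI 263 ms) with IBI CV 0.06, four playable passages
(~4–15 s) separated by pauses, 110 half-note steps, a bow that reverses
at the passage's prevailing note value, head–bow lead/lag of a few tens
of ms, and occasional marker dropouts on the bow.

**Tempo.**  Step durations are 2·IBI with i.i.d. multiplicative
lognormal jitter calibrated to the target CV (σ² = ln(1+cv²), mean
corrected), times one slow sinusoidal drift per take with random phase.
Lognormal jitter keeps durations positive; it is the simplest process
matching a target CV.  Beat phase is piecewise linear through the
(jittered) beat times; level phases divide it by the beats per note, so
all component frequencies follow the local tempo exactly.

**Kinematics.**  The analysis consumes *speed*, so the generator
prescribes each effector's speed profile directly and integrates it:

* head speed = baseline + Σ_L a_L cos(φ_L(t−τ) + ε_L(t)), with
  a_L = A_L·2πf_L (A_L are the per-level displacement-equivalent
  amplitudes in mm), τ the head–bow lag (negative = head leads; the
  whole head signal is evaluated at t−τ, so every shared component
  carries the same lead), and ε_L slowly varying von-Mises phase noise
  (knots every 0.5 s, linear interpolation, concentration κ);
* bow speed = v·(1 + Σ_L μ_L cos φ_L) — constant-speed strokes whose
  pace is modulated at the metrical levels, giving the harmonically
  rich bow spectrum seen in real playing; v is set so a quarter-note
  stroke covers `bow_amplitude` mm;
* direction along a fixed axis alternates at metrically locked
  reversals (bow: every note of the passage's note value; head: every
  whole note).  The alternation carrier is in exact quadrature with the
  speed modulation at the single frequency they share, so the noiseless
  trajectory has zero net drift; positions are additionally re-zeroed
  at each passage start (players reposition during pauses) and held
  during pauses.

A direct "position = sum of sinusoids" construction was rejected: the
speed of a single-axis sinusoid is a rectified cosine whose power sits
at *twice* the component frequency, so that construction cannot place
speed-spectrum peaks at the metrical levels where measured spectra show
them.  Prescribing the speed profile makes the injected lag, the
per-level power and the relative phase all exact, analysable properties
of the generated data.

Slow transverse sway (low-pass noise below the 0.5 Hz analysis band,
SD = 0.3× the main-axis displacement SD, on the two orthogonal axes)
gives trajectories genuine 3D extent so hull volumes scale cubically
with amplitude.  The three head markers are exact rigid offsets (an
~80 mm triangle) from the head centre plus i.i.d. white positional
noise (`noise_sd`, default 0.3 mm), so marker averaging recovers the
centre plus noise/√3.  Bow-marker gaps are injected at `gap_rate` per
second with lengths uniform in 10–80 ms (non-overlapping, so the
missing-sample budget is exact); dropouts afflict bow markers in real
recordings.

**Condition profiles.**  The normal (conductor-facing) regime has a
single head component at the whole-note level (A = 25 mm) with κ = 1;
the perturbed regime spreads smaller amplitudes over all four levels
(12/5/3/1.5 mm), scales the whole profile by 0.3 (reduced spatial
extent), tightens phase locking (κ = 2) and leads slightly more
(−7 vs −3 ms).  κ is a modelling choice — measured data constrain the
resulting vector lengths (~0.45–0.55), not the noise process — set a
priori from those magnitudes.  The bow profile is identical across
conditions.  A study is 4 violinists × 2 conditions × 6 takes, with
per-violinist amplitude multipliers {0.8, 1.0, 1.2, 1.4} and a fresh
tempo realization per take; everything is a pure function of one master
seed via spawned seed sequences.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no rigid-body head rotation (markers
translate rigidly), no audio, no conductor or second-section player
models, no col-legno/page-turn artifacts (covered abstractly by played
flags and gap injection), phase noise is stationary von-Mises rather
than behaviourally structured, and condition effects are injected
rather than emergent.  The pipeline's *recovery* of injected structure
is what the tests certify.

## Numerical conventions and degenerate inputs

* Fisher z clips |r| at 1−10⁻¹², keeping z finite (~14) for perfect
  correlation.
* Correlation is undefined (NaN) at lags where either sub-segment has
  zero variance; windows with no defined lag are excluded from
  aggregation.
* Zero-variance passages refuse to z-score; all-zero bands refuse a
  Hilbert phase; levels with fewer than 10 pooled phase samples are
  flagged by omission.
* Angle wrapping maps to (−π, π] (so ±π → π, and a raw difference of
  +3π/2 is stored as −π/2).
* All randomness flows through `numpy.random.Generator` seeded
  explicitly; repeated runs with the same seeds are byte-identical.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the full-length default
study (48 takes of ~58 s at 100 Hz) for the directional end-to-end
checks, 20 seeds per condition for recovery properties, 1000 simulated
null datasets for Friedman calibration, and 10⁴-draw permutation
oracles; these sizes give comfortable margins on every threshold while
keeping a complete run in the low minutes on one CPU.

## Known limitations

* The replicated-Friedman variant is *a* principled generalization,
  validated against its permutation oracle; other software may rank
  replicates differently.
* MAA is reported on pooled samples; with strongly multimodal phase
  distributions MAA and VL answer different questions and should be read
  together.
* Spectral power is take-averaged per level from single periodograms;
  absolute power units are only comparable within a fixed window-length
  policy.
* The speed-profile construction fixes waveform shape (cosine
  components over a positive baseline); real effector speeds are less
  stereotyped, so absolute correlation magnitudes are optimistic even
  though every directional contrast is generated, not assumed.
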