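# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of `seegdecode`.

## The decoding model

The pipeline treats a session as `contacts × samples` microvolt traces
with stimulus-onset markers and two balanced classes (own / other
name).  The analysis quantity is instantaneous band power — the squared
magnitude of the analytic signal of the zero-phase, 6th-order
Butterworth band-passed trace — normalized per trial to z-units against
the 200 ms pre-onset baseline (mean and per-sample SD of that trial's
baseline power).  The canonical band is high gamma (60–145 Hz), which
tracks local population firing; beta (13–30 Hz) and alpha (8–12 Hz) are
available.

Features are mean z-power in 100 non-overlapping 10 ms bins per contact
(contact-major, bin-minor order).  Selection correlates each feature
with the binary labels (Spearman r, i.e. Pearson on ranks), builds a
surrogate distribution from 1000 label shuffles, fits a normal to the
surrogates and takes the two-sided tail of |r| as the p-value.  The
Gaussian fit, rather than the empirical tail, is what allows p-values
below 1/1000 — necessary because the Bonferroni level `0.05/dim(V)` is
usually smaller than the permutation resolution.  An empirical-tail
mode is config-selectable.  Ties in p are broken by larger |r|, then by
provenance order.  The 20 smallest-p features form V20; always exactly
20 are returned, with the count clearing Bonferroni reported separately.

Classification is leave-one-out: for each held-out trial the selection
(in the default `per_fold` mode), PCA (components to >90 % explained
variance) and LDA — or a 200-tree random forest with √d feature
subsetting — are fitted on the remaining trials only.  A `one_shot`
selection mode (select once on all trials) exists solely for
region-contribution reporting, which mirrors how per-region feature
counts are usually tabulated; it is leaky by construction and never
used for accuracy claims.  Significance of an accuracy keeps the
predictions fixed and shuffles the true labels (preserving class
counts); the threshold is the 95th percentile of the permuted
accuracies, and p is the fraction of permuted accuracies at or above
the observed one.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| line screen | 50 ± 1 Hz, median + 10·MAD (strict >) | Welch power; the band half-width is our choice — ±1 Hz isolates the line |
| comb notch | 2nd-order IIR notches at 50, 100, … Hz, bandwidth 2 Hz, forward–backward | zero-phase; ≥30 dB at harmonics, ≤1 dB ripple away from notches |
| Laplacian | nearest kept neighbors on the same shaft | end contacts use their single inner neighbor; isolated contacts are excluded (`no_neighbor`) |
| baseline | 200 ms pre-onset, per trial | z-scoring is per-trial against that trial's own baseline |
| smoothing | 80 ms total support Gaussian, σ = 80/6 ms, reflect boundaries | "80 ms window" read as ±3σ support; unit-area kernel preserves constants |
| artifact rule | SE(t) > \|M(t)\| at any t with \|M(t)\| ≥ max(0.1 z, 3·median_t SE(t)) | see below |
| selection | k = 20, n_perm = 1000, Bonferroni α = 0.05/dim(V) | per-fold by default |
| classifiers | PCA >90 % + LDA (SVD solver); RF 200 trees | LDA conditioning is handled by the SVD solver rather than an explicit ridge |
| accuracy test | n_perm = 1000, 95th percentile | label permutation, not relabeling |
| latency | per-bin α = 0.05, uncorrected; optional persistence criterion | first significant 10 ms bin, reported as bin start |

The artifact sentence ("standard error larger than its average at a
time point") is ambiguous; both readings are implemented
(`pointwise` default, `se_time_average` alternative).  The pointwise
rule needs a minimal-magnitude floor so that mean-zero crossings do not
trigger removal; a fixed 0.1 z floor is only calibrated for ~120-trial
sessions (SE shrinks as 1/√trials), so the floor is
`max(0.1, 3 × median SE)` per contact, which reduces to the fixed rule
at full trial counts and stays calibrated in smaller fixtures.

## Latency estimation

Activation latency compares per-trial 200 ms baseline power means
against per-trial 10 ms bin means of raw (unsmoothed) post-onset power;
the difference latency compares own vs other per-bin means of z-power
recomputed from unsmoothed power.  Two numerical choices matter:

- **Studentized permutation statistic.**  The baseline average and a
  10 ms bin mean have very different variances; a raw mean-difference
  permutation test is anti-conservative (~12 % per-bin false positives
  at α = 0.05 in simulation).  Using the Welch t statistic inside the
  permutation restores per-bin FPR ≈ α.
- **Unsmoothed power.**  The 80 ms smoothing correlates adjacent bins
  and spreads onsets ~40 ms backwards; latency tests therefore run on
  the raw binned power (the 10 ms binning itself provides smoothing).

No multiple-comparison correction is applied across the 100 bins — the
latency is the first crossing of a per-bin test.  With ~30 pre-onset
null bins at α = 0.05 this makes spuriously early onsets likely in any
single run; the optional persistence criterion (`min_consecutive=2`,
requiring two consecutive significant bins) curbs most of them, and
recovery claims are made on medians over seeds, which are robust to the
remainder.

## The synthetic-session generator

`generate_session` emulates what the analysis assumes about real SEEG:

- **Background**: per-contact 1/f^β Gaussian noise (power-spectral
  exponent β = 2, broadband RMS 20 µV) plus a white broadband floor
  (2 µV RMS).  The floor mimics the flat high-frequency portion of real
  SEEG spectra; without it the 60–145 Hz band is nearly empty, which
  makes any effect component dominate the band at *every* contact the
  Laplacian touches and destroys spatial attribution.
- **Line noise**: optional 50 Hz sinusoid per contact.
- **Events**: balanced pseudo-random own/other sequence, 1000 ms
  stimuli, 1000 ms ITI, optional uniform jitter.
- **Effects**: each `EffectSpec` adds one FFT-brick-wall band-limited
  noise component (base RMS 0.5 µV) at one contact; during
  `[onset, onset+duration]` of matching-class trials its amplitude is
  multiplied by `effect_size`, with 20 ms cosine ramps to avoid gating
  clicks.  `effect_size = 1` is an exact null (classes exchangeable by
  construction).  The brick-wall band limit keeps the component from
  leaking power into the 50 Hz screening band.  Multiple specs per
  contact compose; a shared (both-class) activation plus weaker
  class-specific effects reproduces the qualitative structure of real
  name responses (strong common stimulus activation, subtler own/other
  difference), which is what makes the rest state the most separable
  class in the three-class control.

Default problem sizes are desk-scale — 2 shafts × 8 contacts and
60 + 60 trials — chosen so that a full pipeline run takes seconds; real
montages (~100–150 contacts) are available by configuration.  The
default effect amplitudes were chosen once so that a gain-3 effect is
decoded far above the significance threshold while a null session stays
at chance, and so that Laplacian leakage onto neighboring contacts
(−½ amplitude, ¼ power) stays near the in-band noise floor — the
physical regime in which single-contact attribution is meaningful.

What the generator does **not** model: volume conduction and realistic
spatial correlation of background activity, non-stationary drifts,
epileptiform artifacts, evoked phase-locked potentials, or real speech
and image stimuli.  Passing tests on this generator therefore validate
the *statistical machinery* (calibration, recovery, invariances), not
performance claims on patient data.

Stimulus pairs: auditory stimuli are amplitude-modulated 1 kHz tones
whose low-pass (≤50 Hz) modulators are constructed with an exact sample
correlation equal to the requested similarity; visual stimuli are
balanced binary rasters where flipping a fraction (1−s)/2 of the pixels
produces mean-centered correlation ≈ s.  `stimulus_similarity`
mean-centers both inputs and normalizes by the geometric mean of their
energies, so self-similarity is exactly 1 and a mean-centered negation
gives exactly −1.

## Three-class control

The 1000 ms pre-onset interval of every trial is cut as a rest epoch
and z-scored against its own first 200 ms (symmetric with stimulus
epochs; the protocol names no baseline for the rest window).  A rest
window that would overlap the previous stimulus is an error.  Selection
runs three pairwise permutation tests (rest–own, rest–other, own–other),
10 features each, duplicates kept as distinct slots (30 total),
Bonferroni-corrected per execution.  Sensitivity and precision follow
`100·TP/(TP+FN)` and `100·TP/(TP+FP)`; the per-class accuracy equals
the sensitivity by construction (confusion diagonal over row sum).

## Known limitations

- **Significance under in-fold selection.**  The fixed-prediction label
  permutation calibrates the accuracy's *agreement* variability
  (hypergeometric, sd ≈ 4.6 % at n = 120) but not the variability
  induced by re-selecting features in every fold: on null data the LOO
  accuracy spread is ~2× larger (sd ≈ 8–12 %, reproduced even with iid
  Gaussian features), so the nominal 5 % exceedance rate of the 95 %
  threshold is closer to 15 %.  This is a property of the published
  procedure itself (prediction herding on shared selected features); a
  nested permutation that re-runs selection per shuffle would calibrate
  it, at ~1000× the cost.  The test suite documents this honestly: the
  null-calibration exceedance test asserts the nominal bound and fails.
- **Discrete threshold lattice.**  With 120 trials, accuracies move in
  steps of 1/120; the hypergeometric CDF hits 0.950 exactly at 34
  agreements per class, so the empirical 95th percentile legitimately
  alternates between 56.7 % and 58.3 % across permutation streams.
- **EDF support** is import-only (via mne) and lossy (16-bit); the
  native HDF5 container is lossless and is what round-trip guarantees
  refer to.
- Latency estimates are bounded below by the band's envelope response
  time and the 20 ms effect ramps; recovered onsets are typically one
  bin late (e.g. 310 ms for a 300 ms gated effect).
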