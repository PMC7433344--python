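# Methods

## The measurement chain

The pipeline models a standard acoustic-startle / fear-conditioning rig: a
motion-sensitive piezo platform records a voltage proportional to the
animal's force on the floor at 5 kHz, a camera records the arena, and a
stimulus controller presents white-noise bursts, tone trains and footshocks
on a timed schedule. The package reimplements the analysis side of that rig
— scheduling, event detection, scoring and statistics — and pairs it with a
generative model of the raw signals so every stage can be validated against
known ground truth.

## Stimulus schedules

The startle session fixes: 300 s silent acclimation; 20 noise bursts of
20 ms in five blocks, each block a uniform random permutation of
{70, 80, 90, 100} dB SPL (so each intensity occurs exactly five times);
inter-stimulus intervals uniform on [30, 50] s. Two conventions were open
and are fixed as follows:

* **ISI convention** — measured stimulus-offset to next-stimulus-onset.
  With 20 ms bursts the alternative (onset-to-onset) differs negligibly;
  offset-to-onset keeps silent gaps in range by construction.
* **Nominal duration** — the 1110 s total is treated as a fixed scoring
  denominator, not a constraint on the sampled schedule: 300 s + 19 sampled
  ISIs is stochastic (mean ≈ 1060 s before the final observation window),
  so sessions are scored over [0, 1110] s with truncation/zero-padding.

Conditioning: 180 s baseline, then three pairings of a CS train (twenty
7.5 kHz, 75 dB, 500 ms beeps at a 1 s period, spanning 19.5 s) with a 1 s,
0.7 mA footshock whose onset coincides with the last beep's offset
("back-to-back", taken literally). Inter-pairing gaps are uniform on
[80, 120] s: the 80 s minimum is specified, the upper bound is a modelling
choice (configurable). Retrieval: four CS-only trains after 180 s.

## Startle amplitude

For each burst: baseline mean μ and population SD σ over the half-open
500 ms window before onset; peak = max |v(t) − μ| over the half-open 100 ms
window after onset; response iff peak > 2σ. Choices:

* **Rectification.** Piezo transients are oscillatory, so the "maximum
  amplitude above a mean ± 2 SD threshold" is read as the maximum absolute
  deviation exceeding 2σ in either direction.
* **Sub-threshold trials** score 0 and stay in the 5-trial per-intensity
  mean (policy `zero`); `drop` excludes them instead. No exclusion rule is
  published, and zero-scoring keeps the denominator fixed at 5.
* **Population SD** (1/n). At n = 2500 baseline samples the 1/(n−1)
  difference is ~2·10⁻⁴ relative; fixing one convention keeps runs
  bit-reproducible.
* **Indexing.** Time t maps to sample ⌊t·rate⌋; all windows are half-open,
  ties in the argmax go to the earliest sample.

## Freezing detection

Motion is the mean absolute pixel difference between consecutive frames
(the first difference is stamped on the second frame). Bout calling:
(1) maximal runs of frames with motion strictly below an absolute
threshold; (2) merge runs separated by gaps strictly shorter than 200 ms;
(3) keep bouts strictly longer than 2 s. Merging runs *before* the duration
filter — the stated rules are unordered, but merging first lets a long
freeze fragmented by single-frame twitches survive, which is the evident
purpose of a merge rule. Bout edges are at frame resolution
(frame/frame-rate seconds). The absolute threshold itself is unpublished;
the default (5 a.u.) is the midpoint between the simulator's freezing level
(0) and moving level (10), and is a required, documented config value for
real data. Percent freezing divides by the full nominal session duration.

An alternative reading of the merge rule — that *movement* events shorter
than 200 ms are merged away — is operationally identical here (a movement
gap < 200 ms between two immobility runs disappears either way).

## The synthetic-data generators

What they emulate, and the defaults (all configurable in `SimConfig`):

* **Piezo trace**: Gaussian baseline noise (σ = 1 a.u.) plus, per burst
  responding with probability `response_prob` (default 1), a damped 40 Hz
  sinusoid (decay τ = 50 ms) starting 20 ms after onset, amplitude-normalized
  so its true peak equals gain(genotype, dB) × lognormal jitter (CV 0.15).
  The transducer shape is not modelled mechanistically — only the peak
  matters downstream — and the latency is kept below the 100 ms window by
  construction.
* **Behavioral states**: a semi-Markov alternation between `move` and the
  five scored behaviors; from `move` the exit is exponential with the summed
  entry rates and the target behavior is chosen proportionally to its rate;
  behaviors dwell exponentially and return to `move`. States are mutually
  exclusive and exhaustive, which makes ground-truth denominators
  unambiguous (real scoring sheets need not be exclusive).
* **Motion/frames**: non-freezing frames carry `motion_move_level` (10 a.u.)
  plus Gaussian noise (σ = 1), freezing frames |noise| only; the frame
  renderer moves a dark blob by integer steps on a bright field, exactly
  stationary during freezing. Frame rate 30 Hz (a typical behavioral camera;
  no value is published).

**Presets** (`presets/spasmodic.json`, `presets/spastic.json`) give each
line × genotype its gains and state parameters. They are illustrative: they
preserve the ordinal phenotype structure (homozygous spasmodic ≫ wt in
startle gain and freezing, with on-back episodes; heterozygous spastic ≈ wt)
at magnitudes resembling the published group figures, but are not fits — no
per-animal raw data exist to fit to. Freezing dwell means (wt 8 s, hom 14 s)
are in the range reported for conditioned-fear bouts; note the detector
discards true bouts ≤ 2 s, so the attainable error floor on total freezing
time is the exponential-dwell mass in short bouts, 1 − (1 + 2/m)e^(−2/m)
(≈ 2.6 % of freezing time at m = 8 s) — dwell means well below ~6 s would
make an honest 5 %-accurate total unattainable by construction.

What passing recovery tests does *not* show about real data: real piezo
baselines are not white Gaussian noise (line hum, respiration), real motion
signals have illumination drift and compression artifacts, and real
behaviors are not exponentially distributed or mutually exclusive. The
closed-loop tests validate the detectors' logic and calibration interface,
not camera- or transducer-specific thresholds.

## Statistics

* `p_from_t` / `p_from_f` evaluate the exact t and F survival functions
  (regularized incomplete beta); tests check them against adaptive
  quadrature of the t density to 1e-6.
* `student_t_test` is the pooled-variance two-tailed Student t with
  df = n₁+n₂−2 (every published df follows this convention, so Welch is not
  used). Degenerate inputs are defined, not NaN: identical constant groups
  give t = 0, p = 1; a single zero-variance group makes the accompanying
  variance-ratio F infinite (groups that never show a behavior produce
  exactly this). The variance ratio is larger/smaller sample variance and is
  descriptive only — it never switches the test.
* `mixed_anova` is a split-plot decomposition written directly from the cell
  means: SS_total = SS_genotype + SS_subjects-within-groups + SS_intensity +
  SS_interaction + SS_residual, exact even with unequal group sizes because
  every animal contributes every intensity (verified by a brute-force
  partition test and cross-checked against an independent implementation).
  Interaction df = ((G−1)(k−1), (N−G)(k−1)) — (3, 27) at N = 11 and (3, 39)
  at N = 15 for the 2-group, 4-intensity design. Effects whose error mean
  square is at round-off level (exactly additive noiseless tables) are
  reported as F = 0.
* **Post hoc**: per-intensity pooled two-sample t tests with Bonferroni
  adjustment (p × 4, capped at 1). Using the per-comparison error variance
  rather than the ANOVA residual MS is deliberate — it is robust to
  heteroscedasticity across intensities — and localized in one function if a
  pooled-error variant is preferred.
* p-values render at 4 decimals, with "< 0.0001" below that floor.
* Sphericity corrections (Greenhouse–Geisser) and nonparametric alternatives
  are out of scope.

## Problem sizes and determinism

Every simulator and protocol builder is a pure function of its inputs and a
seed; cohort runs derive per-animal seeds from one root seed, and every
report embeds the config hash and seed. The shipped validation runs use
desk-scale sizes chosen to exercise each claim with comfortable statistical
margin: 1000 seeds for schedule invariants, 200/100 random traces for the
bout/peak oracle equivalences, 10 animals (200 bursts) for startle recovery,
20 animals per genotype for freezing recovery, and 10 000 replicates for the
type-I error of the t test (band 0.045–0.056 at α = 0.05).

## Known limitations

* No prepulse-inhibition or habituation modelling across blocks.
* No video decoding (frame stacks enter as arrays/TIFF-like data) and no
  automated recognition of grooming/rearing — ethogram rows beyond freezing
  come from annotation tables, as in observational scoring.
* The freezing threshold and the simulator presets transfer to real rigs
  only after calibration; presets encode ordinal, not quantitative,
  genotype differences.
* CS-locked freezing time-courses are not computed (scoring is
  session-level), and the conditioning/retrieval protocols are modelled for
  scheduling and scoring denominators, not for piezo analysis.
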