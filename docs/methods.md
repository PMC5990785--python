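# Methods

## The data model

One row per measured call: caller identity, sex, age (years and
adult/subadult class), behavioural context (rest / travel / alert),
observer (CC / TG), recording device (`s` directional microphone +
recorder, `cs` video camera + external microphone, `c` camera internal
microphone), bout membership, and twelve acoustic variables. Derived
fields are defined exactly — F0 drop = max F0 − end F0, slope = drop /
(time from F0 max to call end), positions = event time / duration — and
validated on input with an absolute tolerance of 1e−6 in the variable's
units plus a relative term covering 9-significant-digit CSV storage.
Inter-call intervals (gap from a call's end to the next call's onset
within an unbroken same-type bout) are absent for single calls; rows
without one are excluded from any analysis in which that variable is
active.

## Acoustic measurement definitions

Measurements operate on an F0 contour sampled at ≤ 0.01 s intervals and a
framewise spectrum series. Start/end F0 are the **median** of contour
samples within the first/last 0.05 s — the window width follows standard
spectrogram practice for these calls; the median is a robustness choice
because single edge samples of a pitch track jitter. The time of maximum
F0 is the earliest sample attaining the maximum. Slope is defined as 0
when the drop or the remaining time is 0, making the function total; the
variable is discarded in screening anyway. Peak frequency is the
maximum-amplitude bin within the single frame nearest the time of maximum
intensity (mirroring a two-step intensity-then-cursor workflow). Calls
shorter than 0.1 s have their edge windows truncated at the midpoint, with
a warning.

Synthetic spectra use a 256-bin frequency grid over 0–4 kHz and 1000
frames per call. A literal "FFT length 256 points, window 0.05 s, time
step 1000" is not self-consistent for 44.1 kHz audio, so the package
adopts the one consistent reading (256 frequency points, 1000 time steps
per call) and builds the spectra analytically from the harmonic model —
which also makes the generator's ground truth exact to one bin.

## The synthetic generator

The generator is the package's stand-in for field data and defines the
study conditions:

- **Roster.** 29 subjects, 271 calls: rest 137, travel 94, alert 40, with
  11 subjects contributing to all three contexts. Ages are fixed
  (adults 16–28, subadults 11–13).
- **Linear structure.** Each of log duration, log maximum F0 and
  sqrt inter-call interval is context mean + subject intercept + observer/
  device/sex/age terms + Gaussian residual on its transformed scale, so the
  LMM stage's assumptions hold by construction. Context effects default to
  the published mixed-model estimates (duration: rest +0.63, travel −0.28
  vs alert, intercept −1.55 ≈ 0.21 s; F0 max: rest −0.31, travel −0.42 vs
  alert 5.80 ≈ 330 Hz; interval: travel −0.71 vs alert 1.37 ≈ 1.9 s).
  Residual SDs (0.35, 0.15, 0.40) and subject SDs (0.15, 0.08, 0.07) are
  not published anywhere; they are field-plausible choices fixed once.
- **Correlation structure.** Start/end F0 are maximum F0 minus small
  positive offsets (pairwise r ≈ 0.9–0.97), and sqrt(F0 drop) gains 2.6
  per unit log duration (longer calls fall further), which makes the
  drop–slope correlation exceed 0.7 without tying the drop to context.
  These couplings exist so that collinearity screening reproduces the
  canonical outcome for this variable set: discard slope steepness and
  start/end F0, retain six predictors with all VIFs < 2.
- **Observer/device imbalance.** Alert calls are recorded by CC, travel by
  TG, rest split between them; CC mostly uses the directional-microphone
  rig, TG the camera setups. The rest-context mixing is what keeps
  observer and context jointly identifiable.
- **Bout structure.** Exact per-context single-call counts (rest 134/137,
  travel 15/94, alert 2/40); non-single calls carry a measured interval;
  five travel/alert intervals are marked unmeasurable. One in-bout travel
  and alert call per three-context subject is protected from those draws,
  so the bout-level analysis retains the same eleven callers as the
  three-context analysis — as in the design this emulates.
- **Gaps** in generated bouts are Gamma(shape 3) with context means
  travel 0.45 s < alert 1.9 s < rest 4.0 s (positive, right-skewed).
- **Audio-level path.** `generate_call_bout` emits rise–fall contours with
  0.05 s edge holds (so the start/end definitions recover truth exactly)
  and a harmonic stack (3 harmonics, first strongest unless the
  second-harmonic flag is drawn) under a Gaussian envelope; durations use
  a separate 0.25–0.8 s scale so edge windows always fit, with context
  direction preserved. WAV rendering is 44.1 kHz 16-bit.
- **Determinism.** One master seed; every component stream derives from it
  via seed-sequence spawning.

The `null_truth` preset removes all context differences **and** the
call-level observer/device effects: observers are allocated by context, so
a nonzero observer effect would be a real feature–context association that
a correct permutation test must (and does) detect. Subject-level structure
(intercepts, sex, age) is retained because the within-subject permutation
conserves it.

What the generator does *not* emulate: vocal individuality beyond a random
intercept, noise-corrupted pitch tracking, non-Gaussian residuals,
context-dependent within-subject variance, and recording-quality artefacts.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to messy field audio.

## The crossed pDFA

Eligibility (a subject has calls in every analysis context) is computed
once from the observed labels; within-subject shuffling conserves
per-subject context counts, so eligibility is permutation-invariant
(asserted on every shuffle, not assumed). Each permutation is evaluated
with **one** fresh balanced selection while the observed statistic keeps
the full multi-selection average — permutation variance dominates
selection variance, and re-averaging the null would multiply cost by the
selection count. A consequence worth stating: with a multi-selection
observed statistic the test is **conservative** (each null draw carries
selection noise the averaged observed statistic lacks), never
anticonservative. In the exchangeable configuration
(`n_selections = 1`) the test is calibrated: measured type-I error at
α = 0.05 is ~5–7% over 200 replicate null tables, and that is the
configuration the calibration check runs.

Numerical decisions: the p-value uses the add-one estimator and can never
be 0; training priors are the training-set proportions (equal by
construction of the balanced design), with an equal-priors switch;
posterior ties break to the first context in declared order and are
flagged; a pooled covariance with condition number > 1e10 raises a
degeneracy error naming the likely collinear variables — no silent ridge
regularization. Selection and permutation random streams are derived
independently from the config seed, so changing one count does not
reshuffle the other.

## The mixed models

ML (not REML) throughout, because the likelihood-ratio tests compare
models differing in fixed effects. Treatment contrasts use alert as the
reference level. The full-vs-null χ² has d.f. = number of context
contrasts (2 for three contexts, 1 for two). The interval model includes
only sex and age as controls: with travel recorded by one observer and
alert by the other on the bout subset, observer and device are not
identifiable there. No random slopes are fitted — the unbalanced design
has levels with fewer than two distinct fixed-effect values per subject.

Optimization tries lbfgs, then bfgs, powell and cg, accepting the first
converged fit with a finite log-likelihood (a boundary fit can report
"converged" with an infinite likelihood; that is rejected). Non-convergence
is an error, never a silent result. A rank-deficient fixed design raises an
identifiability error listing the aliased terms (pivoted-QR diagnosis).

Leave-one-subject-out stability: a subject is influential if some fixed
estimate moves by more than 50% of max(|estimate|, SE) **and** by more
than one SE. The second gate stops statistically negligible wobbles of
near-zero control estimates (an age slope of ~0.00) from triggering the
flag; genuinely planted outliers move estimates by many SEs and are
caught. On unbalanced designs the diagnostic can still flag noise-level
control terms (e.g. a rarely used device class) — that is reported, not
suppressed.

Bonferroni control across the family of three responses uses strict
inequality at α/3, reported as the conventional 0.017.

## Problem sizes

Default analysis strength is 100 random selections and 10 000 permutations
per pDFA. The test suite and acceptance script use the same strength for
single runs and reduced strengths for Monte-Carlo studies (200 replicate
tables × 200 permutations for type-I calibration; 150–200 replicates for
effect-recovery checks), chosen so the whole suite completes in a few
minutes on one CPU while keeping Monte-Carlo error well inside the asserted
bands.

## Known limitations

- The pDFA's headline configuration is conservative (see above); exact
  calibration holds in the exchangeable configuration.
- Loadings from a single 33-call balanced selection are noisy; influence
  statements about individual variables are stable only on larger fits or
  selection averages.
- The screening drop-policy prefers the canonical victims (slope, start/end
  F0) and otherwise discards the variable with the largest mean absolute
  correlation; other reasonable policies exist and can change the retained
  set on data unlike these.
- Only nested/crossed designs with a single grouping factor (subject) are
  supported; no quadratic or shrinkage DFA, no random slopes, no crossed
  random effects.
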