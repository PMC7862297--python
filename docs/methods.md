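# Methods

This note documents the models, defaults, and design choices behind
qeegpain, and what its tests do and do not establish.

## Synthetic EEG model

A session is a realization of a Gaussian process defined in the
frequency domain. The one-sided target PSD is

    S(f) = [ f^(−β) + Σ_k a_k · N(f; c_k, bw_k) ] · g(f)²

with β = 1 (pink background), Gaussian oscillation bumps at 10 Hz
(FWHM 2 Hz, relative amplitude 2 — an alpha rhythm) and 20 Hz (FWHM
4 Hz, amplitude 0.5 — beta), and an amplitude gain g(f) equal to the
pain-level gain of the 1-Hz band containing f times a per-subject
log-normal factor exp(u), u ~ N(0, 0.2²), shared by a subject's two
sessions. Each rFFT bin draws an independent complex-Gaussian
coefficient with variance matched to S(f), so the expected periodogram
equals S(f) exactly and `spectral_profile` returns the band-mean of
S(f) in closed form — the ground-truth oracle for recovery tests.

Two walking artifacts are superimposed, each Poisson in time:
EMG bursts (4/min, 0.5 s, band-limited 30–100 Hz noise, Hann envelope,
peak ≈ 2× background RMS) and motion transients (2/min, 1 s, ~1.5 Hz
enveloped sway, 4× background RMS). Rates and amplitudes are not
measured values; they were chosen once as plausible for walking with a
consumer headband and are fully configurable.

**Level gains.** The per-quartile gain vectors follow the qualitative
contrast pattern the analysis is meant to expose: moderate elevated at
1–2 Hz (amplitude ×1.40) relative to all other levels; severe elevated
at 5–6 and 11–16, 18, 24 Hz (×1.50) and 4 Hz (×1.30); mild carries a
small broad 3–10 Hz elevation (×1.12); moderate additionally ×1.15 at
4 and 11–13 Hz. Magnitudes are a documented calibration that places
default out-of-fold accuracy in a realistic 60–90 % band (measured
0.86 at seed 1); they are free parameters, not values derived from any
recorded data.

**Cohort layout.** 23 subjects × {pre, post}, quartile counts
none 16 / mild 8 / moderate 15 / severe 7. Severe sessions are always
pre-intervention, pain-free sessions always post, and mild/moderate
fill the remainder with moderate preferentially pre (pre-intervention
pain is what motivates surgery); infeasible layouts (odd totals, more
pain-free sessions than subjects) raise a labeled error. Every
pre-phase session has NRS ≥ 1 by construction. NRS within a quartile
is uniform on the quartile's range.

Not modeled: dipole/forward physics, eye blinks, multi-channel
montages, non-stationarity within a session beyond artifact bursts.
A green pipeline test therefore establishes correctness of the signal
processing and the statistical/classification machinery on data with
the assumed class structure — it says nothing about how well real
walking EEG separates pain levels.

## Preprocessing

Trim 60 s from each end (420 → 300 s); z-score with the population SD
(at n = 153 600 the sample/population distinction is irrelevant, but
the convention is fixed for exactness); Butterworth band-pass 0.5–36 Hz
of order 4, applied forward–backward (zero phase) — filter realization
is our choice, standard qEEG practice. Normalization precedes
filtering; a `normalize_first=False` switch reverses the order for
sensitivity analysis.

EMG removal is implemented as (a) the 36 Hz low-pass edge itself, which
removes most EMG energy, plus (b) amplitude-threshold window flagging
(peak |z| > 5). Flagged windows are retained by default — the target
design always analyzes 10 windows per session — and excluded only on
request (`drop_flagged=True`). The threshold rule is a pragmatic
stand-in: the original EMG-elimination procedure is cited but not
reproducible from the source text.

## Spectral features

Welch's method with Hann-tapered, half-overlapping subsegments;
feature f = mean PSD over [f − 0.5, f + 0.5), f = 1…35 Hz (the source
analysis never defines bin edges; 1-Hz-wide band means centered on f
are our convention). Features are power; `amplitude_features()` gives
the square root for plots.

The default subsegment length is **4 s** (0.25 Hz resolution), not 2 s.
With 0.5 Hz resolution, a Hann-tapered on-bin tone leaks 1/6 of its
power one bin (0.5 Hz) sideways — outside its 1-Hz band — so a 10 Hz
sinusoid would deposit only ≈ 83 % of its power in the 10 Hz feature.
At 0.25 Hz resolution the ±1-bin leakage stays inside the band and
localization is essentially complete. One source passage mentions
1–40 Hz; 1–35 Hz is implemented throughout, consistent with the 36 Hz
filter edge.

**Recovery oracle.** z-normalization removes absolute scale and the
band-pass shapes the band edges (zero-phase filtering applies |H|²
twice), and the tapered periodogram smooths the spectrum by the Hann
kernel (visible as a bias in bands adjacent to sharp gain steps).
`expected_feature_profile` composes all three effects on top of the
generative PSD; recovery tests fit a single scalar and then require
each of the 35 band powers of simulated artifact-free sessions to match
within 10 %.

## Group statistics

Welch's t-test (scipy) for the pain-binary contrast; Kruskal–Wallis
(scipy, tie-corrected; the all-tied degenerate case returns H = 0 by
convention) gating Dunn's pairwise z-tests for quartiles. Dunn's test
is implemented in-package (pooled mid-ranks, tie term Σ(t³ − t)) since
no installed library provides it, and is verified against a brute-force
counting oracle. The source's methods name Welch's t-test while a table
footnote says Student's t — Welch is the default here; for equal group
sizes the two statistics coincide anyway (tested).

Bonferroni family = 35 frequencies within each contrast; a
`strict_pairs` mode multiplies Dunn p-values by the 6 pairs as well.
Default mode is *protected*: all 6 × 35 pairwise rows are emitted (with
the omnibus p alongside), but a pair is flagged significant only when
its Kruskal–Wallis omnibus is also significant at α; `protected=False`
makes significance exactly `p_corrected < α`. Significance is strict
(< 0.05): a corrected p of exactly 0.050 is not significant.

The statistical unit defaults to the window (460 units), matching the
implied n of the reference analysis; `unit="session"` averages features
per session first (46 units). Windows of one session are correlated, so
window-level tests overstate effective sample size — a mixed model
would be the statistically superior treatment but is out of scope.

## Classification

RBF-kernel SVM; features standardized with training-fold statistics;
C ∈ {0.1, 1, 10, 100} × γ ∈ {scale, 0.01, 0.1, 1} by inner stratified
5-fold grid search. The reference evaluation protocol is unstated, but
its confusion-matrix row totals equal the full dataset, implying
out-of-fold predictions for all 460 windows; the default here is
stratified 10-fold at window level, which mimics that. Window-level
folds put windows of one session on both sides of a split and so leak
subject identity — `cv_scheme="session"` (leave-one-session-out) is the
leakage-safe alternative. On the default synthetic cohort the two agree
closely because z-normalization removes the (purely multiplicative)
subject effect; on real data the gap can be large.

Precision for a never-predicted class is reported as `None` and
excluded from summaries rather than silently zeroed. Session-level
predictions are the majority vote over the session's 10 windows; ties
break toward the more severe class (clinically conservative; the
aggregation rule is our choice).

A reference check reproduces published metric arithmetic from a printed
4×4 confusion matrix: accuracy 366/460 = 0.7957, precisions
0.8395/0.6974/0.7975/0.7969, recalls 0.8500/0.6625/0.8400/0.7286. The
F1 for the "none" class is the harmonic mean of 0.8395 and 0.8500,
which is **0.8447**; the commonly printed 0.8477 is inconsistent with
its own precision and recall and is treated as a typo.

## Numerical conventions

- CSV output: 12 significant digits, `.` decimal, LF endings —
  reruns at a fixed seed are byte-identical.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-session seeds derive from the cohort
  seed, and cross-validation shuffling is seeded.
- EDF I/O is not built (no EDF library in the supported environment);
  sessions use the CSV dialect, and `--format edf` raises a labeled
  error.

## Limitations

- Effect sizes, artifact rates and the sampling rate (512 Hz) are
  assumptions, not measurements; the generator states a world rather
  than fitting one.
- The per-subject effect is a flat multiplicative gain, which the
  z-normalization step removes entirely; real between-subject spectral
  shape differences would survive normalization and make session-level
  CV strictly harder than window-level CV.
- Window-level statistics treat correlated windows as independent (by
  design, to mirror the reference analysis).
- Real-data accuracies reported for this kind of system are not
  reproducible here without the original recordings; the synthetic
  defaults are calibrated to land in a comparable accuracy band, and
  tests assert recovery and orderings, not those published numbers.
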