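# Methods

## Data model and time conventions

The unit of data is the expert-annotated seizure event: onset (seconds
since a per-animal epoch), electrographic duration, optional semiology
label. Events shorter than 10 s are not scored as seizures (the usual
electrographic inclusion criterion); the strict loader drops them and
reports the dropped rows, a permissive flag keeps them with a warning.

Two epochs are supported: *injection* (the epileptogenic insult) and
*first_seizure*. Latency analysis runs on the injection epoch; every
frequency, clustering and prediction analysis runs on the first-seizure
epoch with a 30-day window, day *k* meaning the half-open interval
[k, k+1) days, 0-based, starting exactly at the first seizure's onset
(not the next midnight). Wall-clock hour is `clock_offset_h +
onset_s/3600 (mod 24)`, which makes an event's clock hour independent of
the epoch choice — a property the tests enforce. Seizure-free animals
stay in the cohort (they belong in the induction-rate denominator) and
are excluded, with a log note, from analyses that need events.

## Synthetic cohort generator

Each animal draws, from a substream seeded by `(seed, animal_index)`:
induction success (default p = 0.84), an integer latency uniform on 3–7
days, a baseline daily seizure rate r ~ lognormal(ln 3, 0.8) (totals of
tens to hundreds of seizures per month, strongly heterogeneous), and a
daytime surgery clock offset. Events then follow a conditional-intensity
process, sampled exactly by Ogata-style thinning with an adaptive local
bound:

    lambda(u) = r * w(u) * c(clock(u)) * max(0, 1 + E(u) - S(u))

* `w` — weekly step profile anchored at the first seizure, proportional
  to 26:24:36:12 and rescaled to mean 1 (stable first two weeks,
  third-week peak, final-week drop). The recording window runs 30 days
  from the first event, as in long-term monitoring protocols.
* `c` — raised-cosine circadian gate `1 + A cos(2*pi*(h - peak)/24)`,
  default amplitude 0.4 and peak at clock hour 14.5 (mid light phase);
  multiplicative, so seizure-free nights remain possible.
* `E`, `S` — exponentially decaying excitation and suppression sums. Per
  event, E jumps by `g_e / (r * tau_e)` and S by `g_s / (r * tau_s)`, so
  `excitation_gain` g_e is the expected number of extra events triggered
  per event (the Hawkes branching ratio; stability requires g_e < 1) and
  `suppression_gain` g_s the expected number suppressed, independent of
  the animal's rate. Normalising the jumps by r keeps the dynamics
  scale-free across the lognormal heterogeneity — a raw multiplicative
  jump would clamp every animal to the same effective rate and destroy
  the first-week/remaining-count correlation. Defaults g_e = 0.8,
  tau_e = 12 h, g_s = 1.3, tau_s = 3 d were chosen once, by a grid search
  over a coarse lattice, as the regime that reproduces the qualitative
  structure the generator exists to emulate — a significant pair-count
  excess within 24 h, a deficit in the 48–96 h lag band, and a
  (+, −) lag-1/lag-2 partial-autocorrelation pattern — robustly across
  independent seeds. g_s > 1 is deliberate: the intensity clamps at zero
  after a cluster, giving relaxation-oscillator-like cluster/refractory
  alternation. The kernel sums start at their mean-field stationary
  values `g * m`, `m = 1/(1 + g_s - g_e)`, so the realized weekly profile
  tracks `w` instead of showing a burn-in surge while suppression
  accumulates.
* Durations — a two-component lognormal mixture parametrised by its
  modes (weight 0.25 at 20 s, 0.75 at 110 s, log-sd 0.25), scaled by a
  saturating ramp from 35 % of plateau at seizure onset with ~95 %
  recovery by `duration_rampup_days` (default 7), floored at the 10 s
  inclusion criterion. Semiology labels are i.i.d. multinomial with the
  published class frequencies.

What the generator does **not** emulate: ECoG waveforms and interictal
spikes; day-to-day weather/handling covariates; state-dependent
(NREM/REM) gating beyond the light-phase cosine; non-stationarity beyond
the weekly step profile; death or dropout. Passing recovery tests
therefore demonstrates that the analyses detect the *kinds* of structure
these cohorts show at realistic sizes, not that real diaries follow this
exact generative family.

Two systematic interactions are worth knowing. First, self-excitation
delays the *observed* circadian peak by up to about an hour relative to
the configured gate peak (clusters extend past the gate's maximum), so
peak-recovery checks isolate the circadian machinery by zeroing the
kernel gains. Second, because a diary is observed from its first seizure,
one event sits exactly at the window edge; for small event counts this
perturbs the peri-seizure pair statistics slightly relative to the
i.i.d.-uniform baseline.

## Statistical procedures

**Weekly percentages** use only the four complete weeks inside the
30-day window and renormalise to 100 (truncation logged). Box-and-whisker
summaries use Tukey 1.5×IQR whiskers clipped to the data. Medians of
even-sized sets use the midpoint convention; days without seizures are
gaps, never zeros.

**Duration histograms** default to 5-s bins up to 150 s and 25-s bins
beyond (the granularity at which the two duration modes separate). The
normalised mode weights each event by 1/(its animal's total) and divides
by the number of contributing animals — weighted-event pooling, so the
density integrates to 1 and a 300-seizure animal cannot drown a
30-seizure animal; averaging per-animal densities is the noted
alternative.

**Exact signed-rank test.** Day/night duration comparisons use per-animal
median durations as the paired unit (per-event pooling would
pseudo-replicate). Zero differences are dropped, ties get midranks, and
for n ≤ 20 the two-sided p is exact: the null distribution of W+ is
built by convolution over the (doubled, integer) midranks — a lossless
equivalent of enumerating all 2^n sign assignments, which the tests
verify against literal enumeration. Beyond n = 20 a continuity-corrected
normal approximation with tie-corrected variance takes over; the two
paths agree to < 0.02 at n = 15.

**Lilliefors exponentiality.** D is the KS distance between the ISI
empirical CDF and an exponential with the sample mean. Because the mean
is estimated, classical KS tables are invalid and no closed form exists
for the exponential case, so the p-value is Monte Carlo: unit-mean
exponential samples of the same n, mean re-estimated per replicate
(D is scale-free under the null), with the (1 + k)/(1 + n_mc) adjustment;
default n_mc = 10,000, seeded. Calibration: type-I error 0.05 ± 0.01 at
the 5 % level and uniform p-values under the null, verified over
thousands of replicates.

**Peri-seizure histogram.** All ordered pairwise lags (not only
consecutive ISIs — multi-day lags cannot be filled by consecutive
intervals; a consecutive-only mode exists) binned at 1 day with centres
k + 0.5, each bin divided by (T − centre), T = 30 d. Because (T − l) is
linear in the lag, this correction *exactly* cancels the triangular
pair-lag density of uniform events, making the uniform baseline
lag-independent: expected corrected count n(n−1)Δ/T² per bin, divided by
n under per-animal normalisation. The closed form is validated against
brute-force uniform resampling. Cohort inference: each animal's
normalised bin vector is one observation; two-tailed one-sample t-tests
per bin against the animal's own baseline, max lag 7 days by default.
P-values are reported unadjusted (matching per-bin star conventions)
with a clearly-labelled Holm-adjusted column alongside.

**Partial autocorrelation** of daily counts uses biased sample
autocovariances and the Durbin–Levinson recursion (each reflection
coefficient is the lag-k pacf); it agrees with an independent direct
solve of the Yule–Walker system to machine precision and with large-n
AR-model ground truth. Per-lag one-sample t-tests across animals give
the significance stars, again with a Holm column as an extension.

**Prediction.** Per animal, counts are split on [0, 7) and [7, 30) days
(half-open: a day-7.0 event is "remaining"). Animals with a zero count in
either window are excluded with a warning (their log is undefined). Both
axes are modelled on the log scale — the multiplicative rate
heterogeneity makes log-log the natural space, and predictions map back
to counts through the lognormal predictive; a linear-y fallback is not
provided. The GP posterior with kernel σ_b² + σ_v²·x·x′ plus noise σ_n²
equals the Bayesian-linear-regression closed form (the module's core
oracle, enforced to 1e-9). Hyperparameters maximise the log marginal
likelihood from a 27-point log-spaced multi-start grid refined by
Nelder–Mead, since no protocol pins them; a fixed-hyperparameter mode
keeps tests reproducible, and a 1e-8 noise floor guards the Cholesky.
Interval probabilities are Φ differences of the log-scale predictive;
enrollment windows are the integer first-week counts (counts are
integers) where that probability exceeds 0.5, with contiguity reported
rather than assumed. Calibration uses the closed-form leave-one-out
predictive (mean y_i − [K⁻¹y]_i/[K⁻¹]_ii, variance 1/[K⁻¹]_ii): over 200
simulated 10-animal cohorts the central-50 % interval covers the true
log remaining count for 50 ± 7 % of animals. Enrollment balance across
the alternating two-arm assignment is assessed on geometric means, the
natural scale for lognormal counts.

## Problem sizes and numerical choices

Recovery tests use 40–60-animal cohorts (one seed, pre-verified robust
across five); calibration tests use 2000–5000 null replicates with
n_mc = 1000 Monte-Carlo samples per test and 200 cohorts for coverage —
sizes at which the Monte-Carlo error of each asserted quantity is several
times smaller than its tolerance. Ties in the signed-rank statistic are
handled by midranks; degenerate inputs (constant count series, all-zero
differences, < 2 events) are flagged or excluded explicitly rather than
silently coerced. CSV round trips are bit-exact (`repr` on write,
round-trip float parsing on read). All randomness flows from explicit
seeds; the pipeline's `summary.json` is byte-identical for identical
configuration and seeds.

## Known limitations

* The peri-seizure t-tests are slightly anti-conservative on cohorts
  containing very-low-count animals (skewed per-animal deviations); on
  homogeneous-Poisson cohorts of 30 animals the per-bin level is ~1 %
  at nominal 1 %.
* The Lilliefors p-value resolution is 1/(n_mc + 1); use larger n_mc for
  p-values near a decision boundary.
* Hyperparameter optimisation is multi-start but not provably global;
  the fixed-hyperparameter mode exists for exact reproducibility.
* Enrollment windows assume the fitted cohort is exchangeable with the
  animals being enrolled; no covariate adjustment is provided.
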