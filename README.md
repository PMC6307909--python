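# szdiary

Temporal statistics for **seizure diaries** from chronic rodent epilepsy
models — the event lists (onset, duration, behavioural class) that come out
of long-term video-ECoG monitoring of, for example, tetanus-neurotoxin
(TeNT) focal neocortical epilepsy in rats.

Given per-animal diaries, the package answers the questions a preclinical
epilepsy study asks of its natural-history data:

* **Natural history** — latent period, daily/weekly seizure frequency,
  cumulative seizure accumulation, evolution of seizure duration, and the
  induction rate of the model.
* **Semiology** — counts and percentages per behavioural class (non-motor,
  unilateral motor, bilateral motor, generalized tonic-clonic, unknown) and
  per-animal-normalised duration histograms, which in this model are
  bimodal (~20 s and ~110 s modes).
* **Circadian structure** — per-animal-normalised hour-of-day profiles,
  light/dark fractions, and an exact Wilcoxon matched-pairs signed-rank
  test (full enumeration of the 2^n sign assignments) for day-vs-night
  median durations.
* **Clustering and periodicity** — inter-seizure-interval (ISI)
  distributions; a Lilliefors-type exponentiality test (Kolmogorov–Smirnov
  distance against an exponential with the *estimated* mean, null
  distribution by Monte Carlo); the **edge-corrected peri-seizure
  histogram**, where the count in a lag bin with centre *c* is divided by
  (T − c) to undo the triangular pair-lag bias of a T = 30 day recording,
  tested bin-by-bin against the closed-form uniform baseline
  n(n−1)Δ/T²; and the partial autocorrelation (Durbin–Levinson) of daily
  seizure counts, whose (+, −) lag-1/lag-2 pattern signals
  cluster-then-refractory periodicity.
* **Prediction / enrollment** — a Gaussian-process regression with linear
  kernel k(x, x′) = σ_b² + σ_v²·x·x′ (mathematically identical to Bayesian
  linear regression) of log remaining-period seizure count on log
  first-week count. The lognormal posterior predictive yields
  P(remaining count ∈ [a, b] | first-week count) and hence enrollment
  windows with > 50 % confidence, plus a stratified two-arm assignment.

A **synthetic diary generator** reproduces the statistical structure of
such cohorts — 3–7-day latent period, lognormal across-animal rate
heterogeneity, a 26:24:36:12 weekly frequency profile, raised-cosine
light-phase-dominant circadian gating, self-exciting (Hawkes) within-24-h
clustering with a slower suppression kernel producing a 48–96-h refractory
dip, bimodal lognormal durations with a first-week ramp-up — so every
analysis stage has parameter-recovery and calibration tests without any
animal data. See `docs/methods.md` for the model and its assumptions.

## Worked example

Simulate a 10-animal cohort and run the stages from the command line:

```sh
szdiary simulate --out events.csv --meta meta.csv --seed 11 --n-animals 10
# wrote 563 events from 10 animals

szdiary describe --events events.csv --meta meta.csv --out report/
# 8/10 animals developed seizures (80.0%)

szdiary circadian --events events.csv --meta meta.csv --out circ.csv
# peak hour: 13.5
# day vs night duration: W=12, P=0.461 (exact, n=8)

szdiary structure --events events.csv --meta meta.csv --out report/ --seed 11
# ...
# 5/8 diaries depart from exponential ISIs at alpha=0.05

szdiary predict --events events.csv --meta meta.csv --out pred/
# Pearson r = 0.985 (n=8)
# target 20-100 remaining seizures: first-week window with >50% confidence: 7-38
# target 20-200 remaining seizures: first-week window with >50% confidence: 7-80
```

Reading the output: two of the ten injected animals never seized (the
induction-rate numerator counts only seizing animals); the cohort's pooled
hourly profile peaks mid light phase (hour 13–14, the sleep phase for a
7 a.m./7 p.m. light cycle) while day and night seizure *durations* do not
differ (exact signed-rank P = 0.461); most diaries fail the
exponential-ISI test, i.e. seizures cluster rather than arriving as a
Poisson process; and the log first-week count predicts the log remaining
count almost perfectly (r = 0.985), so an animal with 7–38 seizures in its
first week is predicted, with > 50 % confidence, to have 20–100 more in
the remaining 23 days. `szdiary run-all` executes every stage and writes
one reproducible report directory (`summary.json` is byte-identical for
identical config and seeds).

The same operations are available as a library:

```python
from szdiary import SimulatorConfig, simulate_cohort
from szdiary.temporal import peri_seizure_analysis

cohort = simulate_cohort(SimulatorConfig(n_animals=50, seed=1))
peri = peri_seizure_analysis(cohort)
print(peri.to_frame())   # per-lag mean, sem, uniform baseline, t, p
```

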