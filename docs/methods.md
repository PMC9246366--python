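# Methods

This note documents the generative model behind the synthetic recordings,
the estimators the analysis uses, the numerical choices that were genuinely
open, and what the synthetic validation does and does not establish about
recorded data.

## Generative model

A session is a pair of voltage traces sampled at 20 kHz (afferent ganglion
and ventral motor root) of duration `T`, parameterized by
`SimulationConfig`.

**Swim bouts.** Bout onsets follow a renewal process: candidate
inter-onset waits are exponential with rate `bout_rate` (default 0.5 /s);
a candidate falling inside the previous bout or within
`min_inter_bout_gap` (0.25 s) of its offset is redrawn, which by
memorylessness equals restarting the exponential clock after that dead
period.  Durations are drawn from a normal truncated below at 50 ms whose
location is solved numerically so that the *post-truncation* mean equals
`bout_duration_mean` — naive truncation would otherwise bias durations
upward by up to 20% at realistic spreads.  The realized bout count has
mean `T / (mean_duration + min_gap + 1/bout_rate)`.  The 0.25-s gap floor
reflects that two burst groups separated by less than the 200-ms grouping
gap are by definition one bout; without it, the generator would emit
"distinct" bouts no detector could separate.

**Afferent spikes.** An inhomogeneous Poisson process with intensity `λ`
outside bouts and `λ(1 − I)` inside bouts (`I` = inhibition fraction,
a step modulation with no onset/offset transients), realized by thinning a
homogeneous process, followed by deletion-enforced 1-ms absolute
refractoriness.  Because non-paralyzable dead time `τ` reduces a Poisson
rate `r'` to `r'/(1 + r'τ)`, target rates are first converted to the
corrected intensity `r' = r/(1 − rτ)`; the configured rates are therefore
the rates an observer measures, exact to well under 1% even at 50 Hz.
At `I = 1` no spike ever falls inside a bout.

**Motor bursts.** Within each bout, bursts at regular `1/f` intervals
(`f` = `burst_frequency`, default 25 /s, the tail-beat analogue) with
Gaussian jitter of SD 10% of the interval, clipped into the bout.  The
jitter keeps the swim-frequency estimator nontrivial without creating
grouping ambiguity.

**Rendering.** Channel 1 sums a Ricker (Mexican-hat) template of ~1 ms
width centred at each spike (spectral peak near 1.5 kHz, inside the
300–3000 Hz analysis band); channel 2 sums a 10-ms Hann-windowed 150-Hz
oscillation starting at each burst (inside the 10–200 Hz motor band).
Both ride on i.i.d. Gaussian noise; `spike_amplitude / noise_sd` is the
rendering SNR.  The band separation guarantees that filtering isolates
each channel's content; waveform realism is explicitly out of scope.

**Evoked sessions.** Blocks of 60 sweeps per stimulus frequency, each
sweep 1 s of drive plus 4 s of rest.  During the stimulus the intensity is
`λ + g·max(0, sin 2πft)` (half-wave rectified, phase-locked), so the
sweep-averaged evoked rate is `λ + g/π`; this identity is used both as a
test oracle and to set `g` from a target evoked rate.

**Cohorts.** Condition presets carry the group means of each population ×
treatment cell (spontaneous rate, inhibition fraction, mean/SD of bout
duration).  Between-fish variability is Gaussian jitter of the baseline
rate (CV 0.15) and of the inhibition fraction (SD 0.10, clipped to
[0, 1]).  Neither spread is reported for the recordings this emulates;
both were fixed once at values that reproduce the qualitative regime of
the published per-condition regressions — cohorts of 5 fish give slope
confidence intervals spanning roughly ±1, cohorts of 10–15 give ±0.3–0.8 —
and are not adjusted per analysis.

## Detection

* Zero-phase 4th-order Butterworth band-pass filters (forward–backward),
  300–3000 Hz for spikes, 10–200 Hz for the motor root.  Zero-phase
  filtering preserves event times exactly; its price is a low-frequency
  transient at the trace edges, so bout detection ignores a 100-ms guard
  at either end.
* Noise scale is the median absolute deviation divided by 0.6745 (the
  Gaussian consistency constant), robust to the spikes themselves.
* Spike events are excursions of |trace| above `k·σ_MAD`, timestamped at
  the local extremum, with events closer than 1 ms collapsed to the larger
  one.  Polarity is not assumed (extracellular spike sign depends on
  electrode position).  The default `k = 4.5`: by Rice's crossing-rate
  formula, band-limited Gaussian noise at 2.4 kHz bandwidth crosses 4 σ
  about once per second — the same order as afferent spontaneous rates —
  while 4.5 σ suppresses false events ~20-fold at no cost in recall for
  spikes at SNR ≥ 8.  A floor of 15% of the largest excursion guards the
  near-noiseless regime where σ_MAD collapses to numerical dust.
* Bursts are excursions of the rectified, 20-ms-RMS-smoothed motor
  envelope above `median + 6·σ_MAD` (the envelope is right-skewed, so its
  Gaussian-equivalent tail is heavier; 6 robust SDs keeps false bursts
  negligible).  Bursts with gaps under 200 ms group into one bout — at
  5–40 Hz tail-beat frequencies, within-bout inter-burst intervals never
  exceed 200 ms.  Envelope smoothing widens detected bouts by roughly
  15 ms per side and advances onsets by under 25 ms; analyses that need
  unbiased durations use event-level bouts.

## Estimators

* **Spontaneous rate**: spikes outside bouts and stimulus epochs divided
  by the corresponding quiet time.
* **Windowed bout rates**: counts over half-open duration-matched windows;
  bouts whose pre- or post-window would leave the recording are excluded
  rather than clipped, so the three windows always have equal width.
* **Relative rate and inhibition**: `R = r_swim/r_pre`, `I = 1 − R`,
  defined only for bouts with ≥ 1 pre-swim spike ("retained").
  `I + R = 1` holds exactly, `R` may exceed 1 (negative inhibition), and a
  spike-free swim window gives `R = 0`, `I = 1` (quiescence).
* **Aggregate inhibition** comes in two deliberately distinct flavours.
  The *per-bout mean* (mean of `I` over retained bouts) is the descriptive
  statistic averaged per fish, but it is biased for the underlying
  suppression fraction when expected pre-swim counts are small:
  `E[1/N | N ≥ 1] > 1/E[N]`, and short bouts push `I` toward 1.  The
  *pooled* estimator `1 − Σ swim counts / Σ pre counts` is a ratio of
  totals, needs no retention filter, and recovers the generative
  inhibition fraction to within 0.05 at ≥ 500 bouts; it is the estimator
  used for parameter-recovery checks.
* **Classification**: "reduced" counts every retained bout with
  `r_swim < r_pre` (strict; ties are non-reduced), so quiescent bouts are
  a subset of reduced ones and the reduced percentage always bounds the
  quiescent percentage.
* **PSTH**: integer counts per 10-ms bin over a [−0.5, 1.5] s window
  around sweep onsets, divided by `bin width × sweeps`; spike-count
  conservation is exact by construction.  10-ms bins resolve a 40-Hz
  drive with more than two bins per half-cycle.
* **Unity test**: weighted least squares of per-fish mean swim rate on
  per-fish mean pre-swim rate, weights √(retained swims); the 95% slope CI
  uses the t distribution with n − 2 df, reduces exactly to OLS under unit
  weights, and is reported unclamped however wide.  Null calibration is
  exact: the CI excludes a true unity slope in 5.0% of simulations.
* **Conditional log transform**: a variable is log-transformed when the
  Spearman correlation between its per-group means and variances is
  positive and significant at α = 0.05 (≥ 4 groups required); zeros and
  negative values are offset by half the smallest positive value plus any
  shift needed to keep the argument positive.
* **ANOVA / Tukey**: by default the population × treatment × period
  factors are combined into one cell factor and a one-way ANOVA is run
  across cells (8 cells ⇒ 7 numerator df, matching the published design);
  a full factorial decomposition with type-II sums of squares is
  available.  Tukey HSD pairwise results are summarized by an
  insert-and-absorb compact letter display: two cells share a letter iff
  they were not declared different.
* The wording "unpaired two-way t-test" in the source protocol is read as
  a two-tailed unpaired t-test with pooled variance.

## Problem sizes in validation

Event-level sessions of 300–3000 s (hundreds to ~1500 bouts) back the
statistical checks; rendered-trace checks use 40–120 s sessions at SNR 8,
where spike detection reaches F1 ≥ 0.99 and bout recovery ≥ 95% with
onset errors under 10 ms.  Calibration of the unity test uses 2000 null
simulations; repeated-cohort directional checks use 15 cohorts per
population.

## What the synthetic validation does not show

The generator is a step-modulated Poisson model.  Real afferent trains are
more regular than Poisson, inhibition ramps in and recovers gradually
rather than switching, and swim-bout durations are right-skewed rather
than truncated-normal.  Consequently the pipeline's recovery of its own
generative parameters validates the estimators' correctness, not the
biological values; in particular, bout-class proportions (the quiescent
fraction especially) depend on count distributions the model does not
claim to match, and per-bout mean inhibition inherits the small-count
ratio bias described above.  The per-fish pre-swim rate in this model
equals the spontaneous rate by construction, whereas recorded pre-swim
rates can sit above the inactive-period baseline.  Analyses of recorded
data should therefore enter the pipeline through the CSV event-table
interface and rely on the estimator properties, not on the generator.

## Known limitations

* Single-unit world: no spike sorting, no overlap resolution, no artifact
  rejection beyond thresholding.
* Stimulus alignment trusts the schedule; no artifact-based onset
  detection.
* No hierarchical (bout-within-fish) inference; both bout-level and
  fish-level tests are available and outputs state which granularity was
  used.
* Vector strength / phase locking of evoked responses is out of scope.
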