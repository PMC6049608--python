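# Methods

## The model

Under minimal stimulation — stimulation tuned so weak that transmission
fails on a sizable fraction of trials — the number of transmitter quanta
released per trial is modeled as Poisson with mean quantal content *m*:

    P(k) = m^k e^(−m) / k!,   r_f = P(0) = e^(−m),   m = −ln(r_f)

Silent synapses carry NMDA receptors but no functional AMPA receptors, so
they conduct at a depolarized holding potential (+40 mV, where the NMDA
channel's Mg²⁺ block is relieved) but not at a hyperpolarized one
(−60 mV).  If a fraction *s* of the stimulated synapses is silent and all
synapses share the same release behavior, the effective quantal content is
*m* at +40 mV and *m·(1 − s)* at −60 mV.  Taking logs of the two failure
rates and dividing cancels *m*:

    s = 1 − ln(r_f,−60) / ln(r_f,+40)

This estimator is exact under the model for every *m* > 0 and
0 ≤ *s* < 1 (a property test verifies it to machine precision over a
grid).  Sampling noise can push the estimate below zero when the two
failure rates are close; such values are flagged and reported as-is, never
clipped, so group averages stay unbiased.

Synaptic potency *S* — the mean amplitude of the trials classified as
successes — relates to the mean quantal size *q* through the
zero-truncated Poisson mean.  Two variants of the potency–failure-rate
relation are always fitted and reported:

* **published**: S = −ln(r_f)·q.  This is the published relation; under the
  Poisson model it equals the mean over *all* trials, not over successes.
* **corrected**: S = −ln(r_f)·q / (1 − r_f), the exact conditional mean
  E[k | k ≥ 1]·q.  Parameter-recovery checks use this variant; on
  simulated data it recovers the programmed quantal size to within a few
  percent, while the published variant is biased upward by the factor
  1/(1 − r_f) averaged over the design.

Both models are linear in *q* given r_f, so the fit is through-origin
least squares with x = −ln(r_f) (or −ln(r_f)/(1 − r_f)); standard errors
and confidence intervals follow from the usual linear-model algebra with
n − 1 degrees of freedom.

## Event detection

A sweep's **baseline** is the mean of a pre-stimulus window (default 8 ms,
ending 1 ms before the stimulus).  The baseline window is deliberately
longer than the 3-ms **noise window**: the baseline mean's sampling error
integrates across the 35-ms charge window, and with a 3-ms baseline the
resulting charge error (~0.02 pC at 2 pA noise) would rival the failure
threshold on the simulated quantal scale.  Signal **noise** follows the
published definition: the per-sweep sample SD in the 3-ms window, averaged
over all sweeps at a holding potential.

**Failure classification** implements the two published criteria with
their boundary semantics taken literally:

* +40 mV: failure ⇔ charge in the 5–40 ms post-stimulus window does
  *not exceed* the threshold (equality is a failure).  Charge is the
  baseline-subtracted trapezoidal integral over the closed interval
  [5, 40] ms, returned as a magnitude in pC (1 pA·ms = 1 fC).
* −60 mV: failure ⇔ peak magnitude *smaller than* twice the signal noise
  (equality is a success).  A 10⁻⁹ pA floor on the threshold keeps the
  classification meaningful on noise-free synthetic data.

**Peak measurement** subtracts the average-failure trace (which removes
the stimulus artifact), subtracts the baseline, applies a short boxcar
(default 0.6 ms), and takes the windowed extremum (default window 1–10 ms
post-stimulus at −60 mV).  The smoothing exists because the extremum of
band-limited noise over a multi-millisecond window is systematically
larger than the per-sample SD — at 5 kHz the expected extremum of the
default window is above 2 SD, so comparing raw-sample extrema against a
2×SD criterion would classify most true failures as successes.  A 3-sample
boxcar reduces the effective noise at the extremum by ~√3 while
attenuating the fast EPSC peak by < 1%.  Set `peak_smoothing_ms = 0` for
raw extrema.

The average-failure template is itself defined by the failures, so
classification iterates to a fixed point: classify on raw (unsmoothed)
peaks — raw because without the template the artifact is still in the
trace — build the template from the failures, re-measure, re-classify, at
most `max_template_iterations` (default 5) rounds.  On simulated data it
converges in two.  With `max_template_iterations = 0` the raw single-pass
classification is used.

**QC.** An experiment is excluded when the failure indicator or the
success amplitudes trend linearly with acquisition order (run-up /
run-down) at either potential, or when the noise SD exceeds a ceiling
(default 3 pA on the simulated scale; the published rule names no number).
Trend detection is an OLS slope t-test; the four component tests share the
experiment-level α by Bonferroni (each runs at α/4), so stationary
experiments are falsely excluded at ~α (measured 3.3% at α = 0.05 over
300 simulated seeds) while strong drift (release changing by ±75% over the
recording) is excluded essentially always.  Fewer than 10 sweeps at a
potential makes the verdict "indeterminate", never a silent pass.  The
acquisition-time rule that +40 mV failures should fall in ~10–40% of
events is surfaced as an advisory warning, not an exclusion.

**Thresholds on simulated data.**  `DetectionParams` defaults to the
published 0.9 pC charge threshold.  That number presumes compound events
much larger than a single ~4 pA quantum (whose 5–40 ms charge is
~0.14 pC), so analyses of simulator output use
`DetectionParams.for_simulation(config)`, which sets the threshold to a
quarter of the analytic single-quantum window charge: the integrated
charge noise (~0.005 pC SD) leaves that cut > 6 SDs above zero, while
quanta drawn small by amplitude variability (cv_q = 0.3) still clear it —
a half-quantum cut would miscount ~5% of single quanta as failures and
bias the silent fraction by ~−0.04.

## The synthetic-data generator

The generator inverts the analysis model.  Per sweep the quantum count is
Poisson(*m·(1 − s)*) at −60 mV and Poisson(*m*) at +40 mV; each quantum
contributes a peak-normalized biexponential EPSC — fast kinetics at −60 mV
(τ_rise 1 ms, τ_decay 8 ms, inward/negative), slow at +40 mV (τ_rise 5 ms,
τ_decay 60 ms, outward/positive, so the 25-ms read captures ~89% of the
peak) — scaled by q·(1 + cv·ε) with ε standard normal truncated below
−1/cv so amplitudes never change sign.  A biphasic 1-ms artifact at the
stimulus exercises the artifact-removal path, and white Gaussian noise is
added per sample.  All draws come from one `numpy` generator seeded from
the config: identical config ⇒ bit-identical sweeps.

Defaults mirror the recordings the analysis was designed for: 5 kHz
sampling, quantal sizes 4.4 pA (slow component) and 9.7 pA magnitude
(fast component), 2 pA noise, 0.2 Hz stimulation timestamps, and
m = 1.5, which puts the +40 mV failure fraction (e^−1.5 ≈ 22%) inside the
10–40% acquisition target.  The amplitude CV (0.3) and the kinetics are
generator choices — the source recordings report neither — picked as
typical values for hippocampal minimal-stimulation EPSCs.  `drift_slope`
imposes a linear trend on the per-sweep release mean (fractional change
from first to last sweep) solely to exercise the QC exclusion.

Because q at +40 mV parameterizes the waveform *peak* while the potency
measurement reads the averaged amplitude 25 ms post-stimulus, the ground
truth also carries the single-quantum 25-ms read
(q_nmda · w(25 ms) ≈ 3.93 pA at defaults); quantal-size recovery at
+40 mV is judged against that read value.

What the generator does **not** emulate: finite release-site (binomial)
statistics, short-term plasticity across the 0.2 Hz train, voltage-
dependent Mg²⁺ unblock kinetics, correlated (1/f or line) noise, series-
resistance errors, or electrode drift in anything but the release mean.
Passing tests therefore certify the estimators and the pipeline under the
Poisson model's own assumptions — including the assumption that silent and
functional synapses share release probability, which is exactly what makes
the estimator exact — not the model's adequacy for any particular
recording.

The fEPSP course generator emits one single-trace field sweep per time
point: a negative-going biexponential (τ 2/12 ms) delayed 3 ms after the
stimulus (a synaptic delay, which also keeps the onset clear of the
fiber-volley exclusion), with amplitude set so the 20–80% rising slope
equals the requested value, stepped by the potentiation factor at the
induction time, with optional multiplicative noise.

## Plasticity conventions

The fEPSP rising slope is the least-squares line through the samples whose
baseline-subtracted amplitude lies between 20% and 80% of the fEPSP peak
on the rising phase.  The peak is the deepest negative deflection in a
1.5–20 ms post-stimulus search window whose onset latency (10%-amplitude
crossing) exceeds 2 ms — the fiber-volley exclusion; both windows are
configurable since the source conventions are unstated.  LTP time courses
are normalized to the pre-induction baseline mean (≥ 5 baseline sweeps
required; baseline = 100% by construction) and quantified as the mean
normalized response minus 100% in a named window: 2–3 h post-induction for
the long-lasting form ("3h-LTP"), 1–2 h for the short-lasting form
("2h-LTP").  Input–output slopes are through-origin least squares of fEPSP
slope vs fiber-volley amplitude (the function passes through (0, 0)
physically; an intercept variant is available), normalized per recording
condition to the wild-type population mean, which is 1.00 exactly by
construction.

## Group reporting

Parametric summaries are mean ± SE (t-based CI); nonparametric summaries
are median [25th 75th percentile] plus min/max, with percentiles by linear
interpolation between order statistics (numpy's default), fixed and
documented.  Group-level silent fractions are computed both from the
group-mean failure rates and as the mean of per-experiment estimates; both
appear in reports because the two aggregations differ under nonlinearity
(at the published knockout group means they give 50.9%; the wild-type
means back-compute to 10.4% vs the printed ~11%, a rounding-of-inputs
discrepancy).  Binomial confidence intervals for failure rates are exact
Clopper–Pearson at 95%.  Inferential hypothesis tests are out of scope and
delegated to standard tools.

## Problem sizes and numerical checks

The test suite runs the full pipeline at n = 300 sweeps per potential,
where the silent-fraction estimate's binomial sampling floor is a median
absolute error of ~0.07 at s = 0; recovery is evaluated over 100 seeds per
silent-fraction level and quantal-size recovery over 30 experiments with
quantal content spread over m ∈ [1.0, 2.3].  QC calibration uses 300
stationary and 100 drifting simulations of 100 sweeps per potential.
Closed-form agreement of the generator is checked at n = 10⁴ sweeps within
3 binomial SEs, and the Poisson pmf against a 60-digit decimal-arithmetic
oracle to 10⁻¹² for k ≤ 30.  The whole suite completes in well under a
minute.

## Known limitations

* The failure-rate estimators inherit the classification thresholds'
  biases; the published 2×noise peak criterion in particular misses quanta
  attenuated by amplitude variability (~2.5% of single quanta at
  cv = 0.3), slightly inflating r_f at −60 mV.
* The published-variant potency fit is reported for fidelity but is not a
  consistent estimator of q when potency is computed over successes; use
  the corrected variant for inference.
* The silent-fraction estimator assumes equal release probability at
  silent and functional synapses and a single pooled Poisson count; finite
  site counts or heterogeneous release probabilities violate it in ways
  the generator cannot detect.
* File formats are the package's own documented layouts (see
  `file_formats.md`); vendor acquisition formats must be converted
  upstream.
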