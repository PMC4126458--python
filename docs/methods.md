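# Methods

## Model

The synthetic cerebellum is a trial-based, discrete-time model of delay
eye-blink conditioning operating on binary detection trains.  Its
assumptions: the CS reaches the circuit only through the PN pathway and the
US/error signal only through the IO pathway; learning is carried by a single
synaptic-efficacy scalar `w`; the CR is produced by dis-inhibition modeled
as a threshold crossing of a decaying, `w`-scaled CS trace; and a delayed
inhibitory feedback from the output stage onto the IO (nucleo-olivary
inhibition, NOI) gates the error signal once a response has been issued.

Per 2-ms step, in order: (a) a PN detection restarts the CS trace and arms
one eligibility window (rectangular, duration `lambda_tau_elig` = 0.3 s,
delayed `lambda_noi` = 0.1 s); (b) if a trace is active, has not fired, and
`w*trace(t) < theta_cr` (strict, per the falls-below convention), a CR is
triggered — one per trace, a new detection re-arms — and an NOI window of
the same duration, delayed by `lambda_noi`, is scheduled from the trigger;
(c) IO detections inside any NOI (or artifact-mask) window are discarded;
(d) potentiation `+delta_p` per eligible step and depression `-delta_d` per
surviving coincident IO detection are summed, then `w` is clipped to
[0, 1].  Eligibility windows union (the indicator is binary); NOI windows
union.  All latencies are rounded to the grid with round-half-up.

The trace decays **linearly** from `tau0` = 1 to `tau1` = 0.5 over
`lambda_tau` = 350 ms.  The shape is pluggable (an exponential variant with
matched endpoints exists), but only the linear form reproduces the three
anchor values simultaneously: no CR above `theta_cr/tau1` = 0.4, a 140-ms
trigger delay at `w` = 0.25, and an anticipation boundary of 0.28 for a
300-ms ISI with a 96.2-ms CS detection latency.  The trace duration (350
ms) and the eligibility duration (300 ms) are kept as two separate
parameters rather than assumed identical.

Latency identities: the minimum learnable ISI is `omega_cs + omega_cr`
(detection latency plus effector latency); the NOI delay must exceed
`omega_cr + omega_us` for CRs to anticipate the US, plus 75 ms (half the
150-ms stimulation train) to center the response on the US; the internal
timing to acquire is `t_cr = ISI - (omega_cs + omega_cr)`.

## Calibration

Plasticity events are counted from training data: `P = sum(Pi)` eligible
steps and `D = Pi^T I` coincidences, with `D` scaled by `sigma_bar` (the
mean unsuppressed fraction) in conditions where CRs gate the IO.  Three
condition summaries (acquisition, extinction, stability) feed a weighted
least-squares solve with targets `(-Delta_a/T_a, +Delta_e/T_e, 0)` and
weights `(1, 1, stability_weight)`.  Defaults: `Delta = 0.2`, `T = 40`
trials, `stability_weight = 100` — large enough that the stability ratio
`delta_d/delta_p = P3/D3` holds to well under 1% while the first two rows
still set the scale.  The CS-alone summaries are synthesized from the
paired-trial PN data plus the spontaneous-period IO data; the spontaneous
depression count is the rate estimate times the mean eligible time per
trial (`D3 = far_hat * kappa`, `kappa = P_bar * dt`), which is exactly the
dependence the adaptive update later refreshes, making the initial
calibration a fixed point of the recalibration.  The solver uses the 2x2
weighted normal equations; rank deficiency raises; a negative component is
clamped to zero with a flag rather than re-solved under constraints, so the
closed form below stays exact in the regular case.

`sigma_bar` defaults to 0 (full suppression — the regime of a deployed
system that blanks the IO channel after each stimulation).  For runs where
gating is the model's own trigger-anchored NOI, an empirical estimator is
provided: the fraction of the eligibility window the NOI never covers at
the trigger delay of the target acquired weight,
`(t_trig + noi_delay - elig_delay)/lambda_tau_elig` clipped to [0, 1].

Operating points are selected by iterating calibration over a grid of
threshold configurations and keeping the one with minimum weighted
residual; ties break toward the lower spontaneous IO rate.

## Adaptive recalibration

Every 150 s (about 10 trials) the spontaneous IO rate is re-estimated as
the raw detection count over the elapsed window — the system cannot tell
evoked from spontaneous events, so paired stimulation biases the estimate
upward, a bias that shrinks with the 10–15-s inter-trial intervals.  Only
the stability row is updated.  Writing the weighted normal equations with
`D3 = kappa*f`, Cramer's rule gives each step as a ratio of polynomials in
`f` with coefficients fixed by the training data: `delta_p` is degree 2
over degree 2, `delta_d` degree 1 over the same denominator.  (The degree
is derived symbolically from the weighting scheme rather than assumed; a
sympy-based test solves the normal equations independently and confirms
both the values and the degree-2 denominator.)  Step changes take effect at
the first trial starting after each boundary, never mid-trial.  An
exponentially-weighted smoothing of successive rate estimates is available
behind `ewma_alpha` but off by default.

## Synthetic data

Generators reproduce a channel's detection statistics rather than its
biophysics: background false alarms are per-step Bernoulli at `FAR*dt`
(optionally with a time-varying rate profile — constant, sinusoid, or
clipped random walk within a band), and stimulus-locked true detections
fill an a-priori window (10–150 ms post-trigger for PN, 5–205 ms for IO)
under one of two latency models.  The `per_step` model converts TDR through
`1 - (1-TDR)^(1/n)` and may emit several events per stimulus; the `draw`
model emits at most one (probability TDR, latency uniform in the window).
`per_step` is the package default for `simulate_channel`; the experiment
presets use `draw`, because recorded trains come from a threshold detector
with a refractory period that yields about one event per stimulus burst —
with `per_step` at IO TDR 0.75 the evoked coincidence count (~1.4 per
stimulus) overweights the acquisition row until the three calibration
constraints cannot be jointly approached and extinction stalls outright.
The unpaired control is the within-trial shuffle (per-trial counts
preserved, positions redrawn uniformly); post-CR artifact masking removes
IO events for a fixed span after each trigger, with an optional
resample-from-donor-rate replacement mode.

What the generators do not emulate: latency histograms beyond a uniform
(or narrow-uniform) support, refractory structure and burstiness of real
detection trains, correlations between channels, and any
stimulation-artifact waveform.  Passing tests therefore demonstrate the
model and calibration logic under matched detection statistics, not
robustness to every property of real recordings.

## MUA detection front-end

The detector is deliberately low-complexity and fully causal: subtract a
running mean (exponential moving average by default, trailing simple
moving average behind a flag), rectify (squared variant behind a flag),
smooth with a trailing short-term average (10 ms default), and emit an
event at each upward threshold crossing with a 10-ms refractory period —
without it a sustained burst fires every sample.  Causality bounds the
detection latency by the smoothing window.  TDR/FAR scoring excludes the
stimulus-locked windows from the false-alarm denominator.  ROC curves are
monotone in the threshold only above the rectified noise floor: below it
the variability signal never dips under the threshold and a crossing
detector goes silent, a property of crossing detectors the tests respect by
sweeping thresholds above the floor.

## Study conditions and problem sizes

The reference statistics are: simulation operating point PN (TDR 0.95,
FAR 0) and IO (0.75, 1.0 Hz); bio-hybrid operating point PN (0.914,
0.11 Hz — essentially all of it late CS-locked detections, so training sets
and the drift study use a silent PN baseline) and IO (0.486, 1.14 Hz);
protocol ISI 300 ms, ITI uniform 10–15 s (10 s fixed in training sets);
training sets of 30 paired trials plus 120 s of spontaneous activity.  The
prediction study runs 200 replicate 120-trial sessions; the drift study 100
replicate 360-trial unpaired sessions with the baseline sweeping the
0.5–2 Hz band as one slow sinusoid over the session (the recorded
non-stationarity rose through acquisition and fell through extinction,
i.e. about one swing), random phase per replicate; calibration statistics
average 50 seeds.  These sizes keep the full acceptance run under a minute
while leaving Monte-Carlo standard errors well inside the tolerances the
tests assert.

## Numerical and design notes

* The session engine iterates only the spans where a trace, eligibility
  window or trigger can exist plus IO event steps; IO detections outside
  eligibility cannot change `w`, so the skipping is exact.  A numba-compiled
  kernel is used when available; the pure-python kernel is the reference and
  both are checked against an independent dense per-step oracle.
* Net-then-clip: potentiation and depression within a step are summed
  before clipping, making the update order-independent.
* Trial windows are half-open and open 1 s before each CS; events in
  inter-trial intervals belong to the enclosing trial.  CS-alone trials
  classify CR timing against the virtual US implied by the training ISI.
* Weight bounds default to [0, 1]; the no-stability runaway case is the
  reason they are configurable.
* Threshold ties: triggering requires strictly `< theta_cr`, so the
  boundary weight 0.4 produces no CR.
* Acquisition onset has no canonical criterion; the session analysis
  reports four candidates (first CR, first well-timed CR, weight crossing
  the 0.4 CR level, weight crossing the 0.28 anticipation level).  The
  headline onset statistic is the first well-timed CR: the calibration's
  own design ties `T_a` to reaching the well-timed weight level, and the
  0.4 crossing occurs at `~T_a/2` trials by construction for any consistent
  calibration, so it cannot measure "acquisition in `T_a` trials".

## Known limitations

* **Extinction is asymptotic under trigger-anchored gating.**  IO
  coincidences that arrive before the CR trigger can never be suppressed by
  a causal NOI, so the CS-alone extinction rate is proportional to the
  NOI-covered fraction of the eligibility window and vanishes as CRs become
  late; complete behavioral extinction then relies on noise carrying the
  weight across the CR-production level.  This mirrors the in-vivo pattern
  (rapid extinction of well-timed CRs, late CRs lingering for ~100 trials)
  but means idealized tens-of-trials full extinction is not reachable at
  the reference statistics.
* **Unpaired-drift excursions are shot-noise limited.**  With the
  calibrated per-coincidence depression step (~0.015) and ~0.3
  coincidences per trial, a 360-trial unpaired session accumulates a
  zero-mean random walk with terminal sd ~0.16 even under perfect rate
  tracking; the adaptive recalibration removes the systematic drift (its
  95th-percentile maximum excursion is about two-thirds of the static
  model's on identical inputs) but cannot beat that floor.
* The rational-form coefficients freeze the training set's PN statistics;
  PN-rate non-stationarity is out of scope, as are real-time operation,
  spike sorting, band-pass filter design and stimulation-artifact
  cancellation.
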