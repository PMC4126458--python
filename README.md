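# eyeblink

A trial-based synthetic cerebellum for delay eye-blink conditioning, built
for neuroprosthetics research: the package implements the microcircuit
model that maps detected pontine-nucleus (PN, conditioned-stimulus pathway)
events to conditioned-response (CR) triggers and adapts a single memory
weight from detected inferior-olive (IO, unconditioned-stimulus pathway)
events, together with everything needed to run it against noisy,
non-stationary biosignals: a constraint-based calibration of the plasticity
step sizes, a periodic adaptive recalibration with an exact rational-form
update, stimulus-locked synthetic event generators, and a low-complexity
event-detection front-end for multi-unit-activity (MUA) signals.  It is
aimed at computational neuroscientists and neuroprosthetics engineers who
need a tested, reproducible reference implementation of this class of
closed-loop conditioning models.

## The model

Time advances on a 2-ms grid.  Each PN detection starts a decaying CS trace
with initial value τ₀, final value τ₁ and duration Λ_τ (linear by default);
a CR is triggered at the first time *t* where the scaled trace crosses the
decision threshold,

    w · trace(t) < θ_CR ,

so smaller weights give earlier responses: CRs exist only for
w < θ_CR/τ₁ = 0.4 (defaults τ₀ = 1, τ₁ = 0.5, Λ_τ = 350 ms,
θ_CR = 0.2), and anticipatory ones require w ≲ 0.28.  Each PN detection
also arms a rectangular *eligibility window* Π (duration 0.3 s, delayed
0.1 s), and each CR trigger arms a delayed *nucleo-olivary inhibition*
(NOI) window that discards IO detections — the negative feedback that
stabilizes learning and sets CR anticipation.  Plasticity is linear and
event-driven:

    P = ΣΠ           (potentiation events: eligible time steps, +δ_p each)
    D = Πᵀ(σ̄ I)      (depression events: unsuppressed IO coincidences, −δ_d each)

Calibration solves for (δ_p, δ_d) by weighted least squares over three
conditions — acquisition (paired CS–US), extinction (CS-alone with CRs) and
stability (spontaneous activity, drift-free by construction, weighted
dominant):

    [ P̄₁  −D̄₁ ] [ δ_p ]   [ −Δ_a/T_a ]
    [ P̄₂  −D̄₂ ] [ δ_d ] = [ +Δ_e/T_e ]
    [ P̄₃  −D̄₃ ]           [     0    ]

Because only D̄₃ depends on the spontaneous IO rate, the solution is a
ratio of degree-≤2 polynomials in that rate; the adaptive mode re-estimates
the rate every 150 s and evaluates this closed form, keeping learning
associative under the 0.5–2 Hz baseline drift seen in vivo.

## A worked example

`examples/acquisition_session.py` calibrates on a synthetic 30-trial
training set (PN: 91.4% detected stimuli over a silent baseline; IO: 48.6%
detected stimuli over a 1.14-Hz spontaneous background) and runs 120 paired
trials (ISI 300 ms, ITI 10–15 s):

```
calibrated steps: delta_p = 4.00e-05, delta_d = 1.98e-02

 block  n_trials  pct_cr  pct_well_timed  mean_w
     0        10    0.00            0.00    0.48
     1        10   10.00            0.00    0.44
     2        10   70.00           10.00    0.33
     3        10  100.00            0.00    0.30
     4        10  100.00           60.00    0.28
     ...
    10        10  100.00           40.00    0.32
    11        10  100.00           40.00    0.31

first CR at trial            : 20
first well-timed CR at trial : 29
final weight                 : 0.340
```

The weight falls from 0.5 by the calibrated ~0.005/trial; CRs appear when
it crosses 0.40 (initially late), and well-timed CRs (triggered ≥ 20 ms
before the air-puff trigger) stabilize around 40% as the weight settles
near the 0.28 anticipation level, where NOI gating balances depression
against potentiation.  The other examples cover the latency algebra,
calibration, adaptive recalibration under baseline drift, and the MUA
detection front-end with its ROC analysis; `eyeblink --help` exposes the
same capabilities as a thin command line.

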