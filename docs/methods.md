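# Methods

## Model

The reservoir is one Mackey-Glass node with delayed self-feedback, driven
through the delay line:

    ẋ(t) = −x(t) + η·X(t) / (1 + X(t)^ρ),    X(t) = x(t−τ) + J(t)

`J(t) = γ·M_seg(t mod τ)·[u(t̄); φ(t̄)]` is the masked forcing: inputs and
feedback channels are held constant over one reservoir step t̄ (one delay
cycle) and modulated by a random ±μ mask that is piecewise constant over
the segments of n virtual nodes. Node i is sampled at the end of its
segment once per cycle; those n samples per step are the regression
predictors.

With the default η = 0.5, ρ = 1 the unforced system has equilibria at 0
(stable) and η − 1 = −0.5 (unstable). Operation in the stable
fixed-point regime gives fading memory: any two state histories driven by
the same input converge at rate ≈ η per delay cycle. For non-integer ρ
the power is evaluated as the signed power sign(X)·|X|^ρ, preserving the
odd symmetry of the ρ = 1 nonlinearity; the second equilibrium is then
−(1−η)^(1/ρ).

### Parameters (defaults)

| parameter | default | meaning |
|---|---|---|
| γ | 0.01 | input scaling (dimensionless) |
| η | 0.5 | delayed-nonlinearity scaling; contraction rate per cycle |
| ρ | 1 | chaoticity exponent; 1 ⇒ single stable fixed point |
| μ | 0.1 | mask bit amplitude |
| n | 300 | virtual nodes |
| τ | 600 | delay, in simulation time units |
| grid | 600 | simulation points per delay ⇒ h = τ/grid = 1 |
| denom_guard | 1e−6 | smallest allowed magnitude of 1 + X^ρ (hard error) |

The simulation time unit is fixed by choosing h = 1 so the grid is
integer-indexed; the paper-level quantities (τ = 600 units, 600 points,
node relaxation time 1 unit) are unchanged by this convention.

## Numerics

**Method of steps.** Over one delay interval the delayed term x(t−τ) is
the stored previous cycle, so each cycle is a scalar ODE. The state
buffer holds the grid+1 samples of the last cycle (both endpoints); the
delayed value at grid index g is the previous cycle's sample at g.

**Heun integration.** Explicit trapezoidal rule. The predictor uses the
delayed value at the step's left grid point, the corrector the delayed
value at the right grid point; the forcing value of the interval is used
for both stages (it is genuinely constant within a mask segment).
Freezing the delayed value at the left index for both stages would make
the scheme first order — the delayed trajectory varies O(h) across a
step — so the right-endpoint corrector is required for the scheme's
second order.

**Convergence measurement.** `heun_convergence_order` integrates 10
forced cycles at step sizes h, h/2 and h/64 (reference) and reports
log2(err(h)/err(h/2)). The measurement defaults to base step h = 0.25:
at h = 1 a single step cannot resolve the unit-time relaxation transient
launched at every mask-segment boundary and the pre-asymptotic slope
overshoots (≈ 2.5 for any forcing); from h ≤ 0.25 the quadratic term
dominates and the measured slope is ≈ 2.1.

**Initial history.** Constant 0 over [−τ, 0] — the stable unforced fixed
point. Any choice washes out by fading memory, and each phase is
preceded by a discarded 50-step offset.

**Singularity guard.** The denominator 1 + X^ρ stays near 1 for all
intended operating points; if its magnitude falls below 1e−6 the
integrator raises a hard error naming the time rather than clipping,
since a trip indicates misconfiguration (e.g. forcing driving X to −1).

## Readouts and teacher forcing

All regressions include a trailing constant bias column (the readout
formula itself has no intercept; the bias may fit to 0 but is needed for
constant targets). Feedforward coefficients α are fit on the training
phase by least squares against the clean targets. Feedback coefficients
β are fit on the teacher-forcing phase: the feedback input at step t̄
carries z̃(t̄−1) = z(t̄−1) + ε(t̄−1) and the regression target is the
noisy z̃(t̄) — the objective is Σ(z̃ − ẑ)², exactly the stated teacher
signal, not the clean series.

**Teacher noise.** ε is zero-mean Gaussian with standard deviation 1% of
the feedback target's peak-to-peak range (configurable; a uniform
variant is available). The noise is the stabilising ingredient: it
enters the reservoir through the clamped feedback channel, so the
regression cannot rely on loop-sensitive directions it cannot control,
and the fitted loop contracts toward the target levels.

**Numerical rank.** Virtual-node activities are strongly collinear
(condition numbers ~1e13 at n = 300). `fit_least_squares` therefore
truncates the design's numerical rank at relative singular value 1e−8
(LAPACK gelsd `cond`), returning the minimum-norm solution over the
numerically meaningful directions. Directions below that cutoff carry no
information at float64 precision but would amplify target noise by
> 1e8 and destabilise the closed loop. Small well-conditioned systems
are unaffected (agreement with a brute-force normal-equations solve to
1e−8 relative error). An explicit ridge penalty (bias unpenalised) is
available but defaults to 0; heavy ridge shrinks the loop gain below 1
and causes level drift, so rank truncation is preferred.

**Closed loop.** In training and validation, φ̂(t̄) = β·x(t̄−1) + b. The
first step of each phase anchors the feedback channel to the phase's
first target value (some anchor is required; the per-phase offsets
absorb the transient). The stability test's free-running phase
deliberately does *not* re-anchor — it continues the loop from the cued
test phase, since re-anchoring would feed the answer in.

## Synthetic tasks

* **Cues**: rectangular pulses of amplitude 1 lasting 5 steps; gaps
  between onsets uniform on [50, 400] steps during teacher forcing
  (more cues for the regression) and [100, 800] afterwards; in
  two-channel tasks the cue identity alternates strictly. Before the
  first cue every task behaves as if a u− cue occurred at step 0 (ramps:
  as if the ramp had completed), so targets are total functions. Branch
  switches take effect at the onset step.
* **Noise streams**: i.i.d. uniform on [−5, 15] per step, smoothed with
  a normalised Gaussian kernel of σ = 5 reservoir steps (truncated at
  4σ, reflected boundaries). The σ is interpreted in reservoir steps:
  one step is one τ-cycle, the only reading that yields finite smoothing
  of a per-step sequence.
* **Sine drive**: amplitude·sin(2πt̄/period) + mean with defaults (1,
  100 steps, 1/3), then the same σ = 5 smoothing. A literal amplitude
  of 100 with period 2π steps would be annihilated by the smoothing, so
  the drive keeps the structure (sine + offset + Gaussian filter) with a
  usable period; all three constants are configurable.
* **Two-level feedback code**: 18 after a u+ cue, 10 after u−
  (configurable). The levels set the operating point of the
  nonlinearity: the loop-gain difference between levels scales with
  γμ·level, and at (9, 5) it is ~1% — too weak to carve two attractors
  at the reduced teacher-forcing scale, where runs intermittently drift
  to mid-levels. At (18, 10) the two-level memory is robust across
  seeds with the 1% teacher noise. The elapsed-time ramps keep their
  printed 9 → 5 amplitudes.
* **Experiment targets**: d = sine/constant switching (exp1);
  d1 = u1 | 2u2, d2 = u1+u2 | |u1−u2|, d3 = 0.1u1³ + 0.2u1u2 (exp2);
  fast/slow ramps of 300/600 steps with d3 = |u| − 2.5·fast (exp3); the
  supplementary product task d = ramp·|u|. All are verified in the test
  suite against independent per-step scan implementations.

## Phase schedule and metrics

Published durations: teacher forcing 50 000, training and validation
10 000 each (20 000 for the elapsed-time experiment), each phase preceded
by a 50-step offset that is excluded from every design matrix and every
metric. The desk-scale schedule used by the tests and the acceptance
script is 5 000 / 2 000 / 2 000 with the same offsets — small enough for
seconds-scale runs, large enough for ~20 teacher-forcing cues.
Performance is the Pearson correlation between desired and observed
series per phase; a constant series in a (short) window yields NaN in
the result table rather than a silent 0, while the public `pearson`
raises.

The no-feedback baseline runs the identical task, input mask bits, node
layout and schedule with the feedback columns removed (teacher-forcing
steps are still consumed, keeping the training/validation windows
aligned), making feedback-vs-baseline comparisons seed-for-seed paired.

## Stability test

Switching-task inputs with the sine replaced by bounded filtered noise;
one feedback readout trained at the reduced scale; 1 000 cued
closed-loop steps; then no more cues. The loop must hold the last cue's
level; the run stops when |φ̂ − level| exceeds the margin (default: half
the gap between the two levels — breach means closer to the wrong
attractor than the right one) or when the step budget (default 50 000)
is exhausted. The report records survived steps, the termination cause
and a down-sampled feedback trace; drift toward the opposite level — a
known failure mode of under-trained loops — shows up as a margin breach
rather than being suppressed.

## What the synthetic data does and does not show

The generators emulate the study conditions exactly (pulse cues with
irregular gaps, smoothed bounded noise, two-level and ramp feedback
codes); they contain no measurement noise, no drift in the reservoir
constants and no hardware imperfections, so passing tests demonstrate
the computational mechanism — not robustness of a physical
(optoelectronic or electronic) realisation, which is out of scope here.
Tasks demanding fading *and* persistent memory simultaneously are not
part of the suite.

## Known limitations and edge cases

* The echo-state bound "below 1e−6 within 20 cycles" is knife-edge by
  construction: the contraction rate is η = 0.5 per cycle and
  0.5²⁰ ≈ 9.5e−7, so random full-range history pairs measure 19–21
  cycles, and histories concentrated at the unstable equilibrium −0.5
  (the lower edge of the admissible range) converge arbitrarily slowly.
  The diagnostic reports the measured cycle count.
* Closed-loop quality at the reduced schedule depends on the ~20 cues
  seen during teacher forcing; occasional seeds show visibly lower
  (though still large) correlations on the nonlinear cued task.
* Integer grid indexing assumes τ/grid divides the mask segments
  exactly; non-integer layouts are rejected rather than interpolated.
* ρ > 1 regimes are supported by the integrator (signed power) but
  untested against chaotic dynamics, which the package does not target.
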