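# delayrc

Single-node **delay-coupled reservoir computing** (DCR) with **trained
linear feedback**: a simulator and experiment suite for studying how
teacher-forced feedback readouts turn a fading-memory reservoir into one
that stores cues stably for arbitrarily long times.

The package is for computational-neuroscience and reservoir-computing
researchers who want a fully reproducible, pure-software testbed for
delay-based reservoirs: the forced Mackey-Glass delay differential
equation, time-multiplexed input masking, least-squares readouts, teacher
forcing, closed-loop feedback, and the four canonical experiments
(cue-switched computation, concurrent nonlinear tasks, elapsed-time
coding, and longitudinal memory stability).

## The model

A single nonlinear node is coupled to itself through a delay line of
length τ:

    ẋ(t) = −x(t) + η·X(t) / (1 + X(t)^ρ),    X(t) = x(t−τ) + γ·M·[u(t̄); φ(t̄)]

* `u(t̄) ∈ R^m` — inputs, held constant over each reservoir step t̄ (one
  delay cycle); `φ(t̄) ∈ R^q` — feedback channels.
* `M` — a random binary mask with entries ±μ, piecewise constant over the
  segments θᵢ of n *virtual nodes* placed randomly on the delay line
  (Σθᵢ = τ). Time-multiplexing replaces the spatial input expansion of a
  classical recurrent-network reservoir.
* Readouts are linear in the per-step virtual-node activities xᵢ(t̄):
  feedforward outputs ŷ(t̄) = Σᵢ αᵢxᵢ(t̄), feedback
  φ̂(t̄) = Σᵢ βᵢxᵢ(t̄−1). Only α and β are trained, by least squares.
* **Teacher forcing**: β is fit while the feedback input is clamped to a
  noise-corrupted copy z̃ = z + ε of its target, minimising
  Σ(z̃(t̄) − ẑ(t̄))². The injected noise is what makes the closed loop
  robust: it forces the regression to find a contracting map around the
  target levels, which become attractors of the free-running loop.

Defaults are γ = 0.01, η = 0.5, ρ = 1 (single stable fixed point at the
origin ⇒ echo-state property), μ = 0.1, n = 300 virtual nodes, τ = 600
with 600 simulation points per delay (Heun integration via the method of
steps). Phases follow the offset / teacher-forcing / training /
validation schedule with 50-step wash-out offsets that never enter a
regression or metric.

## Worked example

```python
from delayrc import FeedbackReservoir, PhaseSchedule, run_stability_test

# cue-switched task: output follows a smoothed sine after a u+ cue,
# the constant 5 after a u- cue; one trained feedback loop stores the cue
result = FeedbackReservoir.from_experiment(
    "exp1", PhaseSchedule.reduced(), seed=1
).fit()
print(result.summary())
```

```
Delay-coupled reservoir with trained feedback
============================================================
virtual nodes n=300  tau=600  grid=600  mu=0.1
Mackey-Glass gamma=0.01  eta=0.5  rho=1
schedule offset=50  teacher_forcing=5000  training=2000  validation=2000

Pearson r (desired vs observed output)
        training  validation
target
d         1.0000      0.9999

Pearson r (feedback target vs free-running feedback)
         training  validation
channel
tf         0.9977      0.9949
```

The validation correlation of 0.9999 means the trained-feedback reservoir
tracks the correct branch across cue gaps of 100–800 steps — far beyond
the ~10-step fading memory of the same reservoir without feedback, whose
validation r on the identical task and seeds is ≈ 0.31
(`feedback=False`). The free-running feedback itself reproduces its
two-level target with r ≈ 0.995.

The stored memory is effectively permanent:

```python
report = run_stability_test(seed=1, max_steps=50_000)
print(report.summary())
# stability test: survived 50000 steps (budget 50000),
# terminated by step-budget; holding level 10 within margin 4
```

The same objects drive the other experiments (`"exp2"`: three concurrent
linear/nonlinear readouts, `"exp3"`: two ramping feedback loops encoding
time since the last cue), and `result.plot_traces()` shows desired vs
observed outputs per phase.

## Command line

```bash
delayrc exp1 --schedule reduced --seed-base 42 --outdir runs/exp1
delayrc baseline --experiment exp1 --schedule reduced --outdir runs/base
delayrc stability --schedule reduced --max-steps 50000 --outdir runs/stab
```

Every run writes the resolved `config.yaml`, per-step `trace.csv`,
readout weight tables and a `metrics.json`; a single `--seed-base`
integer reproduces a run bit for bit.

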