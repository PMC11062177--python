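# Methods

## Continuous allocation model (`intergen.analytic`)

Two sequential players each hold a time budget `T`.  Efficiency of
exploitation is a learning curve `f(t)` of cumulative exploration time `t`,
assumed non-negative, strictly increasing and log-concave on `[0, 2T]`.
Log-concavity is what makes the marginal benefit `f'/f` monotonically
decreasing, so the marginal balance `f'(t)/f(t) = 1/(H − t)` has at most one
crossing and the optimum is unique.  The repaid condition (the predecessor
receives the successor's pay-off as a bonus) is solved by reduction: since
both parts of the pay-off carry equal weight and there is no conflict over
the successor's switching time, the problem equals the unrepaid problem with
budget `2T`.  A rational allocation never fragments exploration, hence
either the predecessor stops inside its own budget (`t_s* = 0`) or it
explores throughout and the successor continues (`t_p* = T`, `t_s* > 0`,
possible only for convex `f`).

Numerical choices:

* The crossing is solved as `(H − t) f'(t) − f(t) = 0` rather than
  `f'/f = 1/(H − t)`, which avoids dividing by `f(0) = 0` for power curves.
* The boundary case `t* = 0` is detected by the sign of that expression on a
  dense grid (4097 points) rather than by a closed-form test at `t = 0`: for
  curves with `f(0) = 0` the marginal benefit diverges at the origin and a
  test evaluated only at 0 misclassifies them.
* Root refinement uses a bracketed Brent solve to `1e-12·H`; bracketing is
  safe because log-concavity permits at most one sign change.
* Missing derivatives fall back to central differences with step
  `1e-6·(1+|t|)`.
* Curve validation checks `f ≥ 0`, `f' > 0` and second differences of
  `log f ≤ 1e-8` on a 1001-point grid over `[0, 2T]`; points with
  `f < 1e-30` are skipped so isolated zeros are tolerated.  Validation
  raises by default (`strict=False` returns the violation list instead).
* `grid_oracle` is a deliberately brute-force maximiser (two-dimensional in
  the repaid condition, chunked to bound memory) kept independent of the
  root-finding path; it exists to cross-check the solver.

## Task environment (`intergen.landscape`)

Designs are integer triples in `[1, 100]³`.  Expected score ("efficiency")
is a unimodal quadratic `peak − Σ w_i (x_i − opt_i)²`, floored at 0 and with
`peak ≤ 1000` so every score lies in `[0, 1000]`.  A hunt displays
`round(efficiency + N(0, 5²))` clamped to `[0, 1000]`; noise is independent
across trials.  The expected score stays real-valued for analysis; only the
displayed score is an integer.  Clamping is applied after rounding (a
convention; it matters only within half a calorie of the range ends).

The coefficients of the original behavioural task are not public, so the
packaged default is a *calibration*: `scripts/calibrate_landscape.py`
searches per-attribute weights and initial distances until the agent
ensemble reproduces the reference optima (12 unrepaid / 22 repaid).  Two
regularities emerged in that search: moderate-distance valleys pin the gap
between the two optima at about 9 exploration trials, while a wide, shallow
valley (weights 0.05, initial distances 63–66 units, near the maximum the
attribute bounds allow) slows the decay of the marginal gain enough to
separate the optima by the required 10.  The frozen default — optimum
(92, 9, 88), weights (0.05, 0.05, 0.05), peak 1000, noise sd 5, common
initial design (28, 72, 22) — yields exactly (12, 22) for every master seed
tried at the 10,000-agent ensemble size.  The default initial design is
fixed and common to all first-generation agents, as in the behavioural
task; its value is part of the calibration, recorded in
`src/intergen/config/default_landscape.yaml` and not claimed to be the
original task's value.

## Agent (`intergen.agent`)

Win-stay/lose-shift with four memory slots (last hunt score + one direction
sign per attribute).  Decisions the rule leaves open, resolved as follows:

* Initial direction signs are independent uniform ±1 per agent (seeded);
  any fixed choice would bias the walk toward or away from the optimum.
* The first hunt initialises the score memory and never flips a direction.
* Ties are wins: a direction flips only when the new score is strictly
  lower.
* Moves clipped at the attribute walls still register as the latest
  modification; there is no automatic bounce — a subsequent losing hunt
  flips the direction.
* Consecutive hunts with no exploration in between keep comparing and may
  flip the same attribute repeatedly (the simplest consistent reading).
* Comparisons always use the noisy displayed scores; the latent efficiency
  is never visible to the agent.

The allocation family is the alternating one: trial 1 always exploits
(a design can only be assessed by hunting), explorations occupy even trials
`2..2τ`, `0 ≤ 2τ ≤ T−1`.  The unrestricted strategy space (2^49 sequences
for T=50) is deliberately not searched.

## Ensembles and optima (`intergen.simulate`)

`estimate_learning_curve` runs every agent at the maximal alternating
schedule and records the latent efficiency of the design after each
exploration, so a single pass estimates the whole curve
`g(τ), τ = 0..⌊(T−1)/2⌋`; `g(0)` is the initial design's efficiency,
exactly.  We read "after τ explorations" literally: the efficiency is
recorded at the moment the design changes, before the confirming hunt.
The master seed spawns one child stream per agent, so enlarging an ensemble
extends it without reshuffling existing agents.  The default ensemble size
is 10,000 agents (the reference size; about two seconds on one CPU).

Expected pay-offs come from the alternating-phase sum plus the exclusive
exploitation term, with horizon `T` (unrepaid/asocial) or `2T` (repaid);
the repaid optimum therefore needs no second-generation simulation
(`run_chain` exists for trajectory-level studies, transmitting the final
design bit-exactly and resetting agent memory).  Argmax ties break toward
smaller τ — less exploration at equal pay-off.

## Statistics pipeline (`intergen.expstats`)

Welch's unequal-variance t statistic, Welch–Satterthwaite df and two-sided
p come from `scipy.stats.ttest_ind(equal_var=False)`; Cohen's d uses the
classical pooled-SD form (the convention when none is stated); the
Bonferroni-adjusted alpha is `0.05 / n_comparisons` (0.025 for the two
planned condition contrasts).  The payment rule (`2W/50` rounded up to the
nearest 10 JPY, plus the 700 JPY show-up fee) is computed in exact integer
arithmetic.

### Synthetic participants

The generator emulates first-generation cohorts of the three conditions.
Parametric mode draws each participant's exploration count τ from
Normal(mean, sd), rounds, and clips to `[0, T−1]`.  The default
per-condition parameters are the observed first-generation summary
statistics of the behavioural data the generator emulates — asocial
20.10 (sd 3.51), unrepaid 19.45 (6.42), repaid 24.60 (5.56), n = 20 each.
Note the repaid mean exceeds the alternating-family cap of 24: human
participants were not confined to strict alternation.  The generator
therefore synthesises trajectories from a generalised schedule — the
alternating backbone on even trials, with additional explorations filling
odd trials from trial 3 — so any τ ≤ 49 round-trips through
`exploration_count`.  Clipping at 24 instead would truncate the repaid
distribution severely enough to destroy the group separation the cohorts
are meant to carry.

Agentic mode instead derives behaviour from the landscape: it estimates a
learning curve, computes the per-trial pay-off curve of the participant's
condition, and draws τ from a softmax over that curve with inverse
temperature `beta` (default 0.25 per calorie) — a quantal-response model
giving quasi-rational agents with non-degenerate within-condition variance.

What the synthetic cohorts do *not* emulate: within-participant strategy
changes (real participants sometimes explored in bursts late in the
session), any correlation between a participant's τ and their learning
success, and second-generation behaviour.  Pipeline tests on these cohorts
show that the statistics are computed correctly and that the configured
group separation is detectable at n = 20 — not that the behavioural effect
itself is reproduced from raw data.

### Overshoot

A participant overshoots an attribute if its trajectory visits values on
both sides of the attribute's optimal coordinate.  Reported as a
per-condition fraction; exploratory output only.

## Problem sizes used in the test suite

Full-scale checks use the reference ensemble (10,000 agents, seeds 1 and 2)
for the simulation optima and 100 seeded replicates for the
significance-pattern property; unit and property tests use ensembles of
30–4,000 agents and short horizons, which keeps the whole suite under about
15 seconds without changing any scientific parameter of the task
(T=50, L=5, noise sd 5, n=20 cohorts).

## Known limitations

* The default landscape is a calibration target, not the original task's
  surface; conclusions about *which* τ is optimal transfer only through the
  (12, 22) anchor, though the orderings (repaid ≥ unrepaid) hold on every
  non-degenerate landscape tested.
* The continuous solver requires log-concave curves; multimodal landscapes
  (where `f' > 0` fails) are out of scope.
* The repaid margin between τ = 22 and its neighbours is shallow
  (≈0.3 calories per trial), so single-seed estimates at much smaller
  ensembles can land at 21 or 23; the ±2 tolerance reflects this.
* `run_chain` models two generations only; longer chains and free-rider
  designs are not implemented.
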