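# Methods

`cogtrace` implements an instance-based learning (IBL) account of repeated
two-alternative decisions in a time-pressured rescue task, a model-tracing
procedure that personalizes that account to an observed decision trace, and
a prospective-memory analytic that converts the timing of task events into
a cognitive-load measure and a per-chunk probability of forgetting.  This
note records the model equations, the parameters that matter, what the
synthetic task emulates (and does not), and the design choices made where
the design was genuinely open.

## 1. Declarative memory model

Every experience is stored as an *instance*: context attributes (the counts
of critical and non-critical victims in the room), the action taken
(`CRITICAL_FIRST` or `IN_ORDER`), and the observed outcome (points
collected, seconds taken).  An instance presented or rehearsed at times
`t_j` has, at time `now`, activation

    A_i = ln( Σ_j (now − t_j)^(−d) )  +  MP · Σ_k Sim(v_k, c_k)  +  ε_i

with decay `d = 0.5`, mismatch penalty `MP = 1.0`, and transient noise
`ε_i ~ logistic(0, s)` with scale `s = 0.1` (`s = 0` makes retrieval
deterministic; a seeded generator makes the stochastic path reproducible).
Numeric similarities are linear, `Sim(a, b) = −min(|a − b| / range, 1)`,
where `range` defaults to the largest victim count in play; symbolic
similarities are 0 on identity and −10 otherwise, which makes the action
attribute an effectively hard filter while retaining a single retrieval
mechanism.  Within one decision a single noise draw per instance is shared
across the two action probes, so both expectations see the same momentary
memory state.

Retrieval probabilities are Boltzmann in activation at temperature
`t = 1.0`, computed with max-activation subtraction (algebraically exact,
overflow-safe).  The blended value of an outcome slot is the minimizer of
the retrieval-probability-weighted squared similarity loss; for numeric
outcomes under linear similarity this is the probability-weighted average,
and the closed form is used.  A generic bounded scalar minimization of the
same loss (`blend_minimize`) is retained and must agree with the closed
form to 1e−6; the test suite additionally checks both against a
brute-force grid search.  Each outcome slot (points, duration) is blended
independently.

Repeated identical experiences deliberately create separate instances.
Reinforcement (appending presentations) is used only by the victim-memory
chunks of the load analytic, not by decision instances.

## 2. Decision model and bootstrap

For each room-entry decision the model blends expected points and expected
duration per action, forms the rate `points/time`, and picks the higher
rate; exact ties break toward `CRITICAL_FIRST`, mirroring the documented
human prior for high-value critical victims (with noise on, ties have
measure zero).  After acting, exactly one new instance holding the
*observed* outcome is stored: expectations are never stored and no
counterfactual instance is created for the action not taken.

Memory is seeded with one prior instance per action in a neutral context
(one victim of each type, task time 0).  In `biased` mode the
critical-first prior has exactly twice the rate of the in-order prior; in
`unbiased` mode the two priors are identical.  Only the 2:1 ratio is
theoretically constrained; the magnitudes are configuration.  The defaults
are `base_points = 10`, `base_time = 60` (prior rates 1/6 and 1/3 points
per second), chosen to sit *below* the 0.3–0.7 rate range that actual task
outcomes produce.  This matters: a prior whose rate exceeds every
achievable outcome rate could never be overturned by experience, because
the unchosen action's expectation stays frozen at its prior (the model
does not reason counterfactually), and tracing could then never learn any
player's preference.  A weak prior with the prescribed ratio preserves the
initial critical-first bias and remains learnable.

## 3. Model tracing and baselines

Tracing a player replays their decision events in order.  For each event
the model first registers its own prediction from its current store (the
prediction can never see the observed action), then is forced to store the
observed action and outcome.  The store persists across runs and maps with
a globally monotonic task clock.  Contexts with no non-critical victims
are *ambiguous* — both strategies prescribe identical behaviour — and are
scored correct for either prediction, per the task's scoring convention;
they are traced into memory (they are real experiences) but can be
excluded from summaries with a flag.

Baselines: the recency heuristic predicts the previous observed choice,
the frequency heuristic the modal one; empty histories and ties fall back
to `CRITICAL_FIRST` so that all three predictors share one prior.
Accuracy summaries pool records across players by within-player experience
index (default bin width 5) and by decision difficulty, defined as the
absolute rate gap between the two actions' expectations (default bins:
quintiles of the observed gaps).

## 4. Cognitive load and forgetting

Pending victims — encountered but not yet evacuated — must be held in
memory.  Each such chunk is created at ENCOUNTER, rehearsed by each
processing step (TRIAGE, MOVE, MARK), and retired at EVACUATE.  With
activation `A` (base-level term only: there is no probe, and noise is
absorbed into the scale), the probability of forgetting is
`p = 1/(1 + e^(−(τ−A)/t))` and the chunk's load is the odds
`e^((τ−A)/t) = p/(1−p)`: exactly 1 at threshold, exponentially smaller for
stronger memories.  Total load sums over active chunks; a run's load
series is sampled on a 1 s grid plus every event time, with maximum and
time-weighted (trapezoidal) mean summaries.  Per-victim forgetting
profiles time-average `p` over each victim's active interval.

Defaults `τ = 0.0`, `t_scale = 0.25` are conventional activation-scale
magnitudes.  At 15-minute lags they put most pending chunks well below
threshold, i.e. the measure operates in a saturated regime where loads are
large and forgetting probabilities near 1.  Every property built on the
measure here is ordinal or correlational (monotonicity under rehearsal,
additivity, load–error association), and those are invariant to τ and
`t_scale`; absolute load values should not be interpreted without
calibrating both parameters to retention data.  Activation lags are
clamped at 0.05 s so that sampling exactly at a rehearsal instant stays
finite; the strict decision-memory activation keeps its non-causal error
instead.

`inject_forgetting` turns the same formula into a generative error
mechanism: at each deferred victim's scheduled return time, the remaining
processing is dropped with probability `p` computed from the chunk's
rehearsal history, and score and error counts are recomputed from the
modified event log.  This makes the load→error dependence recoverable by
the correlation analysis, which is exactly what the recovery test checks
(Pearson r between time-weighted mean load and error count across 50
seeded runs).

## 5. Synthetic task

The simulator emulates the study task's statistical structure: 15-minute
runs (deadline for critical victims at half time), 8–16 rooms per map with
Poisson victim counts (difficulty presets `easy`/`medium`/`hard` increase
rooms, density, and traversal time), critical victims worth 30 points and
taking 60 s, non-critical worth 10 points and taking 15 s.  These
magnitudes are configuration; they were chosen to make the strategic
trade-off real — critical victims are worth more, take longer, and expire
earlier — and are not calibrated to any dataset.  A critical victim scores
only if evacuated by the deadline.

A run has three phases: a pre-deadline sweep in which each victim-bearing
room entered triggers one strategy decision (critical-first processes
criticals immediately and defers non-criticals, with a MARK or MOVE
rehearsal per deferred victim at the player's diligence rate; in-order
processes everything as encountered; with no criticals present the
strategies coincide); a return phase revisiting deferred victims in
encounter order; and a final sweep of remaining rooms.  The outcome
charged to a decision is the points and duration of its immediate
processing window.  Victims left unevacuated at the end of the run are the
run's errors.

Three player families stand in for individual differences: `FIXED` players
always take one strategy; `CONTEXT_RULE` players apply a threshold rule on
the critical/non-critical ratio; `SOFTMAX_IBL` players run their own IBL
memory and choose by a Boltzmann rule over the two expected rates (choice
temperature 0.1).  The softmax family embodies the behavioural assumption
the traced model makes of humans — choices driven by experienced outcome
rates — and is therefore the cohort on which model-tracing recovery is
meaningful.  A threshold player whose rule contradicts experienced rates
is not identifiable by any rate-based observer, because the player never
explores against its own rule and the model stores no counterfactuals;
such cohorts bound what tracing can do rather than demonstrate it.  A
single softmax learner may also amplify its earliest experiences into a
fixed preference, which is expected behaviour for this model class, not a
defect.

What the simulator does not emulate: teammates and communication, map
geometry and navigation, perceptual or motor error, and any natural
variation in processing skill beyond a uniform ±10% duration jitter.
Passing tests therefore show that the analysis pipeline recovers structure
that the generator truly contains, under the model's own behavioural
assumptions — not that human data would show the same effect sizes.

## 6. Statistical design choices in the checks

* Cohort accuracy curves pool players by experience index.  When every
  player sees the *same* map realization, context sequences are perfectly
  correlated across players and rule-based players switch strategies in
  lockstep, so per-bin accuracies swing wildly; cohorts used for curve
  properties therefore give each player independent map draws from the
  same difficulty distribution.
* The recency heuristic's flatness is a property of a one-back predictor
  under a stationary choice process.  It is evaluated on stationary
  (threshold-rule) cohorts, on one-back predictions only (the history-free
  first prediction is the shared prior, not recency), with bins of 10
  decisions across 100 players so that per-bin sampling error (~0.015
  s.e.) cannot masquerade as a trend.
* The fixed-policy recovery check pools decisions 26–40 of 20 players
  (10 per strategy) over 12 maps; by then the chosen strategy's blended
  rate (~0.4–0.6) clears the frozen opposing prior (1/6 or 1/3) by several
  times the noise-induced jitter, so late accuracy is stably perfect.
* The blending oracle uses a three-stage zoomed grid (resolution far below
  the 1e−4 tolerance); the forgetting-odds identity evaluates retention as
  `p_forget(2τ − A)` — algebraically identical to `1 − p` — to avoid
  floating-point cancellation where `p` is within 1e−16 of 1.

## 7. Known limitations

* The load analytic's absolute scale is uncalibrated (see §4); only
  ordinal and correlational uses are supported by the tests.
* Outcome attribution truncates at the immediate processing window;
  strategies' delayed consequences (deferred victims recovered later)
  influence score but not the decision instances.
* Blending of the duration slot assumes linear similarity over seconds;
  no log or ratio scaling is applied.
* The CLI's `load` command computes scores with the default point values
  unless overridden; event logs do not carry point values themselves.
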