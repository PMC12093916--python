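# cogtrace

Instance-based learning (IBL) cognitive models of human decision making,
personalized to individuals by model tracing, plus a prospective-memory
cognitive-load analytic — exercised end to end on a synthetic
search-and-rescue task.

## The problem

In a time-pressured rescue task a player repeatedly faces a strategic
choice on entering a room with victims: triage everyone *in the order
encountered*, or *prioritize critical victims*, which are worth more
points and take longer to process but expire at a mid-run deadline.  An
assistive agent that wants to anticipate a particular player needs (1) a
generative model of how experience drives such decisions, (2) a way to
align that model with one individual's observed history, and (3) a
measure of how heavily the player's prospective memory is loaded by
victims they have deferred — because forgetting deferred victims is a
dominant error mode.

`cogtrace` provides all three for researchers in cognitive modeling and
human–machine teaming:

* **`cogtrace.memory`** — an ACT-R style declarative memory: instances
  with activation `A_i = ln Σ_j (now−t_j)^−d + MP·Σ_k Sim(v_k,c_k) + ε_i`
  (power-law base level, partial matching, logistic noise), Boltzmann
  retrieval probabilities `P_i = e^{A_i/t} / Σ_j e^{A_j/t}`, and blended
  (consensus) values `V = argmin_V Σ_i P_i · Sim(V, v_i)²`, which for
  numeric outcomes reduces to the retrieval-probability-weighted average.
* **`cogtrace.decision`** — the two-strategy triage model: blended
  expected points and duration per strategy, choice by highest
  points/time rate, observed outcomes stored back as new instances.
* **`cogtrace.tracing`** — model tracing: predict each observed decision
  from the current store, then force the observed action and outcome into
  memory, so predictions always rest on the player's own history; recency
  and frequency heuristics as baselines; accuracy by experience,
  decision difficulty, and map.
* **`cogtrace.load`** — cognitive load as the summed odds of forgetting
  over pending-victim chunks, `load = Σ_i e^{(τ−A_i)/t}` with
  `P(forget) = 1/(1+e^{−(τ−A_i)/t})`: each chunk contributes 1 exactly at
  the retrieval threshold; load series, per-victim forgetting profiles,
  error counts, and load–error/score correlations.
* **`cogtrace.synthetic`** — a seeded task simulator (maps, victim
  distributions, deadlines, player policies) standing in for human data,
  including a mode in which the forgetting model itself generates errors.
* **`cogtrace.evaluate` / `cogtrace` CLI** — reproducible end-to-end
  experiments and CSV reports.

## Worked example

```python
from cogtrace import ExperimentConfig, run_experiment

config = ExperimentConfig(seed=7, n_players=12, map_cycles=2)
bundle = run_experiment(config)

print(bundle.accuracy_by_experience.to_string(index=False))
print(bundle.correlations.round(3).to_string(index=False))
```

prints

```
 experience_bin  first_decision  n  accuracy
              0               0 60  0.833333
              1               5 60  0.950000
              2              10 60  0.916667
              3              15 60  0.950000
              4              20 60  0.850000
              5              25 49  0.836735
              6              30 15  0.933333

load_measure target      r  p_value
    max_load errors  0.809      0.0
    max_load  score -0.450      0.0
   mean_load errors  0.787      0.0
   mean_load  score -0.442      0.0
```

The first table is the traced model's prediction accuracy on a 12-player
mixed cohort (fixed-preference, threshold-rule, and softmax-IBL players),
pooled in bins of five decisions: about 83% on the first five decisions —
before any personalization, ambiguous rooms and the shared critical-first
prior already carry the model — rising into the 0.9s as each player's
store fills with their own experiences.  The second table shows that runs
with higher maximum and time-weighted mean cognitive load have more
forgotten-victim errors (r ≈ 0.8, here with errors generated by the
forgetting model itself) and lower scores (r ≈ −0.45).

The same pipeline is scriptable from the shell:

```sh
cogtrace simulate --players 12 --seed 7 --out-dir out/sim
cogtrace trace --input out/sim/traces/player-000.jsonl --bootstrap biased \
    --noise 0.1 --seed 7 --out out/pred.csv
cogtrace load --events out/sim/events/player-000-run0.jsonl --duration 900 \
    --tau 0.0 --tscale 0.25 --out out/load.csv
cogtrace report --seed 7 --out-dir out/report
```

## Repository layout

```
src/cogtrace/      memory.py, decision.py, tracing.py, load.py,
                   synthetic.py, evaluate.py, cli.py
tests/             unit + property tests, test_acceptance.py
scripts/           acceptance.py
docs/methods.md    model equations, parameter choices, limitations
```
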