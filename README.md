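# oilab

**Outcome-irrelevant value learning under working-memory load: simulation
and hierarchical Bayesian analysis.**

When people learn the value of actions by trial and error, credit should
go only to features that actually predict the outcome. In a two-offer
card bandit where only the *cards* pay off, people nevertheless assign
value to the *response key* used to select a card: after a rewarded first
offer they are more likely to press the same key again at the second
offer. `oilab` implements the full computational apparatus for measuring
this effect and asking whether visual working-memory capacity moderates
it:

* **Task simulator** — a restless four-card bandit (reflected
  Gaussian-random-walk reward probabilities) interleaved with change
  detection under no/low/high load, plus a standalone set-size-4/8
  change-detection capacity task.
* **Synthetic cohorts** — agents with a delta-rule learner over cards
  *and* one over response keys (`Q(card) + V(key)` softmax), a slot-model
  memory responder with capacity `kappa`, optionally a negative
  capacity→key-learning link, and RT contamination to exercise the
  filters. Ground-truth parameters are retained for recovery tests.
* **Preprocessing** — the trial filters (first-of-block; RT outside
  (200, 4000) ms), participant exclusions (below-chance memory accuracy,
  > 30% lost trials, > 80% same-key), stay/previous-outcome coding, and
  Cowan's `K = N(2·accuracy − 1)` capacity estimators (standalone and
  embedded).
* **Inference** — four nested Bernoulli-logit mixed models
  (null / capacity / load / full, shared random-effects structure) fitted
  by an exact Pólya-Gamma Gibbs sampler; posterior reporting with median,
  95% HDI, probability of direction, ROPE (±0.013 log-odds, from a
  negligible d = 0.007), Savage–Dickey and ROPE Bayes factors, odds
  ratios; PSIS-LOO stacking model comparison; marginal stay
  probabilities; Bayesian correlation between capacity and per-subject
  learning coefficients.

The core quantity is the coefficient of previous outcome on
`Stay_key ∈ {0,1}` in

```
stay_it ~ Bernoulli(logit⁻¹(X_it β + Z_it u_s)),   u_s ~ N(0, Σ),
```

with previous outcome coded ±1/2, load sum-coded, capacity z-scored; a
positive β_prev is outcome-irrelevant learning, and a negative
β_prev×capacity is the capacity moderation.

## Worked example

```python
from oilab import CohortSpec, InferenceConfig, RunConfig, TaskConfig, run_pipeline

config = RunConfig(
    task=TaskConfig(),                      # 6 blocks x 50 trials, loads none/low/high
    cohort=CohortSpec(),                    # 40 subjects, capacity-linked key learning
    inference=InferenceConfig(chains=2, draws=500, warmup=500, seed=0),
    models=("M3_capacity", "M4_null"),
    output_dir="example_run",
    seed=0,
)
result = run_pipeline(config)
for coef, s in result.summaries["M3_capacity"].items():
    print(coef, "->", s.report_line())
print("M3 stacking weight:", round(result.stacking.weights["M3_capacity"], 2))
```

prints:

```
intercept -> median 0.30, HDI95% [0.23, 0.35], pd 100%, 0% in ROPE, BF10 10000.00+, BF-ROPE 10000.00, OR 1.35
prev_outcome -> median 0.73, HDI95% [0.63, 0.82], pd 100%, 0% in ROPE, BF10 10000.00+, BF-ROPE 10000.00, OR 2.08
capacity -> median -0.10, HDI95% [-0.15, -0.04], pd 100%, 0% in ROPE, BF10 5.04, BF-ROPE 5.23, OR 0.91
prev_outcome:capacity -> median -0.18, HDI95% [-0.29, -0.08], pd 100%, 0% in ROPE, BF10 10.25, BF-ROPE 10.47, OR 0.83
M3 stacking weight: 0.92
```

Read: the cohort shows strong group-level outcome-irrelevant learning
(`prev_outcome` median 0.73 — rewarded first offers make key repetition
much more likely; the generator's effect is deliberately larger than
human-scale effects so 40-subject experiments are decisive), and the
negative `prev_outcome:capacity` interaction recovers the generative
capacity link: higher-capacity agents assign less value to the keys.
Individual cohorts vary: re-running with other seeds gives interaction
medians around −0.05 to −0.2 and capacity-model stacking weights from
~0.6 upward.
The run directory additionally contains the trial/probe logs, the stay
table, `exclusions.json` (~5.5% of trials removed by the RT/first-trial
filters under the default contamination), `stacking.json`, and a
`report.md` with one reporting line per coefficient.

A command-line layer wraps the same functions:

```bash
oilab init-config cfg.yaml
oilab run --config cfg.yaml --seed 11 --out example_run
oilab recover --config cfg.yaml --replicates 10   # parameter-recovery grid
oilab ingest --path deposited_data/ --mapping mapping.yaml
```

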