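# lbarace

Linear-ballistic-accumulator (LBA) modelling of explicit risky choice.

The package implements a complete, reproducible analysis of a four-gamble
pairwise-choice task:

- **`lbarace.task`** — task structure (four gambles over {0, 20, 40} points
  with EV 24/20 and variance 384/96; 4 blocks × 24 trials; each of the 6
  stimulus pairs encountered 16 times) and synthetic-subject generation with
  ground-truth accumulator parameters, a concave utility curve,
  counterfactual (regret) sensitivity, and an independent trait-anxiety
  score.
- **`lbarace.lba`** — closed-form defective first-passage CDF/PDF of a
  single accumulator, the two-accumulator race likelihood (normalized for
  non-terminating accumulators), the summed negative log likelihood, and a
  vectorized race simulator.
- **`lbarace.fitting`** — per-subject maximum-likelihood fits of two
  7-parameter variants: a *drift model* (one drift per stimulus; shared
  threshold, start range, non-decision time) and a *boundary model* (one
  threshold per stimulus; shared drift).  Nelder–Mead simplex in a
  constraint-respecting transformed space, best of N jittered restarts.
- **`lbarace.prediction`** — per-pair choice probabilities by quadrature of
  the race density, predicted-vs-actual Pearson correlations across
  subjects, and stratified half-split held-out validation.
- **`lbarace.assessment`** — quantile-probability tables (data vs
  simulated model), chi-square choice goodness of fit, per-stimulus
  two-sample Kolmogorov–Smirnov RT tests, and the 2×2 risk-by-EV
  repeated-measures ANOVA on normalized drift rates.
- **`lbarace.behavior`** — relative subjective utility of 20 points (the
  utility-concavity index), risk seeking, counterfactual sensitivity, and
  their Pearson associations.
- **`lbarace.pipeline` / `lbarace.cli`** — seeded end-to-end orchestration
  and the `lbarace` command-line interface.

## Command line

```sh
# synthetic cohort (writes trials.csv + subjects.csv)
lbarace simulate --seed 1 --out results/ --n-subjects 44

# per-subject ML fits of either model variant
lbarace fit --seed 1 --trials results/trials.csv --variant drift --out results/fits.csv

# predicted-vs-actual and held-out per-pair correlations
lbarace predict --seed 1 --trials results/trials.csv --out results/
lbarace holdout --seed 1 --trials results/trials.csv --out results/

# goodness of fit + drift-rate ANOVA; behavioral summaries
lbarace assess --seed 1 --trials results/trials.csv --out results/
lbarace behavior --trials results/trials.csv --subjects results/subjects.csv --out results/

# everything, from a YAML config or defaults
lbarace run-all --seed 1 --out results/ --n-subjects 44
```

All interchange files are plain CSV (RTs in seconds; use `--units ms` for
millisecond inputs).  Every stochastic command takes `--seed`, and outputs
are byte-identical across runs with the same seed.

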