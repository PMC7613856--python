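# ridgescreen

Two-stage detection of biomarker–treatment interactions in randomized
clinical trials, with a multivariate ridge-regression screening stage that
accounts for biomarker–biomarker correlation.

## What it does

Testing every biomarker–treatment interaction one at a time with a
Bonferroni correction loses power when the number of biomarkers `m` is
large. `ridgescreen` implements two-stage alternatives that first *screen*
biomarkers using a statistic that is (asymptotically) independent of the
final interaction test, then spend the overall significance budget `alpha`
where the screen points:

| Procedure | Stage 1 | Stage 2 |
|---|---|---|
| `no_screening` | — | Wald interaction tests at `alpha/m` (single-step Bonferroni baseline) |
| `univariate_threshold` | marginal regression of outcome on each biomarker; keep p < `alpha1` | Bonferroni at `alpha/m*` over the `m*` selected biomarkers |
| `univariate_rank` | same screen, but keep the full p-value ranking | weighted bucket thresholds: top `B` tested at `(alpha/2)/B`, next `2B` at `(alpha/4)/(2B)`, next `2^k B` at `(alpha/2^(k+1))/(2^k B)`, … |
| `ridge_rank` | one multivariate ridge regression of outcome on treatment + all biomarkers (shared L2 penalty chosen by five-fold CV), ranking by absolute coefficient | same weighted bucket thresholds on the ridge ranking |

The stage-2 test is always the one-biomarker-at-a-time linear interaction
model `E[Y|Xj,T] = b0 + bX*Xj + bT*T + bXT*Xj*T` with a two-sided t-test of
`bXT = 0` (n−4 df, homoscedastic errors).

A full simulation harness (block-correlated Gaussian biomarkers,
Bernoulli(0.5) treatment, linear outcome) estimates cluster-discovery power
and familywise error rate for all four procedures over replicate trials
with common random numbers, and a between-stage diagnostic checks the
empirical correlation of stage-1 and stage-2 statistics.

## Library quick start

```python
from ridgescreen import (SimulationConfig, default_effects, default_structure,
                         generate_trial, run_procedure)

cfg = SimulationConfig(n=1500, effects=default_effects(),
                       structure=default_structure(m=1000, rho=0.6), seed=1)
data = generate_trial(cfg)
decisions = run_procedure(data, "ridge_rank", alpha=0.05, B=5,
                          ridge_options={"cv_seed": 1})
print(decisions.rejected)          # 1-based indices of rejected biomarkers
print(decisions.table.head())      # p-value / threshold / decision per biomarker
```

## Command-line interface

```sh
# simulate a trial from the built-in correlated scenario
ridgescreen simulate --preset panelA --n 1500 --m 1000 --seed 7 --out sim/

# run one procedure on a delimited trial table (CSV or TSV; columns
# "outcome", "treatment" plus one column per biomarker)
ridgescreen run --input sim/dataset.csv --procedure ridge_rank \
    --alpha 0.05 --seed 7 --out results/

# Monte-Carlo power/FWER for the scenarios in a YAML plan
ridgescreen evaluate --scenario plan.yaml --out eval/

# between-stage independence diagnostic on one dataset
ridgescreen diagnose --input sim/dataset.csv --seed 7
```

`run` applies the preprocessing pipeline first: biomarker columns with more
than 10% missing values are dropped, remaining missing values are
mean-imputed, and `--top-k` optionally restricts to the k most variable
biomarkers. Every command writes a `resolved_config.json` and a `run.log`
next to its outputs; all randomness is controlled by `--seed`.

A minimal evaluation plan:

```yaml
replicates: 200
seed: 1
procedures: [no_screening, univariate_threshold, univariate_rank, ridge_rank]
scenarios:
  - name: correlated
    n: [500, 1000, 1500]
    m: 1000
    cluster_size: 20
    rho: 0.6
    effects:
      treatment: 0.5
      main: {1: 0.5, 21: 1.5, 41: 1.5, 61: 1.5, 81: 1.5}
      interaction: {1: 1.0}
      noise_sd: 5
```

## Notes on conventions

- Ridge objective: `||y_c - D d||² + lambda ||d||²` on the centered
  outcome, centered treatment and standardized biomarkers; the treatment
  coefficient is penalized but excluded from the ranking; the intercept is
  absorbed by centering and never penalized.
- Rejection uses strict inequality (`p < threshold`); the truncated final
  weighted bucket keeps its per-test threshold (unused alpha is not
  redistributed).
- The familywise error event is, by default, a rejection in any cluster
  containing no truly interacting biomarker ("cluster discovery" logic);
  `error_level="biomarker"` switches to the stricter per-biomarker event.
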