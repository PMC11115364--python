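# riskshift

Dynamic risk-preference analysis for accept/reject gambling tasks under
changing environmental richness.

## The scientific problem

In a classical economic view, a person's risk preference is a stable trait: a
gamble paying *m* points with probability *p* should be accepted or rejected
the same way regardless of what other gambles surround it. Risk-sensitive
foraging theory predicts otherwise: an agent maximizing long-term fitness
rather than per-trial utility should become more risk-prone when the
environment is poor (mean reward rate below its needs) and more risk-averse
when it is rich — and the reward already accumulated, i.e. the environments
experienced in the past, should matter too.

`riskshift` implements the full computational pipeline for testing these
predictions in a two-experiment task where participants repeatedly accept or
reject a gamble (win *m* ∈ {15, 20, …, 65} with probability *p*, or take a
sure 10 points) while the reward-probability distribution changes between
blocks: poor (*p* ∈ {0.2…0.6}, mean 0.4), intermediate ({0.4, 0.5, 0.6},
mean 0.5), and rich ({0.4…0.8}, mean 0.6). Group schedules are Poor–Rich and
Rich–Poor (Experiment 1) and Intermediate–Poor–Intermediate /
Intermediate–Rich–Intermediate (Experiment 2). Because the study's raw data
are not redistributable, a synthetic-cohort generator with known ground truth
stands in for them, so every analysis stage is runnable and testable
end to end.

## What is inside

* **Task design** (`riskshift.task`) — environments, blocks (66 trials for
  poor/rich incl. 8 reject-catch + 3 accept-catch trials; 39 for
  intermediate incl. 3 + 3), per-participant randomized order, and the
  analyzed-trial mask (*p* ∈ {0.4, 0.5, 0.6}, *m* > 10, non-catch).
* **Decision models** (`riskshift.models`) — risk-return utility
  U = *mp* − α·*m*²*p*(1−*p*); prospect-theory multiplicative
  U = *m*^λ·π(*p*) and additive U = (1−w_p)·ṽ(*m*) + w_p·π(*p*) with Prelec
  weighting π(*p*) = exp(−(−log *p*)^γ); sigmoid and approach-avoidance
  choice rules.
* **Fitness simulation** (`riskshift.fitness`) — survival probability and
  mean accumulated reward as functions of α under different survival needs.
* **Synthetic cohort** (`riskshift.cohort`) — choices generated from a
  trial-varying α driven by current-environment statistics, past-environment
  statistics, and accumulated reward, plus catch-trial attention modelling,
  non-responses, and inattentive participants.
* **Descriptives** (`riskshift.descriptive`) — a-priori exclusion criteria,
  pooled and per-participant acceptance proportions q, 5-trial moving
  averages, binomial acceptance-curve fits.
* **Bootstrap inference** (`riskshift.bootstrap`) — participant-level
  resampling, percentile CIs, the one-tailed difference test and two-tailed
  one-sample tests with Bonferroni correction.
* **Hierarchical EM** (`riskshift.hier_em`) — empirical-Bayes fitting of the
  18 candidate decision models with group-level priors and iBIC comparison.
* **State-space model** (`riskshift.statespace`) — a bootstrap particle
  filter with Cauchy transitions, fixed-lag smoothing (L = 20), (σ, β) grid
  search, and a step-change recovery experiment.
* **Regression & simulation** (`riskshift.regression`) — the eight
  trial-level regressors (EV, Risk, Δp_c, Δp_p, previous choice/reward/
  success, accumulated reward), pooled logistic fits (ML and L1), BIC, VIF,
  bootstrap coefficient tests, forward choice simulation, and ablations.
* **IO / CLI** (`riskshift.io`, `riskshift.cli`) — the long-format trial CSV
  schema, YAML run configuration, an end-to-end `reproduce-all` pipeline,
  and a `riskshift` command with one subcommand per stage.

## Worked example

```python
import riskshift as rs

table, truth = rs.generate_cohort(rs.CohortConfig(n_per_group=60),
                                  groups=("PR", "RP"), seed=7)
kept, report = rs.apply_exclusions(table)
print(f"kept {report.kept.sum()} of {len(report)} participants")

q = rs.pooled_acceptance(kept, by=["group", "block_index", "environment"])
print(q.to_string(index=False))

first = kept[kept.block_index == 1]
res = rs.one_tailed_diff_test(first[first.group == "PR"],
                              first[first.group == "RP"], B=9999, seed=7)
print(f"first-block difference D = {res.observed:.3f}, p = {res.p_value:.4f}")
```

prints

```
kept 104 of 120 participants
group  block_index environment  n_accept  n_choices        q
   PR            1        poor      1165       1711 0.680888
   PR            2        rich      1133       1715 0.660641
   RP            1        rich       952       1710 0.556725
   RP            2        poor      1010       1709 0.590989
first-block difference D = 0.124, p = 0.0001
```

Sixteen of 120 simulated participants trip the exclusion criteria (mostly
catch-trial errors by the inattentive fraction). The pooled acceptance
proportion q is higher in the poor than in the rich environment within each
block position, and the PR group stays more gamble-prone than the RP group
even in the shared rich environment — the current- and past-environment
effects the pipeline is designed to detect. The one-tailed participant-level
bootstrap test (B = 9,999) confirms the first-block difference
(D = 0.124, p = 1/10⁴, the smallest attainable p at this B).

The same stages are available from the shell:

```bash
riskshift simulate-cohort --seed 7 --n-per-group 60 --groups PR,RP --out cohort.csv
riskshift exclusions cohort.csv --out kept.csv
riskshift bootstrap-test kept.csv --group-a PR --group-b RP --block 1 --seed 7
riskshift reproduce-all --seed 7 --scale smoke --out report/
```

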