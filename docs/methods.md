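# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `riskshift`. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Task and analyzed trials

Each trial offers a gamble (magnitude *m* ∈ {15…65} points, probability *p*)
against a sure 10 points. A block presents each (*p*, *m*) pair of its
environment grid exactly once — the published block totals force this
composition (66 − 11 catch = 55 = 5 probabilities × 11 magnitudes for
poor/rich; 39 − 6 = 33 = 3 × 11 for intermediate) — plus catch trials with a
dominant answer: magnitude-10 gambles (reject) and probability-1 gambles
(accept). Catch-trial probabilities/magnitudes are drawn from the
environment's own sets so they look locally typical; catch positions are
uniformly interleaved (no minimum-spacing constraint is imposed because none
is specified by the design). Analyses use only trials whose parameters occur
in every environment: non-catch, *p* ∈ {0.4, 0.5, 0.6}, *m* > 10 — 33 per
block regardless of environment.

Exclusion criteria: incomplete sessions; non-response on ≥ 5% of presented
trials (the boundary excludes, reading "at least" conservatively; catch
trials count toward the denominator); one identical response on all trials;
errors on strictly more than 10% of catch trials. With 22 (Experiment 1) or
12 (Experiment 2) catch trials the strict-vs-non-strict reading of the 10%
boundary cannot differ, since no integer error count lands exactly on 10%.

## Decision models

* Risk-return: U = *mp* − α·*m*²*p*(1−*p*). The sure option has zero
  variance, so ΔU = (*mp* − 10) − α·*m*²*p*(1−*p*).
* Multiplicative: U = *m*^λ · π(*p*) with Prelec weighting
  π(*p*) = exp(−(−log *p*)^γ); π(0) ≔ 0 by continuous limit.
* Additive: U = (1 − w_p)·ṽ(*m*) + w_p·π(*p*). The normalization scheme of
  the additive value term is open in the task description; we divide by the
  design maximum, ṽ(*m*) = (*m*/65)^λ, so both components lie in (0, 1], and
  apply the same ṽ, π to the sure option (10, 1) so both utilities are in
  the same currency. This is a package design choice, configurable in
  principle by editing one constant.
* Choice rules: sigmoid 1/(1 + e^(−βΔU)); approach-avoidance shifts the
  floor by η when η ≥ 0 ((1−η)·sigmoid + η) or the ceiling when η < 0
  ((1+η)·sigmoid). η = 0 reduces to the sigmoid exactly.

Excluded parameters (λ, γ) are fixed at 1, giving 1 + 4 + 4 utility models
× 2 choice rules = 18 candidates.

## Synthetic cohort: what it emulates and what it does not

The generator produces the statistical structure the analyses assume, with
every ground-truth parameter persisted:

α_t = α₀ − e_env·Δp_c − e_past·Δp_p + e_acc·z(accumulated reward), with a
perseveration bias added to the choice logit after an accepted trial.

Defaults (the study conditions):

| parameter | default | rationale |
|---|---|---|
| n_per_group | 120 | the scale used by the study's own simulations |
| α₀ mean / sd | 1.8e-2 / 0.4e-2 | midpoint and spread of the particle-filter group estimates (1.59–2.00 ×10⁻²) |
| β mean / sd | 0.5 / 0.1 | β = 0.5 reproduces the printed pooled acceptance (q ≈ 0.66 in poor at α = 1.59e-2); also mid-grid of the state-space search range [0.1, 1] |
| e_env | 2.0e-2 | poor-vs-rich α gap ≈ 0.4e-2 over a 0.2 difference in mean Δp_c |
| e_past | 1.2e-2 | RP-vs-PR α gap in the shared poor environment ≈ 0.24e-2 over Δp_p = 0.2 |
| e_acc | 0.1e-2 | one standard deviation of accumulated reward shifts α by 0.1e-2 |
| perseveration | 1.0 utility point | β·1.0 = 0.5 on the logit, matching the observed previous-choice effect (~0.4–0.55) |
| non-response rate | 0.003 | observed 0.26–0.37% |
| inattentive fraction | 0.15 | observed catch-failure exclusion rates (17–22%) |
| catch accuracy (attentive) | 0.98 | lapse-style attention model, see below |

z(accumulated reward) standardizes the running total against a nominal
expected trajectory (20 points/trial, spread 150 points) — a simple online
surrogate for the within-participant z-scoring used in the analysis.

Attentive agents answer catch trials correctly with probability 0.98 rather
than through the sigmoid rule: at realistic β the sigmoid would produce
~20% errors on reject-catch trials, which no attentive human makes on a
dominated option, and which would absurdly trip the exclusion criterion for
attentive agents. Inattentive agents answer catch trials at chance (and are
excluded with probability ≈ 1 given ≥ 12 catch trials).

Not emulated: response times, demographic structure, payment effects,
learning or fatigue trends beyond the modelled α dynamics, and any
non-linear interaction between the three environmental drivers. Passing
tests therefore show that the pipeline recovers effects of this linear
generative form at realistic sizes — not that the real data contain them.

## Bootstrap inference

Resampling is at the participant level. The one-tailed difference test uses
the recentered null D_null = (q_A* − q_A) − (q_B* − q_B) and
p = (1 + #{D_null > D})/(1 + B), B = 9,999 by default. The two-tailed
one-sample test (used for regression coefficients) is the natural
extension: recenter the draws at the observed statistic, double the smaller
tail (with the same +1 smoothing), Bonferroni-multiply, cap at 1.
Confidence intervals are empirical percentiles (the alternative
normal-approximation interval is not offered). Draws are made
order-invariant by sorting participants canonically before index sampling.
Type-I calibration of the difference test at B = 999 over 500 null
replicates of 120 + 120 participants is 5.2% (tested at [3%, 7%]).

## Hierarchical EM and iBIC

Priors per parameter: β, γ, λ ~ gamma; α ~ normal; w_p ~ beta;
η ~ beta affinely mapped to [−1, 1] (x = 2u − 1). Initial hyperparameters
are broad: gamma(1, 0.1), normal(0, 10), beta(1, 1).

The E-step computes each participant's posterior moments by importance
weighting a shared set of prior draws; the draws use common random numbers
(fixed uniforms pushed through the prior quantile functions), so the
marginal-likelihood objective is a smooth function of the hyperparameters
and the convergence criterion — relative change < 1e-4, at most 200
iterations — is meaningful. The M-step moment-matches each prior family to
the averaged posterior moments. The prior is initialized by moment-matching
coarse-grid best fits per participant (the choice likelihood is multimodal
in (α, β); a fixed starting point reliably finds the wrong mode). We chose
this over the more common per-participant MAP + Laplace E-step after
verifying—against an exact two-dimensional quadrature EM and against direct
marginal-likelihood evaluation—that the MAP variant converges slowly and is
pulled off target by boundary estimates under the broad initial prior. A
final pass still reports per-participant MAP estimates with
diagonal-Laplace standard deviations under the fitted prior.

iBIC = −2·Σ_i log p̂(data_i) + k_hyper·log(n_obs), with the per-participant
marginal likelihood estimated by averaging the data likelihood over 2,000
draws from the fitted prior (log-space throughout) and k_hyper = 2 per free
parameter. Ties rank the model with fewer hyperparameters first.

Parameter recovery is a genuinely shrinkage-limited problem at 33 trials
per participant: the empirical-Bayes optimum (we verified the marginal
likelihood is higher there than at the generating prior) sits slightly
inside the generating values. Recovery is therefore assessed against the
realized sample means of the simulated cohort — the quantity an
empirical-Bayes fit actually targets — within two standard errors
(population sd/√n) at 120 participants × 33 trials.

## State-space model and particle filter

Observation: pooled Bernoulli choices with μ = sigmoid(β·ΔU(α_t)); system:
α_t ~ Cauchy(α_{t−1}, σ); α₀ ~ Normal(0, 1). Bootstrap filter with
systematic resampling at every informative step (resampling is skipped when
all participants are masked, so the state propagates with uniform weights);
log weights use the numerically stable −logaddexp(0, −x) form; the
marginal-likelihood increment is the log mean unnormalized weight.
Fixed-lag smoothing (L = 20) reads the time-t coordinate of particles
surviving at t + L via stored ancestry; the last L trials fall back to the
terminal filtering distribution. The point estimate is the smoothing
median; the 5th/95th percentiles form the 90% band.

The reported grid bound "10⁻⁵ ≤ log σ ≤ 10⁻¹" is internally inconsistent (it would put σ near 1, four orders of magnitude
above the α scale); we read it as σ log-spaced in [10⁻⁵, 10⁻¹]. Default
grids are 50 × 50 (σ log-spaced, β equally spaced in [0.1, 1]),
configurable; the recovery experiment scans a reduced grid with 800–1,000
particles and re-runs the argmax at 2,000 particles (reproducing
10,000-particle results within the stated tolerances at a fraction of the
cost). The step-change recovery study uses 2 × 66 trials, 120 participants,
Δα = 0.2e-2, within-block Cauchy jitter of scale 5e-5, and scores the
plateau difference of the smoothed median against the realized true path
(±25%) and the 90%-band coverage (≥ 80%).

## Regression and forward simulation

Eight regressors per presented trial: EV = *mp*; Risk = *m*²*p*(1−*p*);
Δp_c = *p* − p̄_current; Δp_p = p̄_current − p̄_previous (the immediately
preceding block; 0 in the first block — only one past environment exists at
each transition in both designs); previous choice/reward/success (from the
previous presented trial, including catch trials, since history is
experienced regardless of analysis masks; zeros on each participant's first
trial and after a missing response); accumulated reward before the current
trial, z-scored within participant. All columns are then pooled per
experiment and z-scored; fitting uses analyzed responded trials only, and
z-scoring always precedes subsetting. Fits are maximum-likelihood logistic
regressions (scikit-learn; an independent IRLS implementation exists only
as a test oracle, agreement ≤ 1e-6); the L1 variant picks its penalty by
5-fold cross-validated deviance, a choice the task description leaves open.
An intercept is always included. BIC = −2·loglik + k·log(n) with k counting
the intercept. VIF_j = 1/(1 − R²_j), capped at 1e6 for exact collinearity.
Coefficient significance uses participant-resampled refits and the
two-tailed one-sample bootstrap test, Bonferroni-corrected by the subset
size.

Forward simulation standardizes static regressors with the stored pooled
statistics and pseudo-standardizes history regressors online: previous
choice/reward/success use their stored pooled statistics (their z-scoring
is single-stage, so this is exact), while accumulated reward — whose
pipeline z-scoring is two-stage — is standardized by the corresponding
group's mean/SD of raw cumulative points, the closest online analogue of
the within-participant stage. Ablations refit and re-simulate with each of
Δp_c, Δp_p, previous choice, accumulated reward dropped, or with lag-2/3
previous-choice regressors added.

The coefficient bootstrap resamples participants (not trials), consistent
with every other inferential step in the pipeline.

## Problem sizes used by the automated checks

Fitness optimum: analytic, 41-point α grid, both environments × 3 needs.
Particle-filter recovery: 120 participants, 132 trials, 6 × 5 (σ, β) grid
at 800 particles, final run at 2,000. Hierarchical EM: one 120 × 33
recovery fit plus 20 model-recovery replicates at 30 participants with
1,500 E-step samples and 1,000 iBIC draws. Bootstrap calibration: 500
replicates, B = 999. Regression: 240-participant cohort, coefficient
bootstrap B = 399 (the smallest B whose attainable p-values clear the
Bonferroni-corrected 5% level with margin). The end-to-end `reproduce-all`
pipeline has a `smoke` scale (≤ 24 participants/group, reduced grids and
draws) and a `full` scale matching the defaults above.

## Known limitations

* Per-participant latent α trajectories are not estimated (single-participant
  choice data are too uninformative for the state-space model; the filter is
  group-level by design).
* The hierarchical EM reports diagonal Laplace covariances only; posterior
  parameter correlations within participants are not propagated.
* Empirical-Bayes prior means shrink slightly at 33 trials/participant (see
  above); comparisons between conditions are unaffected since all conditions
  shrink alike.
* Gains only: losses and loss aversion are outside the task's design space.
* The L1 path and VIF flags support robustness checks, not model selection;
  BIC comparisons use the unpenalized fits.
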