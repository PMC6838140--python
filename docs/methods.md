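# Methods

## Task model

Four conditions cross required action (go / no-go) with outcome domain
(gain / loss-avoidance). Outcomes are coded r ∈ {−1, 0, +1}; the monetary
unit of the original paradigm is absorbed into the outcome-impact parameter
ρ, so the gain domain has support {0, +1} and the loss domain {−1, 0}. The
correct action yields the domain's better outcome with probability 0.8,
the incorrect one with probability 0.2. Schedules are block-randomized:
each consecutive block of four trials is an independent uniform permutation
of the four conditions (the constraint across block boundaries is not
specified by the design; adjacent repeats across boundaries are allowed).
The default session is 60 blocks = 240 trials.

## Learning model

Action values Q(a, s) and stimulus values V(s) start at zero — the
symmetric choice consistent with unbiased first choices — and update by the
delta rule with prediction error δ = ρr − Q (or ρr − V). Only the chosen
action's Q updates; V updates on every trial when the Pavlovian term is
present, since it is conditioned on the stimulus, not the action. Choice is
a softmax over action weights; the go weight adds the bias b and π·V(s)
additively when both terms are present (the only construction consistent
with both single-term definitions simultaneously). There is no separate
inverse temperature: ρ sets the scale of values entering the softmax.

Split learning rates select by the sign of the relevant prediction error
and the trial's domain; δ = 0 (possible only at exact equality ρr = Q) is
deterministically assigned the positive-PE rate. In split-rate models the V
update uses the rate selected by the sign of its own prediction error
(ρr − V) and the trial's domain, and the domain's ρ under a split ρ — one
concrete reading of "the same parameters as the action value", which is
ambiguous under 4-way splits.

The softmax is computed in log-sum-exp form; no overflow for |W| ≤ 700.

## Hierarchical fitting

Per-parameter population distributions are independent normals on a
transformed scale: logit for learning rates, log for ρ, identity for b and
π (π deliberately unconstrained in sign). Fitting alternates:

* **E-step** — per-subject MAP of the transformed parameters by L-BFGS-B
  with an analytic gradient (forward-mode propagation of ∂Q/∂θ and ∂V/∂θ
  through the recursion; the PE-sign selection is treated as locally
  constant, non-differentiable only on a measure-zero set). Bounds ±16
  (logit ε), ±10 (log ρ), ±20 (b, π) prevent overflow while remaining
  effectively unconstrained. Cold starts use 10 restarts (prior mean plus
  prior draws); warm E-steps start from the previous MAP, the prior mean,
  and `n_restarts_warm` fresh draws (default 2).
* **Laplace curvature** — the full Hessian of the negative log-posterior at
  the MAP, by central differences of the analytic gradient (step 1e−4),
  symmetrized and eigenvalue-floored at 1e−6. Posterior variances are the
  diagonal of the inverse **full** Hessian. This matters: the posterior is
  strongly correlated (learning rates with ρ, bias with π), and inverted
  diagonal curvatures understate marginal variances by factors of 2–4,
  which feeds a collapse loop — the M-step shrinks the population variance,
  which pins subject MAPs to the mean, which shrinks the variance further —
  erasing real between-subject structure.
* **M-step** — μ ← mean of subject MAPs; σ² ← mean of squared deviation
  from μ plus the Laplace variance, floored at 1e−6 to prevent collapse.

Iteration stops when hyperparameters move less than 1e−3 (cap 200); a final
E-step is run at the converged prior so the returned subject fits are
consistent with the returned hyperparameters. The per-iteration Laplace
approximation to the total log evidence is traced; under moment-matching
M-steps it is not exactly monotone — small decreases up to ~0.05 units per
subject per step are within numerical behavior.

Degenerate sessions (a subject who always or never responds) are fitted
normally — the population prior regularizes them — with a logged warning.

## Model comparison

The integrated BIC draws k parameter vectors from the fitted population
prior (default k = 1,000; one shared draw matrix per scoring call),
computes each subject's session likelihood per draw, takes the per-subject
log mean likelihood (log-sum-exp minus log k), sums over subjects, and adds
the penalty |M|·log(n_obs), with n_obs the total choice count of the cohort
and |M| the population-level parameter count — by default 2 per model
parameter (a mean and a variance), configurable to 1; rankings are
convention-dependent and reported under the configured convention.

The stepwise search starts from the base model (one ε, one ρ) and tries
every single refinement of the incumbent: add b, add π, split ε one level
(single → by sign → by sign and domain), split ρ by domain. Each candidate
is refitted by EM — warm-started from the incumbent's fitted **means**
embedded into the candidate's space, with variances reset to the vague
initial value (inheriting the incumbent's small fitted variances pins the
split parameters together and they never differentiate) — and scored with a
shared Monte-Carlo seed for comparability. The largest iBIC decrease is
accepted; ties within 1e−6 keep the smaller model; the search stops when no
candidate improves. Because the search is greedy, structure is only
detectable when it is expressed *along the path*: a 4-way rate split whose
contrast is purely domain-within-sign cannot be reached, because the
mandatory intermediate by-sign split brings no improvement.

## Synthetic cohorts

Group-structured cohorts draw each subject's transformed-scale parameters
from the group's normal distribution, build a block-randomized schedule,
and simulate choices with the generative model. All randomness descends
from one seed through spawned per-subject seed sequences, so a manifest
regenerates a cohort bit-exactly.

Three named conditions:

* `experiment1_groups()` — 21 + 22 subjects whose ε_LP population means
  differ (0.330 vs 0.494) with other learning rates near 0.16; ρ = 2.0,
  b = 0.3, π = 0.4 are free configuration, not published values;
  transformed-scale SDs 0.5. This is the parameter-recovery condition.
* `pavlovian_demo_group()` — π = 0.8, b = 0.2. Expresses the task's
  characteristic error asymmetry (more errors withholding for reward than
  going for reward; the reverse in the loss domain). A strong π trades off
  against recoverability — it partly aliases with b and ε_LP (cohorts
  generated at π ≥ 0.5–0.6 admit an alternative solution with low ε_LP and
  inflated b at essentially equal evidence) — so behavior demonstration and
  recovery use different conditions. At the recovery preset's modest π the
  loss-domain half of the asymmetry is not reliably visible.
* `well_separated_group()` / `base_model_group()` — model-recovery
  conditions for the stepwise search: rates separated along both split axes
  (ε_GP = 0.30, ε_GN = 0.05, ε_LP = 0.70, ε_LN = 0.15, SD 0.25) with
  substantial b and π, and a homogeneous base-model cohort (ε = 0.30,
  ρ = 2.0).

What the generator does *not* emulate: trial-level non-stationarity
(attention lapses, fatigue), response times, within-subject parameter
drift, and any questionnaire/trait structure. Passing recovery tests shows
the estimator is consistent with its own generative assumptions at these
sample sizes — not that real data satisfy those assumptions.

## Recovery checks and problem sizes

Parameter recovery runs 10 cohorts of 2 × 20 subjects × 240 trials from the
experiment1 preset; each group's population is fitted separately (the
generating model has two distinct populations — a single pooled prior
shrinks both groups to the grand mean and erases the ε_LP difference), and
recovered means are the fitted prior means on the natural scale. Learning
rates in this task are weakly identified per subject (the information
saturates once values reach asymptote; ~0.3 nats per session for ε_LP near
the preset), so recovery is a population-level, not subject-level, claim.

Model recovery runs 10 base-model cohorts (the search should keep the base
model) and 10 well-separated full-model cohorts (the search should find the
Pavlovian term and the 4-way rate split), 40 subjects each, with a lighter
EM configuration for the many candidate fits (5 cold restarts, 1 warm
restart, tolerance 2e−3, cap 60 iterations, k = 1,000).

## Known limitations

* Diagonal population covariance: correlated individual differences are not
  modeled.
* The Laplace approximation can misstate evidence for strongly skewed
  posteriors (weakly identified learning rates at small trial counts).
* Greedy selection explores one path through the lattice, not all 2^k
  subsets.
* iBIC values carry Monte-Carlo noise (typically < 2 units at k = 1,000 on
  a 40-subject cohort); decisions within that margin are unstable.
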