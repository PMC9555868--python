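# Methods

## Observer models

All three observers share the same encoding stage: on a trial with true
visuotactile asynchrony `s` (ms; positive = the real hand touched first),
the observer obtains a noisy measurement `x ~ N(s, σ²)`, with one σ per
visual-noise level (0/30/50% of white-noise pixels). The models differ in
the decision stage.

**BCI (Bayesian causal inference).** The observer carries a prior `p_same`
on the common-cause hypothesis `C=1`, believes `s = 0` exactly under `C=1`
and `s ~ N(0, σ_S²)` under `C=2`, and reports "yes" when the posterior
log-odds

    d(x) = ln[p_same/(1−p_same)] + ln[N(x; 0, σ²)/N(x; 0, σ_S²+σ²)]

are positive, i.e. when `|x| < k` with
`k² = [σ²(σ_S²+σ²)/σ_S²]·[2 ln(p_same/(1−p_same)) + ln((σ_S²+σ²)/σ²)]`.
When the bracketed term is non-positive (small priors), no measurement can
favour a common cause: the criterion is undefined and the response
probability reduces to the lapse floor λ/2. `k` increases with σ, so a
Bayesian observer widens the acceptance window under visual noise.

**BCI\*.** Identical, but σ_S is a free parameter instead of a constant.

**FC (fixed criterion).** The decision threshold is a free constant `k₀`
that ignores the trial's noise level; encoding noise still varies with it.

Response probability for every model:

    p(yes | s) = λ/2 + (1−λ)·[Φ((c−s)/σ) − Φ((−c−s)/σ)],   c = k or k₀.

This is the probability that `x` falls in `(−c, c)`, mixed with a lapse
that guesses "yes" half the time; it is even in `s` and confined to
`[λ/2, 1−λ/2]`. (The interval form is the only reading of the
double-Φ expression that yields a valid probability; a literal
`Φ(s;c,σ²) − Φ(s;−c,σ²)` is negative.) The lapse guess probability is
fixed at ½ rather than free.

### Parameters, units, defaults

| parameter | meaning | units | default / bounds |
| --- | --- | --- | --- |
| `p_same` | prior probability of a common cause | — | fit in [10⁻³, 1−10⁻³] |
| `σ0, σ30, σ50` | measurement-noise SD per visual-noise level | ms | fit in [1, 2000] |
| `σ_S` | assumed distinct-cause asynchrony SD | ms | 348 (constant for BCI/FC); fit in [10, 2000] for BCI* |
| `k₀` | fixed decision criterion (FC) | ms | fit in [1, 2000] |
| `λ` | lapse rate (random 50/50 guess) | — | fit in [0, 0.5]; forward model admits [0, 1] |

σ_S = 348 ms is the root-mean-square (population SD about 0, divisor n) of
the six nonzero asynchronies of the wider task's design
({±150, ±300, ±500} → 347.6), rounded. The narrower synchrony design has
its own RMS (195.8 ms), but the joint extension/transfer fits use the
348 ms constant for both tasks by default; both choices are configurable
per design.

## Estimation

Per participant and task, the Bernoulli likelihood of the per-cell
yes-counts is maximised (binomial coefficients omitted — constant in the
parameters; cell probabilities clipped to [1e−12, 1−1e−12] so saturated
cells with discordant counts stay finite). The optimiser is a multi-start
bounded local search: `n_starts` (default 100) start vectors drawn
uniformly inside the bounds from a seeded stream, each refined by
Nelder-Mead, with an L-BFGS-B polish of the incumbent; the better result is
kept, with a convergence tolerance of 10⁻⁶ on the objective. Nelder-Mead
carries the load because the surface has genuine plateaus (the
undefined-criterion region, lapse pinned at a bound) where finite-difference
gradients stall. Every fit is deterministic given its seed.

Free-parameter counts: BCI 5, BCI* 6, FC 5 (three noise levels). The
extension fit shares σ0/σ30/σ50 and λ across tasks — the stimulation is
identical, only the instruction differs — and uses one shared prior (5
parameters) or task-specific priors (6). Transfer evaluation re-uses one
task's fitted parameters on the other task's counts either verbatim
(full, 0 free parameters) or with only the prior (or k₀ for FC)
re-optimised (partial, 1). BIC's `n_trials` is the trial count entering
that particular likelihood (252 single-task, 504 joint, 252 for a
transfer target).

## Model comparison

AIC = 2·n_par − 2·logL*, BIC = n_par·ln(n_trials) − 2·logL*. Group
summaries: per-participant criterion differences are summed and given a
percentile bootstrap 95% CI (resample participants with replacement,
10,000 draws). Goodness of fit uses the Nagelkerke pseudo-R² against a
fair-coin null responder, divided by its maximum. Group-level
random-effects Bayesian model selection uses the standard variational
Dirichlet scheme over per-participant log-evidence (−AIC/2 by default,
−BIC/2 switchable): responsibilities and Dirichlet weights are iterated to
convergence (max |Δα| < 10⁻⁶ or 10⁴ iterations), exceedance probabilities
are estimated from 10⁵ Dirichlet samples, the Bayes omnibus risk compares
the random-effects free energy against an equal-frequency null, and
protected EPs blend the two (pEP = EP·(1−BOR) + BOR/K). Model families are
aggregated by summing Dirichlet weights within families.

## Synthetic data

The generator reproduces the factorial design exactly — 7 signed
asynchronies × 3 noise levels × 12 repetitions per participant and task —
and draws each cell's yes-count from `Binomial(12, p(yes|s))` under a
specified observer. Each (participant, task) pair gets an independent
named RNG stream derived from the master seed. Trial order and the
no-more-than-two-repeats pseudorandomisation are not simulated: under
independent trials the per-cell counts are sufficient for the likelihood.

What the generator does *not* emulate: individual heterogeneity beyond
what a caller passes in (cohorts are as homogeneous as their parameter
lists), serial dependence or learning across trials, questionnaire
responses, proprioceptive drift, reaction times. Passing tests on this
generator therefore validate the estimator and the comparison machinery
under the model's own assumptions, not the model's adequacy for real
observers.

### Parameter-recovery conditions

Two sampling-range sets ship with the generator. The broad
`DEFAULT_RECOVERY_RANGES` (prior 0.3–0.95, σ 60–300 ms, λ 0–0.2)
stress-test the fitter. The recovery *validation* uses
`PAPER_TYPICAL_RANGES` (prior 0.3–0.95, σ 60–200 ms, λ 0.02–0.14),
matching the regime of empirically fitted participants (group-mean σ of
116/141/178 ms, lapse 0.08). The distinction matters for identifiability:
when σ and the prior are jointly large, the Bayesian criterion exceeds the
widest probed asynchrony (±500 ms) and the response curve is flat over the
whole design, so the prior cannot be recovered by any estimator; and at
high lapse rates the prior and lapse trade off along a likelihood ridge at
12 repetitions per cell. Inside the typical regime the criterion stays
within the probed range and all parameters are identifiable. Recovery at
the study's scale (20 observers, 12 reps/cell) yields a truth-estimate
prior correlation above 0.8; at 100× repetitions all parameters converge
(median relative error < 5%).

## Numerical choices and degenerate inputs

- Undefined criterion (K ≤ 0) → response probability λ/2, by design.
- Boundary identity d(±k) = 0 holds to 10⁻⁹ relative tolerance.
- Likelihood is invariant to row order, to splitting/merging cells with the
  same (task, noise, asynchrony), and to a common rescaling of all
  asynchronies and ms-parameters.
- The paired t-test raises on zero-variance differences rather than
  returning ±∞; Pearson correlation likewise requires non-degenerate input.
- Bootstrap CIs are percentile (not BCa); with identical inputs the CI
  collapses to the point sum.

## Problem sizes

The test suite and the acceptance script run cohorts of 6–15 simulated
participants at the full 252-trial design, 20-observer recovery studies at
12 and 1,200 reps/cell, and 10–40 optimizer starts per fit; the library
defaults remain 100 starts and 10,000 bootstrap draws.

## Known limitations

- Exceedance probabilities come from this package's own variational
  implementation; other RFX-BMS implementations agree qualitatively but
  not to the last digit (sampling error of the Dirichlet EP estimate is
  ~10⁻³ at 10⁵ draws).
- λ is intrinsically hard to pin down: even at 1,200 reps/cell its
  single-fit relative error can exceed 5% for small true λ (the absolute
  error is bounded by tail-cell binomial noise, ≈0.003–0.005).
- σ of a noise level whose criterion saturates beyond the probed
  asynchronies is weakly identified; its fitted value should be read with
  care when `k > max |s|`.
- The models are symmetric in `s` by construction; real asymmetries
  between fake-hand-leading and real-hand-leading asynchronies are outside
  the model family.
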