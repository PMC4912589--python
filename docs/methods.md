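# Methods

## The multistate model

`famstate` implements a multistate Cormack–Jolly–Seber model over the four
observable winter states of family association (with parents `P`, with
siblings `S`, independent/nonbreeder `INB`, independent/breeder `IB`) plus
an unobservable absorbing dead state. Everything is conditioned on first
capture: a bird enters the analysis alive, in state `P`, at age 1, in its
marking winter. Ages are classes 1..7 with 7 pooling all older ages ("7+").

Assumptions worth keeping in mind:

* **Forward-only states.** Birds never return to an earlier state; the
  numeric codes are ordered so the rule is a monotonicity constraint on
  observed nonzero codes. `IB` is absorbing among the living states —
  repeat breeding is not modelled, reflecting how rarely it occurs in this
  population.
* **Age-linear survival.** `logit φ_s(a) = α_s + β_s a` with state-specific
  intercept *and* slope (the survival curves of the different states cross,
  which a shared slope could not produce). Survival for `S`, `INB`, `IB` is
  effectively estimated from age 2 because no bird can occupy them at
  age 1.
* **Fully age-specific transitions** in the default variant: a multinomial
  logit per (from-state, age), with the last allowed destination as the
  reference category, recovered as 1 − (sum of the back-transformed free
  destinations). The `age_constant` variant shares one multinomial per
  from-state across ages.
* **State-specific, time-constant detection** `p_s`; no misclassification
  (a bird seen in a state is truly in it).

### Priors

Coefficients (survival and transition logits) get Normal(0, sd = 31.62)
priors, i.e. variance 1000 — flat on the probability scale for practical
purposes. The `prior_sd` is exposed in `PriorConfig`. Detection gets
Uniform(0, 1). These choices resolve two ambiguities in the conventions of
BUGS-style model descriptions: "variance 0.001" in that notation is a
*precision*, and a "uniform prior with mean 0 and variance 1" is not a
proper description of a probability; we use the noninformative readings.

### Likelihood

The latent state sequence is marginalized with the hidden-Markov forward
algorithm over {P, S, INB, IB, dead}: transition matrices combine survival
and movement (`phi_s(a)·psi_{s→s'}(a)`, death mass `1 − phi_s(a)`);
emission is `p_s` for a sighting in the true state, `1 − p_s` for a zero
from a living state, and 1 for a zero from the dead state. The pass
rescales each step and accumulates the log normalizer. This replaces
latent-state data augmentation: the posterior is identical and mixing is
far better at desk scale. The kernel is numba-compiled and identical
encounter histories are pooled with multiplicities (typically a 2–3×
saving), giving ≈0.2 ms per likelihood evaluation for 3,000 individuals ×
15 occasions.

Event order within a year: survive, then transition, then age (saturating
at class 7), then detection at the next occasion — the standard multistate
convention; the transition out of age *a* uses the age-*a* parameters.

### Sampler

Adaptive random-walk Metropolis in five blocks: survival coefficients (8),
transition coefficients per from-state (21 / 12 / 6 age-specific), and
detection probabilities (4, proposed on the probability scale and rejected
outside (0, 1)). Each block's proposal scale follows a Robbins–Monro
recursion on the log scale toward 30 % acceptance during burn-in (step
`min(0.1, t^-0.6)`, clipped to [1e-4, 5]) and is frozen afterwards, so the
post-burn-in chain is a valid fixed-kernel Metropolis sampler. Initial
values: coefficients ~ Normal(0, 0.1), detection ~ Uniform(0.3, 0.9),
re-drawn (bounded attempts) until the posterior is finite. Chains use
independent `numpy` generators seeded from `(seed, chain_index)`; runs are
bit-reproducible.

### Diagnostics and summaries

`gelman_rubin` uses the classic (non-split, non-rank-normalized) potential
scale reduction factor `sqrt(((n−1)/n·W + B/n)/W)`; identical chains of
length n give exactly `sqrt((n−1)/n)`. It is computed by default on the
*derived probability scales* (φ, ψ, p), which are the identified
quantities; raw multinomial-logit coefficients of nearly empty cells (for
example breeding from independence at an age with no events) drift in the
flat region of the prior and can flag without any consequence for the
probabilities. Posterior summaries are means with central 2.5–97.5 %
intervals. Posterior "P-values" for differences count draws strictly below
zero; ties count as not-below (a fixed, documented policy so results are
exactly reproducible).

## Synthetic data

The generator emulates the study design: annual cohorts of first-winter
birds, all entering with parents; yearly survival/transition/detection as
above; dead birds recorded 0 forever. It can retain latent trajectories
for recovery tests. What it does **not** emulate: family structure shared
between marked birds (each individual is independent), individual
heterogeneity or frailty, trap-dependence, calendar-year (environmental)
effects, or within-winter sighting processes. Passing recovery tests
therefore demonstrate correctness of the estimator under the model's own
assumptions — not robustness to their violation in field data.

`default_truth()` pins every parameter that was reported as a posterior
mean in the source analysis of the Wexford population (remain-with-parents
at ages 2, 5, 6, 7+; sibling→breeder at ages 3, 5, 6, 7+;
independent→breeder at ages 5, 6, 7+; breeder and independent-nonbreeder
resighting). All other entries — survival intercepts/slopes, the split of
the leave-parents mass, sibling-state stay probabilities, detection for the
two family states, independent→breeder at ages 2–4 — were published only as
figures; the defaults reproduce their qualitative shape (family survival
highest and increasing, independent-nonbreeder lowest, breeder flat; most
birds skipping the sibling state; detection between 0.64 and 0.94) and are
documented as non-authoritative. They were fixed once, before any fitting.

The default recovery experiment uses 3,000 individuals in 8 cohorts over
15 occasions, fitted with 3 chains × 30,000 iterations (burn-in 10,000,
thin 10, 6,000 retained draws). These sizes make the seven pinned
parameters data-dominated while a full experiment runs in a few minutes on
a single CPU; the pooled 7+ class stays reachable for every cohort.

## Fitness projection

Stages are (age 1–7) × {P, S, INB} — 21 stages. The breeder state is *not*
a stage: transitions to breeding contribute a fecundity of 1 into (age 1,
P) — every real bird starts there — weighted by the parent's survival that
year, and the breeder is then lost to population growth. λ is therefore a
relative fitness proxy (clutch size and fledging success independent of
age), not a population growth rate; λ < 1 simply reflects that few marked
recruits ever breed.

Numerical choices:

* `dominant_eigenvalue` is a shifted power iteration on `M + I` (for a
  nonnegative matrix the Perron root is then strictly dominant in modulus,
  so periodic toy Leslie cases converge too), with a strict stopping rule —
  four consecutive near-stationary Rayleigh quotients at relative 5e-15 —
  and a dense `eigvals` fallback on non-convergence. Tests compare it
  against the dense solver as an independent oracle.
* The matrix is restricted to stages **reachable from the recruitment
  stage** before the eigenvalue is taken. Unoccupiable stages (age-1 S/INB;
  the abandoned with-parents chain under a forced early-departure strategy)
  would otherwise contribute spurious high-survival cycles. A forced
  schedule that keeps a bird in the sibling state through class 7+ remains
  reachable, and its λ is then the sibling-survival decay rate — the
  correct value for a never-breeding strategy.
* Age-1 rows for S and INB in internal ψ tables are deterministic
  placeholders; they are never reachable and never influence results.

## Strategy cost–benefit

A strategy (p, s) forces: remain with parents through age p (departure on
the transition out of age p), then s years with siblings, then
independence — each forced move with probability 1 — while survival and
the observed age-specific breeding probability from independence are kept.
The default grid is p = 1..7, s = 0..7−p (28 strategies: independence
reached by class 7+); schedules with larger s saturate in class 7+ and are
representable but excluded from the grid as degenerate duplicates. Forced
family phases cannot breed directly by default, because in this population
breeding is observed only after independence is available as a route; the
observed sibling→breeder shortcut can be retained with
`allow_sibling_breeding=True` (it exists in the wild-type either way).

ω = λ_wt − λ_s is computed draw-for-draw on the same posterior sample, so
parameter uncertainty cancels coherently within draws.
`monitor_draw_correlations` reports posterior correlations of transition
probabilities at consecutive ages within each from-state (|r| > 0.9
flagged) to check that neighbouring-age trade-offs are not driving the
grid; survival is excluded because its age-linear form makes those
correlations ±1 by construction.

## Descriptive summaries

Parent-association duration counts winters assigned state `P` from marking
until the first different nonzero state; a `0` between two sightings in the
same state is bridged (the field protocol's repeated within-winter
sightings cannot be reconstructed from annual codes, and bridging is the
conservative deterministic choice); trailing unseen winters never extend a
duration. Sibling durations are computed the same way over the `S` run.
"Ever-breeder" means observed at least once in state `IB`. Standard errors
are sample SD/√n. Only observed state-years are counted — a bird whose
associates died mid-study contributes whatever was observed, nothing more.

## Known limitations

* No state misclassification, individual covariates, calendar-year
  effects, or model selection (WAIC etc.).
* The sampler is a random-walk Metropolis: adequate here (posterior means
  and R-hat on derived scales are stable across seeds at the default
  experiment size), but gradient-based samplers would give better effective
  sample sizes per iteration for much larger models.
* Identity of unreported generating values is qualitative; recovery claims
  are made only for the pinned parameters.
* The cost–benefit machinery compares *forced* schedules under observed
  rates; it is not a game-theoretic optimum and ignores inclusive-fitness
  contributions.
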