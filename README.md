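# famstate

Bayesian multistate capture–recapture modelling of **family-association
states** in long-lived geese, with matrix-projection fitness and a
stay/leave cost–benefit simulator.

Greenland white-fronted geese keep uniquely long parent–offspring and
sibling–sibling bonds (up to 13 years). Staying with the family raises
survival; leaving is the only route to breeding. `famstate` is for
population ecologists who want to quantify that trade-off from winter
resighting data of individually marked birds: it estimates age- and
state-specific survival, state-transition and resighting probabilities from
encounter histories, turns each posterior draw into an age × state
projection matrix whose dominant eigenvalue is a relative fitness proxy,
and asks whether forced "leave the family at age x" strategies would have
been credibly better or worse than the observed ("wild-type") life history.

## The model

Each marked bird is observed each winter in one of four states —
`1` with parents, `2` with ≥1 sibling, `3` independent/nonbreeder,
`4` independent/breeder — or not seen (`0`). Latent states add an
unobservable absorbing `dead`. Conditional on first capture (all birds are
marked in their first winter, with parents):

* **Survival** `logit φ_s(a) = α_s + β_s·a` — a linear age trend per state
  over age classes 1..7+ (ages ≥7 pooled).
* **Transitions** ψ_{s→s′}(a), forward-only (1→{1,2,3,4}, 2→{2,3,4},
  3→{3,4}, 4 absorbing), fully age-specific, parameterized by multinomial
  logits with the last destination recovered as βₙ = 1 − Σ βᵢ. An
  `age_constant` variant shares one multinomial across ages.
* **Detection** p_s per state, Uniform(0,1) prior; coefficients get
  Normal(0, sd 31.62) priors.

The likelihood marginalizes latent states by the hidden-Markov forward
algorithm (numba-compiled); the posterior is sampled with adaptive block
random-walk Metropolis and checked with the Gelman–Rubin statistic.

Fitness: a draw's tables populate a 21-stage (age 1–7 × states {parents,
siblings, independent/nonbreeder}) projection matrix; breeding contributes
a fecundity of 1 into (age 1, with parents) and breeders are then lost to
population growth. λ_wt is the dominant eigenvalue, computed per draw. A
forced strategy (leave parents after age p, stay s more years with
siblings, then independence) replaces the transitions — survival and
breeding-from-independence stay observed — giving λ_s, and
ω = λ_wt − λ_s with P = Pr(ω < 0) ("credible" when P < 0.05 or P > 0.95).

Because the underlying field data are not deposited, the package ships a
first-class synthetic-data generator (`famstate.synthetic_data`) whose
default truth pins every parameter that was reported as a posterior mean;
all validation is parameter recovery against that truth.

## Worked example

`python examples/fitness_and_strategies.py` simulates 600 birds, fits a
short 2-chain model and prints:

```
wild-type fitness lambda_wt: mean 0.827, 95% CRI [0.788, 0.862]

 strategy  lambda_s    omega            95% CRI      P credible
     p1s0     0.814    0.013 [   0.004,   0.032]  0.000 True
     p1s1     0.818    0.009 [   0.002,   0.030]  0.001 True
     p2s0     0.820    0.007 [   0.001,   0.025]  0.005 True
     p3s0     0.826    0.001 [  -0.005,   0.016]  0.564 False
     p5s0     0.836   -0.009 [  -0.020,   0.003]  0.964 True
     p7s0     0.842   -0.015 [  -0.029,  -0.005]  0.983 True
```

`p1s0` means "forced independent at age 1, no sibling years". ω > 0 with
P ≈ 0 for ages 1–2: leaving the family that early is credibly worse than
the wild type (the survival benefit of family association is lost before
breeding ages are reached). By middle age the difference vanishes, and
forcing departure at old ages would actually have been credibly better —
the same qualitative shape as in the source population. λ < 1 is expected:
it is a relative fitness proxy for a cohort of marked recruits, not a
population growth rate.

The other examples cover simulation + descriptive summaries
(`simulate_and_describe.py`: duration histograms, fraction of bonds
≤ 3 years, breeder percentages) and model fitting with parameter recovery
(`fit_multistate_model.py`).

A thin CLI wraps the pipeline stages:

```sh
famstate all --out run1 --seed 1 --chains 3 --iters 4000 --burnin 1500
```

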