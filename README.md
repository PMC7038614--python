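# acidevo

In silico evolution of microbial organic-acid production.

Filamentous fungi such as *Aspergillus niger* are industrial organic-acid
factories: in phosphate-limited batch fermentation at low pH they secrete
large amounts of citric acid. Redirecting that output to other valuable
acids (succinate, lactate, malate, acetate, gluconate) requires many
simultaneous, finely tuned changes to metabolic flux — far beyond what
exhaustive knock-out screening can explore. `acidevo` couples
constraint-based metabolic modelling (FBA/dFBA) with a genetic algorithm
that evolves the *flux bounds* of every reaction in a genome-scale model,
so that knock-down and knock-up strategies with continuous strength are
searched directly.

## What it implements

- **Flux-balance core** (`acidevo.fba`): steady-state LPs
  `max c·v  s.t.  S·v = 0, lb ≤ v ≤ ub` on persistent GLPK problems
  (microsecond re-solves for the GA hot loop), with degenerate optima
  resolved by minimising total absolute flux.
- **Two-phase batch fermentation** (`acidevo.fermentation`): explicit-Euler
  dFBA of a culture that first grows on external phosphate while storing
  polyphosphate (phase 1), then — after phosphate depletion at time
  `t_c` — grows slowly on released phosphate while maximising proton
  export (phase 2). Organic acids leave the cell as dissociation products
  carrying those protons (Henderson–Hasselbalch fractions at broth pH).
- **Closed-form fitness** (`acidevo.fitness`): volumetric productivity
  estimated from a *single* phase-2 FBA snapshot plus constants
  `t_c, A_c, S_c` taken once from a wild-type dFBA run:

  ```
  c(t_f) = p₂·S_c / f₂              h(t_f) = h·S_c / f₂
  t_f    = t_c + (1/μ₂)·ln(1 + S_c·μ₂/(f₂·A_c))     (μ₂ > 0)
  F      = c(t_f)/t_f               (simple)
  F      = (h(t_f) + 10·c(t_f))/t_f (adapted, for acids the wild type
                                     does not produce)
  ```

- **Genetic algorithm** (`acidevo.ga`): two-chromosome genomes (lower /
  upper bounds per reaction), population 500, 5% elimination from the
  fitness-ranked bottom half, 1%/2%/7% selection (population-wide /
  fresh wild-types / bottom half), per-gene recombination at rate 0.04,
  Laplace mutation at rate 0.02 with flux-forcing control steps (sign
  forcing at the default scale, 30% acceptance gate, cap at 1% of the
  reaction's maximum flux).
- **Solution analysis** (`acidevo.analysis`): recorded individuals above
  95% of the best fitness are pruned by complementation (a mutation is
  kept only if reverting it costs > 5% fitness), then summarised as
  mutation-frequency tables and a representative solution.
- **Toy network** (`acidevo.toy`): a deterministic ~40-reaction core
  carbon model (glycolysis, pyruvate node, TCA + glyoxylate shunt,
  fumarate reductase, electron transport chain, biomass with phosphate
  demand, six exportable acids with pH-2 dissociation stoichiometry)
  so that the whole pipeline is testable without a genome-scale model.

A genome-scale SBML model (FBC or legacy bounds) can be loaded through
`acidevo.read_sbml` / the `acidevo stats` command.

## Worked example

```
$ acidevo simulate --out runs/wt
status=substrate_depleted t_c=13.827422306921605 t_f=33.70561069461577
```

The wild-type batch: phase 1 grows exponentially at μ₁ ≈ 0.29 h⁻¹ until
external phosphate (4 mmol/L) is gone at `t_c ≈ 13.8 h` with biomass
`A_c ≈ 5.5 g/L` and substrate `S_c ≈ 263 mmol/L` remaining; phase 2 then
secretes citrate (and only citrate) at ≈ 1.09 mmol gDW⁻¹ h⁻¹ until the
glucose runs out at `t_f ≈ 33.7 h` — about 204 mmol/L ≈ 39 g/L citrate,
a simple fitness of `F ≈ 6.06`. The full time series lands in
`runs/wt/trajectory.csv`.

Evolving a lactate producer (the wild type makes none, so the adapted
fitness is used):

```
$ acidevo evolve --out runs/lac --target lactate --mode adapted \
      --generations 2000 --population 500 --seeds 1
seed 1: best fitness 121.7049 (11507 recorded)
$ acidevo analyze runs/lac/evolution_seed1.json --out runs/lac/analysis
6 pruned solutions; 1 mutated reactions
```

Complementation pruning reduces this run's near-optimal solutions to a
single essential mutation — an upper-bound constraint of 0 on citrate
synthase — which closes the citrate route entirely; lactate
dehydrogenase then becomes the proton source and acid output switches
completely from citrate (flux exactly 0) to lactate. The
complementation table for the representative solution
(`analysis/…_complementation.csv`):

```
reaction_id,mutation_effect,...,fitness_decrease_pct,acid_flux_decrease_pct,growth_increase_pct
CS,UC,...,99.6,100.0,-0.0
```

i.e. reverting that one bound to wild-type costs 99.6% of the fitness
and 100% of the lactate flux. (An alternative optimum blocks both
electron-transport branches instead, forcing lactate as the redox
valve; different seeds settle on either route.)

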