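# Methods

## The model of batch organic-acid fermentation

The framework treats organic-acid fermentation as two successive
quasi-steady growth phases of a batch culture, each described by one
flux-balance problem over a stoichiometric network.

**Phase 1 — phosphate storage.** External phosphate is available; the FBA
objective is growth. Most of the phosphate taken up is routed to a
polyphosphate store (a fixed specific storage flux), the remainder meets
the biomass phosphorus requirement. With constant specific rates
(μ₁, substrate uptake f₁, phosphate uptake q), biomass grows
exponentially and the external phosphate pool `P` obeys `dP/dt = −q·A`,
which gives closed forms for the switch time and state:

```
t_c = (1/μ₁)·ln(1 + P₀μ₁/(q·A₀))   A_c = A₀ + μ₁P₀/q   S_c = S₀ − f₁P₀/q
```

(with the μ₁ → 0 limit `t_c = P₀/(q·A₀)`). The simulator does not use
these forms — they are the independent oracle in the tests; the package
reads `t_c, A_c, S_c` off the simulated trajectory.

**Phase 2 — proton production.** External phosphate uptake is closed;
stored phosphate is released at a small fixed specific rate, which caps
growth at `μ₂ ≤ r/π` (π = biomass phosphorus coefficient). The FBA is
solved lexicographically: growth is maximised first (phosphate-limited
growth continues as observed in fermenters), then proton export is
maximised at that growth rate, then total absolute flux is minimised to
select a unique flux vector. Letting growth float below the release cap
— rather than pinning it with an equality — is what allows
growth-constraining mutations to remain feasible and trade biomass for
acid, the central phenomenon the evolutionary searches exploit; it also
makes the "% growth increase" complementation metric meaningful.

Acids leave the model through dissociation pseudo-reactions
`HA → A⁻(ext) + n·H⁺(ext)` where `n` sums `1/(1+10^(pKa−pH))` over the
acid's dissociation steps at the (fixed) broth pH. At pH 2 this strongly
favours citrate (n ≈ 0.071) over lactate (0.014), succinate (0.006) and
acetate (0.002) — which is exactly why a proton-maximising wild type is
a citrate producer and why switching output requires rewiring redox
metabolism rather than re-weighting the objective.

**Dynamic integration.** Explicit Euler with Δt = 0.01 h. Within a step
all rates are constant, so the phosphate-depletion and substrate-
depletion crossings are located exactly inside the step (the limit of
bisecting the step); the phase switch happens at `P = 0` to machine
precision. Because bounds do not change between events, consecutive
steps reuse the cached flux solution and a full trajectory costs a
handful of LP solves. Step-halving moves `t_c` and `t_f` by ≪ 0.5%
(first-order convergence, tested). pH is held at its initial value for
all FBA problems; a reported pH series is derived from cumulative proton
export but does not feed back. Stored-phosphate exhaustion during phase
2 is not modelled (the store built in phase 1 exceeds phase-2
consumption several-fold under the default conditions).

## Fitness

Evaluating a full dFBA per individual would be orders of magnitude too
slow for an evolutionary search, so fitness is a closed form over one
phase-2 FBA snapshot (μ₂, f₂, target-acid flux p₂, proton flux h) plus
the constants `t_c, A_c, S_c` precomputed from a single wild-type dFBA
run. Mutant bounds are applied to phase 2 only — mutations "switch on"
at the phase boundary — which is what makes those three quantities
constants across all individuals. Yields are `c(t_f) = p₂S_c/f₂` and
`h(t_f) = hS_c/f₂` (mmol per litre of broth; gram conversions only at
reporting time via molar masses); the depletion time integrates
`S' = −f₂A, A' = μ₂A`. Guards: μ₂ below 1e−10 uses the μ₂ = 0 branch;
the log argument is clamped to ≥ 1; `f₂ = 0` flags the result and yields
fitness 0; an infeasible LP yields fitness 0, never an exception (flux-
forcing mutations do produce infeasible genomes and the GA must absorb
that).

The simple fitness `F = c(t_f)/t_f` is zero for any acid the wild type
does not secrete, leaving selection nothing to climb. The adapted form
`F = (h(t_f) + 10·c(t_f))/t_f` keeps a proton-production gradient alive
while weighting the target acid 10× once it appears; the weight applies
to the target yield in the same mmol/L units as the proton yield.

## Genetic algorithm

Genomes are the two bound vectors (chromosome 1 = lower, chromosome 2 =
upper; one "gene" per bound entry). Defaults follow the published
parameterisation: population 500, 5% elimination drawn uniformly from
the fitness-ranked bottom half (ceil rounding at sizes where 5% is not
integral), selection of twice the eliminated count split 1% population-
wide / 2% fresh wild-types / 7% bottom-half (no eliminated or already-
selected individual is ever picked; wild-type re-introduction keeps
original bounds in the gene pool), shuffle-pairing into parent pairs,
per-gene recombination at rate 0.04 from a uniformly chosen dominant
parent, mutation rate 0.02 over non-protected genes in random order.
Biomass, maintenance-ATP, transport, exchange and dissociation reactions
are immutable.

Mutation adds a Laplace(0, b) draw where `b` is 0.1·|wild-type flux| of
the reaction, falling back to 0.1·(wild-type maximum flux), falling back
to the default 0.01. The first mutation of a still-wild-type gene starts
from the reaction's **wild-type flux value** rather than the (±1000)
default bound — without this no single mutation could ever place a
meaningful constraint. Three control steps tame flux-forcing mutations
(bound changes that make `v = 0` infeasible, i.e. lb > 0 or ub < 0):
at the default scale the draw's sign is forced constraining-ward; a
forcing mutation survives only with probability 0.3; surviving forcing
bounds are capped at 1% of the reaction's maximum flux. The cap's
reference is, by default, recomputed under the individual's current
bounds; a config flag (`maxflux_cache`) uses wild-type-bounds maxima
instead, which the long-running end-to-end tests and the acceptance
script enable for speed (the gate statistics are unaffected; only the
cap magnitude can differ slightly). Bounds are always clipped into the
original interval (irreversible reactions can never become reversible)
and lb ≤ ub is restored by clipping the other chromosome to the mutated
bound — a deliberate convention for the unspecified crossing case.

Recording: if the wild type does not produce the target, every producing
individual is recorded; otherwise individuals beating the running best
or 110% of the wild-type fitness (in the run's own fitness mode) are
recorded. Recorded genome diffs keep only *phenotypic* mutations — those
whose reaction flux sits on the mutant bound (tolerance 1e−6) in the
tie-broken flux vector.

## Analysis

Solutions are recorded individuals above 95% (strict) of the best
recorded fitness. Pruning visits mutations in ascending
(reaction index, side) order, complements each against the current
already-pruned baseline, and discards it unless fitness drops by more
than 5% — a fixed order makes pruning reproducible; it is idempotent by
construction. Complementation metrics are
`100·(X_intact − X_complemented)/X_intact` for fitness and target-acid
flux, and the growth *increase* relative to intact μ₂. Frequencies count
a mutated reaction once per solution (an LC and a UC on the same
reaction are one occurrence) divided by the number of solutions; the 0.2
cutoff applies to the plot export only. The representative solution
maximises the summed cross-solution frequency of its mutation sites
among the > 95% set (ties: fewer mutations, then higher fitness) — a
concrete operationalisation of "best represents the average", which has
no canonical formula.

## The toy network

`build_toy_model` generates a deterministic 42-reaction core-carbon
network: glucose/phosphate/oxygen exchanges and transporters, lumped
glycolysis (2 ATP + 2 NADH per glucose), glucose dehydrogenase to
gluconate, the pyruvate node (lactate dehydrogenase, pyruvate
decarboxylase → acetaldehyde → acetate, pyruvate dehydrogenase, pyruvate
carboxylase), TCA reactions, the glyoxylate shunt, an NADH-dependent
fumarate reductase, two electron-transport branches (NADH → 2 ATP,
FADH₂ → 1 ATP, each consuming ½ O₂), an amino-acid-pool biomass
precursor, maintenance ATP (NGAM 1.9 mmol gDW⁻¹ h⁻¹), a biomass
reaction (10 AA + 2.5 OAA + 30 ATP + 0.05 P per gDW, ≈ 0.48 g C/g), a
polyphosphate store boundary and per-acid dissociation/exchange pairs.
Every internal reaction is carbon-balanced (audited in tests) and the
same config yields byte-identical SBML.

Default study conditions: glucose uptake 2.0 (phase 1) / 1.4 (phase 2)
mmol gDW⁻¹ h⁻¹, phosphate uptake cap 0.25 with fixed storage 0.2
(phase 1), release cap 0.0025 (phase 2, so μ₂ ≤ 0.05 h⁻¹), pH 2, batch
A₀ = 0.1 g/L, S₀ = 300 mmol/L glucose, P₀ = 4 mmol/L phosphate. These
were chosen once so the toy reproduces the qualitative phenomena the
framework is about: the wild type grows at μ₁ ≈ 0.29 h⁻¹, stores
phosphate, and after the switch secretes citrate and nothing else;
citric productivity has an *interior* optimum in μ₂ (≈ 0.035 h⁻¹, ≈ 1%
above wild type) so growth-constraining mutations are adaptive under
the simple fitness; and for lactate the adapted fitness admits two
near-equal optima — blocking both respiratory branches (citrate's NADH
can no longer be recycled, lactate dehydrogenase becomes the redox
valve) or blocking citrate synthase outright — and in either case
citrate output is exactly zero: a complete acid switch. The
phosphate pool size matters here: with too little biomass accumulated
by t_c the depletion-time term dominates and growth constraint is never
adaptive.

What the toy does **not** emulate: genome-scale redundancy (dozens of
isoenzymes and compartments per function), realistic P/O ratios and
proton-translocation stoichiometry, transporter kinetics, pH drift, or
biomass-composition changes under stress. Passing tests therefore show
the *machinery* (operators, estimators, pruning) is correct and that the
evolutionary phenomena are reachable on a well-posed network — not that
predictions transfer to any particular organism.

## Numerical choices

GLPK simplex on persistent problems (warm-started; a stale basis
triggers one retry from a standard basis), feasibility/bound tolerances
1e−9; flux-vs-bound phenotype tolerance 1e−6; genome-diff tolerance
1e−12. Lexicographic stages fix earlier objectives by pinning the
objective column (single-reaction objectives) or an extra row (the
total-flux stage) at the achieved value. The total-|flux| tie-break uses
a split-variable formulation (v = v⁺ − v⁻). Scaled-down study sizes in
tests and the acceptance script: population 500 (as published) but 2000
generations on the toy network — at population 100 the complete acid
switch is rarely reached within 2000 generations, so the published
population size is retained as load-bearing.

## Known limitations

- The two model-dependent checks (genome-scale model statistics and the
  published phase-2 citrate flux) require the supplementary SBML, which
  cannot be redistributed here; the loaders are exercised on generated
  SBML instead.
- `max_flux` on an infeasible polytope returns 0 with a warning rather
  than raising, matching its use inside the mutation operator.
- The dFBA terminates with a status flag on mid-run infeasibility;
  trajectories of drastically constrained mutants can therefore end
  before substrate depletion.
- Exchange-bound phase parameterisations are capacities (uptake ≤ cap),
  not forced equalities; networks whose observed fluxes are inputs
  should encode them as paired bounds.
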