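# Methods

## The question and the model

When an organism meets a new environment, its phenotype changes twice: an
immediate, mutation-free *plastic* response, and a subsequent *genetic*
response accumulated during adaptation. For any trait measured at the three
stages — adapted ancestor in the original environment (o), ancestor right
after the shift (p), evolved organism in the new environment (a) — define

```
PC = |L_p − L_o|    plastic change
GC = |L_a − L_p|    genetic change
TC = |L_a − L_o|    total change
```

A change is *appreciable* when it exceeds the effective cutoff
`max(θ·|L_o|, ε)` with θ = 0.2 by default. Traits with both changes
appreciable are *reinforcing* (same direction) or *reversing* (opposite
directions); the package also labels plastic-only, genetic-only, and
unchanged traits, subdivides reversions into restored / over-restored /
under-restored, and labels plasticity as facilitating (GC < TC) or hindering
(GC > TC). Per adaptation it reports the fractions C_RI, C_RV, C_FAC, C_HIN,
the restoration breakdown, q = fraction of traits with PC > TC, and exact
binomial tests at null probability ½.

The central quantitative law: whenever PC > TC, the genetic change must by
geometry reverse the plastic change. If a fraction q of traits is forced
this way and the rest split evenly, the expected ratio is

```
C_RI / C_RV = (1 − q) / (1 + q)
```

implemented as `expected_ratio`, and reproduced by simulation in the test
suite.

## Metabolic simulation

Flux traits come from constraint-based analysis of a metabolic network with
stoichiometric matrix S, flux bounds α ≤ v ≤ β, and a single biomass
objective c:

* **stage o** — FBA: maximize cᵀv s.t. Sv = 0, α ≤ v ≤ β in the original
  environment;
* **stage p** — MOMA: minimize ‖v − v_o‖² under the new environment's
  constraints (metabolic homeostasis immediately after the shift);
* **stage a** — FBA in the new environment, or alternatively MOMA-b:
  minimize ‖v − v_p‖² with the extra equality cᵀv = b at the FBA optimum b,
  which removes the LP-vs-QP solver asymmetry between stages.

Relative fitnesses f_p, f_a divide each stage's biomass rate by the stage-o
rate. An environment is *adaptable* when f_p > 10⁻⁴; below that the
organism is not expected to survive the shift. Environments are sets of
available carbon sources; each available source's exchange reaction gets an
uptake bound of 10 mmol·gDW⁻¹·h⁻¹ (the benchmark glucose-limited setting),
all other carbon uptakes are closed (secretion stays open — a modelling
choice recorded here because the alternative, closing secretion too, is
equally defensible; on the models tested it does not change any reported
statistic).

Traits are the *mutable* reactions: exchanges and enzyme-free
inter-compartment diffusion are excluded via a configurable predicate
(default: boundary reactions, plus gene-less multi-compartment transport).
The predicate is configurable because published reconstructions annotate
spontaneous transport inconsistently; the default reproduces the intent
(no dedicated enzyme ⇒ not independently mutable) rather than any one
model's bookkeeping.

### Numerical choices

* Global tolerance ε = 10⁻⁴: optimal solutions must satisfy ‖Sv‖∞ ≤ ε and
  the bounds within ε; flux values and differences below ε are treated as 0,
  and ε is also the absolute floor of the classification cutoff for fluxes
  (for expression data the floor is 0).
* FBA is solved with HiGHS's interior-point method (barrier-style); MOMA and
  MOMA-b with OSQP at eps_abs = eps_rel = 10⁻⁹ with solution polishing. On
  the analytic fixtures both agree with hand solutions to 10⁻⁶.
* MOMA's objective is strictly convex, so its optimum is unique; FBA optima
  can be degenerate. Degeneracy is accepted as-is; `shuffle_reaction_order`
  permutes the reaction columns so its effect on downstream statistics can
  be measured directly.
* MOMA-b with b above the FBA optimum is reported infeasible rather than
  clipped.

### Random mixed-carbon environments

For each environment and candidate source an availability probability g is
drawn from an exponential distribution with mean 0.1 (g > 1 truncated to 1,
a ~e⁻¹⁰ event) and presence is Bernoulli(g). Two draw modes exist because
the generative description is ambiguous: `per_source` redraws g for every
(environment, source) pair — the literal reading, implying a marginal
presence frequency E[min(g,1)] = (1 − e⁻¹⁰)/10 ≈ 0.09995 and hence ≈ 25.8
sources per environment — while `per_environment` shares one g across all
sources of an environment, giving the same mean but a strongly right-skewed
count distribution (mean well above median). Reported summary statistics of
mixed-carbon environments in the literature (mean 28, median 21) fit the
skewed mode better than the literal one; both are provided, neither is
asserted as canonical, and the default is `per_source`. Each environment
draws from its own seed substream, so extending an ensemble never reshuffles
earlier environments.

## Synthetic data

Three generators cover the test surface without external data:

* **Planted categories** (`gen_triplets`): L_o is log-normal; appreciable
  changes are planted at ≥ (0.2 + margin)·L_o and inappreciable ones at
  ≤ (0.2 − margin)·L_o with margin 0.1, so the ground truth is unambiguous
  at θ = 0.2 and survives the default multiplicative log-normal noise
  (sd 0.02, an optimistic but realistic replicate-averaged measurement
  error). Downward moves are capped at 0.45·L_o per step to keep expression
  positive.
* **Planted forcing fraction** (`gen_forced_reversion_triplets`): a fraction
  q of traits overshoot (PC > TC, reversal forced); the rest have PC < TC
  with the genetic direction chosen by a fair coin. This is the clean
  embodiment of "no other bias": C_RI/C_RV converges to (1 − q)/(1 + q) and
  removing PC > TC traits leaves an exactly balanced remainder.
* **Latent fitness coupling** (`gen_mechanism_triplets`): trait values are
  monotone (power-law) functions of the fitness trajectory 1 → f_p → f_a
  plus an independent displacement of the new optimum. Deep plastic fitness
  drops produce large stage-p excursions, hence high q and a strong
  reversion excess, and mean PC falls as f_p → 1. Note a known property:
  because trait responses are multiplicative while the classifier compares
  additive changes, the direction split among the PC ≤ TC remainder is not
  exactly symmetric in this generator; symmetric-null calibration therefore
  uses the planted-q generator.

What the synthetic data do **not** emulate: study-specific library-size or
batch effects, count discreteness at low expression, gene–gene correlation,
and partial adaptation at the end of an experiment. Passing tests therefore
demonstrate the correctness of the computation and the internal consistency
of the mechanism, not the biological result on any real dataset; the real
fluxome analysis requires the genome-scale model (see below) and the real
transcriptome analysis requires the original study matrices.

Toy metabolic networks (`gen_toy_model`) ship with their closed-form optima:
a linear chain (FBA = uptake × yield), a diamond with two parallel paths
(MOMA projection onto a reduced-uptake polytope stays on the reference
path), and a two-source network in which the carbon swap has closed-form
plastic and adapted fitnesses (with yields 1 and 0.5 and uptake 10:
f_p = 1/9, f_a = 1/2; the MOMA flux through the new path is
y₂B₀/(2 + y₂²) = 20/9).

## Transcriptome pipeline

Expression matrices are filtered (drop genes with any missing value,
configurable missing sentinels), rescaled by one scalar per dataset so grand
means agree (classification at θ·L_o cutoffs is provably invariant to this,
and the test suite asserts it), replicate-averaged by arithmetic mean on the
provided scale, and assembled into per-case (L_o, L_p, L_a) tables from a
YAML manifest mapping samples to stages — replicate-specific stage-a samples
may share stage-o/p samples across cases. A gene is growth-rate-independent
when its expression is not monotone across ordered chemostat growth rates;
by default ties within a monotone run still count as dependent (non-strict
convention, configurable, recorded in output metadata).

## Problem sizes and scope of the shipped runs

The default test suite and the acceptance script run entirely on generated
inputs: toy networks of 3–5 reactions, triplet sets of 1 811–20 000 traits,
40–200 seeded replicates for null calibration, 2 000–10 000 random
environments, and a 44-case bundle of 800 genes per case. These sizes put
Monte-Carlo error well inside the asserted intervals while keeping the whole
suite in seconds. The genome-scale study (258 carbon exchanges, 1 811 trait
reactions, 257 screening MOMA problems, ~50 adaptations) is implemented in
`plastevo.reproduce` and driven by `scripts/reproduce_iaf1260.py`; it needs
the iAF1260 SBML from BiGG supplied locally and roughly an hour of CPU, and
is therefore not part of the default suite.

## Known limitations

* FBA degeneracy means stage-o/a flux vectors are solver- and
  order-dependent on large models; the classification statistics are robust
  in aggregate (the shuffle utility quantifies this) but individual trait
  labels are not guaranteed stable.
* OSQP is a first-order method; for genome-scale MOMA the 10⁻⁹ tolerances
  with polishing are slow compared to commercial barrier solvers. The solver
  sits behind a narrow contract (status, fluxes, objective) and can be
  swapped.
* The diffusion/trait-exclusion predicate is a heuristic; on reconstructions
  other than the ones it was designed around, the trait list should be
  reviewed (and can be overridden per call).
* Multi-source environments give every available source the same uptake
  bound; no crowding or transport competition is modelled.
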