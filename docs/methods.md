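# Methods

## Model

`counselnet` represents a small pedigree as a discrete Bayesian network.
Per individual there are five nodes: genotype `G` (states `AA`, `AB`,
`BB`; `A` wild allele, `B` mutant), phenotype `P` (`signs`/`healthy`),
and three binary risk-factor roots `D`, `E`, `A` (diet, exercise, age;
states `T`/`F`). Optional test nodes `T` hang off genotypes.

Four CPT families are constructed:

1. **Founder genotype priors.** Uniform (1/3 each) by default — the
   no-information starting point — or Hardy–Weinberg
   ((1−q)², 2q(1−q), q²) when a population allele frequency q is
   trusted, or a point mass for a genotyped animal.
2. **Mendelian transmission.** With b(g) the probability that a parent
   of genotype g transmits `B` (0, ½, 1 for `AA`, `AB`, `BB`),
   P(BB) = b_s·b_d, P(AA) = (1−b_s)(1−b_d), P(AB) the remainder. This is
   symmetric in the parents and conserves expected allele dosage.
3. **Phenotype: leaky noisy-OR.** Each active cause fires an independent
   mechanism with its link probability; the leak p₀ stands for unmodeled
   causes; signs appear iff some mechanism fires, so
   P(signs|X_p) = 1 − (1−p₀)·∏_{i∈X_p}(1−p_i). The leak multiplies into
   every row (the all-absent row is exactly (p₀, 1−p₀)). The genetic
   cause is active for `BB` under the default recessive model
   (`dominant` activates `AB` too). Probabilities 0 and 1 are legal;
   they give the deterministic limit used by several counseling
   queries.
4. **Test nodes.** P(positive|BB) = sensitivity,
   P(positive|AA) = 1 − specificity. The heterozygote is ambiguous in
   principle and therefore explicit: under the default `genotype_bb`
   semantics the assay targets the BB genotype and `AB` behaves as a
   negative animal; under `allele` semantics `AB` is a true positive.

## Priors and their propagation

Leak and link probabilities are uncertain; each carries a Beta prior.
Elicitation supports three spellings: `{mean, sd}` (exact moment
matching, rejected when sd² ≥ mean(1−mean)), `{mean, nu}` with
concentration ν = α + β, and raw `{alpha, beta}`. The package default is
ν = 9 for every prior: at a 10% mean this gives sd 9.49%, the right
"weakly informed" spread for link probabilities, and a single rule keeps
the seven packaged groups comparable. A bare float is accepted as a
degenerate (point-mass) prior. The packaged groups sweep non-genetic
link means over 10/30/50% and genetic link means over 10/50/90% with the
leak mean fixed at 1%.

`summarize_risk` propagates the priors through the gate by Monte Carlo:
per draw, sample the leak and the links of the active causes and
evaluate the risk formula. Two draw modes exist because the three
non-genetic factors share one prior: `independent` (default — each
cause is its own mechanism and gets its own draw) and `shared_ng` (one
draw reused across the non-genetic causes within a realization); the two
coincide exactly for degenerate priors. Draws use common random numbers
across activity levels — one fixed (n_draws × 3) matrix of non-genetic
draws per seed, level k consuming the first k columns — so the risk
ordering in the summary table holds draw by draw, not merely in
expectation. Each sampled quantity gets its own stream, split from the
root seed with `SeedSequence.spawn`, so adding a query never perturbs
another query's draws.

Exact published summary-table cells are **not** reproduction targets:
they came from unpublished Monte-Carlo code (draw count, seed and Beta
shapes unstated; the printed standard deviations imply per-prior
concentrations — e.g. ~24 at mean 90%, uniform at mean 50% — and the
printed means for identical prior settings disagree across columns and
sit below the analytic expectation 1−(1−m₀)∏(1−mᵢ)). What the package
asserts instead is the table's full ordering (risk increases with the
number of active non-genetic factors and with the genetic factor) and
agreement of independent-mode means with the closed form within Monte-
Carlo error.

## CPT construction modes

`point_mean` (default) plugs prior means into the gate: deterministic,
fast, and what hand-checkable counseling answers assume. `mc_mean`
averages the full CPT over parameter draws. A third route,
`posterior_over_draws`, recomputes the *posterior* per draw and averages
those; it is exposed as experimental because several published backward
numbers can only arise under some such averaging (with any point-valued
gate, non-genetic factors cancel from the healthy-parent likelihood
ratio), but the exact scheme behind them is undocumented.

## Inference

Production inference is variable elimination over named-state factors;
the elimination order is min-degree with lexicographic tie-breaks —
reproducibility matters more than speed on networks this small (a trio
is 15 nodes). The independent oracle is full-joint enumeration (factor
product over the entire scope, no elimination), capped at 24 nodes; the
suite checks VE ≡ enumeration to 1e-10 per state on 1,000 seeded random
networks and on random pedigree scenarios. Evidence with zero joint
probability (e.g. an `AA` sire with a `BB` offspring) raises an explicit
inconsistent-evidence error rather than normalizing an arbitrary vector.

## Decision layer

Utilities attach to the offspring genotype; the expected utility of an
alternative (an evidence assignment describing a mating) is
Σ_g P(G_offspring = g | evidence)·u(g). Expected utility is affinely
equivariant in the utilities and bounded by their range, so
recommendations are invariant to positive affine rescaling. Exact ties
are broken lexicographically by alternative label and flagged.

## Scenarios and synthetic inputs

The packaged scenario set (17 fixtures) covers the seven prior groups,
the forward risk grid, forward and backward trio queries including
deterministic-limit and Hardy–Weinberg variants, a perfect-test variant,
and two utility settings. Each records its expected value (where one
exists), a provenance tag, and *which parameterization reproduces it* —
the headline forward posteriors (56.25/37.5/6.25%, 0/50/50%) hold in the
deterministic limit, not at the stated prior means. Fixture definitions
are frozen by SHA-256 digests under test. Five published figures (6.42%,
66.5%, a 100% parent-BB probability, 93.69 and 74.88) are registered as
irreproducible — no stated parameter set yields them (e.g. 2/3 is the
maximum parent-BB probability reachable from offspring-only evidence
under uniform priors; the deterministic limit gives 93.75 and 75.00 for
the utilities) — and the scenario runner prints them as "not
reproduced" rows with the reason, never dropping them silently.

Random generators provide property-test inputs: `random_scenario` builds
3–5 individual pedigrees with random feasible priors and evidence drawn
by ancestral sampling (hence guaranteed consistent); `random_network`
builds generic 4–12 node discrete networks for oracle sweeps. Both are
seed-deterministic. These synthetic inputs exercise the machinery, not
canine epidemiology: they say nothing about real DM penetrance, and
passing tests certify the probabilistic computations, not the clinical
priors a practitioner should use.

## Numerical choices and limitations

- CPT rows are validated to sum to 1 within 1e-12; posteriors match the
  oracle within 1e-10; the empty-active-set risk returns the leak
  exactly (no 1−(1−p₀) round trip).
- Risk-factor roots default to P(T) = 0.5; counseling queries always
  instantiate them as evidence, so this prior only matters for
  unqueried relatives. It is configurable.
- Percentages are parsed ("1%") and printed (2 decimals) only at the
  interface; all internal values are full-precision fractions.
- Single autosomal diallelic locus; binary risk factors (age is "in the
  highest-susceptibility range" yes/no); no modifier loci, mutation,
  X-linkage, structure learning, or approximate inference. Feedback
  loops are structurally impossible (nodes are inserted parents-first
  and the DAG is re-validated).
- The monogamous-pair pedigree builder requires two distinct parents per
  child; half-sib structures are expressible by adding relatives that
  share one parent.

## Problem sizes

Default suite sizes: 10,000 Monte-Carlo draws for risk summaries, 1,000
random networks for the oracle sweep, 10,000 random gate specs for the
mechanism-enumeration check — chosen so Monte-Carlo error (≈4 standard
errors) cleanly separates the orderings under test; the whole suite runs
in a few seconds on one CPU.
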